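import itertools
import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gyrogait.agreement import (
    Z95,
    build_report,
    ccc,
    cia,
    compare_models,
    error_metrics,
    fit_steps_lmm,
    inter_unit_reliability,
    loa_repeated,
    tdi,
    tdi_normal,
)


# ---------------------------------------------------------------------------
# error metrics
# ---------------------------------------------------------------------------

def test_error_metrics_symmetric_example():
    m = error_metrics([110, 90], [100, 100])
    assert m.mape == pytest.approx(10.0)
    assert m.mae == pytest.approx(10.0)
    assert m.rmse == pytest.approx(10.0)


def test_error_metrics_perfect():
    m = error_metrics([3, 4, 5], [3, 4, 5])
    assert (m.mae, m.rmse, m.mape) == (0.0, 0.0, 0.0)


def test_error_metrics_hand_example():
    m = error_metrics([3, 5], [1, 1])
    assert m.mae == pytest.approx(3.0)
    assert m.rmse == pytest.approx(math.sqrt(10), abs=1e-12)
    assert m.mape == pytest.approx(300.0)


def test_error_metrics_zero_reference_rejected():
    with pytest.raises(ValueError, match="zero"):
        error_metrics([1.0], [0.0])


# ---------------------------------------------------------------------------
# CCC
# ---------------------------------------------------------------------------

def test_ccc_identity():
    r = ccc([1, 2, 3, 4], [1, 2, 3, 4])
    assert r.estimate == pytest.approx(1.0)


def test_ccc_perfect_reversal():
    r = ccc([-1, 0, 1], [1, 0, -1])
    assert r.estimate == pytest.approx(-1.0)


def test_ccc_hand_example():
    r = ccc([1, 2, 3, 4], [1.1, 2.0, 2.9, 4.2])
    assert r.estimate == pytest.approx(0.9942, abs=0.0005)
    assert r.ci_low < r.estimate < r.ci_high


def test_ccc_zero_variance_rejected():
    with pytest.raises(ValueError, match="variance"):
        ccc([2, 2, 2], [2, 2, 2])


@given(st.integers(0, 10_000))
@settings(max_examples=30, deadline=None)
def test_ccc_bounded_by_pearson(seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(0, 1, 20)
    y = 0.5 * x + rng.normal(0.3, 0.8, 20)
    est = ccc(x, y).estimate
    r = np.corrcoef(x, y)[0, 1]
    assert abs(est) <= abs(r) + 1e-12


def test_ccc_equals_pearson_when_moments_match():
    rng = np.random.default_rng(5)
    x = rng.normal(0, 1, 2000)
    y = np.roll(x, 1)  # same mean and variance exactly
    est = ccc(x, y).estimate
    r = float(np.corrcoef(x, y)[0, 1])
    assert est == pytest.approx(r, abs=1e-12)


# ---------------------------------------------------------------------------
# repeated-measures limits of agreement
# ---------------------------------------------------------------------------

def test_loa_constant_differences():
    df = pd.DataFrame({"subject": ["a", "a", "b", "b"], "diff": [2.0] * 4})
    r = loa_repeated(df, n_boot=0)
    assert r.bias == pytest.approx(2.0, abs=1e-8)
    assert r.upper - r.lower == pytest.approx(0.0, abs=1e-6)


def test_loa_single_replicate_reduces_to_classical():
    rng = np.random.default_rng(0)
    d = rng.normal(1.0, 2.0, 12)
    df = pd.DataFrame({"subject": [f"s{i}" for i in range(12)], "diff": d})
    r = loa_repeated(df, n_boot=0)
    assert r.method == "classical"
    sd = d.std(ddof=1)
    assert r.bias == pytest.approx(d.mean(), abs=1e-12)
    assert r.upper == pytest.approx(d.mean() + Z95 * sd, abs=1e-12)
    assert r.lower == pytest.approx(d.mean() - Z95 * sd, abs=1e-12)


def test_loa_single_subject_warns():
    df = pd.DataFrame({"subject": ["a"] * 5, "diff": [1.0, 2.0, 3.0, 2.0, 1.5]})
    with pytest.warns(RuntimeWarning, match="single-subject"):
        r = loa_repeated(df, n_boot=0)
    assert r.method == "classical"


def _mom_oneway(df):
    """Balanced one-way ANOVA method-of-moments oracle."""
    groups = [g["diff"].to_numpy() for _, g in df.groupby("subject")]
    k = len(groups)
    n = len(groups[0])
    grand = np.concatenate(groups).mean()
    msb = n * sum((g.mean() - grand) ** 2 for g in groups) / (k - 1)
    msw = sum(((g - g.mean()) ** 2).sum() for g in groups) / (k * (n - 1))
    s2a = max((msb - msw) / n, 0.0)
    return grand, s2a, msw


def test_loa_matches_anova_oracle():
    rng = np.random.default_rng(42)
    subj_eff = {"a": 1.0, "b": -1.0, "c": 0.5, "d": -0.5}
    rows = [
        (s, 1.5 + e + rng.normal(0, 1.0))
        for s, e in subj_eff.items()
        for _ in range(6)
    ]
    df = pd.DataFrame(rows, columns=["subject", "diff"])
    r = loa_repeated(df, n_boot=0)
    mu, s2a, s2e = _mom_oneway(df)
    assert r.bias == pytest.approx(mu, abs=1e-4)
    assert r.sigma_subject**2 == pytest.approx(s2a, abs=0.05 * max(s2a, 0.1))
    assert r.sigma_residual**2 == pytest.approx(s2e, rel=0.05)


def test_loa_bootstrap_seed_reproducible():
    rng = np.random.default_rng(3)
    df = pd.DataFrame({
        "subject": np.repeat([f"s{i}" for i in range(6)], 5),
        "diff": rng.normal(1.0, 2.0, 30),
    })
    a = loa_repeated(df, n_boot=50, seed=9)
    b = loa_repeated(df, n_boot=50, seed=9)
    assert a.bias_ci == b.bias_ci and a.upper_ci == b.upper_ci


# ---------------------------------------------------------------------------
# TDI
# ---------------------------------------------------------------------------

def test_tdi_standard_normal():
    assert tdi_normal(0.0, 1.0, 0.95) == pytest.approx(Z95, abs=1e-9)


def test_tdi_shifted_normal():
    assert tdi_normal(1.0, 1.0, 0.95) == pytest.approx(2.65, abs=0.01)


def test_tdi_scale_equivariance():
    for k in (0.5, 2.0, 7.3):
        assert tdi_normal(0.0, k, 0.9) == pytest.approx(
            k * tdi_normal(0.0, 1.0, 0.9), rel=1e-9
        )


def test_tdi_monte_carlo_containment():
    rng = np.random.default_rng(0)
    for mu, sigma in [(0.0, 1.0), (1.0, 1.0), (-2.0, 3.0)]:
        kappa = tdi_normal(mu, sigma, 0.95)
        draws = rng.normal(mu, sigma, 1_000_000)
        contained = np.mean(np.abs(draws) <= kappa)
        assert contained == pytest.approx(0.95, abs=0.01)


def test_tdi_from_sample():
    rng = np.random.default_rng(1)
    d = rng.normal(0.5, 2.0, 5000)
    r = tdi(d, p=0.95, n_boot=0)
    assert r.estimate == pytest.approx(tdi_normal(0.5, 2.0, 0.95), rel=0.05)


def test_tdi_validation():
    with pytest.raises(ValueError):
        tdi_normal(0.0, 0.0, 0.95)
    with pytest.raises(ValueError):
        tdi_normal(0.0, 1.0, 1.5)
    with pytest.raises(ValueError):
        tdi([1.0, 2.0], 0.95)


# ---------------------------------------------------------------------------
# CIA
# ---------------------------------------------------------------------------

def _cia_oracle(df):
    """Exhaustive MSD-ratio oracle over all replicate pairs."""
    num = den = 0.0
    for _, cell in df.groupby("subject"):
        devs = sorted(cell["device"].unique())
        a = cell.loc[cell["device"] == devs[0], "value"].to_numpy()
        b = cell.loc[cell["device"] == devs[1], "value"].to_numpy()
        wa = [  # noqa: F841 - readable enumeration
            (x - y) ** 2 for x, y in itertools.combinations(a, 2)
        ]
        wb = [(x - y) ** 2 for x, y in itertools.combinations(b, 2)]
        msd_a = 2 * sum(wa) / (len(a) * (len(a) - 1))
        msd_b = 2 * sum(wb) / (len(b) * (len(b) - 1))
        msd_ab = sum((x - y) ** 2 for x in a for y in b) / (len(a) * len(b))
        num += 0.5 * (msd_a + msd_b)
        den += msd_ab
    return num / den


def test_cia_toy_table_matches_exhaustive_oracle():
    rng = np.random.default_rng(7)
    rows = []
    for s in ("s1", "s2", "s3"):
        for d in ("u1", "u2"):
            for lap in range(4):
                rows.append((s, d, lap, rng.normal(10 if s == "s2" else 5, 1.5)))
    df = pd.DataFrame(rows, columns=["subject", "device", "lap", "value"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        r = cia(df, n_boot=0)
    assert r.estimate == pytest.approx(_cia_oracle(df), abs=1e-12)


def test_cia_interchangeable_devices_near_one():
    rng = np.random.default_rng(0)
    rows = []
    for s in range(25):
        m = rng.normal(0, 5)
        for d in ("u1", "u2"):
            for lap in range(12):
                rows.append((f"s{s}", d, lap, m + rng.normal(0, 1)))
    df = pd.DataFrame(rows, columns=["subject", "device", "lap", "value"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        r = cia(df, n_boot=0)
    assert r.estimate == pytest.approx(1.0, abs=0.1)


def test_cia_large_systematic_shift_near_zero():
    rng = np.random.default_rng(0)
    rows = []
    for s in range(5):
        for lap in range(5):
            rows.append((f"s{s}", "u1", lap, rng.normal(0, 0.1)))
            rows.append((f"s{s}", "u2", lap, 100 + rng.normal(0, 0.1)))
    df = pd.DataFrame(rows, columns=["subject", "device", "lap", "value"])
    r = cia(df, n_boot=0)
    assert r.estimate < 0.01


def test_cia_requires_replicates():
    df = pd.DataFrame({
        "subject": ["a", "a"], "device": ["u1", "u2"], "lap": [0, 0],
        "value": [1.0, 2.0],
    })
    with pytest.raises(ValueError):
        cia(df, n_boot=0)


# ---------------------------------------------------------------------------
# variance-components model
# ---------------------------------------------------------------------------

def simulate_steps_table(seed, vc, n_subj=15, n_act=6, n_rep=10, mu=100.0,
                         dev_eff=1.3):
    rng = np.random.default_rng(seed)
    a = rng.normal(0, math.sqrt(vc["subject"]), n_subj)
    g = rng.normal(0, math.sqrt(vc["activity"]), n_act)
    ag = rng.normal(0, math.sqrt(vc["subject_activity"]), (n_subj, n_act))
    ab = rng.normal(0, math.sqrt(vc["subject_device"]), (n_subj, 2))
    rows = []
    for i in range(n_subj):
        for l in range(n_act):
            for j in range(2):
                eps = rng.normal(0, math.sqrt(vc["residual"]), n_rep)
                for t in range(n_rep):
                    rows.append((
                        f"s{i:02d}", f"a{l}", t, f"d{j}",
                        mu + dev_eff * j + a[i] + g[l] + ag[i, l] + ab[i, j]
                        + eps[t],
                    ))
    return pd.DataFrame(rows, columns=["subject", "activity", "lap", "device",
                                       "value"])


SMALL_VC = {"subject": 9.0, "activity": 25.0, "subject_activity": 4.0,
            "subject_device": 0.5, "residual": 2.0}


def test_lmm_single_fit_recovers_components_roughly():
    df = simulate_steps_table(0, SMALL_VC, n_subj=10, n_act=4, n_rep=6)
    fit = fit_steps_lmm(df, "final")
    assert fit.converged
    assert set(fit.variance_components) == {
        "subject", "activity", "subject_activity", "subject_device", "residual"
    }
    assert fit.variance_components["residual"] == pytest.approx(
        SMALL_VC["residual"], rel=0.3
    )
    assert all(v >= 0 for v in fit.variance_components.values())
    assert math.isfinite(fit.aic) and math.isfinite(fit.bic)


def test_lmm_zero_noise_all_components_vanish():
    rows = [
        (f"s{i}", f"a{l}", t, d, 50.0)
        for i in range(4) for l in range(3) for d in ("d0", "d1")
        for t in range(3)
    ]
    df = pd.DataFrame(rows, columns=["subject", "activity", "lap", "device",
                                     "value"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = fit_steps_lmm(df, "final")
    assert all(abs(v) < 1e-6 for v in fit.variance_components.values())


def test_lmm_validates_design():
    df = pd.DataFrame({
        "subject": ["a"] * 4, "activity": ["x", "x", "y", "y"],
        "lap": [0, 0, 0, 0], "device": ["d0", "d1", "d0", "d1"],
        "value": [1.0, 2.0, 3.0, 4.0],
    })
    with pytest.raises(ValueError, match=">= 2 subjects"):
        fit_steps_lmm(df)
    with pytest.raises(ValueError, match="unknown variant"):
        fit_steps_lmm(df, "bogus")


def test_compare_models_prefers_smaller_under_null():
    # device_activity component is absent from the truth: AIC should prefer
    # the model without it in the clear majority of null repeats
    wins = 0
    reps = 12
    for seed in range(reps):
        df = simulate_steps_table(seed, SMALL_VC, n_subj=8, n_act=4, n_rep=4)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ranked = compare_models(df, variants=("final", "full"))
        if ranked[0].variant == "final":
            wins += 1
    assert wins >= reps * 0.75


# ---------------------------------------------------------------------------
# inter-unit reliability
# ---------------------------------------------------------------------------

def _unit_table(values1, values2, subjects=None):
    n = len(values1)
    subjects = subjects or [f"s{i % 4}" for i in range(n)]
    rows = []
    for i, (v1, v2) in enumerate(zip(values1, values2)):
        rows.append((subjects[i], i, "u1", v1))
        rows.append((subjects[i], i, "u2", v2))
    return pd.DataFrame(rows, columns=["subject", "lap", "device", "value"])


def test_inter_unit_identical():
    vals = [100.0, 110.0, 95.0, 105.0, 99.0, 101.0, 98.0, 102.0]
    r = inter_unit_reliability(_unit_table(vals, vals), n_boot=0)
    assert r.mean_difference == 0.0
    assert r.cv == 0.0


def test_inter_unit_constant_shift():
    v1 = [100.0] * 8
    v2 = [102.0] * 8
    r = inter_unit_reliability(_unit_table(v1, v2), n_boot=0)
    assert r.mean_difference == pytest.approx(2.0)
    assert r.loa.upper - r.loa.lower == pytest.approx(0.0, abs=1e-6)
    assert r.cv == pytest.approx(0.0, abs=1e-12)


def test_inter_unit_constructed_normal():
    rng = np.random.default_rng(4)
    v1 = rng.normal(100, 5, 30)
    v2 = v1 + rng.normal(1.0, 1.5, 30)
    subjects = [f"s{i % 6}" for i in range(30)]
    r = inter_unit_reliability(_unit_table(v1, v2, subjects), n_boot=0)
    assert r.mean_difference == pytest.approx(1.0, abs=0.6)
    half = (r.loa.upper - r.loa.lower) / 2
    assert half == pytest.approx(Z95 * 1.5, rel=0.35)
    assert r.n_pairs == 30


def test_inter_unit_drops_unpaired_with_warning():
    df = _unit_table([100.0, 101.0, 99.0, 100.0], [101.0, 102.0, 100.0, 101.0])
    df = df.drop(index=df.index[-1])  # orphan one row
    with pytest.warns(RuntimeWarning, match="unpaired"):
        r = inter_unit_reliability(df, n_boot=0)
    assert r.n_pairs == 3


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------

def _paired_tables(seed=0, n_subj=6, n_lap=5):
    rng = np.random.default_rng(seed)
    est, ref = [], []
    for s in range(n_subj):
        base = rng.normal(40, 6)
        for act in ("walking", "sprinting"):
            for lap in range(n_lap):
                true = base + rng.normal(0, 3)
                ref.append((f"s{s}", act, lap, true))
                est.append((f"s{s}", act, lap, true + rng.normal(1.0, 2.0)))
    cols = ["subject", "activity", "lap", "value"]
    return pd.DataFrame(est, columns=cols), pd.DataFrame(ref, columns=cols)


def test_build_report_structure():
    est, ref = _paired_tables()
    rep = build_report(est, ref, n_boot=25, seed=1)
    d = rep.to_dict()
    assert {"mae", "rmse", "mape_percent", "ccc", "loa", "tdi", "cia"} <= set(
        d["overall"]
    )
    assert set(d["by_activity"]) == {"walking", "sprinting"}
    assert set(d["bland_altman"]) == {"walking", "sprinting"}
    loa = d["overall"]["loa"]
    assert loa["lower"] <= loa["bias"] <= loa["upper"]
    assert -1 <= d["overall"]["ccc"]["estimate"] <= 1
    assert d["overall"]["tdi"]["estimate"] >= 0


def test_build_report_requires_overlap():
    est, ref = _paired_tables()
    ref2 = ref.copy()
    ref2["subject"] = "zz_" + ref2["subject"]
    with pytest.raises(ValueError, match="in common"):
        build_report(est, ref2, n_boot=0)
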