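"""Method-agreement statistics for paired step-count / distance tables.

The central data structure is a long-format :class:`pandas.DataFrame` with
columns ``subject``, ``activity``, ``lap``, ``method`` (or ``device``) and
``value`` — one row per measurement.  Everything here treats *subjects* as
the independent sampling units: confidence intervals are produced by a
seeded cluster bootstrap that resamples subjects with replacement.

Implemented estimators:

* :func:`error_metrics` - MAE / RMSE / MAPE;
* :func:`ccc` - Lin's concordance correlation coefficient with the
  asymptotic z-transform confidence interval;
* :func:`loa_repeated` - repeated-measures Bland-Altman limits of
  agreement from a random-intercept model on paired differences
  (``d_it = mu + a_i + e_it``), collapsing to the classical Bland-Altman
  interval when each subject contributes a single difference;
* :func:`tdi` - total deviation index under a normal model for the
  differences, solved numerically;
* :func:`cia` - coefficient of individual agreement: mean within-device
  mean squared deviation over between-device mean squared deviation,
  aggregated over subject(-activity) cells;
* :func:`fit_steps_lmm` / :func:`compare_models` - REML variance-component
  fits of the step-count model (random subject, activity and their
  interactions; fixed device effect) ranked by AIC then BIC;
* :func:`inter_unit_reliability` - mean difference, repeated-measures LoA
  and coefficient of variation between two units worn simultaneously.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.regression.mixed_linear_model import MixedLM

__all__ = [
    "error_metrics",
    "ccc",
    "loa_repeated",
    "tdi",
    "tdi_normal",
    "cia",
    "fit_steps_lmm",
    "compare_models",
    "inter_unit_reliability",
    "LMMFit",
    "AgreementReport",
    "build_report",
]

Z95 = 1.959963984540054  # standard normal 97.5% quantile


def validate_paired_table(
    df: pd.DataFrame, group_col: str, required: tuple[str, ...]
) -> None:
    """Check the at-most-one-value-per-cell invariant of a paired table."""
    missing = set(required) - set(df.columns)
    if missing:
        raise ValueError(f"paired table missing columns: {sorted(missing)}")
    if "lap" not in df.columns:
        return  # no replicate identifier: duplicates are indistinguishable
    keys = [c for c in ("subject", "activity", "lap", group_col) if c in df.columns]
    if df.duplicated(subset=keys).any():
        raise ValueError(f"duplicate measurements for the same {tuple(keys)} cell")


# ---------------------------------------------------------------------------
# simple error metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ErrorMetrics:
    mae: float
    rmse: float
    mape: float  # percent


def error_metrics(estimated, reference) -> ErrorMetrics:
    """MAE, RMSE and MAPE (percent) of estimates against references."""
    e = np.asarray(estimated, dtype=float)
    r = np.asarray(reference, dtype=float)
    if e.shape != r.shape or e.size < 1:
        raise ValueError("estimated and reference must have equal length >= 1")
    err = e - r
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    if np.any(r == 0):
        raise ValueError("MAPE undefined: reference contains zeros")
    mape = float(100.0 * np.mean(np.abs(err) / np.abs(r)))
    return ErrorMetrics(mae=mae, rmse=rmse, mape=mape)


# ---------------------------------------------------------------------------
# Lin's concordance correlation coefficient
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CCCResult:
    estimate: float
    ci_low: float
    ci_high: float


def ccc(x, y, alpha: float = 0.05) -> CCCResult:
    """Lin's CCC with the asymptotic z-transform confidence interval.

    Uses population (1/n) moments:
    ``ccc = 2 s_xy / (s_x^2 + s_y^2 + (mean_x - mean_y)^2)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if y.size != n or n < 3:
        raise ValueError("ccc requires two equal-length sequences of length >= 3")
    mx, my = x.mean(), y.mean()
    sx2 = float(np.var(x))
    sy2 = float(np.var(y))
    sxy = float(np.mean((x - mx) * (y - my)))
    denom = sx2 + sy2 + (mx - my) ** 2
    if denom == 0:
        raise ValueError("ccc undefined: zero total variance")
    est = 2.0 * sxy / denom

    zq = stats.norm.ppf(1 - alpha / 2)
    if sx2 == 0 or sy2 == 0 or abs(est) >= 1.0:
        return CCCResult(est, est, est)
    r = sxy / math.sqrt(sx2 * sy2)
    u = (mx - my) / (sx2 * sy2) ** 0.25
    c2 = est**2
    se_z2 = (
        (1 - r**2) * c2 / ((1 - c2) * r**2)
        + 2 * est**3 * (1 - est) * u**2 / (r * (1 - c2) ** 2)
        - est**4 * u**4 / (2 * r**2 * (1 - c2) ** 2)
    ) / (n - 2)
    se_z = math.sqrt(max(se_z2, 0.0))
    z = math.atanh(est)
    return CCCResult(est, math.tanh(z - zq * se_z), math.tanh(z + zq * se_z))


# ---------------------------------------------------------------------------
# cluster bootstrap (subjects are the independent units)
# ---------------------------------------------------------------------------

def _cluster_bootstrap(
    df: pd.DataFrame,
    stat_fn,
    n_boot: int,
    seed: int | None,
    subject_col: str = "subject",
):
    """Percentile bootstrap resampling subjects with replacement.

    ``stat_fn`` maps a resampled frame to a 1-D array of statistics;
    returns an ``(n_stats, 2)`` array of (low, high) 95% bounds, or None
    when ``n_boot`` is 0.
    """
    if n_boot <= 0:
        return None
    rng = np.random.default_rng(seed)
    subjects = df[subject_col].unique()
    groups = {s: g for s, g in df.groupby(subject_col, sort=False)}
    draws = []
    for _ in range(n_boot):
        picked = rng.choice(subjects, size=subjects.size, replace=True)
        parts = []
        for j, s in enumerate(picked):
            g = groups[s].copy()
            g[subject_col] = f"boot{j}"  # resampled clusters stay distinct
            parts.append(g)
        sample = pd.concat(parts, ignore_index=True)
        try:
            draws.append(np.atleast_1d(stat_fn(sample)))
        except (ValueError, np.linalg.LinAlgError):
            continue
    if not draws:
        return None
    draws = np.vstack(draws)
    return np.stack(
        [np.percentile(draws, 2.5, axis=0), np.percentile(draws, 97.5, axis=0)],
        axis=1,
    )


# ---------------------------------------------------------------------------
# repeated-measures limits of agreement
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LoAResult:
    bias: float
    lower: float
    upper: float
    sigma_subject: float
    sigma_residual: float
    bias_ci: tuple[float, float] | None = None
    lower_ci: tuple[float, float] | None = None
    upper_ci: tuple[float, float] | None = None
    method: str = "lmm"  # or "classical"


def _loa_point(df: pd.DataFrame) -> tuple[float, float, float]:
    """(bias, sigma_subject, sigma_residual) for per-subject differences."""
    d = df["diff"].to_numpy(dtype=float)
    counts = df.groupby("subject")["diff"].count()
    if len(counts) < 2 or counts.max() < 2:
        # degenerate design: classical Bland-Altman
        return float(d.mean()), 0.0, float(d.std(ddof=1)) if d.size > 1 else 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM(d, np.ones((d.size, 1)), groups=df["subject"].to_numpy())
        res = model.fit(reml=True)
    mu = float(np.asarray(res.fe_params)[0])
    sa = math.sqrt(max(float(np.asarray(res.cov_re)[0, 0]), 0.0))
    se = math.sqrt(max(float(res.scale), 0.0))
    return mu, sa, se


def loa_repeated(
    differences: pd.DataFrame,
    n_boot: int = 2000,
    seed: int | None = None,
) -> LoAResult:
    """Repeated-measures limits of agreement for paired differences.

    ``differences`` needs columns ``subject`` and ``diff`` (one row per
    replicate).  Fits ``d_it = mu + a_i + e_it`` by REML and reports
    ``LoA = mu +- 1.96 * sqrt(sigma_a^2 + sigma_e^2)``; with a single
    subject, or a single replicate everywhere, it falls back to the
    classical Bland-Altman interval (with a warning in the first case).
    Confidence intervals come from a seeded cluster bootstrap.
    """
    validate_paired_table(differences, "subject", ("subject", "diff"))
    counts = differences.groupby("subject")["diff"].count()
    method = "lmm"
    if len(counts) < 2:
        warnings.warn(
            "single-subject design: falling back to classical Bland-Altman",
            RuntimeWarning,
            stacklevel=2,
        )
        method = "classical"
    elif counts.max() < 2:
        method = "classical"

    mu, sa, se = _loa_point(differences)
    half = Z95 * math.sqrt(sa**2 + se**2)

    def stat(sample: pd.DataFrame) -> np.ndarray:
        m, a, e = _loa_point(sample)
        h = Z95 * math.sqrt(a**2 + e**2)
        return np.array([m, m - h, m + h])

    ci = _cluster_bootstrap(differences, stat, n_boot, seed) if method == "lmm" else None
    return LoAResult(
        bias=mu,
        lower=mu - half,
        upper=mu + half,
        sigma_subject=sa,
        sigma_residual=se,
        bias_ci=tuple(ci[0]) if ci is not None else None,
        lower_ci=tuple(ci[1]) if ci is not None else None,
        upper_ci=tuple(ci[2]) if ci is not None else None,
        method=method,
    )


# ---------------------------------------------------------------------------
# total deviation index
# ---------------------------------------------------------------------------

def tdi_normal(mu: float, sigma: float, p: float = 0.95) -> float:
    """Boundary kappa with P(|D| <= kappa) = p for D ~ N(mu, sigma^2)."""
    if not (0 < p < 1):
        raise ValueError("p must lie in (0, 1)")
    if sigma <= 0:
        raise ValueError("sigma must be positive")

    def contain(k: float) -> float:
        return stats.norm.cdf((k - mu) / sigma) - stats.norm.cdf((-k - mu) / sigma) - p

    hi = abs(mu) + 10.0 * sigma
    return float(optimize.brentq(contain, 0.0, hi, xtol=1e-12))


@dataclass(frozen=True)
class TDIResult:
    estimate: float
    ci_low: float | None
    ci_high: float | None
    p: float


def tdi(
    differences,
    p: float = 0.95,
    n_boot: int = 1000,
    seed: int | None = None,
    subjects=None,
) -> TDIResult:
    """Total deviation index of a sample of differences.

    Estimates ``mu`` and ``sigma`` from the sample (ddof=1) and solves the
    normal containment equation numerically.  The bootstrap CI resamples
    subjects when ``subjects`` labels are given, otherwise individual
    differences.
    """
    d = np.asarray(differences, dtype=float)
    if d.size < 3:
        raise ValueError("tdi requires at least 3 differences")
    est = tdi_normal(float(d.mean()), float(d.std(ddof=1)), p)
    if n_boot <= 0:
        return TDIResult(est, None, None, p)
    frame = pd.DataFrame(
        {
            "subject": np.asarray(subjects) if subjects is not None else np.arange(d.size),
            "diff": d,
        }
    )

    def stat(sample: pd.DataFrame) -> float:
        v = sample["diff"].to_numpy()
        return tdi_normal(float(v.mean()), float(v.std(ddof=1)), p)

    ci = _cluster_bootstrap(frame, stat, n_boot, seed)
    if ci is None:
        return TDIResult(est, None, None, p)
    return TDIResult(est, float(ci[0, 0]), float(ci[0, 1]), p)


# ---------------------------------------------------------------------------
# coefficient of individual agreement
# ---------------------------------------------------------------------------

def _msd_within(values: np.ndarray) -> float:
    """Mean squared deviation over all unordered replicate pairs."""
    n = values.size
    if n < 2:
        raise ValueError("within-device MSD needs >= 2 replicates")
    diffs = values[:, None] - values[None, :]
    return float(np.sum(diffs**2) / (n * (n - 1)))


def _msd_between(a: np.ndarray, b: np.ndarray) -> float:
    """Mean squared deviation over all cross-device pairs."""
    diffs = a[:, None] - b[None, :]
    return float(np.mean(diffs**2))


def _cia_point(df: pd.DataFrame) -> float:
    cell_cols = ["subject"] + (["activity"] if "activity" in df.columns else [])
    num = 0.0
    den = 0.0
    n_cells = 0
    for _, cell in df.groupby(cell_cols, sort=False):
        devices = cell["device"].unique()
        if devices.size != 2:
            raise ValueError("cia requires exactly 2 devices per cell")
        a = cell.loc[cell["device"] == devices[0], "value"].to_numpy(dtype=float)
        b = cell.loc[cell["device"] == devices[1], "value"].to_numpy(dtype=float)
        num += 0.5 * (_msd_within(a) + _msd_within(b))
        den += _msd_between(a, b)
        n_cells += 1
    if n_cells == 0 or den == 0:
        raise ValueError("cia undefined for this table")
    return num / den


@dataclass(frozen=True)
class CIAResult:
    estimate: float
    ci_low: float | None
    ci_high: float | None


def cia(
    table: pd.DataFrame, n_boot: int = 1000, seed: int | None = None
) -> CIAResult:
    """Coefficient of individual agreement from a replicated two-device table.

    Needs columns ``subject``, ``device`` (two levels) and ``value``, with
    at least 2 replicates per device within each subject(-activity) cell.
    The estimate is the ratio of the summed within-device mean squared
    deviations (averaged over the two devices) to the summed between-device
    mean squared deviations.  Values above 1 are reported as-is with a
    warning, not clipped.
    """
    validate_paired_table(table, "device", ("subject", "device", "value"))
    est = _cia_point(table)
    if est > 1.0:
        warnings.warn(
            f"CIA estimate {est:.4g} exceeds 1; within-device disagreement "
            "dominates between-device disagreement",
            RuntimeWarning,
            stacklevel=2,
        )
    ci = _cluster_bootstrap(table, lambda s: _cia_point(s), n_boot, seed)
    if ci is None:
        return CIAResult(est, None, None)
    return CIAResult(est, float(ci[0, 0]), float(ci[0, 1]))


# ---------------------------------------------------------------------------
# variance-components model for step counts
# ---------------------------------------------------------------------------

#: variance-component structures, keyed by model variant
_VARIANTS: dict[str, dict[str, str]] = {
    "base": {
        "subject": "0 + C(subject)",
        "activity": "0 + C(activity)",
    },
    "final": {
        "subject": "0 + C(subject)",
        "activity": "0 + C(activity)",
        "subject_activity": "0 + C(subject):C(activity)",
        "subject_device": "0 + C(subject):C(device)",
    },
    "full": {
        "subject": "0 + C(subject)",
        "activity": "0 + C(activity)",
        "subject_activity": "0 + C(subject):C(activity)",
        "subject_device": "0 + C(subject):C(device)",
        "device_activity": "0 + C(device):C(activity)",
    },
}


@dataclass
class LMMFit:
    variant: str
    fixed_effects: dict[str, float]
    variance_components: dict[str, float]
    loglike: float
    aic: float
    bic: float
    n_obs: int
    converged: bool
    residuals: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        for k, v in self.variance_components.items():
            if v < -1e-8:
                raise ValueError(f"negative variance component {k}={v}")
        if not (math.isfinite(self.aic) and math.isfinite(self.bic)):
            raise ValueError("AIC/BIC must be finite")


def fit_steps_lmm(
    table: pd.DataFrame, variant: str = "final"
) -> LMMFit:
    """REML variance-component fit of the paired step-count model.

    ``table`` needs columns ``subject``, ``activity``, ``device`` (two
    levels: e.g. estimated vs video reference) and ``value``.  The model has
    a fixed device effect and random subject and activity effects; the
    ``final`` variant adds subject x activity and subject x device
    interaction components.
    """
    if variant not in _VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; pick from {list(_VARIANTS)}")
    validate_paired_table(table, "device", ("subject", "activity", "device", "value"))
    if table["subject"].nunique() < 2 or table["activity"].nunique() < 2:
        raise ValueError("need >= 2 subjects and >= 2 activities")
    if table["device"].nunique() != 2:
        raise ValueError("need exactly 2 devices/methods")

    df = table.copy()
    df["_one"] = 1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM.from_formula(
            "value ~ C(device)",
            groups="_one",
            vc_formula=_VARIANTS[variant],
            data=df,
        )
        res = model.fit(reml=True, maxiter=200)
    if not res.converged:
        warnings.warn(
            f"variance-component fit ({variant}) did not converge; "
            "estimates may be unreliable",
            RuntimeWarning,
            stacklevel=2,
        )
    vcomp = {
        name: max(float(v), 0.0)
        for name, v in zip(model.exog_vc.names, res.vcomp)
    }
    vcomp["residual"] = float(res.scale)
    k = len(res.fe_params) + len(res.vcomp) + 1
    n = len(df)
    llf = float(res.llf)
    fit = LMMFit(
        variant=variant,
        fixed_effects={n_: float(v) for n_, v in res.fe_params.items()},
        variance_components=vcomp,
        loglike=llf,
        aic=-2 * llf + 2 * k,
        bic=-2 * llf + k * math.log(n),
        n_obs=n,
        converged=bool(res.converged),
        residuals=np.asarray(res.resid),
    )
    return fit


def compare_models(
    table: pd.DataFrame, variants: tuple[str, ...] = ("base", "final", "full")
) -> list[LMMFit]:
    """Fit the requested variants and rank them by AIC, then BIC."""
    fits = [fit_steps_lmm(table, v) for v in variants]
    return sorted(fits, key=lambda f: (f.aic, f.bic))


# ---------------------------------------------------------------------------
# inter-unit reliability
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InterUnitResult:
    mean_difference: float
    loa: LoAResult
    cv: float
    n_pairs: int


def inter_unit_reliability(
    table: pd.DataFrame,
    n_boot: int = 1000,
    seed: int | None = None,
) -> InterUnitResult:
    """Consistency of per-lap values from two units worn simultaneously.

    ``table`` needs columns ``subject``, ``lap``, ``device`` (two levels)
    and ``value``.  Differences are second unit minus first (device labels
    sorted); unpaired rows are dropped with a warning.  The CV is the SD of
    the within-pair differences divided by the grand mean of all paired
    values, reported as a ratio.
    """
    validate_paired_table(table, "device", ("subject", "lap", "device", "value"))
    devices = sorted(table["device"].unique())
    if len(devices) != 2:
        raise ValueError("inter_unit_reliability requires exactly 2 devices")
    keys = [c for c in ("subject", "activity", "lap") if c in table.columns]
    wide = table.pivot_table(
        index=keys, columns="device", values="value", aggfunc="first"
    )
    n_unpaired = int(wide.isna().any(axis=1).sum())
    if n_unpaired:
        warnings.warn(
            f"dropped {n_unpaired} unpaired row(s)", RuntimeWarning, stacklevel=2
        )
        wide = wide.dropna()
    diffs = (wide[devices[1]] - wide[devices[0]]).rename("diff").reset_index()
    loa = loa_repeated(diffs[["subject", "diff"]], n_boot=n_boot, seed=seed)
    d = diffs["diff"].to_numpy(dtype=float)
    grand_mean = float(wide.to_numpy().mean())
    sd_diff = float(d.std(ddof=1)) if d.size > 1 else 0.0
    cv = sd_diff / grand_mean if grand_mean != 0 else math.inf
    return InterUnitResult(
        mean_difference=float(d.mean()), loa=loa, cv=cv, n_pairs=int(d.size)
    )


# ---------------------------------------------------------------------------
# full agreement report (CLI `agree`)
# ---------------------------------------------------------------------------

@dataclass
class AgreementReport:
    overall: dict
    by_activity: dict[str, dict]
    bland_altman: dict[str, list[tuple[float, float]]]

    def to_dict(self) -> dict:
        return {
            "overall": self.overall,
            "by_activity": self.by_activity,
            "bland_altman": self.bland_altman,
        }


def _pairwise(est: pd.DataFrame, ref: pd.DataFrame) -> pd.DataFrame:
    keys = ["subject", "activity", "lap"]
    merged = est.merge(ref, on=keys, suffixes=("_est", "_ref"))
    merged["diff"] = merged["value_est"] - merged["value_ref"]
    merged["mean"] = 0.5 * (merged["value_est"] + merged["value_ref"])
    return merged


def _metrics_block(merged: pd.DataFrame, n_boot: int, seed: int | None) -> dict:
    em = error_metrics(merged["value_est"], merged["value_ref"])
    c = ccc(merged["value_est"], merged["value_ref"])
    loa = loa_repeated(merged[["subject", "diff"]], n_boot=n_boot, seed=seed)
    t = tdi(
        merged["diff"].to_numpy(), n_boot=n_boot, seed=seed,
        subjects=merged["subject"].to_numpy(),
    )
    return {
        "n": int(len(merged)),
        "mae": em.mae,
        "rmse": em.rmse,
        "mape_percent": em.mape,
        "ccc": {"estimate": c.estimate, "ci": [c.ci_low, c.ci_high]},
        "loa": {
            "bias": loa.bias,
            "lower": loa.lower,
            "upper": loa.upper,
            "bias_ci": loa.bias_ci,
            "lower_ci": loa.lower_ci,
            "upper_ci": loa.upper_ci,
            "method": loa.method,
        },
        "tdi": {"estimate": t.estimate, "ci": [t.ci_low, t.ci_high], "p": t.p},
    }


def build_report(
    estimated: pd.DataFrame,
    reference: pd.DataFrame,
    by_activity: bool = True,
    n_boot: int = 1000,
    seed: int | None = None,
) -> AgreementReport:
    """Agreement report between two per-lap tables.

    Both inputs need columns ``subject``, ``activity``, ``lap``, ``value``.
    Metrics are computed overall and, when ``by_activity``, per activity;
    the report also carries the (mean, difference) scatter used for
    Bland-Altman plots.
    """
    for name, df in (("estimated", estimated), ("reference", reference)):
        missing = {"subject", "activity", "lap", "value"} - set(df.columns)
        if missing:
            raise ValueError(f"{name} table missing columns: {sorted(missing)}")
    merged = _pairwise(estimated, reference)
    if merged.empty:
        raise ValueError("no (subject, activity, lap) pairs in common")

    overall = _metrics_block(merged, n_boot, seed)

    # CIA needs within-device replicates: laps within subject-activity cells
    long = pd.concat(
        [
            merged[["subject", "activity", "lap", "value_est"]]
            .rename(columns={"value_est": "value"})
            .assign(device="estimated"),
            merged[["subject", "activity", "lap", "value_ref"]]
            .rename(columns={"value_ref": "value"})
            .assign(device="reference"),
        ],
        ignore_index=True,
    )
    replicated = long.groupby(["subject", "activity", "device"])["value"].count()
    if (replicated >= 2).all():
        ci = cia(long, n_boot=n_boot, seed=seed)
        overall["cia"] = {"estimate": ci.estimate, "ci": [ci.ci_low, ci.ci_high]}

    per_act: dict[str, dict] = {}
    ba: dict[str, list[tuple[float, float]]] = {}
    if by_activity:
        for act, sub in merged.groupby("activity"):
            if len(sub) >= 3:
                per_act[str(act)] = _metrics_block(sub, n_boot, seed)
            ba[str(act)] = list(zip(sub["mean"].tolist(), sub["diff"].tolist()))
    else:
        ba["all"] = list(zip(merged["mean"].tolist(), merged["diff"].tolist()))
    return AgreementReport(overall=overall, by_activity=per_act, bland_altman=ba)
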