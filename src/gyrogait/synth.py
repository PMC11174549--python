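"""Synthetic shank pitch-rate sessions with exact ground truth.

Each gait cycle is built from three raised-cosine (``sin^2``) lobes: a
toe-off trough, an opposite-sign mid-swing lobe and an initial-contact
trough, separated by short zero gaps.  The mid-swing lobe amplitude is
solved so that its analytic area equals the profile's per-step target
angle, which makes the generator and the detector/distance pipeline close
exactly: the dominant (positive for forward steps) angular displacement
integrated over the TO->IC window equals ``theta_target``.

Cycle timing is chosen so that every step remains individually detectable
under the default detector configuration (1 rad/s magnitude threshold,
250 ms post-IC refractory, 80 ms minimum flight time): by the time the
refractory lockout of one step ends, the next toe-off trough is either
still ahead or still deeper than the magnitude threshold.

Backward profiles invert the polarity of the whole waveform, so the
detector sees inverted peaks, emits negative displacements and flips its
search polarity, exactly as with a real backward-walking athlete.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .core import AthleteConfig, GyroSeries, TrackSegment
from .distance import step_distance

__all__ = [
    "PaceProfile",
    "StepTruth",
    "SyntheticSession",
    "default_profiles",
    "generate_step_waveform",
    "generate_session",
    "generate_two_device_session",
]

#: default amplitude/duration of the three sync jump spikes
_JUMP_AMP = 8.0
_JUMP_DUR = 0.08
_JUMP_SPACING = 0.6
_REST_BETWEEN_SEGMENTS = 1.5


@dataclass(frozen=True)
class PaceProfile:
    """Waveform recipe for one pace.

    ``theta_target`` is the per-step swing angle (rad); ``trough_amp`` must
    exceed the detector magnitude threshold or the generated steps are
    undetectable by construction.  ``theta_jitter`` draws a per-step
    multiplicative perturbation of the mid-swing lobe (and therefore of the
    true step angle), used for irregular paces.
    """

    name: str
    cadence: float  # steps / s
    theta_target: float  # rad, per-step net swing angle
    trough_amp: float  # rad/s, TO/IC lobe magnitude
    trough_dur: float  # s
    msw_dur: float  # s
    inner_gap: float  # s, gap between lobes
    noise_sd: float = 0.0  # rad/s, additive white noise
    direction: str = "forward"
    theta_jitter: float = 0.0  # fractional, uniform +-
    bias: float = 0.0  # rad/s constant offset (drift exercise)

    def __post_init__(self) -> None:
        if self.cadence <= 0 or self.theta_target <= 0:
            raise ValueError("cadence and theta_target must be positive")
        if self.direction not in ("forward", "backward"):
            raise ValueError("direction must be 'forward' or 'backward'")
        if self.flight_time >= self.period:
            raise ValueError("lobes do not fit inside one cycle")

    @property
    def period(self) -> float:
        return 1.0 / self.cadence

    @property
    def flight_time(self) -> float:
        """TO-minimum to IC-minimum interval."""
        return self.trough_dur + 2 * self.inner_gap + self.msw_dur

    @property
    def msw_amp(self) -> float:
        """Mid-swing lobe amplitude solving area == theta_target."""
        return 2.0 * self.theta_target / self.msw_dur

    @property
    def sign(self) -> int:
        return -1 if self.direction == "backward" else +1

    def check_feasible(self, magnitude_threshold: float = 1.0) -> None:
        headroom = self.trough_amp - 3.0 * self.noise_sd
        if headroom <= magnitude_threshold:
            raise ValueError(
                f"profile {self.name!r} infeasible: trough amplitude "
                f"{self.trough_amp} with noise sd {self.noise_sd} leaves no "
                f"headroom over the {magnitude_threshold} rad/s threshold"
            )


def default_profiles() -> dict[str, PaceProfile]:
    """Per-pace simulator defaults.

    Cadences are capped so that the 250 ms post-IC refractory of the
    default detector never swallows the following toe-off trough; the
    per-step angles are plausible swing magnitudes, not measured values.
    """
    return {
        "walking": PaceProfile(
            "walking", cadence=1.7, theta_target=0.55, trough_amp=4.0,
            trough_dur=0.10, msw_dur=0.16, inner_gap=0.02,
        ),
        "jogging": PaceProfile(
            "jogging", cadence=2.0, theta_target=0.65, trough_amp=5.0,
            trough_dur=0.10, msw_dur=0.13, inner_gap=0.02,
        ),
        "sprinting": PaceProfile(
            "sprinting", cadence=2.0, theta_target=0.85, trough_amp=6.5,
            trough_dur=0.10, msw_dur=0.13, inner_gap=0.015,
        ),
        "run_CoD": PaceProfile(
            "run_CoD", cadence=2.0, theta_target=0.70, trough_amp=5.0,
            trough_dur=0.10, msw_dur=0.13, inner_gap=0.015, theta_jitter=0.06,
        ),
        "ball_dribbling": PaceProfile(
            "ball_dribbling", cadence=2.0, theta_target=0.45, trough_amp=3.3,
            trough_dur=0.10, msw_dur=0.13, inner_gap=0.02, theta_jitter=0.06,
        ),
        "backward": PaceProfile(
            "backward", cadence=1.6, theta_target=0.50, trough_amp=4.0,
            trough_dur=0.10, msw_dur=0.14, inner_gap=0.02, direction="backward",
        ),
    }


@dataclass(frozen=True)
class StepTruth:
    """Ground truth for one generated step."""

    t_TO: float
    t_MSW: float
    t_IC: float
    theta: float  # signed, rad
    distance: float  # m
    direction: str
    pace: str
    lap: int = 0
    segment_index: int = 0


@dataclass
class SyntheticSession:
    series: GyroSeries
    truth: list[StepTruth]
    segments: list[TrackSegment] = field(default_factory=list)
    seed: int | None = None

    @property
    def total_distance(self) -> float:
        return float(sum(s.distance for s in self.truth))


def _lobe(tau: np.ndarray, start: float, dur: float) -> np.ndarray:
    """Unit sin^2 lobe supported on [start, start + dur)."""
    x = (tau - start) / dur
    inside = (x >= 0) & (x < 1)
    out = np.zeros_like(tau)
    out[inside] = np.sin(np.pi * x[inside]) ** 2
    return out


def _render_train(
    profile: PaceProfile,
    n_steps: int,
    sample_rate: float,
    t_start: float,
    rng: np.random.Generator,
    lap: int,
    segment_index: int,
    leg_length: float,
) -> tuple[np.ndarray, list[StepTruth]]:
    """Render ``n_steps`` cycles; returns the samples and ground truth.

    The returned array covers ``round(n_steps * period * fs)`` samples
    starting at ``t_start`` on the global uniform grid.
    """
    T = profile.period
    dt = 1.0 / sample_rate
    n = int(round(n_steps * T * sample_rate))
    t = t_start + np.arange(n) * dt
    k = np.minimum(((t - t_start) / T).astype(int), n_steps - 1)
    tau = t - t_start - k * T

    if profile.theta_jitter > 0:
        jit = 1.0 + rng.uniform(-profile.theta_jitter, profile.theta_jitter, n_steps)
    else:
        jit = np.ones(n_steps)
    msw_amp_k = profile.msw_amp * jit

    d_t, d_m, g = profile.trough_dur, profile.msw_dur, profile.inner_gap
    rem = T - (2 * d_t + 2 * g + d_m)
    g0 = rem / 2.0  # centre the lobes within the cycle

    s = profile.sign
    w = np.zeros(n)
    w -= s * profile.trough_amp * _lobe(tau, g0, d_t)
    w += s * msw_amp_k[k] * _lobe(tau, g0 + d_t + g, d_m)
    w -= s * profile.trough_amp * _lobe(tau, g0 + d_t + g + d_m + g, d_t)

    truth = []
    for i in range(n_steps):
        base = t_start + i * T + g0
        theta = s * profile.theta_target * jit[i]
        truth.append(
            StepTruth(
                t_TO=base + d_t / 2,
                t_MSW=base + d_t + g + d_m / 2,
                t_IC=base + d_t + g + d_m + g + d_t / 2,
                theta=float(theta),
                distance=step_distance(theta, leg_length),
                direction=profile.direction,
                pace=profile.name,
                lap=lap,
                segment_index=segment_index,
            )
        )
    return w, truth


def generate_step_waveform(
    profile: PaceProfile,
    leg_length: float,
    sample_rate: float = 200.0,
    rng: np.random.Generator | None = None,
    padding: float = 0.5,
) -> tuple[GyroSeries, StepTruth]:
    """One gait cycle with quiet padding on both sides."""
    profile.check_feasible()
    rng = np.random.default_rng() if rng is None else rng
    w, truth = _render_train(
        profile, 1, sample_rate, padding, rng, lap=0, segment_index=0,
        leg_length=leg_length,
    )
    n_pad = int(round(padding * sample_rate))
    w = np.concatenate([np.zeros(n_pad), w, np.zeros(n_pad)])
    if profile.noise_sd > 0:
        w = w + rng.normal(0.0, profile.noise_sd, w.size)
    if profile.bias:
        w = w + profile.bias
    t = np.arange(w.size) / sample_rate
    series = GyroSeries(t, w, sample_rate_nominal=sample_rate)
    return series, truth[0]


def _jump_block(sample_rate: float, n_jumps: int = 3) -> np.ndarray:
    dur = n_jumps * _JUMP_SPACING
    n = int(round(dur * sample_rate))
    t = np.arange(n) / sample_rate
    w = np.zeros(n)
    for j in range(n_jumps):
        w += _JUMP_AMP * _lobe(t, j * _JUMP_SPACING, _JUMP_DUR)
    return w


def generate_session(
    circuit: Sequence[TrackSegment],
    athlete: AthleteConfig,
    profiles: dict[str, PaceProfile] | None = None,
    laps: int = 1,
    seed: int | None = None,
    sample_rate: float = 200.0,
    noise_sd: float | None = None,
    bias: float = 0.0,
    include_jumps: bool = True,
) -> SyntheticSession:
    """Assemble a labelled multi-segment session.

    Starts with three sync jump spikes (suppressed by
    ``include_jumps=False``), then for each lap renders every
    circuit segment with ``round(reference_distance / step_length)`` steps
    at that pace, with quiet rests in between.  ``noise_sd`` overrides the
    per-profile noise with a single additive white-noise level for the
    whole stream; ``bias`` adds a constant rate offset (drift exercise).
    Fixed ``seed`` gives bitwise-reproducible output.
    """
    profiles = default_profiles() if profiles is None else profiles
    rng = np.random.default_rng(seed)
    dt = 1.0 / sample_rate

    chunks: list[np.ndarray] = []
    truth: list[StepTruth] = []
    segments: list[TrackSegment] = []
    t_cursor = 0.0

    def _append(arr: np.ndarray) -> None:
        nonlocal t_cursor
        chunks.append(arr)
        t_cursor += arr.size * dt

    _append(np.zeros(int(round(1.0 * sample_rate))))
    if include_jumps:
        _append(_jump_block(sample_rate))
    _append(np.zeros(int(round(2.0 * sample_rate))))

    for lap in range(laps):
        for seg_idx, seg in enumerate(circuit):
            try:
                profile = profiles[seg.pace]
            except KeyError:
                raise ValueError(f"no profile for pace {seg.pace!r}") from None
            profile.check_feasible()
            step_len = step_distance(profile.theta_target, athlete.leg_length)
            n_steps = max(1, int(round(seg.reference_distance / step_len)))
            t_seg_start = t_cursor
            w, seg_truth = _render_train(
                profile, n_steps, sample_rate, t_cursor, rng,
                lap=lap, segment_index=seg_idx, leg_length=athlete.leg_length,
            )
            if noise_sd is None and profile.noise_sd > 0:
                w = w + rng.normal(0.0, profile.noise_sd, w.size)
            _append(w)
            truth.extend(seg_truth)
            segments.append(
                replace(seg, time_window=(t_seg_start, t_cursor))
            )
            _append(np.zeros(int(round(_REST_BETWEEN_SEGMENTS * sample_rate))))

    w_all = np.concatenate(chunks)
    if noise_sd is not None and noise_sd > 0:
        w_all = w_all + rng.normal(0.0, noise_sd, w_all.size)
    if bias:
        w_all = w_all + bias
    t = np.arange(w_all.size) * dt
    series = GyroSeries(t, w_all, sample_rate_nominal=sample_rate)
    return SyntheticSession(series=series, truth=truth, segments=segments, seed=seed)


def generate_two_device_session(
    base_session: SyntheticSession,
    gain_delta: float = 0.0,
    extra_noise_sd: float = 0.0,
    time_offset: float = 0.0,
    rng: np.random.Generator | None = None,
) -> SyntheticSession:
    """Second-unit variant of a session: gain mismatch, extra noise, delay.

    The second stream is the base stream scaled by ``1 + gain_delta``,
    delayed by ``time_offset`` (rounded to whole samples, zero-padded at
    the start) with independent additive noise.  Ground truth and segment
    labels are shared with the base session.
    """
    rng = np.random.default_rng() if rng is None else rng
    fs = base_session.series.sample_rate_nominal
    w = base_session.series.pitch_rate * (1.0 + gain_delta)
    shift = int(round(time_offset * fs))
    if shift > 0:
        w = np.concatenate([np.zeros(shift), w[:-shift]])
    elif shift < 0:
        w = np.concatenate([w[-shift:], np.zeros(-shift)])
    if extra_noise_sd > 0:
        w = w + rng.normal(0.0, extra_noise_sd, w.size)
    series = GyroSeries(
        base_session.series.timestamps.copy(),
        w,
        sample_rate_nominal=fs,
    )
    return SyntheticSession(
        series=series,
        truth=base_session.truth,
        segments=base_session.segments,
        seed=base_session.seed,
    )
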