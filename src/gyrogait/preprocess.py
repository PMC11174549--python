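"""Signal conditioning: low-pass filtering, spectra and jump-spike sync.

The default filter is a *causal* single-pass 2nd-order Butterworth low-pass
(5 Hz cut-off) because the detector is meant to run in real time; a
zero-phase forward-backward variant is available behind a flag for offline
work.  Filtering assumes the nominal sample rate; if timestamp jitter
exceeds 20% of the nominal interval a warning is attached instead of
resampling.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .core import GyroSeries

__all__ = ["FilterSpec", "lowpass", "spectrum", "synchronize_by_jumps"]


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth low-pass specification."""

    order: int = 2
    cutoff: float = 5.0
    sample_rate: float = 200.0

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if not (0 < self.cutoff < self.sample_rate / 2):
            raise ValueError(
                f"cutoff must lie in (0, Nyquist={self.sample_rate / 2} Hz)"
            )


def _butter(spec: FilterSpec):
    return signal.butter(spec.order, spec.cutoff, btype="low", fs=spec.sample_rate)


def lowpass(
    series: GyroSeries, spec: FilterSpec | None = None, zero_phase: bool = False
) -> GyroSeries:
    """Low-pass filter the pitch-rate channel.

    Causal single-pass by default (``scipy.signal.lfilter`` seeded with the
    steady-state initial condition for the first sample, so a constant
    input passes through unchanged).  ``zero_phase=True`` switches to
    forward-backward filtering for offline use.
    """
    series.require_processable()
    if spec is None:
        spec = FilterSpec(sample_rate=series.sample_rate_nominal)
    b, a = _butter(spec)
    x = series.pitch_rate
    if zero_phase:
        y = signal.filtfilt(b, a, x)
    else:
        zi = signal.lfilter_zi(b, a) * x[0]
        y, _ = signal.lfilter(b, a, x, zi=zi)
    out = GyroSeries(
        timestamps=series.timestamps.copy(),
        pitch_rate=y,
        sample_rate_nominal=series.sample_rate_nominal,
        rates_xyz=series.rates_xyz,
    )
    out.warnings = list(series.warnings)
    nominal = 1.0 / series.sample_rate_nominal
    dt = np.diff(series.timestamps)
    if np.any(np.abs(dt - nominal) > 0.20 * nominal):
        out.warnings.append(
            "timestamp jitter exceeds 20% of the nominal interval; the filter "
            "assumed uniform sampling"
        )
    return out


def butter_gain(spec: FilterSpec, freq: float) -> float:
    """Analytic Butterworth magnitude |H(f)| = (1+(f/fc)^(2n))^(-1/2)."""
    return float((1.0 + (freq / spec.cutoff) ** (2 * spec.order)) ** -0.5)


def spectrum(series: GyroSeries, uniformity_tol: float = 0.01):
    """One-sided magnitude spectrum of the pitch-rate channel.

    Returns ``(freq_hz, magnitude)`` where the magnitudes are
    power-normalized so that ``sum(magnitude**2) == mean(x**2)`` (Parseval
    consistency).  Requires (near-)uniform sampling.
    """
    series.require_processable()
    dt = np.diff(series.timestamps)
    med = float(np.median(dt))
    if np.any(np.abs(dt - med) > uniformity_tol * med):
        raise ValueError("spectrum requires uniformly resampled input")
    x = series.pitch_rate
    n = x.size
    X = np.fft.rfft(x)
    freq = np.fft.rfftfreq(n, d=med)
    # one-sided weights: DC (and Nyquist for even n) appear once
    w = np.full(X.size, 2.0)
    w[0] = 1.0
    if n % 2 == 0:
        w[-1] = 1.0
    mag = np.abs(X) * np.sqrt(w) / n
    return freq, mag


# ---------------------------------------------------------------------------
# multi-device synchronization via the session-start jump spikes
# ---------------------------------------------------------------------------

#: spikes below this rectified magnitude (rad/s) are never jump candidates
_JUMP_FLOOR = 2.0
#: gap (s) that separates two spike clusters
_CLUSTER_GAP = 0.25


def _jump_envelope(series: GyroSeries, spec: FilterSpec) -> np.ndarray:
    filt = lowpass(series, spec)
    return np.abs(filt.pitch_rate)


def _find_clusters(env: np.ndarray, t: np.ndarray, window: float) -> list[float]:
    in_win = t <= t[0] + window
    if not np.any(in_win):
        return []
    seg = env[in_win]
    thr = max(float(np.percentile(seg, 99.0)), _JUMP_FLOOR)
    hits = np.flatnonzero(seg >= thr)
    if hits.size == 0:
        return []
    onsets = [float(t[hits[0]])]
    for i, j in zip(hits[:-1], hits[1:]):
        if t[j] - t[i] > _CLUSTER_GAP:
            onsets.append(float(t[j]))
    return onsets


def synchronize_by_jumps(
    series_a: GyroSeries,
    series_b: GyroSeries,
    n_jumps: int = 3,
    search_window: float = 30.0,
    max_offset: float = 5.0,
) -> float:
    """Estimate the time offset of ``series_b`` relative to ``series_a``.

    Both streams must contain at least ``n_jumps`` high-magnitude spike
    clusters (the protocol's vertical jumps) within ``search_window``
    seconds of their start.  The offset maximizing the cross-correlation of
    the rectified, low-passed magnitudes over the jump window is returned;
    a positive value means ``series_b`` lags (is delayed with respect to)
    ``series_a``.
    """
    series_a.require_processable()
    series_b.require_processable()
    spec = FilterSpec(sample_rate=series_a.sample_rate_nominal)
    env_a = _jump_envelope(series_a, spec)
    env_b = _jump_envelope(
        series_b, FilterSpec(sample_rate=series_b.sample_rate_nominal)
    )
    clusters_a = _find_clusters(env_a, series_a.timestamps, search_window)
    clusters_b = _find_clusters(env_b, series_b.timestamps, search_window)
    if len(clusters_a) < n_jumps or len(clusters_b) < n_jumps:
        raise ValueError(
            f"jumps not found: expected {n_jumps} spike clusters, found "
            f"{len(clusters_a)} in series_a and {len(clusters_b)} in series_b"
        )

    dt = 1.0 / series_a.sample_rate_nominal
    horizon = search_window + max_offset
    a = env_a[series_a.timestamps <= series_a.timestamps[0] + horizon]
    b = env_b[series_b.timestamps <= series_b.timestamps[0] + horizon]
    a = a - a.mean()
    b = b - b.mean()
    xc = signal.correlate(b, a, mode="full")
    lags = signal.correlation_lags(b.size, a.size, mode="full")
    keep = np.abs(lags * dt) <= max_offset
    xc, lags = xc[keep], lags[keep]
    lag = int(lags[np.argmax(xc)])
    t0_shift = float(series_b.timestamps[0] - series_a.timestamps[0])
    return lag * dt + t0_shift
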