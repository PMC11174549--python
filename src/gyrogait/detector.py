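"""Real-time TO -> MSW -> IC step-detection state machine.

The detector consumes one (filtered) pitch-rate sample at a time and emits
at most one :class:`~gyrogait.core.StepRecord` per call:

* ``SEEK_TO``    - search for a toe-off extremum of the event-polarity sign
  whose magnitude reaches ``magnitude_threshold``;
* ``SEEK_MSW``   - search for the subsequent opposite-sign mid-swing
  extremum (no magnitude requirement);
* ``SEEK_IC``    - search for the next event-polarity extremum with
  magnitude >= threshold whose flight time ``t_IC - t_TO`` falls inside
  ``[flight_time_min, flight_time_max]``; on success a step is emitted,
  the displacement integrators are reset and the machine locks out for
  ``refractory`` seconds before the next TO search;
* ``REFRACTORY`` - no emissions; ends ``refractory`` seconds after the IC.

Extremum confirmation is causal: a candidate is the running extremum of the
polarity-adjusted signal and is confirmed once the signal retreats from it
by ``hysteresis``.  If ``flight_time_max`` elapses in SEEK_MSW/SEEK_IC the
machine aborts back to SEEK_TO without emitting.

Angular displacement is accumulated sample-by-sample (left-point
rectangular ``omega * dt`` by default, trapezoid behind a config flag) into
separate positive and negative totals; the per-step totals are differences
of snapshots taken at the TO and IC candidates, so a missed event can never
leak displacement into a later step.

When an emitted step's displacement sign opposes the current search
polarity (a backward step under forward search, or vice versa), the
polarity of the searched peaks is inverted for subsequent steps until a
step of the other sign is detected again.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import distance as _distance
from .core import (
    AthleteConfig,
    DetectorConfig,
    GyroSeries,
    SegmentTotals,
    SessionResult,
    StepRecord,
    TrackSegment,
)

__all__ = ["DetectorState", "process_sample", "detect_steps", "update_polarity"]

SEEK_TO = "SEEK_TO"
SEEK_MSW = "SEEK_MSW"
SEEK_IC = "SEEK_IC"
REFRACTORY = "REFRACTORY"


@dataclass
class DetectorState:
    """Mutable state threaded through :func:`process_sample`."""

    phase: str = SEEK_TO
    polarity: int = +1
    t_phase_entered: float = -math.inf
    refractory_until: float = -math.inf

    # candidate extremum of the current phase
    cand_t: float | None = None
    cand_value: float = 0.0
    cand_pos_snap: float = 0.0
    cand_neg_snap: float = 0.0

    # confirmed TO / MSW bookkeeping for the step in progress
    t_to: float | None = None
    to_pos_snap: float = 0.0
    to_neg_snap: float = 0.0
    t_msw: float | None = None

    # displacement accumulators (rad), running since the last reset
    cum_pos: float = 0.0
    cum_neg: float = 0.0

    # previous sample, for integration
    t_prev: float | None = None
    w_prev: float = 0.0

    n_nan_skipped: int = 0
    n_aborted: int = 0

    def _clear_candidate(self) -> None:
        self.cand_t = None
        self.cand_value = 0.0


def update_polarity(
    state: DetectorState, emitted_step: StepRecord, forward_theta_sign: int = +1
) -> DetectorState:
    """Adapt the searched-peak sign to the direction of the emitted step.

    ``forward_theta_sign`` is the sign that a forward step's displacement
    carries under the active mounting convention (+1 for the default
    ``event_polarity="negative"``, -1 for the mirrored convention).
    """
    aligned = emitted_step.theta * forward_theta_sign
    if aligned > 0:
        state.polarity = +1
    elif aligned < 0:
        state.polarity = -1
    return state


def _integrate(state: DetectorState, t: float, w: float, config: DetectorConfig) -> None:
    if state.t_prev is None:
        return
    dt = t - state.t_prev
    if config.integration == "trapezoid":
        dw = 0.5 * (state.w_prev + w) * dt
    else:
        dw = state.w_prev * dt
    if dw > 0:
        state.cum_pos += dw
    else:
        state.cum_neg += dw


def process_sample(
    state: DetectorState,
    t: float,
    w: float,
    config: DetectorConfig,
    leg_length: float,
) -> tuple[DetectorState, Optional[StepRecord]]:
    """Feed one sample; returns the (mutated) state and an optional step.

    Samples must arrive in strictly increasing time order.  NaN samples are
    skipped (counted in ``state.n_nan_skipped``).
    """
    if state.t_prev is not None and t <= state.t_prev:
        raise ValueError(f"non-monotonic time: {t} after {state.t_prev}")
    if not math.isfinite(w):
        state.n_nan_skipped += 1
        return state, None

    _integrate(state, t, w, config)

    emitted: Optional[StepRecord] = None
    # the same sample may need reprocessing after a phase change (e.g. the
    # sample that confirms TO is also the first MSW candidate)
    again = True
    while again:
        again = False
        # sign such that the searched extremum is a maximum of s * w
        s_event = state.polarity * config.event_sign

        if state.phase == REFRACTORY:
            if t < state.refractory_until:
                break
            state.phase = SEEK_TO
            state.t_phase_entered = t
            state._clear_candidate()
            # fall through: process this sample in SEEK_TO
            again = True
            continue

        if state.phase == SEEK_TO:
            v = s_event * w
            if state.cand_t is None or v > state.cand_value:
                state.cand_t = t
                state.cand_value = v
                state.cand_pos_snap = state.cum_pos
                state.cand_neg_snap = state.cum_neg
            elif (
                state.cand_value >= config.magnitude_threshold
                and state.cand_value - v >= config.hysteresis
            ):
                state.t_to = state.cand_t
                state.to_pos_snap = state.cand_pos_snap
                state.to_neg_snap = state.cand_neg_snap
                state.phase = SEEK_MSW
                state.t_phase_entered = t
                state._clear_candidate()
                again = True  # current sample seeds the MSW search

        elif state.phase == SEEK_MSW:
            assert state.t_to is not None
            if t - state.t_to > config.flight_time_max:
                state.n_aborted += 1
                state.phase = SEEK_TO
                state.t_phase_entered = t
                state._clear_candidate()
                state.t_to = None
                again = True
                continue
            v = -s_event * w
            if state.cand_t is None or v > state.cand_value:
                state.cand_t = t
                state.cand_value = v
            elif state.cand_value - v >= config.hysteresis:
                state.t_msw = state.cand_t
                state.phase = SEEK_IC
                state.t_phase_entered = t
                state._clear_candidate()
                again = True  # current sample may already seed the IC search

        elif state.phase == SEEK_IC:
            assert state.t_to is not None and state.t_msw is not None
            v = s_event * w
            confirmed = (
                state.cand_t is not None
                and state.cand_value >= config.magnitude_threshold
                and state.cand_value - v >= config.hysteresis
            )
            if confirmed:
                t_ic = state.cand_t
                theta_pos = state.cand_pos_snap - state.to_pos_snap
                theta_neg = state.cand_neg_snap - state.to_neg_snap
                theta = _distance.select_displacement(theta_pos, theta_neg)
                fwd_sign = -config.event_sign
                emitted = StepRecord(
                    t_TO=state.t_to,
                    t_MSW=state.t_msw,
                    t_IC=t_ic,
                    theta=theta,
                    distance=_distance.step_distance(theta, leg_length),
                    direction="backward" if theta * fwd_sign < 0 else "forward",
                )
                update_polarity(state, emitted, fwd_sign)
                _distance.reset_integrators(state)
                state.refractory_until = t_ic + config.refractory
                state.phase = REFRACTORY
                state.t_phase_entered = t
                state._clear_candidate()
                state.t_to = None
                state.t_msw = None
            elif t - state.t_to > config.flight_time_max:
                state.n_aborted += 1
                state.phase = SEEK_TO
                state.t_phase_entered = t
                state._clear_candidate()
                state.t_to = None
                state.t_msw = None
                again = True
            else:
                eligible = t - state.t_to >= config.flight_time_min
                if eligible and (state.cand_t is None or v > state.cand_value):
                    state.cand_t = t
                    state.cand_value = v
                    state.cand_pos_snap = state.cum_pos
                    state.cand_neg_snap = state.cum_neg

    state.t_prev = t
    state.w_prev = w
    return state, emitted


def detect_steps(
    series: GyroSeries,
    config: DetectorConfig,
    athlete: AthleteConfig,
    segments: Sequence[TrackSegment] | None = None,
    initial_polarity: int = +1,
) -> SessionResult:
    """Batch wrapper: identical output to streaming every sample through
    :func:`process_sample`.

    Steps are assigned to ``segments`` (half-open time windows, matched on
    the step's IC time) when provided.  ``initial_polarity`` seeds the
    adaptive peak-sign search (-1 when the stream is known to start with
    backward locomotion).
    """
    series.require_processable()
    if initial_polarity not in (+1, -1):
        raise ValueError("initial_polarity must be +1 or -1")
    state = DetectorState(polarity=initial_polarity)
    steps: list[StepRecord] = []
    t_arr = series.timestamps
    w_arr = series.pitch_rate
    for i in range(t_arr.size):
        state, step = process_sample(
            state, float(t_arr[i]), float(w_arr[i]), config, athlete.leg_length
        )
        if step is not None:
            steps.append(step)

    result = SessionResult(steps=steps)
    if state.n_nan_skipped:
        result.warnings.append(f"skipped {state.n_nan_skipped} NaN sample(s)")
    if segments is not None:
        for lap_idx, seg in enumerate(segments):
            inside = [s for s in steps if seg.contains(s.t_IC)]
            result.per_segment.append(
                SegmentTotals(
                    segment=seg,
                    lap=lap_idx,
                    step_count=len(inside),
                    distance=float(sum(s.distance for s in inside)),
                )
            )
    return result
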