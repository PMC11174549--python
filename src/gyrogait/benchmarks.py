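"""Published validation-study reference figures.

These constants reproduce the summary tables of the validation study the
algorithm was benchmarked against.  The underlying raw dataset is not
shareable, so they serve two purposes here: arithmetic consistency checks
(ledger sums, mean paired differences) and ground-truth parameter values
for simulation-based recovery tests of the agreement estimators.
"""

from __future__ import annotations

__all__ = [
    "TAGGED_STEPS_BY_ACTIVITY",
    "STEP_COUNT_TABLE",
    "DISTANCE_TABLE",
    "LMM_VARIANCE_COMPONENTS",
    "LOA_REFERENCE",
]

#: video-tagged step totals per activity across the whole study
TAGGED_STEPS_BY_ACTIVITY: dict[str, int] = {
    "backward": 1240,
    "ball_dribbling": 3586,
    "sprinting": 2048,
    "walking": 1978,
    "jogging": 1571,
    "run_CoD": 2779,
}

#: per-lap step counts: (real mean, real sd, estimated mean, estimated sd)
STEP_COUNT_TABLE: dict[str, tuple[float, float, float, float]] = {
    "jogging": (27.6, 4.2, 28.0, 4.3),
    "run_CoD": (44.1, 9.2, 44.0, 8.6),
    "backward": (22.1, 3.2, 20.9, 4.8),
    "ball_dribbling": (53.5, 10.2, 58.5, 11.5),
    "walking": (34.1, 3.9, 35.0, 3.7),
    "sprinting": (37.2, 4.5, 39.3, 5.0),
}

#: distance accuracy: (reference m, estimated mean m, estimated sd m)
DISTANCE_TABLE: dict[str, tuple[float, float, float]] = {
    "jogging": (25.0, 26.4, 2.4),
    "run_CoD": (42.3, 44.5, 7.3),
    "backward": (16.0, 15.3, 4.2),
    "ball_dribbling": (42.3, 44.5, 7.3),
    "walking": (26.0, 28.4, 3.0),
    "sprinting": (50.0, 48.4, 4.9),
}

#: reported mixed-model variance components for the step-count model,
#: used as simulation truths in parameter-recovery tests
LMM_VARIANCE_COMPONENTS: dict[str, float] = {
    "subject": 34.03,
    "activity": 171.45,
    "subject_activity": 20.34,
    "subject_device": 0.65,
    "residual": 8.36,
}

#: reported repeated-measures limits-of-agreement scale for paired
#: step-count differences (bias and the LoA bounds), plus the simulation
#: truths used by the recovery tests
LOA_REFERENCE: dict[str, float] = {
    "bias": 1.26,
    "lower": -6.44,
    "upper": 8.97,
    "sim_sigma_subject": 1.5,
    "sim_sigma_residual": 3.5,
}


def mean_paired_difference(pace: str, decimals: int = 1) -> float:
    """Estimated-minus-real mean per-lap step difference for one pace."""
    real_mean, _, est_mean, _ = STEP_COUNT_TABLE[pace]
    return round(est_mean - real_mean, decimals)
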