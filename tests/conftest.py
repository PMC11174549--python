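import numpy as np
import pytest

from gyrogait import AthleteConfig, DetectorConfig, GyroSeries, TrackSegment
from gyrogait.synth import default_profiles


@pytest.fixture
def athlete() -> AthleteConfig:
    return AthleteConfig(athlete_id="test", leg_length=0.92)


@pytest.fixture
def config() -> DetectorConfig:
    return DetectorConfig()


@pytest.fixture
def profiles():
    return default_profiles()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def make_series(w: np.ndarray, fs: float = 200.0) -> GyroSeries:
    return GyroSeries(np.arange(w.size) / fs, np.asarray(w, dtype=float),
                      sample_rate_nominal=fs)


def single_pace_session(pace: str, n_steps: int, athlete, seed=0, **kwargs):
    """Session with one segment sized to produce ~n_steps ground-truth steps."""
    from gyrogait import generate_session
    from gyrogait.distance import step_distance

    profs = default_profiles()
    p = profs[pace]
    ref = n_steps * step_distance(p.theta_target, athlete.leg_length)
    circuit = [TrackSegment(pace=pace, reference_distance=ref)]
    return generate_session(circuit, athlete, profs, laps=1, seed=seed, **kwargs)
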