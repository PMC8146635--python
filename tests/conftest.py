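import numpy as np
import pytest

from zfsleep import (
    AnalysisWindow,
    LightSchedule,
    ScoringParams,
    Trajectory,
)
from zfsleep.sleep_scoring import IMMOBILE, MISSING, MOVING, SecondClassification


@pytest.fixture
def schedule() -> LightSchedule:
    """14:10 light-dark schedule, lights on 08:00, recording from 13:00."""
    return LightSchedule(lights_on="08:00", lights_off="22:00",
                         recording_start="13:00")


@pytest.fixture
def scoring() -> ScoringParams:
    return ScoringParams()


def labels_from_string(s: str) -> np.ndarray:
    """'M', 'I', '.' (missing) -> per-second label codes."""
    table = {"M": MOVING, "I": IMMOBILE, ".": MISSING}
    return np.array([table[c] for c in s], dtype=np.int8)


@pytest.fixture
def make_classification():
    def _make(s: str, subject="fish", origin=0.0) -> SecondClassification:
        return SecondClassification(subject, labels_from_string(s), origin)

    return _make


def trajectory_with_speeds(per_second_speeds, rate=5, subject="fish"):
    """Trajectory whose sample velocities realise the given per-second speeds.

    Each second contains `rate` samples all moving at that second's speed.
    The x/y path is a straight line consistent with the speeds.
    """
    speeds = np.repeat(np.asarray(per_second_speeds, float), rate)
    t = np.arange(speeds.size) / rate
    step = speeds / rate
    x = np.concatenate(([0.0], np.cumsum(step)[:-1]))
    y = np.zeros_like(x)
    return Trajectory(subject_id=subject, t=t, x=x, y=y, v=speeds)


@pytest.fixture
def night_window() -> AnalysisWindow:
    """The 10-h sleep-analysis window for a 13:00 recording start."""
    return AnalysisWindow(32400, 68400)
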