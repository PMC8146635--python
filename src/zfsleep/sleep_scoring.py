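"""Sleep scoring from per-second mobility.

The scoring rule operates on whole seconds.  A second is MOVING when any
sample velocity within it exceeds the 1.0 mm/s movement threshold (strict
inequality; a sample at exactly 1.0 mm/s is immobile), IMMOBILE when every
sample velocity is at or below it, and MISSING when the second contains no
valid sample.  A maximal run of at least 6 consecutive IMMOBILE seconds is a
sleep bout; every other observed second belongs to a wake bout.  The shortest
possible sleep bout is therefore 6 s.

MISSING seconds are treated conservatively: they break immobility runs,
belong to no bout, and are excluded from every denominator, so sleep is never
scored across unobserved time.

Derived per-subject parameters (per analysis window):

* sleep ratio / wake ratio — fraction of analyzed (non-missing) seconds in
  sleep / wake bouts;
* mean sleep- and wake-bout durations — over bouts not truncated by the
  window edges or by gaps (their true duration is unknown);
* fragmentation — number of awakenings (sleep-to-wake transitions) per
  analyzed hour;
* swim velocity — path length over the window divided by analyzed seconds —
  and total distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ComputationError, RangeError, ValidationError
from .trajectory_io import AnalysisWindow, Trajectory, path_length

# per-second label codes
MOVING = 1
IMMOBILE = 0
MISSING = -1

SLEEP = "SLEEP"
WAKE = "WAKE"

LABEL_NAMES = {MOVING: "MOVING", IMMOBILE: "IMMOBILE", MISSING: "MISSING"}


@dataclass(frozen=True)
class ScoringParams:
    """Movement threshold (mm/s) and minimum sleep-run length (s)."""

    movement_threshold: float = 1.0
    sleep_period_threshold: int = 6

    def __post_init__(self) -> None:
        if not self.movement_threshold > 0:
            raise ValidationError("movement_threshold must be positive")
        if (
            int(self.sleep_period_threshold) != self.sleep_period_threshold
            or self.sleep_period_threshold < 1
        ):
            raise ValidationError("sleep_period_threshold must be an integer >= 1")


@dataclass
class SecondClassification:
    """Per-second mobility labels for one subject.

    ``labels[k]`` covers recording time ``[origin_s + k, origin_s + k + 1)``.
    """

    subject_id: str
    labels: np.ndarray
    origin_s: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)

    def __len__(self) -> int:
        return int(self.labels.size)


@dataclass(frozen=True)
class Bout:
    state: str  # SLEEP or WAKE
    start_s: float  # recording second of bout onset
    duration_s: int
    truncated_start: bool = False
    truncated_end: bool = False

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s

    @property
    def truncated(self) -> bool:
        return self.truncated_start or self.truncated_end


@dataclass
class BoutSegmentation:
    """Alternating sleep/wake bouts plus unobserved time for one subject."""

    subject_id: str
    bouts: list
    missing_s: int
    span_s: int  # length of the classified span in whole seconds
    origin_s: float

    def durations(self, state: str, include_truncated: bool = True) -> np.ndarray:
        return np.array(
            [
                b.duration_s
                for b in self.bouts
                if b.state == state and (include_truncated or not b.truncated)
            ],
            dtype=float,
        )


@dataclass
class SleepMetrics:
    """The derived sleep-parameter vector for one subject and window.

    Undefined means (no bouts of a state) are carried as NaN, never as 0.
    """

    subject_id: str
    fragmentation: float  # awakenings per analyzed hour
    sleep_ratio: float
    wake_ratio: float
    mean_sleep_bout_s: float  # NaN when no countable sleep bout
    mean_wake_bout_s: float  # NaN when no countable wake bout
    velocity: float  # mm/s, path length / analyzed seconds
    total_distance: float  # mm
    n_sleep_bouts: int
    n_wake_bouts: int
    analyzed_s: float
    missing_s: float
    group_label: str = ""

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "group_label": self.group_label,
            "fragmentation": self.fragmentation,
            "sleep_ratio": self.sleep_ratio,
            "wake_ratio": self.wake_ratio,
            "mean_sleep_bout_s": self.mean_sleep_bout_s,
            "mean_wake_bout_s": self.mean_wake_bout_s,
            "velocity": self.velocity,
            "total_distance": self.total_distance,
            "n_sleep_bouts": self.n_sleep_bouts,
            "n_wake_bouts": self.n_wake_bouts,
            "analyzed_s": self.analyzed_s,
            "missing_s": self.missing_s,
        }


METRIC_COLUMNS = [
    "fragmentation",
    "sleep_ratio",
    "velocity",
    "total_distance",
    "mean_wake_bout_s",
    "mean_sleep_bout_s",
]


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_seconds(
    traj: Trajectory,
    params: ScoringParams | None = None,
    window: AnalysisWindow | None = None,
) -> SecondClassification:
    """Label each whole second of the window MOVING / IMMOBILE / MISSING.

    Seconds are aligned to the window start: second ``k`` covers
    ``[start + k, start + k + 1)``.  Samples with undefined (NaN) velocity do
    not count as observations.
    """
    params = params or ScoringParams()
    if traj.v is None:
        raise ValidationError(
            f"subject {traj.subject_id!r}: velocities required; "
            "call compute_sample_velocities first"
        )
    if window is None:
        window = AnalysisWindow(math.floor(traj.t[0]), math.floor(traj.t[-1]) + 1)
    n = window.n_seconds
    if n < 1:
        raise RangeError("window shorter than one second")
    t0, t1 = traj.span
    if window.start_s < math.floor(t0) - 1e-9 or window.end_s > t1 + 1.0 + 1e-9:
        raise RangeError(
            f"window [{window.start_s}, {window.end_s}) outside trajectory "
            f"span [{t0}, {t1}] of subject {traj.subject_id!r}"
        )
    mask = (
        (traj.t >= window.start_s)
        & (traj.t < window.start_s + n)
        & np.isfinite(traj.v)
    )
    sec = np.floor(traj.t[mask] - window.start_s).astype(np.int64)
    counts = np.bincount(sec, minlength=n)
    vmax = np.full(n, -np.inf)
    np.maximum.at(vmax, sec, traj.v[mask])
    labels = np.full(n, IMMOBILE, dtype=np.int8)
    labels[vmax > params.movement_threshold] = MOVING
    labels[counts == 0] = MISSING
    return SecondClassification(traj.subject_id, labels, window.start_s)


def _run_lengths(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """(value, start, length) runs of a 1-D array."""
    n = labels.size
    if n == 0:
        return []
    cuts = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate(([0], cuts))
    ends = np.concatenate((cuts, [n]))
    return [(int(labels[s]), int(s), int(e - s)) for s, e in zip(starts, ends)]


def detect_sleep_bouts(
    cls: SecondClassification, params: ScoringParams | None = None
) -> BoutSegmentation:
    """Segment a per-second classification into sleep and wake bouts.

    Within each contiguous observed segment (delimited by MISSING seconds or
    the window edges) maximal IMMOBILE runs of at least the sleep-period
    threshold become SLEEP bouts; all remaining seconds merge into WAKE
    bouts.  Bouts abutting a segment edge are flagged truncated on that side.
    """
    params = params or ScoringParams()
    thr = int(params.sleep_period_threshold)
    labels = cls.labels
    runs = _run_lengths(labels)
    bouts: list[Bout] = []
    missing = 0

    # group runs into observed segments split at MISSING
    segment: list[tuple[int, int, int]] = []

    def flush(segment):
        if not segment:
            return
        seg_start = segment[0][1]
        seg_end = segment[-1][1] + segment[-1][2]
        # map runs to SLEEP pieces and merged WAKE pieces
        pieces: list[tuple[str, int, int]] = []
        for value, start, length in segment:
            if value == IMMOBILE and length >= thr:
                pieces.append((SLEEP, start, length))
            elif pieces and pieces[-1][0] == WAKE:
                prev = pieces.pop()
                pieces.append((WAKE, prev[1], prev[2] + length))
            else:
                pieces.append((WAKE, start, length))
        for state, start, length in pieces:
            bouts.append(
                Bout(
                    state=state,
                    start_s=cls.origin_s + start,
                    duration_s=length,
                    truncated_start=(start == seg_start),
                    truncated_end=(start + length == seg_end),
                )
            )

    for value, start, length in runs:
        if value == MISSING:
            missing += length
            flush(segment)
            segment = []
        else:
            segment.append((value, start, length))
    flush(segment)

    return BoutSegmentation(
        subject_id=cls.subject_id,
        bouts=bouts,
        missing_s=missing,
        span_s=int(labels.size),
        origin_s=cls.origin_s,
    )


def count_awakenings(seg: BoutSegmentation) -> int:
    """Sleep-to-wake transitions between time-adjacent bouts (no gap between)."""
    n = 0
    for a, b in zip(seg.bouts[:-1], seg.bouts[1:]):
        if a.state == SLEEP and b.state == WAKE and a.end_s == b.start_s:
            n += 1
    return n


def compute_sleep_metrics(
    seg: BoutSegmentation,
    traj: Trajectory | None = None,
    window: AnalysisWindow | None = None,
    include_truncated_in_means: bool = False,
) -> SleepMetrics:
    """Derive the six sleep parameters from a bout segmentation.

    ``traj``/``window`` supply the positional data for velocity and total
    distance; when omitted those two fields are NaN.  Truncated bouts count
    toward the ratios but are excluded from mean bout durations unless
    ``include_truncated_in_means`` is set.
    """
    analyzed = seg.span_s - seg.missing_s
    if analyzed <= 0:
        raise ComputationError(
            f"subject {seg.subject_id!r}: zero analyzed seconds"
        )
    sleep_s = float(seg.durations(SLEEP).sum())
    wake_s = float(seg.durations(WAKE).sum())
    include = include_truncated_in_means
    sleep_d = seg.durations(SLEEP, include_truncated=include)
    wake_d = seg.durations(WAKE, include_truncated=include)

    if traj is not None:
        w = window or AnalysisWindow(seg.origin_s, seg.origin_s + seg.span_s)
        dist = path_length(traj, w)
        velocity = dist / analyzed
    else:
        dist = float("nan")
        velocity = float("nan")

    hours = analyzed / 3600.0
    return SleepMetrics(
        subject_id=seg.subject_id,
        fragmentation=count_awakenings(seg) / hours,
        sleep_ratio=sleep_s / analyzed,
        wake_ratio=wake_s / analyzed,
        mean_sleep_bout_s=float(sleep_d.mean()) if sleep_d.size else float("nan"),
        mean_wake_bout_s=float(wake_d.mean()) if wake_d.size else float("nan"),
        velocity=velocity,
        total_distance=dist,
        n_sleep_bouts=int(seg.durations(SLEEP).size),
        n_wake_bouts=int(seg.durations(WAKE).size),
        analyzed_s=float(analyzed),
        missing_s=float(seg.missing_s),
        group_label=traj.group_label if traj is not None else "",
    )


def score_sleep(
    traj: Trajectory,
    window: AnalysisWindow,
    params: ScoringParams | None = None,
    include_truncated_in_means: bool = False,
) -> tuple[SleepMetrics, BoutSegmentation]:
    """Convenience wrapper: classify, segment and derive metrics in one call."""
    params = params or ScoringParams()
    cls = classify_seconds(traj, params, window)
    seg = detect_sleep_bouts(cls, params)
    metrics = compute_sleep_metrics(
        seg, traj, window, include_truncated_in_means=include_truncated_in_means
    )
    return metrics, seg
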