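"""Locomotor activity per light phase: distance, velocity, time moving.

Distance is the summed length of trajectory segments whose both endpoints
fall inside the phase; average velocity is distance over analyzed phase
seconds; time moving counts MOVING seconds under the same per-second
classification used for sleep scoring, and its complement (IMMOBILE seconds)
is stationary/freezing time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import RangeError, StatisticsError
from .sleep_scoring import IMMOBILE, MOVING, ScoringParams, classify_seconds
from .trajectory_io import (
    DAY,
    FULL,
    NIGHT,
    AnalysisWindow,
    LightSchedule,
    Trajectory,
    path_length,
    phase_windows,
)


@dataclass
class LocomotorSummary:
    """Per-subject locomotor parameters for one phase (DAY / NIGHT / FULL)."""

    subject_id: str
    phase: str
    total_distance: float  # mm
    average_velocity: float  # mm/s over analyzed phase seconds
    time_moving_s: float
    time_moving_fraction: float
    stationary_s: float
    missing_s: float
    analyzed_s: float
    group_label: str = ""

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "group_label": self.group_label,
            "phase": self.phase,
            "total_distance": self.total_distance,
            "average_velocity": self.average_velocity,
            "time_moving_s": self.time_moving_s,
            "time_moving_fraction": self.time_moving_fraction,
            "stationary_s": self.stationary_s,
            "missing_s": self.missing_s,
            "analyzed_s": self.analyzed_s,
        }


def phase_summary(
    traj: Trajectory,
    schedule: LightSchedule,
    params: ScoringParams | None = None,
    phase: str = FULL,
    duration_s: float | None = None,
) -> LocomotorSummary:
    """Locomotor summary over all windows of one light phase.

    ``duration_s`` declares the recording length; by default it is inferred
    from the last sample time (rounded up to a whole second).
    """
    params = params or ScoringParams()
    if phase not in (DAY, NIGHT, FULL):
        raise RangeError(f"unknown phase {phase!r}")
    if duration_s is None:
        duration_s = float(np.ceil(traj.t[-1] + 1e-9))
    windows = phase_windows(schedule, duration_s, None if phase == FULL else phase)
    if not windows:
        raise RangeError(f"phase {phase} absent from the {duration_s}-s recording")

    dist = 0.0
    moving = immobile = missing = 0
    for window, _ph in windows:
        w = AnalysisWindow(window.start_s, window.end_s)
        dist += path_length(traj, w)
        labels = classify_seconds(traj, params, w).labels
        moving += int((labels == MOVING).sum())
        immobile += int((labels == IMMOBILE).sum())
        missing += int((labels == -1).sum())
    analyzed = moving + immobile
    return LocomotorSummary(
        subject_id=traj.subject_id,
        phase=phase,
        total_distance=dist,
        average_velocity=dist / analyzed if analyzed else float("nan"),
        time_moving_s=float(moving),
        time_moving_fraction=moving / analyzed if analyzed else float("nan"),
        stationary_s=float(immobile),
        missing_s=float(missing),
        analyzed_s=float(analyzed),
        group_label=traj.group_label,
    )


@dataclass
class HyperactivityReport:
    """Derived convenience flagging, not a primary assay statistic.

    A group is flagged hyperactive when its mean distance exceeds the
    control's in BOTH light phases and the Tukey-adjusted pairwise p-value
    against control is below alpha in both phases.
    """

    control_label: str
    alpha: float
    flagged: dict  # group -> bool
    detail: dict  # group -> {phase: {"mean_diff": .., "adjusted_p": ..}}


def hyperactivity_flag(
    distances_by_group: dict,
    control_label: str,
    alpha: float = 0.05,
) -> HyperactivityReport:
    """Flag hyperactive groups from per-subject phase distances.

    ``distances_by_group`` maps group label -> {"DAY": array, "NIGHT": array}
    of per-subject distances.  Requires >= 2 groups with >= 2 subjects each.
    """
    from .group_stats import tukey_hsd  # local import to avoid cycle

    groups = list(distances_by_group)
    if control_label not in groups:
        raise StatisticsError(f"control group {control_label!r} absent")
    if len(groups) < 2:
        raise StatisticsError("need at least two groups")
    for g in groups:
        for ph in (DAY, NIGHT):
            arr = np.asarray(distances_by_group[g][ph], dtype=float)
            if arr.size < 2:
                raise StatisticsError(f"group {g!r} has fewer than 2 subjects")

    detail: dict = {g: {} for g in groups if g != control_label}
    flagged: dict = {}
    for ph in (DAY, NIGHT):
        table = {g: np.asarray(distances_by_group[g][ph], float) for g in groups}
        res = tukey_hsd(table, alpha=alpha)
        padj = {}
        for a, b, est, p, _sig in res.pairwise:
            padj[(a, b)] = (est, p)
            padj[(b, a)] = (-est, p)
        for g in groups:
            if g == control_label:
                continue
            est, p = padj[(g, control_label)]
            detail[g][ph] = {"mean_diff": est, "adjusted_p": p}
    for g in detail:
        flagged[g] = all(
            detail[g][ph]["mean_diff"] > 0 and detail[g][ph]["adjusted_p"] < alpha
            for ph in (DAY, NIGHT)
        )
    return HyperactivityReport(
        control_label=control_label, alpha=alpha, flagged=flagged, detail=detail
    )
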