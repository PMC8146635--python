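"""Reading, validation and time alignment of tracking exports.

Video trackers (EthoVision-style) export long-format delimited text with one
row per sample: subject id, time since recording start (s), x/y position (mm)
and optionally an instantaneous velocity (mm/s).  This module parses such
exports into :class:`Trajectory` objects, derives per-sample velocities from
positions when the export lacks them, and maps wall-clock light schedules and
analysis windows onto recording time.

Units are fixed at mm, seconds and mm/s throughout the package; readers
convert from cm when the dialect declares it.  Time conventions are half-open
everywhere: a window covers ``[start, end)`` and the lights-off instant
belongs to NIGHT.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, RangeError, ValidationError

SECONDS_PER_DAY = 86400

DAY = "DAY"
NIGHT = "NIGHT"
FULL = "FULL"


# ---------------------------------------------------------------------------
# core containers
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Time-ordered positional samples for one subject.

    Parameters
    ----------
    subject_id : str
        Identifier of the tracked animal.
    t, x, y : ndarray
        Sample times (s from recording start) and positions (mm).  Times must
        be finite and strictly increasing.
    v : ndarray or None
        Instantaneous sample velocities (mm/s).  NaN marks samples whose
        velocity is undefined (the first sample after velocity derivation).
    group_label, arena_id : str
        Experimental metadata.
    nominal_rate : float or None
        Declared sampling rate in Hz.  Used only for gap diagnostics, never
        for velocity arithmetic (which uses the actual timestamps).
    """

    subject_id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    v: np.ndarray | None = None
    group_label: str = ""
    arena_id: str = ""
    nominal_rate: float | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.v is not None:
            self.v = np.asarray(self.v, dtype=float)
        n = self.t.size
        if self.x.size != n or self.y.size != n:
            raise ValidationError(
                f"subject {self.subject_id!r}: t/x/y lengths differ"
            )
        if self.v is not None and self.v.size != n:
            raise ValidationError(
                f"subject {self.subject_id!r}: velocity column length differs"
            )
        if n and not np.all(np.isfinite(self.t)):
            raise ValidationError(f"subject {self.subject_id!r}: non-finite time")
        if n > 1:
            bad = np.flatnonzero(np.diff(self.t) <= 0)
            if bad.size:
                raise ValidationError(
                    f"subject {self.subject_id!r}: non-monotonic time at row "
                    f"{int(bad[0]) + 1}"
                )
        if self.v is not None:
            with np.errstate(invalid="ignore"):
                if np.any(self.v[np.isfinite(self.v)] < 0):
                    raise ValidationError(
                        f"subject {self.subject_id!r}: negative velocity"
                    )

    def __len__(self) -> int:
        return int(self.t.size)

    @property
    def span(self) -> tuple[float, float]:
        """(first, last) sample time in seconds from recording start."""
        return float(self.t[0]), float(self.t[-1])

    def with_velocities(self, overwrite: bool = False) -> "Trajectory":
        """Alias for :func:`compute_sample_velocities`."""
        return compute_sample_velocities(self, overwrite=overwrite)


@dataclass(frozen=True)
class AnalysisWindow:
    """Half-open time window ``[start_s, end_s)`` in recording seconds."""

    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if not (0 <= self.start_s < self.end_s):
            raise ValidationError(
                f"invalid window [{self.start_s}, {self.end_s})"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def n_seconds(self) -> int:
        """Number of whole seconds covered, aligned to the window start."""
        return int(math.floor(self.duration_s + 1e-9))


def _clock_to_seconds(clock) -> float:
    """Parse 'HH:MM[:SS]' / datetime.time / numeric seconds-of-day."""
    if isinstance(clock, (int, float)):
        s = float(clock)
    elif hasattr(clock, "hour"):  # datetime.time
        s = clock.hour * 3600 + clock.minute * 60 + clock.second
    else:
        parts = str(clock).split(":")
        if not 2 <= len(parts) <= 3:
            raise FormatError(f"unparseable clock time {clock!r}")
        try:
            nums = [float(p) for p in parts]
        except ValueError as exc:
            raise FormatError(f"unparseable clock time {clock!r}") from exc
        s = nums[0] * 3600 + nums[1] * 60 + (nums[2] if len(nums) == 3 else 0)
    if not 0 <= s < SECONDS_PER_DAY:
        raise ValidationError(f"clock time {clock!r} outside a 24-h day")
    return s


@dataclass(frozen=True)
class LightSchedule:
    """Lights-on/off clock times plus the recording's wall-clock start.

    The reference condition is a 14:10 light-dark cycle with lights on at
    08:00 and off at 22:00, recording started at 13:00.
    """

    lights_on: object = "08:00"
    lights_off: object = "22:00"
    recording_start: object = "13:00"

    @property
    def lights_on_s(self) -> float:
        return _clock_to_seconds(self.lights_on)

    @property
    def lights_off_s(self) -> float:
        return _clock_to_seconds(self.lights_off)

    @property
    def recording_start_s(self) -> float:
        return _clock_to_seconds(self.recording_start)

    def __post_init__(self) -> None:
        if self.lights_on_s == self.lights_off_s:
            raise ValidationError("lights_on and lights_off must differ")


def light_phase_of(schedule: LightSchedule, t: float) -> str:
    """Phase (DAY or NIGHT) of recording second ``t``.

    DAY iff the wall clock at ``t`` falls in ``[lights_on, lights_off)``;
    the lights-off instant itself is NIGHT.
    """
    clock = (schedule.recording_start_s + t) % SECONDS_PER_DAY
    on, off = schedule.lights_on_s, schedule.lights_off_s
    if on < off:
        return DAY if on <= clock < off else NIGHT
    # schedule crossing midnight
    return DAY if (clock >= on or clock < off) else NIGHT


def map_clock_window(
    schedule: LightSchedule,
    window_start,
    window_end,
    recording_duration_s: float = SECONDS_PER_DAY,
) -> AnalysisWindow:
    """Convert a wall-clock window into recording seconds.

    Rolls over midnight when the end clock time precedes the start (e.g.
    22:00 -> 08:00).  A window equal to the full recording (start == end ==
    recording start) maps to ``[0, recording_duration_s)``.
    """
    ws = _clock_to_seconds(window_start)
    we = _clock_to_seconds(window_end)
    r0 = schedule.recording_start_s
    start = (ws - r0) % SECONDS_PER_DAY
    end = (we - r0) % SECONDS_PER_DAY
    if end <= start:
        end += SECONDS_PER_DAY
    if end > recording_duration_s + 1e-9:
        raise RangeError(
            f"clock window {window_start}->{window_end} maps to "
            f"[{start}, {end}) s, outside the {recording_duration_s}-s recording"
        )
    return AnalysisWindow(start, end)


def phase_windows(
    schedule: LightSchedule, duration_s: float, phase: str | None = None
) -> list[tuple[AnalysisWindow, str]]:
    """Partition ``[0, duration_s)`` into maximal DAY/NIGHT windows.

    Returns (window, phase) pairs in time order; optionally filtered to one
    phase.
    """
    if duration_s <= 0:
        raise RangeError("non-positive recording duration")
    r0 = schedule.recording_start_s
    boundaries = {0.0, float(duration_s)}
    for clock in (schedule.lights_on_s, schedule.lights_off_s):
        first = (clock - r0) % SECONDS_PER_DAY
        b = first
        while b < duration_s:
            if b > 0:
                boundaries.add(b)
            b += SECONDS_PER_DAY
    cuts = sorted(boundaries)
    out: list[tuple[AnalysisWindow, str]] = []
    for lo, hi in zip(cuts[:-1], cuts[1:]):
        ph = light_phase_of(schedule, (lo + hi) / 2.0)
        out.append((AnalysisWindow(lo, hi), ph))
    if phase is not None and phase != FULL:
        out = [(w, p) for w, p in out if p == phase]
    return out


# ---------------------------------------------------------------------------
# velocities
# ---------------------------------------------------------------------------

def compute_sample_velocities(traj: Trajectory, overwrite: bool = False) -> Trajectory:
    """Fill the velocity column from positions.

    ``v[i]`` is the Euclidean distance from sample ``i-1`` to ``i`` divided by
    the actual time step; the first sample's velocity is undefined (NaN) and
    excluded from downstream per-second classification.  Pre-existing
    velocities are preserved unless ``overwrite`` is requested.
    """
    if len(traj) < 2:
        raise ValidationError(
            f"subject {traj.subject_id!r}: need >= 2 samples for velocities"
        )
    if traj.v is not None and not overwrite:
        return traj
    dt = np.diff(traj.t)
    if np.any(dt <= 0):
        raise ValidationError(
            f"subject {traj.subject_id!r}: zero or negative time step"
        )
    d = np.hypot(np.diff(traj.x), np.diff(traj.y))
    v = np.empty(len(traj))
    v[0] = np.nan
    v[1:] = d / dt
    return Trajectory(
        subject_id=traj.subject_id,
        t=traj.t,
        x=traj.x,
        y=traj.y,
        v=v,
        group_label=traj.group_label,
        arena_id=traj.arena_id,
        nominal_rate=traj.nominal_rate,
    )


def path_length(traj: Trajectory, window: AnalysisWindow | None = None) -> float:
    """Summed segment length (mm) over segments with both endpoints in window."""
    t, x, y = traj.t, traj.x, traj.y
    if window is None:
        keep = np.ones(len(traj), dtype=bool)
    else:
        keep = (t >= window.start_s) & (t <= window.end_s)
    pair = keep[:-1] & keep[1:]
    return float(np.hypot(np.diff(x), np.diff(y))[pair].sum())


# ---------------------------------------------------------------------------
# delimited-text dialect
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DialectConfig:
    """Tracking-table dialect: delimiter, column names and position units.

    Long format with a subject column (supports 96-well multi-subject
    exports); comment lines start with '#'.
    """

    delimiter: str = "\t"
    subject_col: str = "subject"
    time_col: str = "time"
    x_col: str = "x"
    y_col: str = "y"
    velocity_col: str | None = "velocity"
    units: str = "mm"  # 'mm' or 'cm'

    @property
    def scale(self) -> float:
        if self.units == "mm":
            return 1.0
        if self.units == "cm":
            return 10.0
        raise FormatError(f"unsupported position units {self.units!r}")


@dataclass
class ParseReport:
    """Row accounting returned alongside parsed trajectories."""

    rows_read: int = 0
    rows_rejected: int = 0
    rejected_by_subject: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "rows_read": self.rows_read,
            "rows_rejected": self.rows_rejected,
            "rejected_by_subject": dict(self.rejected_by_subject),
        }


def parse_tracking_table(
    source,
    dialect: DialectConfig | None = None,
    nominal_rate: float | None = None,
    group_map: dict | None = None,
) -> tuple[list[Trajectory], ParseReport]:
    """Parse a delimited tracking export into one Trajectory per subject.

    Rows with unparseable coordinates are recorded as gaps in the parse
    report (and later surface as MISSING seconds), never silently dropped
    without accounting.  Non-monotonic time within a subject raises a
    :class:`ValidationError` naming the subject and row.
    """
    dialect = dialect or DialectConfig()
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    df = pd.read_csv(source, sep=dialect.delimiter, comment="#", dtype=str)
    df.columns = [c.strip() for c in df.columns]

    required = [dialect.subject_col, dialect.time_col, dialect.x_col, dialect.y_col]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"missing column: {col}")
    has_v = dialect.velocity_col is not None and dialect.velocity_col in df.columns

    report = ParseReport(rows_read=int(len(df)))

    def _to_float(series: pd.Series) -> pd.Series:
        # python float() is correctly rounded; pandas' fast parser is not
        def conv(s):
            try:
                return float(s)
            except (TypeError, ValueError):
                return float("nan")

        return series.map(conv).astype(float)

    num = pd.DataFrame(
        {
            "t": _to_float(df[dialect.time_col]),
            "x": _to_float(df[dialect.x_col]),
            "y": _to_float(df[dialect.y_col]),
        }
    )
    if has_v:
        num["v"] = _to_float(df[dialect.velocity_col])
    num["subject"] = df[dialect.subject_col].astype(str)

    ok = num["t"].notna() & num["x"].notna() & num["y"].notna()
    rejected = num.loc[~ok, "subject"].value_counts().to_dict()
    report.rows_rejected = int((~ok).sum())
    report.rejected_by_subject = {k: int(v) for k, v in rejected.items()}
    num = num[ok]

    scale = dialect.scale
    trajs: list[Trajectory] = []
    for subject, sub in num.groupby("subject", sort=True):
        t = sub["t"].to_numpy(float)
        if t.size > 1:
            bad = np.flatnonzero(np.diff(t) <= 0)
            if bad.size:
                raise ValidationError(
                    f"subject {subject!r}: non-monotonic time at row "
                    f"{int(sub.index[bad[0] + 1]) + 2}"
                )
        v = sub["v"].to_numpy(float) * scale if has_v else None
        trajs.append(
            Trajectory(
                subject_id=str(subject),
                t=t,
                x=sub["x"].to_numpy(float) * scale,
                y=sub["y"].to_numpy(float) * scale,
                v=v,
                group_label=(group_map or {}).get(str(subject), ""),
                nominal_rate=nominal_rate,
            )
        )
    return trajs, report


def write_tracking_table(
    trajectories: Iterable[Trajectory],
    path_or_buf,
    dialect: DialectConfig | None = None,
) -> None:
    """Write trajectories back to the dialect (mm units, full float repr).

    Round trip: re-parsing the written table reproduces times and coordinates
    bit-identically.
    """
    dialect = dialect or DialectConfig()
    if dialect.units != "mm":
        raise FormatError("writer emits mm units only")
    frames = []
    for traj in trajectories:
        d = {
            dialect.subject_col: traj.subject_id,
            dialect.time_col: traj.t,
            dialect.x_col: traj.x,
            dialect.y_col: traj.y,
        }
        if traj.v is not None and dialect.velocity_col is not None:
            d[dialect.velocity_col] = traj.v
        frames.append(pd.DataFrame(d))
    out = pd.concat(frames, ignore_index=True)
    # repr is the shortest round-trip float form, so re-parsing is bit-exact
    out.to_csv(path_or_buf, sep=dialect.delimiter, index=False,
               float_format=lambda v: repr(float(v)))
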