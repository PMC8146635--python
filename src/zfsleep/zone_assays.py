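"""Zone-occupancy scoring for the social-preference and mirror assays.

Both assays use a rectangular arena divided into bands along its length.
The social arena has a group zone (next to the conspecific shoal), an
individual zone and an empty zone, with the individual zone subdivided into
next-to-group / starting-point / next-to-empty thirds.  The mirror arena has
starting-point / middle / next-to-mirror bands.  Sociability is the time
spent next to the group; aggression is the time spent next to the mirror.

Boundary positions are not physically prescribed, so the default tiling is
equal thirds at both levels, fully overridable.  Zone membership uses
half-open intervals ``[lo, hi)`` with the last zone closed at the far wall,
and a 0.5-mm containment tolerance for tracker jitter.  Each inter-sample
interval is credited to the zone of its starting sample (piecewise-constant
position assumption, unbiased at high sampling rates).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError, RangeError
from .trajectory_io import AnalysisWindow, Trajectory

BOUNDARY_TOL_MM = 0.5

SOCIAL_ZONES = ("group", "individual", "empty")
SOCIAL_SUBZONES = ("next_to_group", "start_point", "next_to_empty")
MIRROR_ZONES = ("start_point", "middle", "next_to_mirror")

# social arena: 40 cm x 10 cm footprint (length x width)
DEFAULT_ARENA_LENGTH_MM = 400.0
DEFAULT_ARENA_WIDTH_MM = 100.0
DEFAULT_ACCLIMATION_S = 30.0
DEFAULT_TEST_DURATION_S = 1200.0


@dataclass(frozen=True)
class Band:
    """Axis-aligned full-width band ``[x_lo, x_hi)`` along the arena length."""

    name: str
    x_lo: float
    x_hi: float

    @property
    def width(self) -> float:
        return self.x_hi - self.x_lo


@dataclass
class ArenaLayout:
    """Named band tiling of a rectangular arena, with optional sub-bands.

    ``zones`` must tile ``[0, arena_length]`` exactly (no overlap, no
    uncovered length); ``sub_zones`` maps one parent zone name to bands that
    tile the parent.
    """

    arena_length: float
    arena_width: float
    zones: list
    sub_zones: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.arena_length <= 0 or self.arena_width <= 0:
            raise GeometryError("arena dimensions must be positive")
        _check_tiling(self.zones, 0.0, self.arena_length, "arena")
        for parent, bands in self.sub_zones.items():
            pband = self.band(parent)
            _check_tiling(bands, pband.x_lo, pband.x_hi, f"zone {parent!r}")

    def band(self, name: str) -> Band:
        for b in self.zones:
            if b.name == name:
                return b
        raise GeometryError(f"no zone named {name!r}")

    @property
    def zone_names(self) -> list:
        return [b.name for b in self.zones]


def _check_tiling(bands, lo: float, hi: float, what: str, tol: float = 1e-6) -> None:
    if not bands:
        raise GeometryError(f"{what}: empty tiling")
    ordered = sorted(bands, key=lambda b: b.x_lo)
    for b in ordered:
        if b.width <= tol:
            raise GeometryError(f"{what}: degenerate zone {b.name!r}")
    if abs(ordered[0].x_lo - lo) > tol or abs(ordered[-1].x_hi - hi) > tol:
        raise GeometryError(f"{what}: zones do not span [{lo}, {hi}]")
    for a, b in zip(ordered[:-1], ordered[1:]):
        if abs(a.x_hi - b.x_lo) > tol:
            verb = "overlap" if a.x_hi > b.x_lo else "leave a gap"
            raise GeometryError(
                f"{what}: zones {a.name!r} and {b.name!r} {verb}"
            )


def _bands_from_boundaries(names, length: float, boundaries, offset: float = 0.0):
    k = len(names)
    if boundaries is None:
        cuts = [offset + length * i / k for i in range(1, k)]
    else:
        cuts = [offset + float(b) for b in boundaries]
        if len(cuts) != k - 1:
            raise GeometryError(
                f"expected {k - 1} boundaries for {k} zones, got {len(cuts)}"
            )
        prev = offset
        for c in cuts:
            if not (prev < c < offset + length):
                raise GeometryError(f"boundary {c - offset} out of range (0, {length})")
            prev = c
    edges = [offset] + cuts + [offset + length]
    return [Band(n, lo, hi) for n, lo, hi in zip(names, edges[:-1], edges[1:])]


def social_arena_layout(
    length_mm: float = DEFAULT_ARENA_LENGTH_MM,
    width_mm: float = DEFAULT_ARENA_WIDTH_MM,
    boundaries=None,
    sub_boundaries=None,
) -> ArenaLayout:
    """Group / individual / empty tiling, individual zone split into thirds.

    ``boundaries`` are the two internal cuts (mm from the group-side wall);
    default is equal thirds.  ``sub_boundaries`` are the two cuts inside the
    individual zone, relative to its own start; default equal sub-thirds,
    ordered next-to-group, starting point, next-to-empty.
    """
    zones = _bands_from_boundaries(SOCIAL_ZONES, length_mm, boundaries)
    iz = zones[1]
    sub = _bands_from_boundaries(
        SOCIAL_SUBZONES, iz.width, sub_boundaries, offset=iz.x_lo
    )
    return ArenaLayout(length_mm, width_mm, zones, {"individual": sub})


def mirror_arena_layout(
    length_mm: float = DEFAULT_ARENA_LENGTH_MM,
    width_mm: float = DEFAULT_ARENA_WIDTH_MM,
    boundaries=None,
) -> ArenaLayout:
    """Starting-point / middle / next-to-mirror tiling (mirror at far wall)."""
    zones = _bands_from_boundaries(MIRROR_ZONES, length_mm, boundaries)
    return ArenaLayout(length_mm, width_mm, zones)


# ---------------------------------------------------------------------------
# point-in-zone
# ---------------------------------------------------------------------------

def _zone_indices(layout: ArenaLayout, x: np.ndarray, y: np.ndarray,
                  eps: float = BOUNDARY_TOL_MM) -> np.ndarray:
    """Vectorised zone index per point; -1 marks out-of-arena beyond eps."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    out = (
        (x < -eps)
        | (x > layout.arena_length + eps)
        | (y < -eps)
        | (y > layout.arena_width + eps)
    )
    xc = np.clip(x, 0.0, layout.arena_length)
    edges = np.array([b.x_lo for b in layout.zones][1:])
    idx = np.searchsorted(edges, xc, side="right")
    idx[out] = -1
    return idx


def assign_zone(
    x: float, y: float, layout: ArenaLayout, eps: float = BOUNDARY_TOL_MM
) -> tuple[str, str | None] | None:
    """Zone (and sub-zone when the zone is subdivided) containing a point.

    Returns None for points outside the arena beyond the tolerance; such
    samples are counted as missing by :func:`occupancy`.  A point exactly on
    an internal boundary belongs to the right-hand zone (half-open rule);
    ``x == arena_length`` belongs to the last zone.
    """
    idx = int(_zone_indices(layout, np.array([x]), np.array([y]), eps)[0])
    if idx < 0:
        return None
    zone = layout.zones[idx]
    sub = None
    if zone.name in layout.sub_zones:
        bands = layout.sub_zones[zone.name]
        edges = np.array([b.x_lo for b in bands][1:])
        xc = min(max(float(x), zone.x_lo), zone.x_hi)
        sub = bands[int(np.searchsorted(edges, xc, side="right"))].name
    return zone.name, sub


# ---------------------------------------------------------------------------
# occupancy
# ---------------------------------------------------------------------------

@dataclass
class ZoneOccupancy:
    """Time spent per zone (and sub-zone) over one analysis window."""

    subject_id: str
    seconds_per_zone: dict
    sub_zone_seconds: dict
    recorded_s: float
    out_of_arena_s: float
    uncovered_s: float  # window time before the first sample

    @property
    def missing_s(self) -> float:
        return self.out_of_arena_s + self.uncovered_s

    def to_dict(self) -> dict:
        d = {"subject_id": self.subject_id, "recorded_s": self.recorded_s,
             "out_of_arena_s": self.out_of_arena_s}
        d.update({f"zone_{k}_s": v for k, v in self.seconds_per_zone.items()})
        for parent, subs in self.sub_zone_seconds.items():
            d.update({f"{parent}_{k}_s": v for k, v in subs.items()})
        return d


def occupancy(
    traj: Trajectory,
    layout: ArenaLayout,
    window: AnalysisWindow,
    eps: float = BOUNDARY_TOL_MM,
) -> ZoneOccupancy:
    """Credit each inter-sample interval to the zone of its starting sample.

    The interval of the last sample extends to the window end.  Window time
    before the first sample, and intervals starting out of arena, count as
    missing.  Conservation: zone seconds + missing = window length.
    """
    start, end = window.start_s, window.end_s
    t = traj.t
    if t.size == 0 or t[0] >= end:
        raise RangeError(
            f"subject {traj.subject_id!r}: no samples inside window"
        )
    # interval i runs from t[i] to t[i+1] (sentinel: window end)
    t_next = np.concatenate((t[1:], [max(end, t[-1])]))
    lo = np.maximum(t, start)
    hi = np.minimum(t_next, end)
    dur = np.clip(hi - lo, 0.0, None)
    active = dur > 0

    idx = _zone_indices(layout, traj.x, traj.y, eps)
    names = layout.zone_names
    seconds = {}
    for k, name in enumerate(names):
        seconds[name] = float(dur[active & (idx == k)].sum())
    out_s = float(dur[active & (idx == -1)].sum())
    uncovered = float(max(t[0] - start, 0.0))

    sub_seconds: dict = {}
    for parent, bands in layout.sub_zones.items():
        pidx = names.index(parent)
        in_parent = active & (idx == pidx)
        edges = np.array([b.x_lo for b in bands][1:])
        pband = layout.band(parent)
        xc = np.clip(traj.x, pband.x_lo, pband.x_hi)
        sidx = np.searchsorted(edges, xc, side="right")
        sub_seconds[parent] = {
            b.name: float(dur[in_parent & (sidx == j)].sum())
            for j, b in enumerate(bands)
        }

    return ZoneOccupancy(
        subject_id=traj.subject_id,
        seconds_per_zone=seconds,
        sub_zone_seconds=sub_seconds,
        recorded_s=float(end - start),
        out_of_arena_s=out_s,
        uncovered_s=uncovered,
    )
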