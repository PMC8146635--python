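"""Synthetic trajectory cohorts with the structure the scoring assumes.

The latent behavior model is a per-second two-state (wake/sleep) Markov
chain, realised by drawing alternating geometrically distributed bout
lengths (the exact bout-length law of the per-second chain).  Transition
probabilities are phase-dependent (light vs dark), so cohorts show the
day/night activity structure of larval recordings.

Within each second the subject emits position samples at the configured
rate.  Sleep-second sample speeds are drawn from a slow log-normal clipped
below the movement threshold, so a sleeping second can never be scored
MOVING.  Wake seconds mix the same slow baseline with a fixed fraction of
"burst" samples drawn strictly above the threshold, so a waking second is
always scored MOVING while the mean swim speed stays at realistic sub-mm/s
levels.  Positions follow a bounded random walk (reflecting walls) whose
per-sample step lengths match the emitted speeds.

Group presets are calibrated, via closed forms of the latent chain, to the
reference cohort means used throughout the package: scored sleep-bout mean
~11.2-11.5 s, scored sleep ratio ~0.43-0.46, night swim velocity
0.18-0.31 mm/s, with the 72-h-exposure group showing night hyperactivity
(velocity ~x1.7) and reduced fragmentation relative to control.

Closed forms used for calibration and as simulation oracles (geometric bout
length L with success p, q = 1 - p, scoring threshold m seconds):

* stationary sleep fraction  pi = p_fs / (p_fs + p_wu)
* P(L >= m) = q^(m-1);  E[L] = 1/p
* E[L; L >= m] = q^(m-1) * ((m-1) p + 1) / p   (memorylessness)
* scored sleep ratio = pi * q^(m-1) * ((m-1) p_wu + 1)
* scored mean sleep bout = (m - 1) + 1 / p_wu
* scored mean wake bout merges latent wake bouts with sub-threshold sleep
  runs: with N = q^-(m-1) latent wake bouts per scored wake bout,
  E = N / p_fs + (N - 1) * E[L | L < m].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigError, ValidationError
from .sleep_scoring import ScoringParams
from .trajectory_io import (
    DAY,
    LightSchedule,
    Trajectory,
    phase_windows,
)
from .zone_assays import ArenaLayout

WAKE_STATE = 1
SLEEP_STATE = 0

# default well footprint for a single larva (96-well plate), mm
DEFAULT_WELL_MM = 6.4


@dataclass(frozen=True)
class StateParams:
    """Emission and transition parameters of one latent phase-state.

    ``p_fall_asleep``/``p_wake_up`` are per-second transition probabilities;
    ``wake_speed_mean``/``wake_speed_sd`` parameterise the supra-threshold
    burst-sample speeds of wake seconds (mm/s, mean above the movement
    threshold); ``sleep_speed_mean`` the sub-threshold baseline speed; and
    ``burst_fraction`` the fraction of samples within a wake second that are
    bursts.
    """

    p_fall_asleep: float
    p_wake_up: float
    wake_speed_mean: float = 2.0
    wake_speed_sd: float = 0.8
    sleep_speed_mean: float = 0.1
    sleep_speed_sd: float = 0.05
    burst_fraction: float = 0.12

    def __post_init__(self) -> None:
        for name in ("p_fall_asleep", "p_wake_up"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1]")
        if self.p_fall_asleep + self.p_wake_up <= 0:
            raise ValidationError("at least one transition probability must be > 0")
        if not 0 < self.burst_fraction <= 1:
            raise ValidationError("burst_fraction must be in (0, 1]")
        if self.sleep_speed_mean < 0 or self.wake_speed_mean <= 0:
            raise ValidationError("speeds must be non-negative")


@dataclass(frozen=True)
class GroupPreset:
    """Phase-dependent latent parameters for one experimental group."""

    group_label: str
    day: StateParams
    night: StateParams
    multipliers: dict = field(default_factory=dict)  # vs control, metadata


@dataclass(frozen=True)
class CohortSpec:
    """Cohort geometry: group size, recording length, sampling rate, seed."""

    n_per_group: int = 30
    duration_s: int = 86400
    sample_rate: float = 25.0
    seed: int = 0
    subject_speed_cv: float = 0.30  # between-subject log-normal speed spread
    well_mm: float = DEFAULT_WELL_MM

    def __post_init__(self) -> None:
        if self.n_per_group < 1 or self.duration_s <= 0 or self.sample_rate <= 0:
            raise ValidationError("invalid cohort spec")


# ---------------------------------------------------------------------------
# closed forms
# ---------------------------------------------------------------------------

def analytic_sleep_fraction(sp: StateParams) -> float:
    """Stationary latent sleep probability p_fs / (p_fs + p_wu).

    The *scored* sleep ratio is lower because latent sleep runs shorter than
    the sleep-period threshold are scored as wake; see
    :func:`expected_scored_sleep_ratio`.
    """
    return sp.p_fall_asleep / (sp.p_fall_asleep + sp.p_wake_up)


def expected_scored_sleep_bout_s(sp: StateParams, threshold_s: int = 6) -> float:
    """Mean scored sleep-bout duration: (m-1) + 1/p_wu by memorylessness."""
    if sp.p_wake_up == 0:
        return float("inf")
    return (threshold_s - 1) + 1.0 / sp.p_wake_up


def expected_scored_sleep_ratio(sp: StateParams, threshold_s: int = 6) -> float:
    """Fraction of seconds inside scored (>= threshold) sleep runs."""
    p = sp.p_wake_up
    if p == 0:
        return analytic_sleep_fraction(sp)
    q = 1.0 - p
    frac_long = q ** (threshold_s - 1) * ((threshold_s - 1) * p + 1.0)
    return analytic_sleep_fraction(sp) * frac_long


def expected_scored_wake_bout_s(sp: StateParams, threshold_s: int = 6) -> float:
    """Mean scored wake-bout duration (latent wake + sub-threshold sleep runs)."""
    p_fs, p_wu = sp.p_fall_asleep, sp.p_wake_up
    if p_fs == 0:
        return float("inf")
    if p_wu == 0:
        return 1.0 / p_fs
    q = 1.0 - p_wu
    p_long = q ** (threshold_s - 1)
    mean_l = 1.0 / p_wu
    mean_long_part = p_long * ((threshold_s - 1) * p_wu + 1.0) / p_wu
    mean_short = (
        (mean_l - mean_long_part) / (1.0 - p_long) if p_long < 1.0 else 0.0
    )
    n_latent = 1.0 / p_long
    return n_latent / p_fs + (n_latent - 1.0) * mean_short


def expected_velocity(sp: StateParams, threshold: float = 1.0) -> float:
    """Expected swim velocity (mm/s) under the emission model."""
    pi_sleep = analytic_sleep_fraction(sp)
    pi_wake = 1.0 - pi_sleep
    bf = sp.burst_fraction
    wake_mean = bf * sp.wake_speed_mean + (1 - bf) * sp.sleep_speed_mean
    return pi_wake * wake_mean + pi_sleep * sp.sleep_speed_mean


def calibrate_state_params(
    sleep_bout_s: float,
    sleep_ratio: float,
    velocity: float,
    threshold_s: int = 6,
    movement_threshold: float = 1.0,
    sleep_speed_mean: float = 0.1,
    burst_fraction: float = 0.12,
) -> StateParams:
    """Invert the closed forms: target scored statistics -> StateParams.

    Solves p_wu from the scored sleep-bout mean, p_fs from the scored sleep
    ratio, and the burst speed from the velocity target, holding the
    baseline speed and burst fraction fixed.
    """
    if sleep_bout_s <= threshold_s - 1:
        raise ConfigError("target sleep bout must exceed threshold - 1 seconds")
    p_wu = 1.0 / (sleep_bout_s - (threshold_s - 1))
    q = 1.0 - p_wu
    frac_long = q ** (threshold_s - 1) * ((threshold_s - 1) * p_wu + 1.0)
    pi = sleep_ratio / frac_long
    if not 0 < pi < 1:
        raise ConfigError("sleep-ratio target unreachable for this bout target")
    p_fs = pi * p_wu / (1.0 - pi)
    pi_wake = 1.0 - pi
    base = sleep_speed_mean * (1.0 - pi_wake * burst_fraction)
    wake_speed_mean = (velocity - base) / (pi_wake * burst_fraction)
    if wake_speed_mean <= movement_threshold:
        raise ConfigError(
            f"velocity target {velocity} mm/s requires burst speed below the "
            f"movement threshold; lower sleep_speed_mean or burst_fraction"
        )
    return StateParams(
        p_fall_asleep=p_fs,
        p_wake_up=p_wu,
        wake_speed_mean=wake_speed_mean,
        sleep_speed_mean=sleep_speed_mean,
        burst_fraction=burst_fraction,
    )


# ---------------------------------------------------------------------------
# reference cohort means (calibration targets, stored as data)
# ---------------------------------------------------------------------------

# night sleep parameters per group: cohort means the presets are tuned to.
REFERENCE_SLEEP_PARAMS = {
    "group1": {"fragmentation": 142.19, "sleep_ratio": 0.445, "velocity": 0.18,
               "total_distance": 296.7, "mean_wake_bout_s": 14.094,
               "mean_sleep_bout_s": 11.513},
    "group2": {"fragmentation": 147.74, "sleep_ratio": 0.455, "velocity": 0.21,
               "total_distance": 256.7, "mean_wake_bout_s": 13.293,
               "mean_sleep_bout_s": 11.208},
    "group3": {"fragmentation": 147.67, "sleep_ratio": 0.456, "velocity": 0.18,
               "total_distance": 237.4, "mean_wake_bout_s": 13.261,
               "mean_sleep_bout_s": 11.237},
    "group4": {"fragmentation": 133.78, "sleep_ratio": 0.426, "velocity": 0.31,
               "total_distance": 467.4, "mean_wake_bout_s": 16.701,
               "mean_sleep_bout_s": 11.379},
}

# daytime targets: day swim velocities per group; larvae sleep little in the
# light, so a nominal low day sleep ratio and short bout target are shared.
REFERENCE_DAY_PARAMS = {
    "group1": {"velocity": 0.30, "sleep_ratio": 0.05, "mean_sleep_bout_s": 8.0},
    "group2": {"velocity": 0.34, "sleep_ratio": 0.05, "mean_sleep_bout_s": 8.0},
    "group3": {"velocity": 0.27, "sleep_ratio": 0.05, "mean_sleep_bout_s": 8.0},
    "group4": {"velocity": 0.48, "sleep_ratio": 0.05, "mean_sleep_bout_s": 8.0},
}

CONTROL_GROUP = "group1"

# time-in-zone targets for the social-preference assay (fraction of the
# 1200-s test in the group zone; control 451.6 s / 1200 s = 0.376)
REFERENCE_GROUP_ZONE_S = {
    "group1": 451.6, "group2": 362.0, "group3": 336.4, "group4": 217.6,
}
SOCIAL_TEST_DURATION_S = 1200.0


def default_presets(
    movement_threshold: float = 1.0, sleep_threshold_s: int = 6
) -> dict:
    """The four calibrated group presets keyed by group label."""
    presets = {}
    ctrl_n = REFERENCE_SLEEP_PARAMS[CONTROL_GROUP]
    ctrl_night = None
    for label in REFERENCE_SLEEP_PARAMS:
        nt = REFERENCE_SLEEP_PARAMS[label]
        dt = REFERENCE_DAY_PARAMS[label]
        night = calibrate_state_params(
            nt["mean_sleep_bout_s"], nt["sleep_ratio"], nt["velocity"],
            threshold_s=sleep_threshold_s, movement_threshold=movement_threshold,
        )
        day = calibrate_state_params(
            dt["mean_sleep_bout_s"], dt["sleep_ratio"], dt["velocity"],
            threshold_s=sleep_threshold_s, movement_threshold=movement_threshold,
        )
        if label == CONTROL_GROUP:
            ctrl_night = night
        presets[label] = GroupPreset(
            group_label=label,
            day=day,
            night=night,
            multipliers={
                "velocity": nt["velocity"] / ctrl_n["velocity"],
                "p_fall_asleep": night.p_fall_asleep / ctrl_night.p_fall_asleep,
                "p_wake_up": night.p_wake_up / ctrl_night.p_wake_up,
            },
        )
    return presets


# ---------------------------------------------------------------------------
# latent state simulation
# ---------------------------------------------------------------------------

def _geometric(rng: np.random.Generator, p: float, size: int, cap: int) -> np.ndarray:
    if p >= 1.0:
        return np.ones(size, dtype=np.int64)
    if p <= 0.0:
        return np.full(size, cap, dtype=np.int64)
    return rng.geometric(p, size=size)


def simulate_latent_states(
    rng: np.random.Generator,
    sp: StateParams,
    n_seconds: int,
    initial_state: int | None = None,
) -> np.ndarray:
    """Per-second latent states (1 = wake, 0 = sleep) via geometric bouts."""
    if initial_state is None:
        initial_state = (
            WAKE_STATE if rng.random() >= analytic_sleep_fraction(sp) else SLEEP_STATE
        )
    states = np.empty(n_seconds, dtype=np.int8)
    filled = 0
    cur = int(initial_state)
    mean_bout = min(
        1.0 / sp.p_fall_asleep if sp.p_fall_asleep > 0 else float(n_seconds),
        1.0 / sp.p_wake_up if sp.p_wake_up > 0 else float(n_seconds),
    )
    while filled < n_seconds:
        remaining = n_seconds - filled
        batch = max(16, int(remaining / max(mean_bout, 1.0) / 2) + 8)
        p_first = sp.p_fall_asleep if cur == WAKE_STATE else sp.p_wake_up
        p_other = sp.p_wake_up if cur == WAKE_STATE else sp.p_fall_asleep
        lens_a = _geometric(rng, p_first, batch, remaining)
        lens_b = _geometric(rng, p_other, batch, remaining)
        lengths = np.empty(2 * batch, dtype=np.int64)
        lengths[0::2] = lens_a
        lengths[1::2] = lens_b
        vals = np.empty(2 * batch, dtype=np.int8)
        vals[0::2] = cur
        vals[1::2] = 1 - cur
        total = np.cumsum(lengths)
        if total[-1] >= remaining:
            # bout containing the last needed second
            stop = int(np.searchsorted(total, remaining, side="left"))
            chunk = np.repeat(vals[: stop + 1], lengths[: stop + 1])[:remaining]
            states[filled : filled + remaining] = chunk
            filled = n_seconds
            # by memorylessness a bout truncated at the fill boundary may be
            # continued with a fresh draw of the same state; only an exact
            # boundary alignment forces the flip
            cur = int(1 - vals[stop]) if total[stop] == remaining else int(vals[stop])
        else:
            chunk = np.repeat(vals, lengths)
            states[filled : filled + chunk.size] = chunk
            filled += chunk.size
            cur = int(1 - vals[-1])
    return states


def _lognormal(rng, mean: float, sd: float, size) -> np.ndarray:
    if mean <= 0:
        return np.zeros(size)
    s2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - s2 / 2.0
    return rng.lognormal(mu, math.sqrt(s2), size)


def _fold(p: np.ndarray, length: float) -> np.ndarray:
    """Reflect an unbounded coordinate into [0, length] (triangle fold)."""
    return length - np.abs(np.mod(p, 2.0 * length) - length)


def simulate_trajectory(
    preset: GroupPreset,
    spec: CohortSpec,
    schedule: LightSchedule,
    subject_seed,
    subject_id: str = "fish",
    scoring: ScoringParams | None = None,
    speed_multiplier: float = 1.0,
) -> Trajectory:
    """One subject's 2-D trajectory under the phase-dependent bout model.

    Identical ``subject_seed`` (plus preset/spec/schedule) reproduces the
    trajectory bit for bit.  Raises :class:`ConfigError` when the emission
    parameters are inconsistent with the movement threshold ordering.
    """
    scoring = scoring or ScoringParams()
    thr = scoring.movement_threshold
    for sp in (preset.day, preset.night):
        if not sp.sleep_speed_mean < thr:
            raise ConfigError("sleep_speed_mean must lie below the movement threshold")
        if not sp.wake_speed_mean > thr:
            raise ConfigError("wake_speed_mean must lie above the movement threshold")

    rng = np.random.default_rng(subject_seed)
    n_sec = int(spec.duration_s)

    # latent states per second, phase by phase
    states = np.empty(n_sec, dtype=np.int8)
    phase_of_sec = np.empty(n_sec, dtype=np.int8)  # 1 = DAY
    cur: int | None = None
    for window, ph in phase_windows(schedule, n_sec):
        s0, s1 = int(window.start_s), int(window.end_s)
        sp = preset.day if ph == DAY else preset.night
        seg = simulate_latent_states(rng, sp, s1 - s0, initial_state=cur)
        states[s0:s1] = seg
        phase_of_sec[s0:s1] = 1 if ph == DAY else 0
        cur = int(seg[-1])

    # emission: per-sample speeds
    rate = spec.sample_rate
    n_samp = int(round(n_sec * rate))
    t = np.arange(n_samp) / rate
    sec_idx = np.minimum(np.floor(t).astype(np.int64), n_sec - 1)
    state_s = states[sec_idx]
    day_s = phase_of_sec[sec_idx]

    speeds = np.empty(n_samp)
    burst_mask = np.zeros(n_samp, dtype=bool)
    n_per_sec = max(int(round(rate)), 1)
    offsets = np.arange(n_samp) % n_per_sec
    for is_day, sp in ((1, preset.day), (0, preset.night)):
        msk = day_s == is_day
        n = int(msk.sum())
        if n == 0:
            continue
        slow = _lognormal(rng, sp.sleep_speed_mean, sp.sleep_speed_sd, n)
        slow = np.minimum(slow, thr * 0.999)  # sleep samples never exceed
        speeds[msk] = slow
        # burst samples inside wake seconds: a rotating sub-grid within each
        # second, at least one per wake second
        nb = max(1, int(round(sp.burst_fraction * n_per_sec)))
        rot = rng.integers(0, n_per_sec, size=n_sec)[sec_idx[msk]]
        is_burst = ((offsets[msk] - rot) % n_per_sec < nb) & (
            state_s[msk] == WAKE_STATE
        )
        nburst = int(is_burst.sum())
        if nburst:
            burst = thr + _lognormal(
                rng, sp.wake_speed_mean - thr, sp.wake_speed_sd, nburst
            )
            tmp = speeds[msk]
            tmp[is_burst] = burst
            speeds[msk] = tmp
        bm = burst_mask[msk]
        bm |= is_burst
        burst_mask[msk] = bm
    # non-burst samples of wake seconds keep the slow baseline; sleep seconds
    # are entirely sub-threshold.  After subject-level scaling, bursts are
    # kept strictly supra-threshold and sleep samples strictly below, so the
    # scored mobility of a second reflects its latent state exactly.
    speeds *= speed_multiplier
    speeds[burst_mask] = np.maximum(speeds[burst_mask], thr * 1.001)
    sleep_samples = state_s == SLEEP_STATE
    speeds[sleep_samples] = np.minimum(speeds[sleep_samples], thr * 0.999)

    headings = rng.uniform(0.0, 2.0 * np.pi, n_samp)
    step = speeds / rate
    L = spec.well_mm
    x = _fold(L / 2.0 + np.cumsum(step * np.cos(headings)), L)
    y = _fold(L / 2.0 + np.cumsum(step * np.sin(headings)), L)

    return Trajectory(
        subject_id=subject_id,
        t=t,
        x=x,
        y=y,
        v=speeds.copy(),
        group_label=preset.group_label,
        arena_id="well",
        nominal_rate=rate,
    )


def simulate_cohort(
    presets: dict,
    spec: CohortSpec,
    schedule: LightSchedule,
    scoring: ScoringParams | None = None,
) -> list:
    """Independent subjects for every preset; one root seed spawns
    per-subject substreams, so output is reproducible and order-independent."""
    root = np.random.SeedSequence(spec.seed)
    children = root.spawn(len(presets) * spec.n_per_group)
    out = []
    i = 0
    for label in presets:
        preset = presets[label]
        for j in range(spec.n_per_group):
            child = children[i]
            i += 1
            mult_rng = np.random.default_rng(child.spawn(1)[0])
            mult = (
                float(_lognormal(mult_rng, 1.0, spec.subject_speed_cv, 1)[0])
                if spec.subject_speed_cv > 0
                else 1.0
            )
            out.append(
                simulate_trajectory(
                    preset,
                    spec,
                    schedule,
                    subject_seed=child,
                    subject_id=f"{label}_s{j:02d}",
                    scoring=scoring,
                    speed_multiplier=mult,
                )
            )
    return out


# ---------------------------------------------------------------------------
# zone-biased walks
# ---------------------------------------------------------------------------

def simulate_zone_walk(
    layout: ArenaLayout,
    stationary_zone_probs: dict,
    duration_s: float,
    seed,
    sample_rate: float = 5.0,
    step_sd_mm: float = 15.0,
) -> Trajectory:
    """Metropolis random walk whose stationary zone occupancy matches a target.

    The target density is piecewise constant: probability mass
    ``stationary_zone_probs[zone]`` spread uniformly over each zone.  Steps
    are isotropic Gaussian proposals accepted with the density ratio, so the
    long-run time in each zone converges to the target.  The start position
    is drawn from the target distribution (no burn-in bias).
    """
    names = layout.zone_names
    probs = dict(stationary_zone_probs)
    unknown = set(probs) - set(names)
    if unknown:
        raise ConfigError(f"unknown zones in target: {sorted(unknown)}")
    p = np.array([float(probs.get(n, 0.0)) for n in names])
    if abs(p.sum() - 1.0) > 1e-9:
        raise ConfigError(f"zone probabilities sum to {p.sum()!r}, expected 1")
    if np.any(p < 0):
        raise ConfigError("zone probabilities must be non-negative")

    rng = np.random.default_rng(seed)
    bands = layout.zones
    widths = np.array([b.width for b in bands])
    dens = np.where(widths > 0, p / widths, 0.0)  # per-mm density along length
    edges = np.array([b.x_lo for b in bands][1:])

    def density(x):
        idx = np.searchsorted(edges, x, side="right")
        return dens[idx]

    n = int(round(duration_s * sample_rate))
    # start at stationarity
    z0 = rng.choice(len(bands), p=p)
    x0 = rng.uniform(bands[z0].x_lo, bands[z0].x_hi)
    y0 = rng.uniform(0.0, layout.arena_width)

    prop = rng.normal(0.0, step_sd_mm, size=(n, 2))
    accept_u = rng.random(n)
    xs = np.empty(n)
    ys = np.empty(n)
    x, y = x0, y0
    L, W = layout.arena_length, layout.arena_width
    dcur = float(density(np.array([x]))[0])
    for i in range(n):
        nx = float(_fold(np.array([x + prop[i, 0]]), L)[0])
        ny = float(_fold(np.array([y + prop[i, 1]]), W)[0])
        dnew = float(density(np.array([nx]))[0])
        if dcur <= 0 or accept_u[i] * dcur <= dnew:
            x, y, dcur = nx, ny, dnew
        xs[i] = x
        ys[i] = y
    t = np.arange(n) / sample_rate
    return Trajectory(
        subject_id="walk",
        t=t,
        x=xs,
        y=ys,
        group_label="",
        arena_id="assay_arena",
        nominal_rate=sample_rate,
    )


def scale_preset_velocity(preset: GroupPreset, factor: float) -> GroupPreset:
    """Scale all emission speeds (not transition structure) of a preset."""
    def scale(sp: StateParams) -> StateParams:
        return replace(
            sp,
            wake_speed_mean=sp.wake_speed_mean * factor,
            wake_speed_sd=sp.wake_speed_sd * factor,
            sleep_speed_mean=sp.sleep_speed_mean * factor,
            sleep_speed_sd=sp.sleep_speed_sd * factor,
        )
    return replace(preset, day=scale(preset.day), night=scale(preset.night))
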