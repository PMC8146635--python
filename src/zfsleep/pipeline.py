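"""End-to-end orchestration: config -> per-subject metrics -> group reports.

A run either parses tracking tables or simulates a cohort, scores sleep over
the configured night window, computes per-phase locomotor summaries, runs the
group statistics, and writes tidy CSVs plus a machine-readable manifest
(package version, seed, config hash, content hash of every output).
Identical config and seed reproduce byte-identical metric files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import ConfigError, NormalizationError, ZfSleepError
from .group_stats import (
    multivariate_comparison,
    summaries_frame,
    summarize_groups,
    tukey_hsd,
)
from .locomotor_metrics import phase_summary
from .sleep_scoring import METRIC_COLUMNS, ScoringParams, score_sleep
from .synthetic_data import CohortSpec, default_presets, simulate_cohort
from .trajectory_io import (
    DAY,
    FULL,
    NIGHT,
    DialectConfig,
    LightSchedule,
    compute_sample_velocities,
    map_clock_window,
    parse_tracking_table,
)

log = logging.getLogger("zfsleep")

DEFAULT_SLEEP_WINDOW = ("22:00", "08:00")


@dataclass
class RunConfig:
    """Validated run configuration (see :func:`run_config_from_dict`)."""

    outdir: Path
    seed: int = 0
    schedule: LightSchedule = field(default_factory=LightSchedule)
    scoring: ScoringParams = field(default_factory=ScoringParams)
    sleep_window_clock: tuple = DEFAULT_SLEEP_WINDOW
    input_path: Path | None = None
    dialect: DialectConfig = field(default_factory=DialectConfig)
    group_map: dict | None = None
    simulate: CohortSpec | None = None
    simulate_groups: tuple = ("group1", "group2", "group3", "group4")
    control_label: str = "group1"
    alpha: float = 0.05
    manova_metrics: tuple = tuple(METRIC_COLUMNS)


def run_config_from_dict(cfg: dict, outdir=None) -> RunConfig:
    """Build a RunConfig from a plain dict (parsed YAML/JSON)."""
    cfg = dict(cfg)
    out = Path(outdir or cfg.get("outdir", "zfsleep_out"))
    sched = LightSchedule(**cfg.get("schedule", {}))
    scoring = ScoringParams(**cfg.get("scoring", {}))
    window = tuple(cfg.get("sleep_window", DEFAULT_SLEEP_WINDOW))
    seed = int(cfg.get("seed", 0))

    input_path = cfg.get("input")
    group_map = cfg.get("group_map")
    sim_cfg = cfg.get("simulate")
    if input_path is None and sim_cfg is None:
        raise ConfigError("config needs either an 'input' table or a 'simulate' block")
    if input_path is not None and group_map is None:
        raise ConfigError("config with an 'input' table requires a 'group_map'")

    sim = None
    groups = ("group1", "group2", "group3", "group4")
    if sim_cfg is not None:
        sim_cfg = dict(sim_cfg)
        groups = tuple(sim_cfg.pop("groups", groups))
        sim = CohortSpec(seed=seed, **sim_cfg)

    stats_cfg = dict(cfg.get("stats", {}))
    return RunConfig(
        outdir=out,
        seed=seed,
        schedule=sched,
        scoring=scoring,
        sleep_window_clock=window,
        input_path=Path(input_path) if input_path else None,
        dialect=DialectConfig(**cfg.get("dialect", {})),
        group_map=group_map,
        simulate=sim,
        simulate_groups=groups,
        control_label=cfg.get("control_label", "group1"),
        alpha=float(stats_cfg.get("alpha", 0.05)),
        manova_metrics=tuple(stats_cfg.get("metrics", METRIC_COLUMNS)),
    )


def normalize_to_control(group_means: pd.DataFrame, control_label: str) -> pd.DataFrame:
    """Divide every parameter's group mean by the control group's mean.

    The control row becomes 1 for every parameter; a zero control mean
    raises :class:`NormalizationError` naming the parameter.
    """
    if control_label not in group_means.index:
        raise NormalizationError(f"control group {control_label!r} absent")
    ctrl = group_means.loc[control_label]
    for col, val in ctrl.items():
        if val == 0 or not np.isfinite(val):
            raise NormalizationError(
                f"control mean for {col!r} is {val}; cannot normalize"
            )
    return group_means.div(ctrl, axis=1)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_trajectories(config: RunConfig):
    if config.simulate is not None:
        presets = {g: default_presets()[g] for g in config.simulate_groups}
        log.info("simulating cohort: %d groups x %d subjects",
                 len(presets), config.simulate.n_per_group)
        return simulate_cohort(presets, config.simulate, config.schedule,
                               scoring=config.scoring)
    trajs, report = parse_tracking_table(
        str(config.input_path), config.dialect, group_map=config.group_map
    )
    log.info("parsed %d rows (%d rejected) -> %d subjects",
             report.rows_read, report.rows_rejected, len(trajs))
    missing = [t.subject_id for t in trajs if not t.group_label]
    if missing:
        raise ConfigError(f"subjects without a group assignment: {missing}")
    return [compute_sample_velocities(t) if t.v is None else t for t in trajs]


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis and write the result bundle to ``outdir``.

    Returns a dict with the in-memory DataFrames and output paths.  Any
    stage error aborts with the stage name and offending subject attached.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    trajs = _load_trajectories(config)

    duration = max(float(np.ceil(t.t[-1] + 1e-9)) for t in trajs)
    window = map_clock_window(
        config.schedule, *config.sleep_window_clock, recording_duration_s=duration
    )

    sleep_rows, bout_rows, loco_rows = [], [], []
    for traj in trajs:
        try:
            metrics, seg = score_sleep(traj, window, config.scoring)
        except ZfSleepError as exc:
            raise type(exc)(f"sleep_scoring[{traj.subject_id}]: {exc}") from exc
        sleep_rows.append(metrics.to_dict())
        for b in seg.bouts:
            bout_rows.append(
                {"subject_id": traj.subject_id, "state": b.state,
                 "start_s": b.start_s, "duration_s": b.duration_s,
                 "truncated_start": b.truncated_start,
                 "truncated_end": b.truncated_end}
            )
        for phase in (DAY, NIGHT, FULL):
            try:
                loco_rows.append(
                    phase_summary(traj, config.schedule, config.scoring, phase,
                                  duration_s=duration).to_dict()
                )
            except ZfSleepError as exc:
                raise type(exc)(
                    f"locomotor_metrics[{traj.subject_id}/{phase}]: {exc}"
                ) from exc
        log.info("scored %s: %d bouts", traj.subject_id, len(seg.bouts))

    sleep_df = pd.DataFrame(sleep_rows).sort_values("subject_id", ignore_index=True)
    bouts_df = pd.DataFrame(bout_rows)
    loco_df = pd.DataFrame(loco_rows).sort_values(
        ["subject_id", "phase"], ignore_index=True
    )

    # group summaries + comparisons over the sleep-parameter set
    summaries, comparisons = [], []
    groups = sorted(sleep_df["group_label"].unique())
    for metric in METRIC_COLUMNS:
        by_group = {
            g: sleep_df.loc[sleep_df.group_label == g, metric].dropna().to_numpy()
            for g in groups
        }
        for s in summarize_groups(by_group):
            summaries.append({"metric": metric, **s.to_dict()})
        if len(groups) >= 2 and all(v.size >= 2 for v in by_group.values()):
            try:
                res = tukey_hsd(by_group, alpha=config.alpha)
            except ZfSleepError:
                continue
            for a, b, est, p, sig in res.pairwise:
                comparisons.append(
                    {"metric": metric, "test": "tukey_hsd", "group_a": a,
                     "group_b": b, "estimate": est, "adjusted_p": p,
                     "significant": sig, "anova_F": res.statistic,
                     "anova_p": res.p_value}
                )
    summary_df = pd.DataFrame(summaries)
    comparison_df = pd.DataFrame(comparisons)

    manova = None
    if len(groups) >= 2:
        mats = {}
        usable = [m for m in config.manova_metrics if m in sleep_df.columns]
        sub = sleep_df.dropna(subset=usable)
        for g in groups:
            mats[g] = sub.loc[sub.group_label == g, usable].to_numpy(float)
        try:
            manova = multivariate_comparison(
                mats, alpha=config.alpha, metric_names=list(usable)
            )
        except ZfSleepError as exc:
            log.warning("group_stats[manova]: %s", exc)

    means = summary_df.pivot(index="group_label", columns="metric", values="mean")
    means = means[[m for m in METRIC_COLUMNS if m in means.columns]]
    try:
        ratios = normalize_to_control(means, config.control_label)
    except NormalizationError as exc:
        log.warning("reporting[ratios]: %s", exc)
        ratios = None

    paths = {}
    outputs = {
        "sleep_metrics.csv": sleep_df,
        "bouts.csv": bouts_df,
        "locomotor.csv": loco_df,
        "group_summaries.csv": summary_df,
        "comparisons.csv": comparison_df,
    }
    if ratios is not None:
        outputs["control_ratios.csv"] = ratios.reset_index()
    for name, df in outputs.items():
        p = out / name
        df.to_csv(p, index=False)
        paths[name] = p

    manifest = {
        "package": "zfsleep",
        "version": __version__,
        "seed": config.seed,
        "n_subjects": len(trajs),
        "sleep_window_s": [window.start_s, window.end_s],
        "config_hash": hashlib.sha256(
            json.dumps(
                {"seed": config.seed, "alpha": config.alpha,
                 "window": list(config.sleep_window_clock),
                 "threshold": config.scoring.movement_threshold,
                 "sleep_period": config.scoring.sleep_period_threshold},
                sort_keys=True,
            ).encode()
        ).hexdigest(),
        "outputs": {name: _sha256(p) for name, p in paths.items()},
    }
    if manova is not None:
        manifest["manova"] = {
            "wilks_lambda": manova.statistic,
            "p_value": manova.p_value,
            "per_metric": manova.per_metric,
        }
    mp = out / "manifest.json"
    mp.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    paths["manifest.json"] = mp

    return {
        "sleep_metrics": sleep_df,
        "bouts": bouts_df,
        "locomotor": loco_df,
        "group_summaries": summary_df,
        "comparisons": comparison_df,
        "control_ratios": ratios,
        "manova": manova,
        "manifest": manifest,
        "paths": paths,
    }
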