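# zfsleep

Behavioral phenotyping of tracked zebrafish: sleep-bout scoring from
actimetry, light-phase locomotor metrics, zone-occupancy scoring for
social-preference and mirror-aggression assays, group statistics, and a
calibrated synthetic trajectory generator.

The package is aimed at labs that record larval or juvenile zebrafish with
video trackers (EthoVision-style text exports) and need a reproducible,
tested implementation of the standard velocity-threshold sleep analysis and
its companion assays.

## The scoring model

Sleep in larval zebrafish is scored behaviorally from per-sample swim
velocities:

* **Per-second mobility.** Each whole second is classified MOVING if *any*
  sample velocity in it exceeds the movement threshold *v*ₜ = 1.0 mm/s
  (strict inequality), IMMOBILE if all samples are at or below *v*ₜ, and
  MISSING if it contains no valid sample.
* **Sleep bouts.** A maximal run of ≥ *m* = 6 consecutive IMMOBILE seconds
  is a sleep bout; every other observed second belongs to a wake bout. The
  shortest possible sleep bout is therefore 6 s. MISSING seconds break runs
  and are excluded from every denominator.
* **Derived parameters** per subject over the night analysis window
  (22:00–08:00 under the default 14:10 light-dark schedule): sleep and wake
  ratios, mean sleep/wake bout durations (truncated bouts excluded), sleep
  fragmentation (awakenings per analyzed hour), swim velocity
  (path length / analyzed time) and total distance.

These definitions satisfy the identity
`fragmentation ≈ sleep_ratio × 3600 / mean_sleep_bout`, which the test
suite verifies against the reference cohort means shipped with the
generator presets.

The synthetic generator drives a per-second two-state (wake/sleep) Markov
chain — geometric bout lengths, phase-dependent rates — with a
burst-plus-baseline velocity emission, calibrated by closed form so that
scored sleep statistics of simulated cohorts land on chosen targets. That
makes every pipeline stage testable without real recordings, including
parameter-recovery and power checks.

## Worked example

```python
from zfsleep import (LightSchedule, AnalysisWindow, score_sleep,
                     simulate_trajectory, default_presets, CohortSpec)

schedule = LightSchedule(recording_start="22:00")      # record from lights-off
spec = CohortSpec(duration_s=36000, sample_rate=10.0)  # one 10-h night
traj = simulate_trajectory(default_presets()["group1"], spec, schedule,
                           subject_seed=1, subject_id="larva01")
metrics, bouts = score_sleep(traj, AnalysisWindow(0, 36000))
print(f"sleep ratio      {metrics.sleep_ratio:.3f}")
print(f"mean sleep bout  {metrics.mean_sleep_bout_s:.2f} s")
print(f"fragmentation    {metrics.fragmentation:.1f} awakenings/h")
print(f"swim velocity    {metrics.velocity:.3f} mm/s")
```

prints

```
sleep ratio      0.435
mean sleep bout  11.40 s
fragmentation    137.4 awakenings/h
swim velocity    0.167 mm/s
```

— one control-preset subject whose scored night sleep sits on the preset's
calibration targets (sleep ratio 0.445, bout 11.5 s, fragmentation ≈ 140/h)
up to single-subject sampling noise. Real exports are read with
`parse_tracking_table` instead of `simulate_trajectory`; everything
downstream is identical.

The same analysis runs from the shell:

```bash
zfsleep simulate --seed 1 --out cohort.tsv --n-per-group 30
zfsleep run-all --config examples/run.yaml
```

`run-all` writes per-subject metrics, bout lists, locomotor summaries,
group mean ± SEM tables, ANOVA/Tukey comparisons, the control-normalised
ratio table and a manifest with content hashes.

## Layout

| module | contents |
| --- | --- |
| `zfsleep.trajectory_io` | tracking-table dialect, velocities, light schedules, clock windows |
| `zfsleep.sleep_scoring` | per-second classification, bout detection, sleep parameters |
| `zfsleep.locomotor_metrics` | per-phase distance/velocity/time-moving, hyperactivity flagging |
| `zfsleep.zone_assays` | arena tilings, zone assignment, occupancy scoring |
| `zfsleep.group_stats` | mean ± SEM, ANOVA + Tukey HSD, t-test, Wilks-lambda MANOVA + Bonferroni |
| `zfsleep.synthetic_data` | two-state bout simulator, presets, calibration, zone walks |
| `zfsleep.pipeline` / `zfsleep.cli` | config-driven orchestration and the `zfsleep` command |

See `docs/methods.md` for the model details, parameter choices and known
limitations.
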