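# ethoscore

Zone-based behavior classification and recognition-memory scoring for
markerless pose-tracking output from three-chamber social-interaction
sessions, plus scoring of novel-object exploration tables.

The pipeline takes per-frame landmark tables (DeepLabCut-style CSV, flat
CSV, or HDF5) and a calibrated arena geometry, and produces:

- **Gated tracking points** — frames are kept only when the mid-body
  point is tracked with likelihood ≥ 0.6; the snout is used as the
  tracking point when confidently tracked, with mid-body fallback.
- **Per-frame behavior labels** — `sniff` / `rear` / `other` / `none`
  per cage: the cage context is the nearest cage footprint within 5 cm
  (inclusive); the snout in the perimeter band outside the footprint is
  sniffing, the snout over the footprint is rearing (inferred from the
  mid-body point when the snout is not tracked).  Labels are smoothed
  with a centered 5-frame moving-average majority vote and collapsed to
  bouts.
- **Interaction times and discrimination indices** — seconds per cage
  and class at 25 fps, DI = (novel − familiar)/(novel + familiar),
  cumulative DI (running mean over trials), per-minute running DI over
  cumulative exploration, early/late trial-block averages, and the
  minutes-1–2 DI with the ±1 saturation exclusion rule.
- **Small-sample statistics** — one-sample t versus zero, Pearson
  correlation with the least-squares fit, and the r ↔ R² consistency
  check.
- **Synthetic sessions** — a semi-Markov trajectory simulator with known
  ground truth (state sequence, cage preference ρ, implied DI = 2ρ − 1,
  landmark jitter, likelihood dropout) and a generator for multi-trial
  exploration tables, so every stage is testable without recordings.

## CLI

```sh
# calibrate pixel scale + arena layout into a geometry file
ethoscore calibrate --refs refs.csv --layout layout.yml -o geometry.yml

# simulate a synthetic session (pose CSV + ground-truth sidecar)
ethoscore simulate --seed 7 --duration 600 --rho 0.75 -o session/

# gate, classify and smooth into per-frame labels (+ QC and bout tables)
ethoscore classify --pose session/sim_pose.csv --geometry session/geometry.yml \
    --smooth 5 --qc qc.csv --bouts bouts.csv -o labels.csv

# score labels into per-minute running DIs and the minutes-1-2 DI
ethoscore score --labels labels.csv --geometry session/geometry.yml \
    --phase social_memory -o di.csv

# score a trial-exploration table (subject_id,group,trial,time_novel_s,time_familiar_s)
ethoscore score-nor --table cnor.csv -o cdi.csv
```

`refs.csv` holds annotated apparatus points (`name,x_px,y_px`);
`layout.yml` declares `calibration_pairs` (pairs of point names with
their known cm separation) and the arena layout with lengths suffixed
`_cm` or `_px`.

## Package layout

| module | role |
| --- | --- |
| `ethoscore.pose_io` | pose-table readers/writers, reference-point calibration, geometry config |
| `ethoscore.trajectory_qc` | confidence gating, snout→mid-body fallback, QC report |
| `ethoscore.behavior_classifier` | per-frame sniff/rear/other labeling, smoothing, bout extraction |
| `ethoscore.memory_metrics` | interaction times, DI / cDI / running DI / block averages / early-window DI |
| `ethoscore.stats` | one-sample t, Pearson + linear fit, r² consistency |
| `ethoscore.synthetic_data` | ground-truth session simulator and exploration-table generator |
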