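# gaitpert

Detection of gait perturbations (laboratory near-falls) from wearable IMU
signals, built as a fully synthetic, end-to-end testable pipeline:

1. **`gaitpert.synthgait`** — virtual cohort generator: per participant one
   60 s gait trial and three perturbation trials, recorded at seven wearing
   positions (lumbar `L`, sternum `S`, left/right hearing aid `LHA`/`RHA`,
   smartphone in jacket pocket `JP`, pants pocket `PP`, shoulder bag `SB`)
   with device-specific sampling rates (128 / 100 / 104±4 Hz), gains and
   carry noise. Nine parameterized perturbation archetypes are injected in
   pseudo-random order at 20–30 s intervals and reported through
   treadmill-style interval markers.
2. **`gaitpert.windowing`** — resampling to a common 100 Hz grid, sliding
   2 s gait windows (1 s step), perturbation windows centered on the
   within-marker acceleration-norm maximum, channel stacking for
   multi-position conditions, and train-fitted z-standardization.
3. **`gaitpert.detector`** — a DeepConvLSTM binary classifier (4 temporal
   conv layers, 64 filters, kernel 5; 2 LSTM layers, 128 units; dropout
   0.5; dense 64 ReLU; single sigmoid output) implemented in pure NumPy
   with analytic backprop, Adam, balanced class weights
   (`w_c = n_total / (2 n_c)`) and early stopping on validation loss.
4. **`gaitpert.experiments`** — the 14-condition matrix (7 single
   positions, 4 everyday-technology combinations, 3 acceleration-only) over
   shared participant-level 70/15/15 splits; precision/recall/F1 per
   condition × split.
5. **`gaitpert.statcompare`** — Shapiro–Wilk screening, one-way and two-way
   repeated-measures ANOVA with Mauchly sphericity testing and Huynh–Feldt
   correction, Friedman test, Bonferroni-adjusted post hocs, partial eta
   squared. The repeated-measures subject is the split index.
6. **`gaitpert.interface`** — CSV/HDF5/YAML formats and the CLI.

## CLI

```bash
# a full (scaled-down) run: cohort -> windows -> detectors -> stats
gaitpert run-all --n-participants 10 --seed 7 --out runs/demo

# individual stages
gaitpert generate --n-participants 10 --seed 7 --out runs/demo/cohort
gaitpert extract  --cohort-dir runs/demo/cohort --condition RHA --out rha.h5
gaitpert train    --cohort-dir runs/demo/cohort --condition RHA --split 0 --out rha_model
gaitpert evaluate --cohort-dir runs/demo/cohort --out runs/demo
gaitpert stats    --results runs/demo/results.csv --out runs/demo
gaitpert report   --run-dir runs/demo
```

All stages are deterministic for a fixed seed; every run directory carries
a manifest with seeds and a config digest. Options can come from a YAML
config (`--config`), with CLI flags overriding it.

Note: the default configuration (66 participants, 14 conditions, 10
splits) is the full study protocol and takes hours on one CPU; use a
smaller cohort / fewer conditions / fewer epochs for exploration.

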