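# pgtrange

Machine-learning proton range-shift verification from prompt gamma-ray
timing (PGT) data.

## The problem

In proton radiotherapy, anatomical changes shift the beam range and can
misplace the dose. Uncollimated PGT detectors record, for every prompt
gamma ray emitted along the proton track, its energy E<sub>γ</sub> (MeV)
and its trigger time Δt relative to the accelerator RF period (ns). The
shape of the resulting 2D time–energy spectrum encodes the proton range:
a range shift ΔR moves the distal fall-off of the time distribution and
changes line intensities and detected counts.

`pgtrange` turns per-spot event lists into range-shift predictions:

1. **simulate** — a physics-informed generator of synthetic event lists
   (Bragg–Kleeman range, relativistic transit times, gamma line catalogue
   with escape peaks, Poisson counting statistics, bunch-phase drift,
   uncorrelated background) emulating a study with static and scanned
   spots, two beam energies and air cavities ΔR ∈ {0, 5, 10, 20} mm;
2. **preprocess** — iterative time-uniform background subtraction, then
   circular phase alignment to the ΔR = 0 reference measurement;
3. **extract** — five feature sets: time-only (15 descriptors of the 1D
   time projection), energy-restricted time (the same per nuclear-line
   window), energy-only (window counts, relative intensities and ratios,
   also per 230-bin time segment), radiomics-style image features of the
   2D spectrum, and their union; then reference normalisation, robustness
   filtering (NaN / variance / intraclass correlation) and |Spearman ρ| ≥
   0.9 feature clustering;
4. **train** — four ranking methods (MRMR, Spearman, forward-selection
   linear regression, Lasso path) × four learners (linear, random forest,
   gradient-boosted trees, RBF-SVM), signature sizes 1–10 selected by
   3×3-fold cross-validated RMSE; a full grid is 5 × 4 × 4 = 80
   configurations per data subset;
5. **evaluate** — per-dataset RMSE over all spot predictions and MRSE

   MRSE = (1/N) Σᵢ | (1/Mᵢ) Σⱼ ŷᵢⱼ − yᵢ |,

   the mean absolute error of per-cavity averaged predictions, with
   percentile-bootstrap confidence intervals (1000 resamples), plus
   median aggregation of all configurations by setup parameter.

## Worked example

`examples/03_signature_search.py` runs a reduced static study (one beam
energy, four cavities, 12 training and 8 test spots per cavity, 5000
events per spot), trains the 16 time-only configurations and scores the
best one on the held-out spots:

```text
configurations trained: 16
best configuration:     time:spearman:random_forest
chosen signature (1):  time:all:all:entropy
cross-validated RMSE:   3.14 mm
held-out RMSE:          3.98 mm  (cavity spacing is 5 mm)
```

The held-out RMSE is below the 5 mm cavity spacing: the time projection
alone carries enough information to resolve adjacent range shifts. The
other examples show the simulator's range signal (`01`), preprocessing
and the time-feature catalogue (`02`), and the RMSE/MRSE semantics with
bootstrap intervals (`04`).

The same pipeline is available from the shell:

```bash
pgt run-all --seed 1 --outdir pgt_out          # desk-scale defaults
pgt simulate|preprocess|extract|train|evaluate --config my.yaml ...
```

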