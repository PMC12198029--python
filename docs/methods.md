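# Methods

## Setting and model

A pencil proton beam stops in a cylindrical acrylic-glass phantom
(15 cm diameter, 40 cm length). An uncollimated CeBr₃-like detector at a
130° backward angle, its axis crossing the beam at half the nominal
range, records prompt gamma rays as (energy, RF-relative trigger time)
pairs per proton spot. Air cavities of thickness ΔR ∈ {0, 5, 10, 20} mm
shorten the track; the package's task is to recover ΔR per spot from the
binned 2D time–energy spectrum.

## Binning conventions

The time bin width is fixed at 1.06/230 ns ≈ 4.6087 ps (five analysis
segments of 230 bins span 1.06 ns each). The nominal RF period of
9.4 ns (isochronous-cyclotron RF ≈ 106 MHz) is not an integer multiple of
that width, so the working period snaps to 2040 bins ≈ 9.4017 ns; the
period must be a whole number of bins for circular phase alignment to be
exact. Energy is binned at 25 keV over [0.1, 8.0) MeV; every nuclear-line
window (0.3–0.6, 0.6–0.8, 1.8–2.1, 3.3–4.6, 5.0–6.3 MeV, escape peaks
included in the ranges) aligns with bin edges on this grid. All binning
is half-open [lo, hi); events at or above the upper energy edge are
excluded and tallied, so counts + tally = events always. Energy-window
crops keep every bin overlapping the window (edge-exact on the default
grid). Time segments are anchored at bin 0 after phase correction; bins
beyond 5×230 belong to no segment.

## Synthetic event generator

The generator produces event lists with the statistical structure the
analysis assumes, not a transport simulation.

* **Range.** Bragg–Kleeman R = αE^p with p = 1.77 and α calibrated so
  R(162 MeV) = 15 cm in acrylic glass (giving R(225 MeV) ≈ 26.8 cm).
  A cavity shortens the radiological track to R − ΔR.
* **Emission depths.** 85 % uniform along the track plus a 15 % Gaussian
  end-of-range bump (σ = 5 mm) — the minimal density producing a
  ΔR-dependent distal fall-off.
* **Times.** Proton transit time to the emission depth is the integral of
  1/v(z) with v from relativistic kinematics of the residual
  Bragg–Kleeman energy (the residual range is floored at 1 µm to keep the
  integrand integrable); plus the gamma time of flight to the detector
  (30 cm from the aim point), Gaussian jitter with
  σ = √(σ²_bunch + σ²_det) (0.30 and 0.15 ns), a constant 3 ns offset
  that centres the signal inside the RF period, and a deterministic
  bunch-phase drift A·e^(−i/τ)·cos(ωi) per spot index i (A = 0.5 ns,
  τ = 10 spots, ω = 0.6 rad) — the effect that motivates excluding the
  first spots of each static measurement. Everything is folded mod T_RF.
* **Energies.** Discrete lines at 0.511, 0.718, 2.000, 4.44 and 6.13 MeV
  with relative yields 0.15/0.05/0.10/0.45/0.25; the 4.44 and 6.13 MeV
  lines carry single/double escape satellites at −0.511/−1.022 MeV with
  full:SE:DE = 0.60:0.25:0.15. Line energies are blurred with a relative
  FWHM of 4 % at 1 MeV scaling as 1/√E. A 30 % exponential continuum
  (decay 1.5 MeV) accompanies the lines, and a time-uniform background
  fraction of 0.25 (0.35 at 225 MeV, emulating the elevated neutron
  background at high beam energy) is exponential in energy.
* **Counts.** Detected events per spot are Poisson with mean
  `events_per_1e9_protons · (protons/10⁹) · Ω(ΔR)`, where Ω is the mean
  inverse-square distance over emission depths normalised to ΔR = 0
  (shorter tracks sit closer to the backward detector, so counts rise
  with ΔR). Defaults: 2×10⁴ detected events for a 10⁹-proton static spot
  and 2×10³ for a 10⁸-proton scanned spot — the delivered proton numbers
  are the study's; the detected-event normalisation is an assumption of
  the generator, chosen to give realistic per-spot statistics for this
  detector class.
* **Study design.** Per (energy, cavity): 100 static spots — first 30
  excluded (phase drift), next 50 train, last 20 test; scanned layers are
  emulated by their analysed central spots only (22 layers × 5 spots),
  test-only; scanned spots of 8 consecutive layers are accumulated into a
  third evaluation dataset. Per-spot seeds derive deterministically from
  the master seed.

What the generator does **not** emulate: Monte-Carlo nuclear physics and
cross-section fidelity, detector pulse shape, pile-up/dead time, gain
drift, lateral spot structure. Passing tests therefore demonstrate that
the analysis machinery recovers range shifts from data with this
statistical structure — not detector-level fidelity.

## Preprocessing

Background first, then phase: the time-uniform background level of each
energy column is estimated as its 10th-percentile time-bin count,
subtracted, clamped at zero and re-estimated until the estimate falls
below 0.1 % of the original total (max 20 iterations, warning on
non-convergence). The estimator is a robust floor: it removes a
time-uniform component exactly in the dense-count regime and degrades
gracefully (to a no-op) on sparse spectra where most time bins are
empty. Phase alignment circularly shifts the time axis by the integer
lag maximising circular cross-correlation with the reference template
(the summed projection of the ΔR = 0 spots of the same energy/dataset
group); ties break toward the smallest |lag|, then the negative lag.
Integer-bin resolution suffices because one bin (≈4.6 ps) is two orders
of magnitude below the time jitter.

## Feature definitions

Conventions fixed project-wide: histograms are treated as discrete
distributions after unit-mass normalisation; quantiles interpolate
linearly with mass uniform inside a bin; entropies use the natural log
and skip zero-mass bins; undefined values are NaN markers removed by the
filter.

* **Time catalogue (15).** mean, median, mode, standard deviation,
  robust mean absolute deviation over the 10–90 % quantile range, mean
  absolute deviation, interquartile range, skewness, excess kurtosis,
  Shannon entropy, total counts, maximum bin height, fall-off position,
  rise position, FWHM. Rise/fall-off are the first/last 50 %-of-maximum
  crossings of the 5-bin boxcar-smoothed histogram with linear
  interpolation; FWHM = fall-off − rise.
* **Energy features (126).** Per full time range and per 230-bin segment:
  five window counts, the total, five relative intensities and all ten
  pairwise window ratios (lower-index window over higher-index; zero
  denominator → NaN).
* **Image features (26 × 6 images: full + five window crops).**
  First-order moments and percentiles of the count image, energy
  (Σ of squared normalised intensities), entropy and uniformity on a
  32-level min–max requantisation; grey-level co-occurrence features at
  distance 1, symmetric, averaged over the four standard directions
  (contrast, dissimilarity, homogeneity, angular second moment,
  correlation — NaN for a constant image — and entropy); and shape of
  the Otsu-threshold mask (foreground fraction, centroid in ns/MeV,
  principal-axis ratio).

## Feature processing

Features are divided by the median of the ΔR = 0 reference spots of the
same (energy, dataset) group — train-labelled spots for static data, the
ΔR = 0 calibration acquisition for scanned/accumulated data (which are
test-only by design). A zero reference median marks the feature
non-normalisable. The filter then drops, judged on training rows only:
features with NaN markers, sample variance < 1e-8, or one-way
intraclass correlation ICC(1,1) < 0.5 across repeated spots of identical
(energy, cavity, mode). Retained features are clustered by average
linkage on 1 − |Spearman ρ| with the dendrogram cut at 0.1 (|ρ| ≥ 0.9
merges); each cluster's representative — the member with the highest
mean |ρ| to its cluster, ties lexicographic — is what the model stage
sees.

## Ranking, signature search, learners

* **Spearman** ranks by |ρ(feature, ΔR)|.
* **MRMR** (correlation-based, MID-style): first the most relevant
  feature, then greedily argmax [relevance − mean |ρ| to the already
  selected].
* **Forward-selection LR**: greedy OLS, adding the feature that most
  reduces the residual sum of squares until all are ranked.
* **Lasso**: order of first activation along a decreasing L1 path on
  standardised features; ties by |coefficient| at the path end.

Signature sizes 1–10 (top-k of the ranking) are scored by 3-times
repeated 3-fold CV, folds stratified by cavity so every fold sees all
four ΔR values; the per-size score is the mean RMSE over the nine
validation folds, ties resolve toward the smaller size, and the chosen
signature is refit on the full training set. Learners are fixed (no
tuning): OLS (minimum-norm on rank-deficient designs, with a warning);
random forest, 500 trees; gradient-boosted trees, 500 rounds, depth 3,
learning rate 0.1, squared error; RBF-SVR with ε = 0.1, C = 1 and kernel
width 1/k on standardised features. Tree/boosting sizes are parameters
so reduced studies can scale them down without changing the procedure.
Rankings, clusters, normalisation references, folds and standardisation
all derive from training rows only; a canary test verifies that
permuting test-set targets leaves every trained bundle byte-identical.

The energy-overarching subset pools both beam energies **without**
providing the beam energy as a feature: reference normalisation is what
lets one model generalise across energies.

## Evaluation

RMSE is computed over all individual spot predictions; MRSE averages the
predictions of each cavity first and then takes the mean absolute error
over cavities (N adapts to the cavities present). Predictions are not
clipped to the trained 0–20 mm range — linear models may extrapolate,
which is precisely what gives them symmetric errors and low MRSE.
Confidence intervals are percentile bootstrap over spots (B = 1000,
95 %); a replicate that loses a cavity recomputes MRSE over the cavities
it retains. Percentile intervals undercover by a few points on very
small prediction sets (a known small-sample property); the coverage test
runs at 150 predictions per cavity where the interval is near nominal.
Configuration-level summaries report the median metric per setup
parameter (feature set / learner / ranking) and dataset, ordered by the
cross-dataset mean.

## Problem sizes used by the test suite and acceptance script

The full experimental campaign (1440 spots at ~10⁹ protons each) is not
reproduced; the package's own study sizes are: parameter recovery on 2
energies × 4 cavities × (40 train + 16 test) static spots at 2×10⁴
events/spot, with a 10×-reduced repeat emulating scanned statistics; the
desk-scale pipeline (one energy, 18 static spots per cavity, 8 scanned
layers × 2 spots, 2×10³ events per static spot, 25-tree ensembles) for
end-to-end determinism; toy tables for grid cardinality and leakage
checks. These sizes are the package's chosen desk-scale study
conditions and are fixed in the tests.

## Known limitations

* The generator's detected-event normalisation and time spreads are
  assumptions; absolute RMSE values depend on them and are not
  comparable to any specific detector without calibration.
* The background estimator is a quantile floor; it does not subtract
  background in the sparse-count regime (most time bins empty).
* Phase alignment against a ΔR = 0 template can absorb part of the mean
  time shift between cavities; shift-invariant features (width, entropy,
  FWHM) carry the remaining signal, which is why the feature catalogue
  includes both positional and shape descriptors.
* The image catalogue is a compact radiomics-style stand-in, not a full
  IBSI-compliant set; no wavelet/filtered variants.
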