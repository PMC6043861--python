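# Methods

## Scope and data model

`nirtraj` builds and compares quantitative NIR calibrations on a
`SpectralDataset`: an `n_samples × n_variables` absorbance matrix over a
strictly monotone spectral axis (wavenumber in cm⁻¹ or wavelength in nm)
with one reference value per sample (% w/w or mg/mL, carried as metadata).
Loading fails loudly on any missing or non-numeric cell: downstream linear
algebra has no sensible treatment for missing absorbances.

Samples are partitioned by the Kennard–Stone algorithm: seed with the two
mutually most distant spectra (Euclidean distance on the raw, un-pretreated
spectra, since splitting precedes pretreatment in the workflow), then
repeatedly add the sample with the largest minimum distance to the selected
set. Ties break to the lowest sample index, making the split fully
deterministic; duplicate spectra are legal.

Region cropping keeps variables whose axis position lies in the *closed*
interval `[lo, hi]`, matching how spectroscopists quote ranges such as
"1,100–1,900 nm".

## Pretreatments

Four pretreatments span the grid: raw passthrough, 9-point Savitzky–Golay
smoothing, and 1st/2nd derivatives. All three filters are SG least-squares
polynomial filters with polynomial order 2 — order 2 being the common
chemometric default where only "SG with 9 points" is specified — so the
family is internally consistent and derivative estimates are noise-robust
rather than finite differences. Derivatives are reported in index-spacing
units (no division by the axis step): the axis is uniform within a dataset,
so only a constant scale separates this from a physical derivative, and
relative model comparisons are unaffected.

Edge handling preserves the variable count, which keeps interval indices
comparable across pretreatments. Boundary points are filled from the
least-squares polynomial fitted over the full window anchored at the edge,
evaluated at the off-centre positions. A symmetric shrink-window scheme was
considered and rejected: it degenerates to a single point at the outermost
sample, where a derivative is undefined. The implemented scheme preserves
the two invariants that matter — polynomials up to the filter order pass
through unchanged (edges included), and the filter is linear.

## PLS core

PLS1 is fitted by NIPALS on mean-centered `X` and `y`; no unit-variance
scaling is applied, the standard choice when all variables share one
physical unit (absorbance). The regression vector is `b = W(PᵀW)⁻¹q`,
truncatable to any component count from one fit — cross-validation exploits
this, fitting once per fold at the deepest feasible component count.

Degenerate deflation (‖Xᵀy‖ collapsing to numerical zero) stops component
extraction early and flags the model rather than raising, so a parameter
grid survives isolated degenerate cells. In cross-validation, a fold whose
training block yields no extractable component at all falls back to the
training-mean predictor — the correct limiting model.

Cross-validation defaults to 5 shuffled folds with a fixed seed; setting
`folds = n` gives leave-one-out. The fold assignment depends only on
(n, folds, seed), so all selectors scoring the same training set share it.

## Interval selection

The spectrum is partitioned into `n_intervals` contiguous intervals of
near-equal width (the first `n mod k` intervals get the extra variable).
The default of 20 intervals follows long-standing interval-PLS practice;
it is configurable per dataset.

- **iPLS** returns the single interval with the lowest RMSECV.
- **BiPLS** starts from all intervals and repeatedly removes the interval
  whose omission minimises RMSECV of the remainder, recording the score
  after every removal; the set along the elimination path with the global
  minimum is returned (ties go to the earlier, larger set).
- **SiPLS** exhaustively scores every combination of `combo_size`
  intervals (default 2), with a combination cap (default 10,000) that
  turns accidental combinatorial explosions into an explicit error.

"Scored at up to ℓ latent factors" means the minimum RMSECV over 1..cap
factors, cap being the trajectory's current latent-factor value further
limited by subset width and fold size; the factor count achieving the
minimum is recorded. All ties break to the lowest interval index /
lexicographically smallest tuple, so selection is deterministic given the
CV seed. Selection sees training data only.

## Bagging-PLS

`B` bootstrap resamples (with replacement, resample size = training size by
default) each yield one PLS1 member; the ensemble predicts the per-sample
mean (median available) of member predictions. `B` defaults to 50 — large
enough that the aggregate stabilises, small enough to keep a 240-path grid
desk-scale; reproduction sweeps use B ∈ {25, 50, 100}. Resamples with a
constant response are redrawn (capped at 100 attempts) so the member count
is exactly `B` for any seed. Variable selection is performed once on the
full training set before resampling; members share the mask — bagging the
selector itself is out of scope.

## Trajectory engine

A path is (pretreatment, selector, latent factors, method); the grid is
the Cartesian product in a fixed pretreatment-major order. Pipeline order
within a path is fixed: pretreat both sets → select variables on the
training set → fit at the path's factor count → predict validation →
RMSEP/RPD and band classification. Selector runs are cached per
(pretreatment, selector, factors) and reused across the method axis and by
the stepwise optimizer. Failures become report rows with a reason, never
crashes.

Per-path randomness (the bagging bootstrap) is seeded from the report seed
combined with a hash of the path's canonical key. Seeding by spec content
rather than by grid position guarantees that an identical spec evaluated in
any context — grid, stepwise baseline, isolated re-run — produces identical
numbers, which makes the dominance property (exhaustive best ≥ stepwise
baseline, in RPD) exact rather than approximate.

The best path maximises RPD, with lower RMSEP then enumeration order as
tie-breaks. RPD classification: very_good ≥ 3.5 (the boundary value 3.5 is
assigned upward), good [3, 3.5), fair [2, 3), poor below 2; the two lower
bands extrapolate the published banding, which only defines the upper two.
RPD is sd(y_val, n−1)/RMSEP without bias correction, so `rpd × rmsep ≡
sd(y_val)` is an exact identity; a bias-corrected SEP variant would break
that identity and is not provided.

The stepwise baseline fixes (raw, no selection, CV-optimal factor count,
PLS), then greedily optimises — by validation RMSEP, holding earlier
choices — pretreatment, selector (among the grid's selectors), factor
count, method, in the order a practitioner tunes them. Its final spec lies
inside the grid by construction.

## Synthetic data

The generator emulates NIR mixture spectra under Beer–Lambert linearity:
`X = C·S + baseline + noise`, with Gaussian absorption bands, per-sample
concentrations drawn uniformly from component-specific ranges, a random
polynomial baseline (degree 2) per sample, and i.i.d. Gaussian noise.
Component 0 is the regressand. Two presets mirror the shapes of the study
datasets: `tablet_like` (310 × 404, 7,000–10,500 cm⁻¹, four broad bands
near 10,000/8,830/8,200/7,840 cm⁻¹, analyte 5–12 % w/w, noise 0.005 AU ≈
1% of peak absorbance) and `lonicera_like` (216 × 2,800, 1,100–2,500 nm,
analyte 0.2–1.5 mg/mL, strong interfering bands above 1,900 nm motivating
the crop to 1,100–1,900 nm).

What the generator does *not* emulate: reference-assay (HPLC) error,
scattering/multiplicative effects, instrument drift between samples, and
correlated component concentrations. Consequently synthetic RPD values run
far higher than those achievable on real process data — passing tests
demonstrate correctness of the machinery and recoverability of planted
structure, not field-realistic error levels.

## Problem sizes and reproducibility

The test suite runs selector-recovery and dominance checks on 20 seeded
replicates of small mixtures (36–60 samples, 60–100 variables, 4–10
intervals) and trajectory bookkeeping on a 120-path grid — sizes at which
the brute-force oracles the tests compare against remain exact and fast.
`scripts/acceptance.py` uses the full preset shapes and the full 240-path
grid on both emulated datasets. Every random draw (generator, CV folds,
bootstrap) flows from explicit integer seeds; reports are bit-reproducible
given (data, config, seed).

## Reproduction of the published figures

The published calibrations (tablet API: RMSEP 0.4126 % w/w, RPD 3.2234;
extract chlorogenic acid: RMSEP 0.0728 mg/mL, RPD 3.9166; plus the
corresponding stepwise baselines) depend on the original datasets and on
toolbox settings that were never recorded: interval count, SiPLS
combination size, CV scheme, ensemble size and aggregation rule.
`nirtraj.reproduce.reproduce_study` therefore sweeps `n_intervals ∈ {10,
20, 40}`, `B ∈ {25, 50, 100}` and `folds ∈ {5, LOO}` and reports every
sweep point; agreement within about ±15% on RMSEP and RPD is the realistic
success criterion, and exact matches should not be expected. The datasets
are not redistributed with the package; the pipeline runs when they are
supplied as CSVs in the package dialect.

## Known limitations

- Single-response (PLS1) only; no PLS2, no OSC/MSC/SNV pretreatments, no
  GA/CARS/UVE selectors, no out-of-bag error estimation.
- The trajectory is evaluated serially; the 240-path grid on the full
  extract shape takes a few minutes on one core.
- RPD of a perfect (zero-residual) prediction is reported as +inf and
  classified very_good rather than raising, so noise-free synthetic paths
  survive; consumers needing a guard should test `math.isinf`.
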