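# Methods

`spectracv` benchmarks training-population designs for predicting cow
phenotypes from Fourier-transform infrared (FTIR) milk spectra. The target
phenotypes are body condition score (BCS, 1–5 scale), blood
β-hydroxybutyrate (BHB, mmol/L) and kappa casein (k-CN, % of milk N); the
prediction target population is Holstein. The core question is how the
composition and size of the training population — within-breed,
across-breed (Brown Swiss), or multi-breed (adding Simmental, Rendena and
Alpine Grey) — changes predictive ability.

Because the underlying cow data are not public, the package ships a
synthetic data generator that reproduces the study's statistical structure,
so every stage of the pipeline is testable end to end. Everything below is
computed by the package itself; numerical claims are limited to what the
test suite and `scripts/acceptance.py` actually verify.

## Synthetic data generator

**Phenotypes.** Each breed × trait is drawn from a truncated normal with
the published per-breed mean, SD, minimum and maximum (e.g. Holstein BCS:
mean 2.81, SD 0.324, range 2.00–3.75). Truncation rather than clipping
keeps the published hard ranges without probability mass at the bounds.
Per-trait missingness is random per animal, with default rates that
reproduce each trait's observed cohort size relative to the 1461-cow total
(k-CN is the sparsest). Days in milk is uniform on [10, 380].

**Herds.** 41 herds host 1–5 breeds each with at least five animals per
breed-herd cell. Allocation assigns each breed to as many herds as its
cohort supports (cells seeded at the minimum, remainder multinomial);
the largest breeds are placed first so every herd is covered. Infeasible
plans raise an explicit allocation error.

**Spectra.** The grid is 1060 points from 5011 to 925 cm⁻¹ (descending).
An animal's noise-free absorbance is

    A(ν) = baseline(ν) + breed offset(ν)
         + Σ_bands  amp_b · mult(breed, b) · z · g_b(ν)
         + animal noise(ν),

where `z` is the animal's phenotype standardized against the pooled
population (so breed mean differences are carried into the spectra),
`g_b` are Gaussian bands whose centers and widths are drawn from the seed
and reported in the metadata, and the animal noise is smoothed white noise
(pointwise SD 0.01 absorbance). Two replicate spectra are emitted per
animal by adding replicate noise (SD 0.004) on the absorbance scale and
transforming to transmittance, T = 10^(−A).

Key calibrations:

* `signal_to_noise` (default 2.0) is the total ratio of phenotype-driven
  variance to noise variance at the scale of the band averages, split
  evenly across a trait's bands (default 6 per trait — real FTIR–trait
  associations are spread over many spectral regions, and spreading the
  signal keeps learning data-limited at realistic cohort sizes, so
  training-set size matters as it does in practice). The total caps the
  attainable prediction R² at snr/(1+snr); the default puts the attainable
  correlation near 0.82, inside the 0.63–0.88 range that FTIR predictions
  of these traits reach in practice.
* breed-level baseline offsets are smooth curves scaled to 0.3 of the
  animal-noise SD — small relative to within-breed variation, so breed
  clouds overlap in principal-component space.
* **breed-specific coupling.** Each breed's band amplitudes are jittered
  multiplicatively (`breed_coupling_sd`, default 0.2), with each breed's
  multiplier vector normalized to unit root-mean-square so the jitter
  rotates the coupling *direction* across bands without changing any
  breed's own signal power (and hence its own predictability). Each
  breed's band centers are additionally displaced by
  `breed_band_shift_sd` = 0.35 band widths, with a deterministic Hadamard
  sign pattern over (breed, band): every breed pair disagrees in about
  half the bands, where their Gaussian signals overlap by
  exp(−(2·0.35)²/4) ≈ 0.89. This emulates breed differences in milk
  composition — the spectra–phenotype link is similar but not identical
  across breeds — and the deterministic pattern makes the across-breed
  transfer penalty a stable property of the design rather than a draw of
  the seed. Without this mechanism an across-breed design cannot degrade
  at all in simulation: Pearson correlation is invariant to the additive
  breed offsets, and the Brown Swiss cohort (646) is larger than the
  9-fold Holstein training set (414), so a generator with identical
  coupling in every breed makes across-breed prediction *better* than
  within-breed — contradicting what multi-population spectral studies
  consistently observe.

**What the generator does not emulate:** mid-IR water-absorption regions
(the full grid is informative), lactation-stage spectral dynamics, pedigree
or herd-level phenotype structure, and trait–trait correlations. Passing
tests therefore demonstrate that the pipeline's machinery and its
statistical conclusions behave correctly under the assumed structure, not
that any particular accuracy level would be attained on real milk spectra.

**Contamination.** `inject_spectral_outliers` displaces a chosen fraction
of animals along a random direction by a multiple of the per-wavenumber SD
and returns the true indices, providing ground truth for outlier-removal
recall.

## Quality control

Fixed order: transmittance → absorbance (A = log₁₀(1/T); base 10 is the
spectroscopy convention), replicate averaging, spectral outlier removal,
per-breed ±3 SD phenotype trimming (single pass, values set to missing),
and the herd filter (breed-herd cells under five animals dropped). An
animal failing spectral QC is removed everywhere; a trimmed phenotype is
lost for that trait only.

Spectral outliers: covariance PCA on the pooled centered spectra, retaining
the smallest number of components explaining ≥ 99% of variance; the squared
Mahalanobis distance of each score vector in the diagonal eigenvalue metric
(eigenvalues on the divide-by-n convention) is compared with the chi-square
quantile at 1 − prob_level (default 0.01) with df = retained components.
The chi-square reference is asymptotic: for points included in the
covariance estimate the exact null distribution is a scaled Beta, whose
0.99 cutoff tail is 0.0098 at n = 500 with two retained components but
drifts to 0.007 by ~40 components. The calibration test therefore uses a
low-dimensional Gaussian null, where the reference is honest; on real
spectra the detector is conservative rather than anti-conservative.
Correlation-matrix PCA and both knobs (prob level, variance fraction) are
exposed.

## Cross-validation designs

Five scenarios, all evaluated on Holstein test animals, built per trait on
the post-QC cohorts (cohort sizes differ by trait):

| name | training set | replications |
|---|---|---|
| `10-fold_HO` | 9 Holstein folds | k × repeats (100) |
| `BS_HO` | all Brown Swiss | 1 |
| `BS+HO_10-fold` | 9 HO folds + all Brown Swiss | 100 |
| `Multi-breed` | + Simmental, Rendena, Alpine Grey | 100 |
| `Multi-breed_CV2` | Multi-breed pool down-sampled to the within-breed training size | 900 |

Folds are drawn fresh per repeat but depend only on (seed, repeat), so all
scenarios share identical test folds — the prerequisite for the
dependent-correlation comparisons. CV2 splits the multi-breed pool into 3
disjoint subsets whose breed composition follows the pool's proportions
via largest-remainder (Hamilton) apportionment, each of exactly the
within-breed training size; the 3-way split is redrawn 3 times per
(repeat, fold), giving 10 × 10 × 3 × 3 = 900 replications at the default
schedule. The published training-set sizes are internally inconsistent in
places (407 vs 423 for the BHB 9-fold size; 417 vs a 414 component sum for
CV2 BCS); sizes here are always derived from the data and logged.

## Gradient boosting

The predictor is an in-package least-squares gradient boosting machine:
F_M(x) = f₀ + lr·Σ tree_m(x), f₀ the training mean, each tree a greedy
depth-limited CART fit to the current residuals, accepted splits must
reduce SSE strictly with both children ≥ `min_samples_leaf`, ties broken
to the lowest wavenumber index then lowest threshold. Split search uses
per-feature histograms (numba kernels, sibling histograms by subtraction);
with ≤ `max_bins` distinct values per feature the candidate thresholds are
exactly the midpoints between sorted unique values, so small problems are
searched exhaustively and the depth-1 model is provably the best stump
(verified against an enumeration oracle and an independent CART
implementation). Training loss is non-increasing by construction — this is
asserted over random instances. The training curve, per-tree structures and
a JSON serialization are exposed.

Hyperparameters (number of trees, learning rate, depth, minimum leaf) are
tuned by uniform random search over the published grids (10–8000 trees by
10; 0.001–1 by 0.001; depth 1–80; leaf 1–100 by 5) with inner 5-fold CV on
the training animals only; the winner minimizes mean held-out RMSE (ties:
higher r², then first drawn). The outer test fold never enters the search;
this is asserted per replication. A `componentwise_stump` base-learner mode
(one wavenumber per boosting stage) is available as the alternative reading
of single-predictor iterations; full trees are the default because depths
up to 80 only make sense for trees.

## Evaluation

Per replication: Pearson rp between observed and predicted, RMSE, mean
percentage error MPE = mean((obs−pred)/obs)·100 (per-observation reading;
a population-mean-numerator variant sits behind a flag), and the OLS slope
of observed on predicted (1 = unbiased). Scenario means and SDs are
tabulated in a trait × scenario layout with the relative difference
RD = (r_m − r_C)/r_C · 100 against the within-breed reference.

Scenario comparisons use the Hotelling–Williams t-test (Williams'
determinant form, df = n−3) and Zou's modified-asymptotic interval for a
difference of overlapping dependent correlations, computed per repeat on
pooled predictions over the repeat's ten test folds (all scenarios share
those animals; CV2 animals contribute their subset-average prediction) and
summarized by the median across repeats. Both statistics are
Monte-Carlo calibrated in the acceptance suite (type-I error and coverage
under trivariate-normal nulls at n = 200, 20 000 simulations).

## Desk-scale benchmark

`benchmark_config()` defines the configuration used by the acceptance
script and the end-to-end ordering test: the full 1461-animal default
cohort, one trait (BCS), 3 repeats, search budget 10 drawn from a reduced
grid (trees 40–200, shrinkage 0.05–0.3, depth 2–4, leaf 1–21), one search
per scenario, and 64-bin histograms. These problem sizes keep the complete
five-scenario experiment at minutes on one CPU while leaving the scientific
conditions (cohort, designs, inner-CV protocol) intact; the reduced tree
grid is adequate because the synthetic signal sits in smooth Gaussian
bands, which modest tree ensembles capture.

## Numerical and degenerate-input choices

* Absorbance uses log base 10; the inverse transform round-trips to 1e−12.
* Identical spectra (zero variance) yield zero Mahalanobis distances and no
  outlier flags; fewer than three animals is an error.
* Phenotype trimming with SD = 0 keeps all (degenerate interval contains
  the common value); breeds with fewer than two values are skipped with a
  warning.
* Split acceptance uses a relative SSE tolerance of 1e−12 to avoid
  spurious splits from floating-point cancellation; constant targets yield
  single-leaf trees.
* Correlations are undefined (error, replication dropped with a logged
  warning) for constant vectors; MPE errors on zero observations (the
  three traits are strictly positive).
* All randomness flows from one integer seed through named, independently
  reproducible sub-streams (CRC-mixed `SeedSequence`); identical configs
  reproduce byte-identical outputs.

## Known limitations

* The generator's breed-coupling heterogeneity (direction jitter plus
  Hadamard-signed band shifts) is a deliberate caricature of real
  milk-composition differences; it reproduces the sign and rough size of
  across-breed degradation, not its trait-specific pattern.
* The chi-square outlier cutoff is slightly conservative at high retained
  dimension (see above).
* Hyperparameter search at the published grid ranges (up to 8000 trees) is
  supported but computationally heavy; the benchmark uses the reduced grid
  described above.
* Statistics are computed per replication on modest test folds (~46
  animals), so single-replication values are noisy; conclusions should be
  read from the aggregated means, as in the tabulated report.
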