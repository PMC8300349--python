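# spectracv

Benchmarking multi-breed training-population designs for predicting cow
phenotypes from Fourier-transform infrared (FTIR) milk spectra.

Routine milk recording produces an FTIR spectrum for every sampled cow —
1060 transmittance points from 5011 to 925 cm⁻¹ — and those spectra carry
information about phenotypes that are expensive to measure directly: body
condition score (BCS), blood β-hydroxybutyrate (BHB, mmol/L) and kappa
casein (k-CN, % of milk N). Calibrating a prediction equation needs a
training population, and for many traits no single breed provides a large
one. This package implements, as a tested and reusable pipeline, the
comparison of five cross-validation designs for predicting phenotypes in
Holstein cows:

* **10-fold_HO** — within-breed: 9 of 10 Holstein folds train, 1 tests;
* **BS_HO** — across-breed: all Brown Swiss train, all Holstein test;
* **BS+HO_10-fold** — specialized multi-breed: Brown Swiss appended to the
  Holstein training folds;
* **Multi-breed** — plus the dual-purpose Simmental, Rendena and Alpine
  Grey cohorts;
* **Multi-breed_CV2** — the multi-breed pool down-sampled to the
  within-breed training size, preserving breed proportions (largest-
  remainder quotas), separating the effect of size from composition.

The prediction engine is an in-package least-squares gradient boosting
machine (GBM): the additive expansion F_M(x) = f₀ + ν·Σₘ treeₘ(x) of
depth-limited CART regression trees with shrinkage ν, hyperparameters
(number of trees, learning rate ν, depth, minimum leaf size) tuned by
random search with inner 5-fold CV on training animals only. Predictive
ability is the Pearson correlation r_p between observed and predicted
phenotypes on the test fold, with RMSE, mean percentage error
MPE = Σᵢ((y_obs,i − y_pred,i)/y_obs,i)·100/n, the bias slope of observed on
predicted, and the relative difference RD = (r_m − r_C)/r_C·100 against the
within-breed reference. Differences between designs are tested with the
Hotelling–Williams t-test and Zou's confidence interval for dependent
overlapping correlations, valid here because all designs share the same
Holstein test folds.

Because the study's cow data are not public, a synthetic generator
(`spectracv.synth`) emulates the study's structure — five breeds with
published phenotype distributions, 41 multi-breed herds, replicate spectra
with phenotype-linked absorbance bands, and breed-specific coupling — so
the entire pipeline runs and is testable from a single seed. See
`docs/methods.md` for the model and its assumptions.

## Worked example

```python
from spectracv import benchmark_config, run_experiment

result = run_experiment(benchmark_config(seed=1, n_repeats=1))
rp = result.aggregated.query("stat == 'rp'")[["scenario", "mean", "sd"]]
print(rp.to_string(index=False))
```

prints (about four minutes on one CPU):

```
       scenario     mean       sd
     10-fold_HO 0.808609 0.069641
          BS_HO 0.791127      NaN
  BS+HO_10-fold 0.825357 0.056738
    Multi-breed 0.833022 0.059868
Multi-breed_CV2 0.774220 0.077993
```

Read: on the synthetic cohort, across-breed calibration (BS_HO) loses
predictive ability relative to within-breed (0.791 vs 0.809), the
multi-breed training set is the best design (0.833), and capping the
multi-breed pool at the within-breed training size (CV2) falls back to
roughly the reference level — the gain comes from size and variability
jointly, not composition alone. `result.comparisons` holds the
Hotelling–Williams and Zou statistics per design pair;
`spectracv.report(outdir)` renders the trait × scenario table with RD rows.

The same pipeline runs from the command line:

```bash
spectracv simulate --seed 7 --out data/
spectracv preprocess --phenotypes data/phenotypes.csv --spectra data/spectra.csv --out qc/
spectracv design --phenotypes qc/phenotypes_qc.csv --scenario Multi-breed --out manifest.tsv
spectracv run --out results/        # full experiment with default config
spectracv report --results results/
```

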