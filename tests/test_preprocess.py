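"""QC: absorbance transform, averaging, outlier removal, trimming, herd filter."""

import numpy as np
import pandas as pd
import pytest

from spectracv.containers import SpectraMatrix
from spectracv.preprocess import (
    MahalanobisOutlierDetector,
    average_replicates,
    herd_filter,
    phenotype_qc,
    remove_spectral_outliers,
    run_qc_pipeline,
    transmittance_to_absorbance,
)
from spectracv.synth import (
    HerdPlan,
    SpectraGenSpec,
    default_breed_specs,
    generate_dataset,
    inject_spectral_outliers,
)


def _matrix(values, scale="transmittance"):
    values = np.asarray(values, dtype=float)
    n, p = values.shape[0], values.shape[-1]
    return SpectraMatrix(
        np.array([f"A{i}" for i in range(n)]), np.linspace(3000, 900, p), values, scale
    )


class TestAbsorbance:
    @pytest.mark.parametrize("t,a", [(1.0, 0.0), (0.1, 1.0), (0.01, 2.0)])
    def test_known_values(self, t, a):
        sm = transmittance_to_absorbance(_matrix([[t, t]]))
        assert sm.scale == "absorbance"
        np.testing.assert_allclose(sm.values, a, atol=1e-14)

    def test_nonpositive_transmittance_names_culprit(self):
        with pytest.raises(ValueError, match="A1"):
            transmittance_to_absorbance(_matrix([[0.5, 0.5], [0.5, -0.1]]))

    def test_round_trip_identity(self, rng):
        A = rng.uniform(0.1, 2.0, size=(5, 8))
        sm = transmittance_to_absorbance(_matrix(10.0 ** (-A)))
        np.testing.assert_allclose(sm.values, A, atol=1e-12)

    def test_rejects_absorbance_input(self):
        with pytest.raises(ValueError):
            transmittance_to_absorbance(_matrix([[0.5]], scale="absorbance"))


class TestAverageReplicates:
    def test_mean_of_two_replicates(self, rng):
        a, b = rng.standard_normal((2, 6))
        sm = average_replicates(_matrix([[a, b]], scale="absorbance"))
        np.testing.assert_allclose(sm.values[0], (a + b) / 2)
        assert not sm.has_replicates

    def test_identical_replicates_unchanged(self, rng):
        a = rng.standard_normal(6)
        sm = average_replicates(_matrix([[a, a]], scale="absorbance"))
        np.testing.assert_allclose(sm.values[0], a)

    def test_requires_replicate_axis(self):
        with pytest.raises(ValueError):
            average_replicates(_matrix([[1.0, 2.0]], scale="absorbance"))


class TestSpectralOutliers:
    def test_identical_spectra_remove_none(self):
        sm = _matrix(np.ones((10, 5)), scale="absorbance")
        kept, report = remove_spectral_outliers(sm)
        assert kept.n_animals == 10
        assert report.total_removed() == 0

    def test_displaced_spectrum_is_flagged(self, rng):
        X = rng.standard_normal((200, 20))
        X[17] += 10.0 * X.std(axis=0)
        kept, report = remove_spectral_outliers(_matrix(X, scale="absorbance"))
        assert "A17" not in kept.animal_ids
        assert report.total_removed() >= 1

    def test_matches_full_covariance_mahalanobis_oracle(self, rng):
        """Distances equal an independently coded full-covariance Mahalanobis
        computation on the retained-PC subspace."""
        X = rng.standard_normal((80, 6)) @ rng.standard_normal((6, 6))
        det = MahalanobisOutlierDetector(var_explained=0.99).fit(X)
        Xc = X - X.mean(axis=0)
        scores = Xc @ det.components_.T
        S = scores.T @ scores / len(X)  # MLE covariance of the scores
        d2 = np.einsum("ij,jk,ik->i", scores, np.linalg.inv(S), scores)
        np.testing.assert_allclose(det.mahalanobis_, d2, rtol=1e-8)

    def test_injected_outliers_recalled(self):
        ds = generate_dataset(
            default_breed_specs(n_scale=0.15),
            SpectraGenSpec(n_points=120),
            HerdPlan(n_herds=4),
            seed=5,
        )
        sm = average_replicates(transmittance_to_absorbance(ds.spectra))
        cont, idx = inject_spectral_outliers(sm, 0.05, 10.0, seed=6)
        kept, _ = remove_spectral_outliers(cont)
        flagged = set(cont.animal_ids) - set(kept.animal_ids)
        truth = {cont.animal_ids[i] for i in idx}
        assert len(truth & flagged) / len(truth) >= 0.9

    def test_too_few_animals(self):
        with pytest.raises(ValueError):
            MahalanobisOutlierDetector().fit(np.ones((2, 4)))

    def test_fit_predict_convention(self, rng):
        X = rng.standard_normal((50, 4))
        X[3] += 50.0
        labels = MahalanobisOutlierDetector().fit_predict(X)
        assert labels[3] == -1
        assert set(labels) <= {-1, 1}


class TestPhenotypeQC:
    def _records(self, values, breed="Holstein"):
        return pd.DataFrame(
            {
                "animal_id": [f"A{i}" for i in range(len(values))],
                "breed": breed,
                "herd": "H1",
                "dim": 100.0,
                "bcs": values,
                "bhb_mmol_l": np.nan,
                "kcn_pct_n": np.nan,
            }
        )

    def test_equal_values_none_removed(self):
        rec, report = phenotype_qc(self._records([2.8] * 10), "bcs")
        assert report.total_removed() == 0
        assert rec["bcs"].notna().all()

    def test_extreme_value_removed(self, rng):
        vals = rng.standard_normal(10000)
        vals[123] = 3.5 * vals.std()
        rec, report = phenotype_qc(self._records(vals + 10.0), "bcs")
        assert np.isnan(rec.loc[123, "bcs"])

    def test_per_breed_trimming_is_independent(self, rng):
        a = self._records(rng.normal(2.8, 0.3, 50), "Holstein")
        b = self._records(rng.normal(16.0, 0.3, 50), "Brown Swiss")
        b["animal_id"] = [f"B{i}" for i in range(50)]
        rec, report = phenotype_qc(pd.concat([a, b], ignore_index=True), "bcs")
        # values far apart across breeds are fine; nothing removed within breed
        assert report.total_removed() == 0

    def test_small_breed_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="fewer than 2"):
            phenotype_qc(self._records([2.8]), "bcs")


class TestHerdFilter:
    def test_small_cell_removed_other_kept(self):
        rec = pd.DataFrame(
            {
                "animal_id": [f"A{i}" for i in range(10)],
                "breed": ["Holstein"] * 4 + ["Brown Swiss"] * 6,
                "herd": "H1",
                "dim": 1.0,
                "bcs": 2.8,
                "bhb_mmol_l": 0.5,
                "kcn_pct_n": 14.0,
            }
        )
        out, report = herd_filter(rec, min_count=5)
        assert set(out["breed"]) == {"Brown Swiss"}
        assert report.total_removed() == 4

    def test_min_count_one_is_identity(self, tiny_dataset):
        out, report = herd_filter(tiny_dataset.phenotypes, min_count=1)
        assert len(out) == len(tiny_dataset.phenotypes)
        assert report.total_removed() == 0

    def test_generator_honors_plan_so_filter_removes_nothing(self, tiny_dataset):
        out, report = herd_filter(tiny_dataset.phenotypes, min_count=5)
        assert report.total_removed() == 0


def test_full_pipeline_counts_reconcile(tiny_dataset):
    sm, rec, report = run_qc_pipeline(tiny_dataset.spectra, tiny_dataset.phenotypes)
    assert sm.scale == "absorbance"
    assert not sm.has_replicates
    assert list(sm.animal_ids) == list(rec["animal_id"])
    n_spec_removed = report.total_removed("spectral_outliers")
    assert sm.n_animals <= tiny_dataset.spectra.n_animals - n_spec_removed
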