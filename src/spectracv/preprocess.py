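"""Quality control for spectra and phenotypes.

Fixed pipeline order: transmittance -> absorbance, replicate averaging,
PCA + Mahalanobis spectral outlier removal, per-breed +/-3 SD phenotype
trimming, and the herd-level inclusion filter (at least five animals of a
breed in a herd).

The spectral outlier detector follows the PCA-score Mahalanobis scheme:
spectra are centered, principal components retaining a fixed fraction of
variance are kept, the squared Mahalanobis distance of each score vector is
computed in the diagonal eigenvalue metric, and animals beyond the
chi-square quantile at ``1 - prob_level`` (df = number of retained
components) are flagged.  One pass, no iterative re-trimming.
"""

from __future__ import annotations

import warnings
from typing import Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, OutlierMixin

from .containers import QCReport, SpectraMatrix, TRAIT_COLUMNS

__all__ = [
    "transmittance_to_absorbance",
    "average_replicates",
    "MahalanobisOutlierDetector",
    "remove_spectral_outliers",
    "phenotype_qc",
    "herd_filter",
    "run_qc_pipeline",
]


def transmittance_to_absorbance(spectra: SpectraMatrix) -> SpectraMatrix:
    """A = log10(1/T), pointwise; shape preserved, scale tag flipped."""
    if spectra.scale != "transmittance":
        raise ValueError("input spectra are not tagged transmittance")
    bad = spectra.values <= 0
    if bad.any():
        where = np.argwhere(bad)[0]
        animal = spectra.animal_ids[where[0]]
        wn = spectra.wavenumbers[where[-1]]
        raise ValueError(
            f"non-positive transmittance for animal {animal} at {wn:.6g} cm^-1"
        )
    return spectra.with_values(np.log10(1.0 / spectra.values), scale="absorbance")


def average_replicates(spectra: SpectraMatrix) -> SpectraMatrix:
    """Arithmetic mean across the replicate axis (absorbance scale expected)."""
    if not spectra.has_replicates:
        raise ValueError("spectra have no replicate axis to average")
    if spectra.values.shape[1] < 1:
        raise ValueError("every animal needs at least one replicate")
    return spectra.with_values(spectra.values.mean(axis=1))


class MahalanobisOutlierDetector(BaseEstimator, OutlierMixin):
    """PCA-score Mahalanobis outlier detection for spectra.

    Parameters
    ----------
    prob_level : float
        Nominal flag probability under the Gaussian null; the cutoff is the
        chi-square quantile at ``1 - prob_level`` with df = retained PCs.
    var_explained : float
        Smallest number of leading PCs explaining at least this fraction of
        variance is retained.
    standardize : bool
        If True, PCA on the correlation matrix (spectra scaled to unit
        pointwise variance) instead of the covariance matrix.

    Attributes (after ``fit``)
    --------------------------
    n_components_ : retained PC count.
    mahalanobis_ : squared distances, one per fitted row.
    threshold_ : chi-square cutoff.
    outlier_mask_ : boolean flags for the fitted rows.
    """

    def __init__(
        self,
        prob_level: float = 0.01,
        var_explained: float = 0.99,
        standardize: bool = False,
    ):
        self.prob_level = prob_level
        self.var_explained = var_explained
        self.standardize = standardize

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 3:
            raise ValueError("need a 2-D matrix with at least 3 rows")
        if not (0.0 < self.prob_level < 1.0):
            raise ValueError("prob_level must be in (0, 1)")
        n = X.shape[0]
        self.mean_ = X.mean(axis=0)
        Xc = X - self.mean_
        if self.standardize:
            sd = Xc.std(axis=0, ddof=0)
            sd[sd == 0] = 1.0
            Xc = Xc / sd
            self.scale_ = sd
        else:
            self.scale_ = None
        _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        eig = s**2 / n  # MLE eigenvalues
        total = eig.sum()
        if total <= 0:
            # all spectra identical: every distance is zero, nothing to flag
            self.n_components_ = 1
            self.components_ = Vt[:1]
            self.eigenvalues_ = eig[:1]
            self.mahalanobis_ = np.zeros(n)
            self.threshold_ = float(stats.chi2.ppf(1.0 - self.prob_level, df=1))
            self.outlier_mask_ = np.zeros(n, dtype=bool)
            return self
        cum = np.cumsum(eig) / total
        k = int(np.searchsorted(cum, self.var_explained) + 1)
        k = min(k, int((eig > 1e-12 * total).sum()))
        scores = Xc @ Vt[:k].T
        d2 = np.sum(scores**2 / eig[:k], axis=1)
        self.n_components_ = k
        self.components_ = Vt[:k]
        self.eigenvalues_ = eig[:k]
        self.mahalanobis_ = d2
        self.threshold_ = float(stats.chi2.ppf(1.0 - self.prob_level, df=k))
        self.outlier_mask_ = d2 > self.threshold_
        return self

    def fit_predict(self, X, y=None):
        """sklearn convention: -1 for outliers, +1 for inliers."""
        self.fit(X)
        return np.where(self.outlier_mask_, -1, 1)


def remove_spectral_outliers(
    spectra: SpectraMatrix,
    prob_level: float = 0.01,
    var_explained: float = 0.99,
    standardize: bool = False,
) -> Tuple[SpectraMatrix, QCReport]:
    """Single-pass PCA+Mahalanobis removal on pooled absorbance spectra."""
    if spectra.scale != "absorbance":
        raise ValueError("outlier removal expects absorbance spectra")
    if spectra.has_replicates:
        raise ValueError("average replicates before outlier removal")
    det = MahalanobisOutlierDetector(prob_level, var_explained, standardize).fit(
        spectra.values
    )
    keep = ~det.outlier_mask_
    report = QCReport()
    report.add(
        "spectral_outliers",
        int(det.outlier_mask_.sum()),
        spectra.animal_ids[det.outlier_mask_],
    )
    return spectra.select(keep), report


def phenotype_qc(
    records: pd.DataFrame, trait: str, k_sd: float = 3.0
) -> Tuple[pd.DataFrame, QCReport]:
    """Per-breed +/- k_sd SD trimming of one trait (value set to missing).

    Mean and SD are computed once on the non-missing values of each breed;
    there is no iterative re-trimming.  Breeds with fewer than two values
    are skipped with a warning.
    """
    col = TRAIT_COLUMNS.get(trait, trait)
    if col not in records.columns:
        raise ValueError(f"trait column {col!r} not found")
    out = records.copy()
    report = QCReport()
    for breed, sub in records.groupby("breed", sort=False):
        vals = sub[col].to_numpy(dtype=float)
        ok = np.isfinite(vals)
        if ok.sum() < 2:
            warnings.warn(
                f"breed {breed!r}: fewer than 2 observations for {trait}; skipped"
            )
            continue
        mu = vals[ok].mean()
        sd = vals[ok].std(ddof=1)
        lo, hi = mu - k_sd * sd, mu + k_sd * sd
        bad = ok & ((vals < lo) | (vals > hi))
        if bad.any():
            idx = sub.index[bad]
            out.loc[idx, col] = np.nan
            report.add("phenotype_qc", int(bad.sum()), sub.loc[idx, "animal_id"], breed, trait)
        else:
            report.add("phenotype_qc", 0, [], breed, trait)
    return out, report


def herd_filter(
    records: pd.DataFrame, min_count: int = 5
) -> Tuple[pd.DataFrame, QCReport]:
    """Drop every (breed, herd) cell with fewer than ``min_count`` animals."""
    report = QCReport()
    if len(records) == 0:
        return records.copy(), report
    sizes = records.groupby(["breed", "herd"])["animal_id"].transform("size")
    keep = sizes >= min_count
    removed = records.loc[~keep]
    for (breed, herd), sub in removed.groupby(["breed", "herd"], sort=False):
        report.add(f"herd_filter[{herd}]", len(sub), sub["animal_id"], breed)
    return records.loc[keep].reset_index(drop=True), report


def run_qc_pipeline(
    spectra: SpectraMatrix,
    records: pd.DataFrame,
    traits: Sequence[str] = ("bcs", "bhb", "kcn"),
    prob_level: float = 0.01,
    var_explained: float = 0.99,
    k_sd: float = 3.0,
    min_herd_count: int = 5,
) -> Tuple[SpectraMatrix, pd.DataFrame, QCReport]:
    """Full QC in the fixed order; returns aligned spectra + records + report.

    An animal failing spectral QC is removed for all traits; an animal
    failing phenotype QC loses only that trait.
    """
    report = QCReport()
    n_input = spectra.n_animals
    if spectra.scale == "transmittance":
        spectra = transmittance_to_absorbance(spectra)
    if spectra.has_replicates:
        spectra = average_replicates(spectra)
    spectra, frag = remove_spectral_outliers(spectra, prob_level, var_explained)
    report.extend(frag)
    keep_ids = set(spectra.animal_ids.tolist())
    records = records[records["animal_id"].isin(keep_ids)].reset_index(drop=True)
    for t in traits:
        records, frag = phenotype_qc(records, t, k_sd)
        report.extend(frag)
    records, frag = herd_filter(records, min_herd_count)
    report.extend(frag)
    keep_ids = set(records["animal_id"].tolist())
    mask = np.array([a in keep_ids for a in spectra.animal_ids])
    spectra = spectra.select(mask)
    # align records to spectra row order
    order = {a: i for i, a in enumerate(spectra.animal_ids)}
    records = records.sort_values("animal_id", key=lambda s: s.map(order)).reset_index(
        drop=True
    )
    report.add("retained", 0, [])
    report.rows[-1]["n_removed"] = 0
    report.rows[-1]["ids"] = f"n_input={n_input};n_retained={spectra.n_animals}"
    return spectra, records, report
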