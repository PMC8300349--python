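"""Synthetic multi-breed herds, phenotypes, and replicate FTIR milk spectra.

The generator emulates the statistical structure a multi-breed spectral
prediction study rests on:

* per-breed phenotype distributions (truncated normals with published
  mean / SD / range for body condition score, blood β-hydroxybutyrate and
  kappa casein),
* a multi-breed herd structure (41 herds, 1–5 breeds each, at least five
  animals per breed within a herd),
* replicate transmittance spectra on a fixed 1060-point grid from
  5011 to 925 cm⁻¹, built as a smooth absorbance baseline plus
  phenotype-linked Gaussian bands plus smooth animal-level noise, with
  small breed-level baseline offsets so breed clouds overlap in PC space.

Band locations are drawn from the seed and reported in the returned
metadata so downstream tests can locate the signal.  All randomness flows
from a single integer seed through named sub-streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple  # noqa: F401

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import substream
from .containers import PHENOTYPE_COLUMNS, SpectraMatrix, TRAIT_COLUMNS, TRAITS

__all__ = [
    "TraitDist",
    "BreedSpec",
    "SpectraGenSpec",
    "HerdPlan",
    "SynthDataset",
    "AllocationError",
    "default_breed_specs",
    "generate_dataset",
    "inject_spectral_outliers",
    "write_phenotypes",
    "read_phenotypes",
    "write_spectra",
    "read_spectra",
]


class AllocationError(ValueError):
    """Raised when animals cannot be allocated to herds under the plan."""


@dataclass(frozen=True)
class TraitDist:
    """Truncated-normal target for one trait within one breed."""

    mean: float
    sd: float
    min: float
    max: float
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("sd must be positive")
        if not (self.min < self.mean < self.max):
            raise ValueError("must have min < mean < max")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")

    def truncnorm(self) -> stats.rv_continuous:
        a = (self.min - self.mean) / self.sd
        b = (self.max - self.mean) / self.sd
        return stats.truncnorm(a, b, loc=self.mean, scale=self.sd)


@dataclass(frozen=True)
class BreedSpec:
    """Cohort size, phenotype targets and spectral offset scale for a breed."""

    name: str
    n_animals: int
    traits: Dict[str, TraitDist]
    spectral_offset_scale: float = 0.3

    def __post_init__(self) -> None:
        if self.n_animals < 0:
            raise ValueError("n_animals must be >= 0")
        unknown = set(self.traits) - set(TRAITS)
        if unknown:
            raise ValueError(f"unknown traits {sorted(unknown)}")


@dataclass(frozen=True)
class SpectraGenSpec:
    """Controls for the spectral layer of the generator.

    ``signal_to_noise`` is the total ratio of phenotype-driven variance to
    animal-level noise variance at the scale of the signal-band averages
    (split evenly across a trait's bands); it bounds the attainable
    prediction R² at snr/(1+snr).  ``replicate_sd`` is replicate-scan noise
    on the absorbance scale.  ``breed_coupling_sd`` perturbs each breed's
    band amplitudes multiplicatively (1 + sd x standard normal, then
    RMS-normalized per trait so only the coupling *direction* varies, never
    a breed's own signal power), emulating breed differences in milk
    composition: the spectra-phenotype link is similar but not identical
    across breeds, so equations calibrated in one breed transfer
    imperfectly to another.
    ``breed_band_shift_sd`` additionally displaces each breed's band centers
    by that multiple of the band width, with a deterministic Hadamard sign
    pattern over (breed, band): every pair of breeds disagrees in about half
    the bands, where their Gaussian signals then overlap by
    exp(-(2 shift)²/4) ~= 0.89 at the default 0.35.  This is the first-order
    mechanism behind the across-breed loss of predictive ability, and the
    sign pattern makes that loss a stable property of the design rather
    than a draw of the seed.
    """

    n_points: int = 1060
    wn_start: float = 5011.0
    wn_end: float = 925.0
    n_signal_bands: int = 6
    signal_to_noise: float = 2.0
    replicate_sd: float = 0.004
    n_replicates: int = 2
    outlier_rate: float = 0.0
    outlier_scale: float = 6.0
    animal_noise_sd: float = 0.01
    smoothing_points: float = 8.0
    breed_coupling_sd: float = 0.2
    breed_band_shift_sd: float = 0.35

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")
        if not self.wn_start > self.wn_end:
            raise ValueError("wn_start must exceed wn_end (descending mid-IR grid)")
        if self.signal_to_noise <= 0:
            raise ValueError("signal_to_noise must be positive")
        if not (0.0 <= self.outlier_rate <= 1.0):
            raise ValueError("outlier_rate must be in [0, 1]")
        if self.outlier_scale <= 0:
            raise ValueError("outlier_scale must be positive")
        if self.replicate_sd < 0 or self.animal_noise_sd <= 0:
            raise ValueError("noise SDs must be non-negative (animal noise positive)")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    @property
    def grid(self) -> np.ndarray:
        return np.linspace(self.wn_start, self.wn_end, self.n_points)


@dataclass(frozen=True)
class HerdPlan:
    """Target herd structure: herd count and per-cell minimum."""

    n_herds: int = 41
    min_breeds_per_herd: int = 1
    max_breeds_per_herd: int = 5
    min_per_breed_herd: int = 5

    def __post_init__(self) -> None:
        if self.n_herds < 1:
            raise ValueError("n_herds must be >= 1")
        if self.min_per_breed_herd < 1:
            raise ValueError("min_per_breed_herd must be >= 1")
        if not (1 <= self.min_breeds_per_herd <= self.max_breeds_per_herd):
            raise ValueError("invalid breeds-per-herd range")


@dataclass
class SynthDataset:
    """Bundle returned by :func:`generate_dataset`."""

    phenotypes: pd.DataFrame
    spectra: SpectraMatrix  # transmittance, (n, n_replicates, n_points)
    true_absorbance: np.ndarray  # (n, n_points), noise-free per-animal absorbance
    metadata: dict = field(default_factory=dict)


# --------------------------------------------------------------------------
# Default study population: five breeds, published per-breed distributions.
# Missing rates reproduce each trait's observed N relative to cohort size.
# --------------------------------------------------------------------------

_DEFAULT_TABLE = {
    # breed: (n, {trait: (mean, sd, min, max, n_observed)})
    "Holstein": (
        468,
        {
            "bcs": (2.81, 0.324, 2.00, 3.75, 460),
            "bhb": (0.55, 0.163, 0.22, 1.01, 449),
            "kcn": (13.73, 2.151, 8.27, 20.15, 392),
        },
    ),
    "Brown Swiss": (
        657,
        {
            "bcs": (2.96, 0.339, 2.00, 4.00, 646),
            "bhb": (0.58, 0.136, 0.32, 1.03, 620),
            "kcn": (16.13, 1.632, 11.31, 21.40, 520),
        },
    ),
    "Simmental": (
        157,
        {
            "bcs": (3.06, 0.342, 2.50, 4.00, 154),
            "bhb": (0.62, 0.146, 0.34, 1.01, 155),
            "kcn": (14.25, 1.386, 9.83, 17.80, 93),
        },
    ),
    "Rendena": (
        104,
        {
            "bcs": (2.97, 0.346, 2.00, 3.75, 99),
            "bhb": (0.53, 0.112, 0.32, 0.90, 97),
            "kcn": (14.53, 2.219, 8.89, 19.55, 95),
        },
    ),
    "Alpine Grey": (
        75,
        {
            "bcs": (3.07, 0.342, 2.50, 4.00, 73),
            "bhb": (0.56, 0.109, 0.33, 0.87, 68),
            "kcn": (15.34, 1.882, 10.60, 20.18, 68),
        },
    ),
}


def default_breed_specs(
    n_scale: float = 1.0, with_missingness: bool = True
) -> List[BreedSpec]:
    """The default five-breed study population.

    ``n_scale`` rescales every cohort (useful for fast tests);
    ``with_missingness=False`` makes every trait observed on every animal.
    """
    specs = []
    for name, (n, traits) in _DEFAULT_TABLE.items():
        dists = {}
        for t, (mean, sd, lo, hi, n_obs) in traits.items():
            rate = max(0.0, 1.0 - n_obs / n) if with_missingness else 0.0
            dists[t] = TraitDist(mean, sd, lo, hi, missing_rate=rate)
        specs.append(BreedSpec(name, int(round(n * n_scale)), dists))
    return specs


# --------------------------------------------------------------------------
# Herd allocation
# --------------------------------------------------------------------------


def _allocate_herds(
    breed_specs: Sequence[BreedSpec], plan: HerdPlan, rng: np.random.Generator
) -> Dict[str, np.ndarray]:
    """Assign each animal to a herd; every (breed, herd) cell present has at
    least ``min_per_breed_herd`` animals and every herd hosts >= 1 breed."""
    m = plan.min_per_breed_herd
    names = [b.name for b in breed_specs]
    n_by_breed = {b.name: b.n_animals for b in breed_specs}

    # how many herds each breed can populate
    capacity = {name: n_by_breed[name] // m for name in names}
    for name in names:
        if n_by_breed[name] > 0 and capacity[name] == 0:
            raise AllocationError(
                f"breed {name!r}: {n_by_breed[name]} animals cannot fill even one "
                f"herd cell of minimum size {m}"
            )

    herds_of: Dict[str, np.ndarray] = {}
    covered = np.zeros(plan.n_herds, dtype=bool)
    # largest breeds first so coverage is satisfied by the big cohorts
    for name in sorted(names, key=lambda nm: -n_by_breed[nm]):
        if n_by_breed[name] == 0:
            herds_of[name] = np.array([], dtype=int)
            continue
        k = min(plan.n_herds, capacity[name])
        uncovered = np.flatnonzero(~covered)
        if len(uncovered) >= k:
            chosen = rng.choice(uncovered, size=k, replace=False)
        else:
            rest = rng.choice(
                np.flatnonzero(covered), size=k - len(uncovered), replace=False
            )
            chosen = np.concatenate([uncovered, rest])
        covered[chosen] = True
        herds_of[name] = np.sort(chosen)
    if not covered.all():
        raise AllocationError(
            f"{int((~covered).sum())} herd(s) could not be covered by any breed; "
            "reduce n_herds or min_per_breed_herd"
        )

    assignment: Dict[str, np.ndarray] = {}
    for b in breed_specs:
        herds = herds_of[b.name]
        if b.n_animals == 0:
            assignment[b.name] = np.array([], dtype=int)
            continue
        counts = np.full(len(herds), m, dtype=int)
        extra = b.n_animals - counts.sum()
        if extra > 0:
            counts += rng.multinomial(extra, np.full(len(herds), 1.0 / len(herds)))
        labels = np.repeat(herds, counts)
        rng.shuffle(labels)
        assignment[b.name] = labels
    return assignment


# --------------------------------------------------------------------------
# Spectral layer
# --------------------------------------------------------------------------


def _smooth_noise(rng: np.random.Generator, shape: Tuple[int, ...], kernel: np.ndarray) -> np.ndarray:
    """White noise convolved along the last axis, unit pointwise SD."""
    from scipy.ndimage import convolve1d

    white = rng.standard_normal(shape)
    return convolve1d(white, kernel, axis=-1, mode="constant")


def _gaussian_kernel(sigma_points: float) -> np.ndarray:
    half = max(1, int(np.ceil(3 * sigma_points)))
    x = np.arange(-half, half + 1, dtype=float)
    k = np.exp(-0.5 * (x / sigma_points) ** 2)
    # normalize so the smoothed series keeps unit pointwise variance
    return k / np.sqrt((k**2).sum())


def _band_average_noise_var(kernel: np.ndarray, window: int) -> float:
    """Exact variance of the mean over `window` consecutive points of
    unit-variance noise produced by convolving white noise with `kernel`."""
    acf = np.correlate(kernel, kernel, mode="full")  # rho(d) at lags -L..L
    mid = len(acf) // 2
    var = 0.0
    for d in range(-(window - 1), window):
        rho = acf[mid + d] if abs(d) <= mid else 0.0
        var += (window - abs(d)) * rho
    return var / window**2


def _draw_band_centers(
    rng: np.random.Generator, grid: np.ndarray, n_bands: int, min_sep: float
) -> np.ndarray:
    lo, hi = min(grid[0], grid[-1]), max(grid[0], grid[-1])
    span = hi - lo
    lo_c, hi_c = lo + 0.05 * span, hi - 0.05 * span
    centers: List[float] = []
    for _ in range(10000):
        if len(centers) == n_bands:
            break
        c = rng.uniform(lo_c, hi_c)
        if all(abs(c - c0) >= min_sep for c0 in centers):
            centers.append(c)
    if len(centers) < n_bands:
        raise ValueError("could not place non-overlapping signal bands; reduce n_signal_bands")
    return np.array(centers)


def generate_dataset(
    breed_specs: Optional[Sequence[BreedSpec]] = None,
    sgen: Optional[SpectraGenSpec] = None,
    herds: Optional[HerdPlan] = None,
    seed: int = 0,
) -> SynthDataset:
    """Generate a multi-breed phenotype table plus replicate transmittance spectra.

    Deterministic given ``seed``: phenotypes, spectra, herd allocation and
    contamination each draw from a named sub-stream of the master seed.
    """
    if breed_specs is None:
        breed_specs = default_breed_specs()
    sgen = sgen or SpectraGenSpec()
    herds = herds or HerdPlan()
    if not any(b.n_animals > 0 for b in breed_specs):
        raise ValueError("at least one breed must have n_animals > 0")

    rng_ph = substream(seed, "phenotypes")
    rng_sp = substream(seed, "spectra")
    rng_hd = substream(seed, "herds")
    rng_ms = substream(seed, "missingness")

    herd_assignment = _allocate_herds(breed_specs, herds, rng_hd)

    # ---- phenotypes --------------------------------------------------
    rows: List[dict] = []
    counter = 0
    values: Dict[str, List[np.ndarray]] = {t: [] for t in TRAITS}
    for b in breed_specs:
        n = b.n_animals
        ids = [f"A{counter + i + 1:06d}" for i in range(n)]
        counter += n
        dim = rng_ph.uniform(10.0, 380.0, size=n)
        breed_vals = {}
        for t in TRAITS:
            if t in b.traits:
                tn = b.traits[t].truncnorm()
                breed_vals[t] = tn.rvs(size=n, random_state=rng_ph)
            else:
                breed_vals[t] = np.full(n, np.nan)
            values[t].append(breed_vals[t])
        for i in range(n):
            rows.append(
                {
                    "animal_id": ids[i],
                    "breed": b.name,
                    "herd": f"H{herd_assignment[b.name][i] + 1:03d}",
                    "dim": dim[i],
                    **{TRAIT_COLUMNS[t]: breed_vals[t][i] for t in TRAITS},
                }
            )
    pheno = pd.DataFrame(rows, columns=PHENOTYPE_COLUMNS)
    n_total = len(pheno)

    y_full = {t: np.concatenate(values[t]) for t in TRAITS}

    # ---- spectra -----------------------------------------------------
    grid = sgen.grid
    p = sgen.n_points
    step = abs(grid[1] - grid[0])
    kernel = _gaussian_kernel(sgen.smoothing_points)

    # smooth absorbance baseline common to all animals
    n_base = 4
    base_centers = rng_sp.uniform(min(grid), max(grid), size=n_base)
    base_widths = rng_sp.uniform(0.1, 0.3, size=n_base) * abs(grid[0] - grid[-1])
    base_amps = rng_sp.uniform(0.2, 0.6, size=n_base)
    baseline = 0.3 + sum(
        a * np.exp(-0.5 * ((grid - c) / w) ** 2)
        for a, c, w in zip(base_amps, base_centers, base_widths)
    )

    # per-trait signal bands, placed with enough separation to stay disjoint
    widths_cm = rng_sp.uniform(15.0, 35.0, size=(len(TRAITS), sgen.n_signal_bands))
    min_sep = 3.0 * widths_cm.max()
    all_centers = _draw_band_centers(
        rng_sp, grid, len(TRAITS) * sgen.n_signal_bands, min_sep
    ).reshape(len(TRAITS), sgen.n_signal_bands)

    # global standardization of each trait so breed mean differences are
    # carried into the spectra (the spectrum reflects the animal's true value)
    pooled_mean = {}
    pooled_sd = {}
    for t in TRAITS:
        v = y_full[t]
        ok = np.isfinite(v)
        pooled_mean[t] = float(np.mean(v[ok])) if ok.any() else 0.0
        pooled_sd[t] = float(np.std(v[ok])) if ok.sum() > 1 else 1.0
        if pooled_sd[t] == 0:
            pooled_sd[t] = 1.0

    A = np.tile(baseline, (n_total, 1))
    breed_of = pheno["breed"].to_numpy()
    breed_names = [b.name for b in breed_specs]
    # per-breed multiplicative jitter of the band amplitudes: breeds share
    # the same signal bands but couple to them with slightly different
    # strength (breed differences in milk composition)
    coupling = {}
    for name in breed_names:
        raw = 1.0 + sgen.breed_coupling_sd * rng_sp.standard_normal(
            (len(TRAITS), sgen.n_signal_bands)
        )
        # normalize each trait's multiplier vector to unit root-mean-square:
        # jitter rotates the coupling direction across bands but leaves every
        # breed's total signal power (hence its own predictability) unchanged
        rms = np.sqrt(np.mean(raw**2, axis=1, keepdims=True))
        coupling[name] = raw / np.where(rms > 0, rms, 1.0)
    # Per-breed band-center displacement, in units of the band width.
    # Signs follow a Hadamard pattern over (breed, band): every pair of
    # breeds disagrees in about half the bands, so the pairwise coupling
    # overlap -- and with it the across-breed transfer penalty -- is a
    # stable property of the design rather than a draw of the seed.
    from scipy.linalg import hadamard

    H = hadamard(8)
    band_shift = {}
    for i, name in enumerate(breed_names):
        row = H[1 + (i % 7)]
        signs = np.array(
            [row[1 + (b % 7)] for b in range(sgen.n_signal_bands)], dtype=float
        )
        band_shift[name] = sgen.breed_band_shift_sd * np.tile(
            signs, (len(TRAITS), 1)
        )
    band_meta = []
    for ti, t in enumerate(TRAITS):
        z = (y_full[t] - pooled_mean[t]) / pooled_sd[t]
        z = np.where(np.isfinite(z), z, 0.0)
        for bi in range(sgen.n_signal_bands):
            c, w = all_centers[ti, bi], widths_cm[ti, bi]
            shape = np.exp(-0.5 * ((grid - c) / w) ** 2)
            window = np.flatnonzero(shape >= 0.5)  # FWHM window
            m_win = max(1, len(window))
            gbar = float(shape[window].mean()) if len(window) else 1.0
            noise_var = (
                _band_average_noise_var(kernel, m_win) * sgen.animal_noise_sd**2
                + sgen.replicate_sd**2 / (m_win * sgen.n_replicates)
            )
            # signal_to_noise is the total phenotype-driven variance ratio
            # across all of a trait's bands, so split it evenly per band
            snr_band = sgen.signal_to_noise / sgen.n_signal_bands
            amp = float(np.sqrt(snr_band * noise_var) / gbar)
            for name in breed_names:
                mask_b = breed_of == name
                if not mask_b.any():
                    continue
                c_b = c + band_shift[name][ti, bi] * w
                shape_b = np.exp(-0.5 * ((grid - c_b) / w) ** 2)
                A[mask_b] += np.outer(
                    z[mask_b] * coupling[name][ti, bi], amp * shape_b
                )
            band_meta.append(
                {
                    "trait": t,
                    "center_cm": float(c),
                    "width_cm": float(w),
                    "amplitude": amp,
                    "breed_multipliers": {
                        name: float(coupling[name][ti, bi]) for name in breed_names
                    },
                    "breed_center_shifts_cm": {
                        name: float(band_shift[name][ti, bi] * w)
                        for name in breed_names
                    },
                    "window_idx": window.tolist(),
                }
            )

    # breed baseline offsets: smooth, small relative to within-breed variation
    offset_meta = {}
    for b in breed_specs:
        mask = (pheno["breed"] == b.name).to_numpy()
        curve = _smooth_noise(rng_sp, (p,), kernel) * (
            b.spectral_offset_scale * sgen.animal_noise_sd
        )
        if mask.any():
            A[mask] += curve
        offset_meta[b.name] = curve

    # animal-level smooth noise
    A += sgen.animal_noise_sd * _smooth_noise(rng_sp, (n_total, p), kernel)
    true_absorbance = A.copy()

    # replicates: absorbance-scale replicate noise, then back to transmittance
    if sgen.replicate_sd > 0:
        reps = A[:, None, :] + sgen.replicate_sd * rng_sp.standard_normal(
            (n_total, sgen.n_replicates, p)
        )
    else:
        reps = np.repeat(A[:, None, :], sgen.n_replicates, axis=1)
    T = np.power(10.0, -reps)

    spectra = SpectraMatrix(pheno["animal_id"].to_numpy(), grid, T, scale="transmittance")

    # trait missingness, random per animal
    for b in breed_specs:
        mask = (pheno["breed"] == b.name).to_numpy()
        for t, dist in b.traits.items():
            if dist.missing_rate > 0 and mask.any():
                drop = rng_ms.random(int(mask.sum())) < dist.missing_rate
                col = TRAIT_COLUMNS[t]
                idx = np.flatnonzero(mask)[drop]
                pheno.loc[idx, col] = np.nan

    meta = {
        "seed": int(seed),
        "bands": band_meta,
        "baseline": baseline,
        "breed_offsets": offset_meta,
        "pooled_mean": pooled_mean,
        "pooled_sd": pooled_sd,
    }
    ds = SynthDataset(pheno, spectra, true_absorbance, meta)

    if sgen.outlier_rate > 0:
        contaminated, idx = inject_spectral_outliers(
            spectra, sgen.outlier_rate, sgen.outlier_scale, seed
        )
        ds.spectra = contaminated
        ds.metadata["injected_outliers"] = idx
    return ds


def inject_spectral_outliers(
    spectra: SpectraMatrix, rate: float, scale: float, seed: int = 0
) -> Tuple[SpectraMatrix, List[int]]:
    """Displace a fraction of animals' spectra along a random direction.

    The displacement is ``scale`` x the per-wavenumber SD of the
    (replicate-averaged) spectra, applied along a random unit direction, to
    every replicate of the chosen animals.  Returns the contaminated matrix
    and the sorted list of injected row indices (ground truth for recall
    tests of the outlier-removal step).
    """
    if not (0.0 <= rate <= 1.0):
        raise ValueError(f"rate must be in [0, 1], got {rate}")
    if scale <= 0:
        raise ValueError("scale must be positive")
    out = spectra.copy()
    n = out.n_animals
    k = int(round(rate * n))
    if k == 0:
        return out, []
    rng = substream(seed, "outliers")
    idx = np.sort(rng.choice(n, size=k, replace=False))
    avg = out.values.mean(axis=1) if out.has_replicates else out.values
    point_sd = avg.std(axis=0, ddof=0)
    for i in idx:
        direction = rng.standard_normal(out.n_points)
        direction /= np.linalg.norm(direction)
        disp = scale * point_sd * direction
        if out.has_replicates:
            out.values[i] += disp[None, :]
        else:
            out.values[i] += disp
    return out, [int(i) for i in idx]


# --------------------------------------------------------------------------
# CSV dialects
# --------------------------------------------------------------------------


def write_phenotypes(pheno: pd.DataFrame, path) -> None:
    """Phenotype CSV: animal_id, breed, herd, dim, bcs, bhb_mmol_l, kcn_pct_n."""
    pheno.to_csv(path, index=False, columns=PHENOTYPE_COLUMNS)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(PHENOTYPE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"phenotype file missing columns {sorted(missing)}")
    return df[PHENOTYPE_COLUMNS]


def write_spectra(spectra: SpectraMatrix, path) -> None:
    """Wide CSV: animal_id, replicate, then one column per wavenumber (cm-1)."""
    wn_cols = [f"{w:.10g}" for w in spectra.wavenumbers]
    if spectra.has_replicates:
        n, r, p = spectra.values.shape
        ids = np.repeat(spectra.animal_ids, r)
        rep = np.tile(np.arange(1, r + 1), n)
        flat = spectra.values.reshape(n * r, p)
    else:
        ids = spectra.animal_ids
        rep = np.ones(spectra.n_animals, dtype=int)
        flat = spectra.values
    df = pd.DataFrame(flat, columns=wn_cols)
    df.insert(0, "replicate", rep)
    df.insert(0, "animal_id", ids)
    df.to_csv(path, index=False)


def read_spectra(path, scale: str = "transmittance") -> SpectraMatrix:
    df = pd.read_csv(path)
    if df.columns[0] != "animal_id" or df.columns[1] != "replicate":
        raise ValueError("spectra file must start with animal_id, replicate columns")
    wn = np.array([float(c) for c in df.columns[2:]])
    reps = df["replicate"].to_numpy()
    ids = df["animal_id"].to_numpy()
    vals = df.iloc[:, 2:].to_numpy(dtype=float)
    r = int(reps.max())
    if r == 1:
        return SpectraMatrix(ids, wn, vals, scale=scale)
    uniq_ids = pd.unique(ids)
    n, p = len(uniq_ids), len(wn)
    cube = np.empty((n, r, p))
    pos = {a: i for i, a in enumerate(uniq_ids)}
    for row in range(len(df)):
        cube[pos[ids[row]], reps[row] - 1] = vals[row]
    return SpectraMatrix(np.asarray(uniq_ids), wn, cube, scale=scale)
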