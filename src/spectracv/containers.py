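"""Core in-memory containers shared across the pipeline.

Phenotype tables are plain :class:`pandas.DataFrame` objects with the
canonical columns ``animal_id, breed, herd, dim, bcs, bhb_mmol_l,
kcn_pct_n`` (missing trait values are NaN).  Spectra live in
:class:`SpectraMatrix`, which tags the photometric scale so transmittance
and absorbance can never be silently mixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "SpectraMatrix",
    "QCReport",
    "TRAITS",
    "TRAIT_COLUMNS",
    "PHENOTYPE_COLUMNS",
]

#: canonical trait keys, in reporting order
TRAITS = ("bcs", "bhb", "kcn")

#: trait key -> phenotype-table column
TRAIT_COLUMNS = {"bcs": "bcs", "bhb": "bhb_mmol_l", "kcn": "kcn_pct_n"}

PHENOTYPE_COLUMNS = ["animal_id", "breed", "herd", "dim"] + [TRAIT_COLUMNS[t] for t in TRAITS]

_SCALES = ("transmittance", "absorbance")


@dataclass
class SpectraMatrix:
    """Spectra for a set of animals on a common wavenumber grid.

    ``values`` is ``(n_animals, n_points)`` after replicate averaging or
    ``(n_animals, n_replicates, n_points)`` before.  The wavenumber grid is
    strictly monotone (descending by mid-IR convention, but ascending grids
    are accepted).  ``scale`` tags the photometric scale of ``values``.
    """

    animal_ids: np.ndarray
    wavenumbers: np.ndarray
    values: np.ndarray
    scale: str = "transmittance"

    def __post_init__(self) -> None:
        self.animal_ids = np.asarray(self.animal_ids)
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.scale not in _SCALES:
            raise ValueError(f"scale must be one of {_SCALES}, got {self.scale!r}")
        if self.values.ndim not in (2, 3):
            raise ValueError("values must be 2-D (animals x points) or 3-D (with replicates)")
        if self.values.shape[0] != len(self.animal_ids):
            raise ValueError("first axis of values must match animal_ids")
        if self.values.shape[-1] != len(self.wavenumbers):
            raise ValueError("last axis of values must match wavenumbers")
        dw = np.diff(self.wavenumbers)
        if len(dw) and not (np.all(dw > 0) or np.all(dw < 0)):
            raise ValueError("wavenumber grid must be strictly monotone")

    @property
    def n_animals(self) -> int:
        return self.values.shape[0]

    @property
    def n_points(self) -> int:
        return self.values.shape[-1]

    @property
    def has_replicates(self) -> bool:
        return self.values.ndim == 3

    def copy(self) -> "SpectraMatrix":
        return SpectraMatrix(
            self.animal_ids.copy(), self.wavenumbers.copy(), self.values.copy(), self.scale
        )

    def with_values(self, values: np.ndarray, scale: Optional[str] = None) -> "SpectraMatrix":
        return SpectraMatrix(
            self.animal_ids.copy(),
            self.wavenumbers.copy(),
            values,
            self.scale if scale is None else scale,
        )

    def select(self, mask_or_index: np.ndarray) -> "SpectraMatrix":
        """Row subset (boolean mask or integer index), preserving order."""
        return SpectraMatrix(
            self.animal_ids[mask_or_index],
            self.wavenumbers.copy(),
            self.values[mask_or_index],
            self.scale,
        )


@dataclass
class QCReport:
    """Bookkeeping of quality-control removals.

    One row per (stage, breed, trait) with the number of animals (or trait
    observations) removed and their ids.  An animal is counted at the first
    rule that fires; ``n_retained = n_input - total removed`` holds per
    stage by construction.
    """

    rows: list = field(default_factory=list)

    def add(self, stage: str, n_removed: int, ids, breed: str = "all", trait: str = "all") -> None:
        self.rows.append(
            {
                "stage": stage,
                "breed": breed,
                "trait": trait,
                "n_removed": int(n_removed),
                "ids": ",".join(str(i) for i in ids),
            }
        )

    def extend(self, other: "QCReport") -> None:
        self.rows.extend(other.rows)

    def total_removed(self, stage: Optional[str] = None) -> int:
        return sum(r["n_removed"] for r in self.rows if stage is None or r["stage"] == stage)

    def to_frame(self) -> pd.DataFrame:
        cols = ["stage", "breed", "trait", "n_removed", "ids"]
        return pd.DataFrame(self.rows, columns=cols)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)
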