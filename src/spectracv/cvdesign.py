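"""Training/testing designs for multi-breed prediction benchmarking.

Five scenarios, all predicting the target breed (Holstein by default):

* ``10-fold_HO``     — within-breed 10-fold CV on the target breed; the
  whole partition/evaluation cycle is repeated (fresh folds each repeat).
* ``BS_HO``          — across-breed: train on all Brown Swiss, test on all
  Holstein (a single replication).
* ``BS+HO_10-fold``  — multi-breed (specialized): the Brown Swiss cohort is
  appended to every 9-fold Holstein training set.
* ``Multi-breed``    — as above plus the dual-purpose breeds (Simmental,
  Rendena, Alpine Grey).
* ``Multi-breed_CV2``— the Multi-breed training pool is down-sampled to the
  size of the within-breed training set, preserving the pool's breed
  proportions (largest-remainder quotas), in 3 disjoint subsets; each
  subset is paired with every Holstein test fold.

Holstein partitions depend only on (seed, repeat), so different scenarios
built with the same seed share identical test folds — the basis for the
dependent-correlation comparisons downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from ._rng import stream_seed
from .containers import TRAIT_COLUMNS

__all__ = [
    "SCENARIOS",
    "FoldPartition",
    "Replication",
    "CVScenario",
    "make_kfold",
    "build_cv2",
    "build_scenario",
    "trait_cohorts",
]

SCENARIOS = ("10-fold_HO", "BS_HO", "BS+HO_10-fold", "Multi-breed", "Multi-breed_CV2")

TARGET_BREED = "Holstein"
ACROSS_BREED = "Brown Swiss"
EXTRA_BREEDS = ("Simmental", "Rendena", "Alpine Grey")


@dataclass
class FoldPartition:
    """A k-fold partition of a set of ids."""

    k: int
    folds: List[np.ndarray]
    seed: int

    @property
    def assignment(self) -> Dict[object, int]:
        return {i: f for f, ids in enumerate(self.folds) for i in ids}

    def training_ids(self, fold: int) -> np.ndarray:
        return np.concatenate([self.folds[j] for j in range(self.k) if j != fold])


@dataclass
class Replication:
    replication_id: str
    repeat: int
    fold: int
    train_ids: np.ndarray
    test_ids: np.ndarray
    subfold: Optional[int] = None


@dataclass
class CVScenario:
    name: str
    replications: List[Replication]
    n_repeats: int
    target_breed: str = TARGET_BREED

    def manifest(self) -> pd.DataFrame:
        rows = []
        for rep in self.replications:
            for role, ids in (("train", rep.train_ids), ("test", rep.test_ids)):
                for a in ids:
                    rows.append(
                        {
                            "replication_id": rep.replication_id,
                            "repeat": rep.repeat,
                            "fold": rep.fold,
                            "role": role,
                            "animal_id": a,
                        }
                    )
        return pd.DataFrame(rows)


def make_kfold(ids: Sequence, k: int = 10, seed: int = 0) -> FoldPartition:
    """Random k folds of near-equal size (sizes differ by at most one)."""
    ids = np.asarray(list(ids))
    n = len(ids)
    if n < k:
        raise ValueError(f"cannot split {n} ids into {k} folds")
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    perm = ids[rng.permutation(n)]
    base, extra = divmod(n, k)
    folds, start = [], 0
    for f in range(k):
        size = base + (1 if f < extra else 0)
        folds.append(np.sort(perm[start : start + size]))
        start += size
    return FoldPartition(k, folds, seed)


def _largest_remainder_quotas(counts: np.ndarray, target: int) -> np.ndarray:
    """Hamilton apportionment of `target` seats proportional to `counts`."""
    total = counts.sum()
    exact = counts * target / total
    base = np.floor(exact).astype(int)
    short = target - base.sum()
    # stable: by descending fractional remainder, ties to earlier entries
    order = np.argsort(-(exact - base), kind="stable")
    base[order[:short]] += 1
    return base


def build_cv2(
    pool_ids: Sequence,
    pool_breeds: Sequence[str],
    target_size: int,
    n_subfolds: int = 3,
    seed: int = 0,
) -> List[np.ndarray]:
    """Split a multi-breed training pool into ``n_subfolds`` disjoint subsets,
    each of exactly ``target_size`` animals with the pool's breed proportions
    (largest-remainder rounding)."""
    pool_ids = np.asarray(list(pool_ids))
    pool_breeds = np.asarray(list(pool_breeds))
    if len(pool_ids) != len(pool_breeds):
        raise ValueError("pool_ids and pool_breeds must align")
    total = len(pool_ids)
    if target_size * n_subfolds > total:
        raise ValueError(
            f"target_size {target_size} x {n_subfolds} subfolds exceeds pool of {total}"
        )
    breeds, counts = np.unique(pool_breeds, return_counts=True)
    quotas = _largest_remainder_quotas(counts, target_size)
    infeasible = quotas * n_subfolds > counts
    if infeasible.any():
        raise ValueError(
            f"breed(s) {breeds[infeasible].tolist()} too small for "
            f"{n_subfolds} disjoint quota subsets"
        )
    rng = np.random.default_rng(seed)
    subsets: List[List] = [[] for _ in range(n_subfolds)]
    for b, q in zip(breeds, quotas):
        members = pool_ids[pool_breeds == b]
        perm = members[rng.permutation(len(members))]
        for s in range(n_subfolds):
            subsets[s].extend(perm[s * q : (s + 1) * q])
    return [np.sort(np.asarray(s)) for s in subsets]


def trait_cohorts(records: pd.DataFrame, trait: str) -> Dict[str, np.ndarray]:
    """Per-breed ids with the trait observed (post-QC cohorts differ by trait)."""
    col = TRAIT_COLUMNS.get(trait, trait)
    ok = records[np.isfinite(records[col].to_numpy(dtype=float))]
    return {b: sub["animal_id"].to_numpy() for b, sub in ok.groupby("breed", sort=False)}


def _require(breed_ids: Mapping[str, Sequence], breed: str) -> np.ndarray:
    ids = np.asarray(list(breed_ids.get(breed, [])))
    if len(ids) == 0:
        raise ValueError(f"scenario requires breed {breed!r} but its cohort is empty")
    return ids


def build_scenario(
    name: str,
    breed_ids: Mapping[str, Sequence],
    k: int = 10,
    n_repeats: int = 10,
    seed: int = 0,
    target_breed: str = TARGET_BREED,
    across_breed: str = ACROSS_BREED,
    extra_breeds: Sequence[str] = EXTRA_BREEDS,
    cv2_subfolds: int = 3,
    cv2_split_repeats: int = 3,
    cv2_target_size: Optional[int] = None,
) -> CVScenario:
    """Construct one named scenario over per-breed id cohorts.

    A fresh Holstein partition is drawn per repeat from (seed, repeat) only,
    so scenarios built with equal seeds share test folds exactly.
    """
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; expected one of {SCENARIOS}")
    target = _require(breed_ids, target_breed)

    if name == "BS_HO":
        train = _require(breed_ids, across_breed)
        rep = Replication(f"{name}:rep0:fold0", 0, 0, np.sort(train), np.sort(target))
        return CVScenario(name, [rep], 1, target_breed)

    if name in ("BS+HO_10-fold", "Multi-breed", "Multi-breed_CV2"):
        appended = [_require(breed_ids, across_breed)]
        if name in ("Multi-breed", "Multi-breed_CV2"):
            appended += [_require(breed_ids, b) for b in extra_breeds]
        appended_ids = np.concatenate(appended)
        appended_breeds = np.concatenate(
            [
                np.full(len(ids), b)
                for ids, b in zip(
                    appended,
                    [across_breed] + (list(extra_breeds) if len(appended) > 1 else []),
                )
            ]
        )
    else:
        appended_ids = np.array([], dtype=target.dtype)
        appended_breeds = np.array([], dtype=object)

    replications: List[Replication] = []
    for r in range(n_repeats):
        part = make_kfold(target, k, stream_seed(seed, f"holstein-partition:{r}"))
        for f in range(k):
            test = part.folds[f]
            ho_train = part.training_ids(f)
            if name == "Multi-breed_CV2":
                pool = np.concatenate([ho_train, appended_ids])
                breeds = np.concatenate(
                    [np.full(len(ho_train), target_breed), appended_breeds]
                )
                tsize = cv2_target_size if cv2_target_size is not None else len(ho_train)
                # the 3-way training split is itself redrawn several times,
                # so the full schedule is k folds x repeats x draws x subsets
                for d in range(cv2_split_repeats):
                    subsets = build_cv2(
                        pool,
                        breeds,
                        tsize,
                        cv2_subfolds,
                        stream_seed(seed, f"cv2:{r}:{f}:{d}"),
                    )
                    for s, sub in enumerate(subsets):
                        replications.append(
                            Replication(
                                f"{name}:rep{r}:fold{f}:draw{d}:sub{s}",
                                r,
                                f,
                                sub,
                                test,
                                subfold=d * cv2_subfolds + s,
                            )
                        )
            else:
                train = (
                    np.sort(np.concatenate([ho_train, appended_ids]))
                    if len(appended_ids)
                    else ho_train
                )
                replications.append(
                    Replication(f"{name}:rep{r}:fold{f}", r, f, train, test)
                )
    return CVScenario(name, replications, n_repeats, target_breed)
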