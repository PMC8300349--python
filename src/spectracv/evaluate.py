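"""Prediction-performance statistics and dependent-correlation comparisons.

Per replication: Pearson correlation between observed and predicted
phenotypes (rp), RMSE, mean percentage error (MPE, signed, in percent), and
the OLS slope of observed on predicted (1 = unbiased).  Across scenarios:
the relative difference in predictive ability

    RD = (r_m - r_C) / r_C * 100,

with the within-breed 10-fold scenario as reference r_C, the
Hotelling–Williams t-test for two dependent correlations sharing the
observed phenotype, and Zou's modified-asymptotic confidence interval for
the difference of overlapping correlations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "pearson_r",
    "rmse",
    "mpe",
    "bias_slope",
    "relative_difference",
    "hotelling_williams",
    "zou_difference_ci",
    "EvalResult",
    "score_replication",
    "aggregate",
]


def _check_pair(obs, pred) -> Tuple[np.ndarray, np.ndarray]:
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("obs and pred must have equal length")
    return obs, pred


def pearson_r(obs, pred) -> float:
    """Product-moment correlation of observed and predicted values."""
    obs, pred = _check_pair(obs, pred)
    if len(obs) < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(obs) == 0 or np.ptp(pred) == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(np.corrcoef(obs, pred)[0, 1])


def rmse(obs, pred) -> float:
    obs, pred = _check_pair(obs, pred)
    if len(obs) < 1:
        raise ValueError("need at least 1 pair")
    return float(np.sqrt(np.mean((obs - pred) ** 2)))


def mpe(obs, pred, population_mean_numerator: bool = False) -> float:
    """Mean percentage error, in percent.

    Default (per-observation): mean over i of (obs_i - pred_i)/obs_i x 100.
    ``population_mean_numerator=True`` replaces obs_i in the numerator with
    the mean observed value (an alternative reading of the statistic).
    """
    obs, pred = _check_pair(obs, pred)
    if np.any(obs == 0):
        raise ValueError("MPE undefined when an observed value is zero")
    num = (obs.mean() - pred) if population_mean_numerator else (obs - pred)
    return float(np.mean(num / obs) * 100.0)


def bias_slope(obs, pred) -> float:
    """OLS slope of observed regressed on predicted (1 = unbiased)."""
    obs, pred = _check_pair(obs, pred)
    if len(obs) < 3:
        raise ValueError("need at least 3 pairs")
    vp = np.var(pred)
    if vp == 0:
        raise ValueError("slope undefined for constant predictions")
    return float(np.cov(pred, obs, ddof=0)[0, 1] / vp)


def relative_difference(rm: float, rc: float) -> float:
    """RD = (rm - rc) / rc * 100 (reference rc is the within-breed design)."""
    if rc == 0:
        raise ValueError("reference correlation must be non-zero")
    return (rm - rc) / rc * 100.0


def hotelling_williams(
    r12: float, r13: float, r23: float, n: int
) -> Tuple[float, float]:
    """Williams' t-test for H0: rho12 = rho13 (correlations sharing variable 1).

    Variable 1 is the observed phenotype; 2 and 3 are two prediction
    vectors.  Returns (t, two-sided p) with n - 3 degrees of freedom.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    for r in (r12, r13, r23):
        if not -1.0 < r < 1.0:
            raise ValueError("correlations must lie strictly inside (-1, 1)")
    detR = 1.0 - r12**2 - r13**2 - r23**2 + 2.0 * r12 * r13 * r23
    if detR <= 1e-12:
        raise ValueError("degenerate correlation matrix (|R| <= 0)")
    rbar = 0.5 * (r12 + r13)
    denom = 2.0 * detR * (n - 1) / (n - 3) + rbar**2 * (1.0 - r23) ** 3
    t = (r12 - r13) * np.sqrt((n - 1) * (1.0 + r23) / denom)
    p = 2.0 * stats.t.sf(abs(t), df=n - 3)
    return float(t), float(p)


def zou_difference_ci(
    r12: float,
    r13: float,
    r23: float,
    n: int,
    alpha: float = 0.05,
    independent: bool = False,
) -> Tuple[float, float]:
    """Zou's modified-asymptotic CI for rho12 - rho13 (overlapping case).

    Individual Fisher-z intervals for each correlation are back-transformed
    and combined using the correlation between the two sample correlations;
    ``independent=True`` forces that term to zero (the limiting case of two
    independent correlations).
    """
    if n < 4:
        raise ValueError("need n >= 4")
    for r in (r12, r13, r23):
        if not -1.0 < r < 1.0:
            raise ValueError("correlations must lie strictly inside (-1, 1)")
    zcrit = stats.norm.ppf(1.0 - alpha / 2.0)
    se = 1.0 / np.sqrt(n - 3)

    def fisher_ci(r):
        z = np.arctanh(r)
        return np.tanh(z - zcrit * se), np.tanh(z + zcrit * se)

    l1, u1 = fisher_ci(r12)
    l2, u2 = fisher_ci(r13)
    if independent:
        c = 0.0
    else:
        num = (r23 - 0.5 * r12 * r13) * (1.0 - r12**2 - r13**2 - r23**2) + r23**3
        den = (1.0 - r12**2) * (1.0 - r13**2)
        c = num / den
    diff = r12 - r13
    lower = diff - np.sqrt(
        (r12 - l1) ** 2 + (u2 - r13) ** 2 - 2.0 * c * (r12 - l1) * (u2 - r13)
    )
    upper = diff + np.sqrt(
        (u1 - r12) ** 2 + (r13 - l2) ** 2 - 2.0 * c * (u1 - r12) * (r13 - l2)
    )
    return float(lower), float(upper)


def simulate_dependent_correlations(
    n: int,
    sims: int,
    rho12: float,
    rho13: float,
    rho23: float,
    seed: int = 0,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample correlation triplets from a trivariate normal.

    Returns (r12, r13, r23) arrays of length ``sims``, the sampling
    distribution used to calibrate the dependent-correlation tests.
    """
    R = np.array([[1.0, rho12, rho13], [rho12, 1.0, rho23], [rho13, rho23, 1.0]])
    L = np.linalg.cholesky(R)
    rng = np.random.default_rng(seed)
    out12 = np.empty(sims)
    out13 = np.empty(sims)
    out23 = np.empty(sims)
    chunk = max(1, int(2e7 // (n * 3)))
    done = 0
    while done < sims:
        m = min(chunk, sims - done)
        X = rng.standard_normal((m, n, 3)) @ L.T
        Xc = X - X.mean(axis=1, keepdims=True)
        S = np.einsum("sni,snj->sij", Xc, Xc)
        d = np.sqrt(np.einsum("sii->si", S))
        C = S / (d[:, :, None] * d[:, None, :])
        out12[done : done + m] = C[:, 0, 1]
        out13[done : done + m] = C[:, 0, 2]
        out23[done : done + m] = C[:, 1, 2]
        done += m
    return out12, out13, out23


@dataclass
class EvalResult:
    """Per-replication scores."""

    scenario: str
    trait: str
    replication_id: str
    rp: float
    rmse: float
    mpe_pct: float
    slope: float


def score_replication(
    scenario: str, trait: str, replication_id: str, obs, pred
) -> EvalResult:
    return EvalResult(
        scenario,
        trait,
        replication_id,
        rp=pearson_r(obs, pred),
        rmse=rmse(obs, pred),
        mpe_pct=mpe(obs, pred),
        slope=bias_slope(obs, pred),
    )


def aggregate(results: Sequence[EvalResult]) -> pd.DataFrame:
    """Mean and SD of each statistic per (scenario, trait), long format.

    With a single replication the SD is reported as NaN (absent), matching
    how single-replication designs are tabulated.
    """
    if len(results) == 0:
        raise ValueError("no results to aggregate")
    df = pd.DataFrame(
        [
            {
                "scenario": r.scenario,
                "trait": r.trait,
                "rp": r.rp,
                "rmse": r.rmse,
                "mpe_pct": r.mpe_pct,
                "slope": r.slope,
            }
            for r in results
        ]
    )
    rows = []
    for (scn, trait), sub in df.groupby(["scenario", "trait"], sort=False):
        for stat in ("rp", "rmse", "mpe_pct", "slope"):
            v = sub[stat].to_numpy()
            rows.append(
                {
                    "scenario": scn,
                    "trait": trait,
                    "stat": stat,
                    "mean": float(v.mean()),
                    "sd": float(v.std(ddof=1)) if len(v) > 1 else np.nan,
                    "n_reps": len(v),
                }
            )
    return pd.DataFrame(rows)
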