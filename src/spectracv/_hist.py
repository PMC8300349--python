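"""Numba kernels for histogram-based CART split search and tree prediction."""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["build_hist", "sub_hist", "best_split", "predict_tree"]


@njit(cache=True)
def build_hist(codes_t, rows, resid, n_bins):
    """Per-feature bin counts and residual sums over the given rows.

    ``codes_t`` is feature-major (p, n) so each feature's code row and the
    residual vector stay cache-resident in the inner loop.
    """
    p = codes_t.shape[0]
    cnt = np.zeros((p, n_bins), np.int64)
    sm = np.zeros((p, n_bins), np.float64)
    for j in range(p):
        for ii in range(rows.size):
            i = rows[ii]
            c = codes_t[j, i]
            cnt[j, c] += 1
            sm[j, c] += resid[i]
    return cnt, sm


@njit(cache=True)
def sub_hist(parent_cnt, parent_sm, child_cnt, child_sm):
    """Sibling histogram by subtraction (parent minus one child)."""
    return parent_cnt - child_cnt, parent_sm - child_sm


@njit(cache=True)
def best_split(cnt, sm, n_edges, min_leaf, n_tot, s_tot, tol):
    """Best (feature, edge) split by SSE reduction.

    Scans features then edges in ascending order and only accepts strictly
    larger gains, so ties resolve to the lowest feature index and then the
    lowest threshold.  Returns (-1, -1, 0.0) when no admissible split
    improves the SSE by more than ``tol``.
    """
    p = cnt.shape[0]
    best_feat = -1
    best_edge = -1
    best_gain = tol
    parent = s_tot * s_tot / n_tot
    for j in range(p):
        nL = 0
        sL = 0.0
        for e in range(n_edges[j]):
            nL += cnt[j, e]
            sL += sm[j, e]
            nR = n_tot - nL
            if nL < min_leaf:
                continue
            if nR < min_leaf:
                break
            sR = s_tot - sL
            gain = sL * sL / nL + sR * sR / nR - parent
            if gain > best_gain:
                best_gain = gain
                best_feat = j
                best_edge = e
    return best_feat, best_edge, best_gain


@njit(cache=True)
def predict_tree(X, feature, threshold, left, right, value, out):
    """Add each row's leaf value to ``out`` (in place)."""
    for i in range(X.shape[0]):
        node = 0
        while feature[node] >= 0:
            if X[i, feature[node]] <= threshold[node]:
                node = left[node]
            else:
                node = right[node]
        out[i] += value[node]
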