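"""Independent straight-line reference implementations used as test oracles.

Everything here is deliberately naive (pure-python loops, exhaustive
enumeration) and shares no code with the package internals it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def brute_tmm_pair_factor(
    y_k, y_r, n_k: float, n_r: float, trim_m: float = 0.30, trim_a: float = 0.05
) -> float:
    """Trimmed weighted mean of M-values for one sample vs the reference."""
    genes = [i for i in range(len(y_k)) if y_k[i] > 0 and y_r[i] > 0]
    M = {i: math.log2((y_k[i] / n_k) / (y_r[i] / n_r)) for i in genes}
    A = {i: 0.5 * math.log2((y_k[i] / n_k) * (y_r[i] / n_r)) for i in genes}
    W = {
        i: (n_k - y_k[i]) / (n_k * y_k[i]) + (n_r - y_r[i]) / (n_r * y_r[i])
        for i in genes
    }

    def keep_ranks(stat: dict, trim: float) -> set:
        order = sorted(stat, key=lambda i: (stat[i], i))
        n_cut = int(math.floor(trim * len(order)))
        return set(order[n_cut : len(order) - n_cut])

    kept = keep_ranks(M, trim_m) & keep_ranks(A, trim_a)
    if len(kept) < 10:
        return 1.0
    num = sum(W[i] * M[i] for i in kept)
    den = sum(W[i] for i in kept)
    if den <= 0:
        return 1.0
    return 2.0 ** (num / den)


def brute_tmm_factors(matrix: np.ndarray, ref: int, trim_m=0.30, trim_a=0.05):
    """All-sample TMM factors (vs column ``ref``), geometric mean 1."""
    n = matrix.sum(axis=0)
    fs = []
    for k in range(matrix.shape[1]):
        if k == ref:
            fs.append(1.0)
        else:
            fs.append(
                brute_tmm_pair_factor(matrix[:, k], matrix[:, ref], n[k], n[ref], trim_m, trim_a)
            )
    g = math.exp(sum(math.log(f) for f in fs) / len(fs))
    return [f / g for f in fs]


def bh_by_hand(p_values):
    """Benjamini-Hochberg step-up, written from the definition."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adj = [0.0] * m
    running_min = 1.0
    for rank in range(m - 1, -1, -1):
        i = order[rank]
        running_min = min(running_min, p_values[i] * m / (rank + 1))
        adj[i] = running_min
    return adj


def best_two_partition_inertia(X: np.ndarray) -> float:
    """Exhaustive minimum k=2 within-cluster sum of squares."""
    n = X.shape[0]
    best = math.inf
    for bits in range(1, 2 ** (n - 1)):
        a = [i for i in range(n) if bits >> i & 1]
        b = [i for i in range(n) if not bits >> i & 1]
        inertia = 0.0
        for members in (a, b):
            if not members:
                continue
            centroid = X[members].mean(axis=0)
            inertia += float(((X[members] - centroid) ** 2).sum())
        best = min(best, inertia)
    return best


def brute_average_linkage_heights(D: np.ndarray) -> list[float]:
    """Merge heights of naive average-linkage agglomeration on a distance
    matrix (average of the original pairwise distances between clusters)."""
    n = D.shape[0]
    clusters: list[list[int]] = [[i] for i in range(n)]
    heights = []
    while len(clusters) > 1:
        best = (math.inf, None)
        for i, j in itertools.combinations(range(len(clusters)), 2):
            d = np.mean([D[a, b] for a in clusters[i] for b in clusters[j]])
            if d < best[0] - 1e-15:
                best = (d, (i, j))
        d, (i, j) = best
        heights.append(float(d))
        merged = clusters[i] + clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return heights


def poisson_lrt_pvalues(y_t: np.ndarray, y_c: np.ndarray, lib_t, lib_c):
    """Two-group Poisson LRT p-values with per-sample exposures."""
    from scipy.stats import chi2

    def ll(y, lib):
        rate = y.sum() / lib.sum()
        if rate == 0:
            return 0.0
        mu = rate * lib
        return float(np.sum(np.where(y > 0, y * np.log(mu), 0.0) - mu))

    out = []
    for g in range(y_t.shape[0]):
        l1 = ll(y_t[g], lib_t) + ll(y_c[g], lib_c)
        l0 = ll(np.concatenate([y_t[g], y_c[g]]), np.concatenate([lib_t, lib_c]))
        lr = max(2 * (l1 - l0), 0.0)
        out.append(float(chi2.sf(lr, 1)))
    return np.array(out)
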