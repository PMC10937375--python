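"""Independent brute-force oracles used by the test suite.

Everything here is written as explicit position-by-position loops, kept
deliberately separate from the package's vectorized implementations.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import rankdata


def ssgsea_oracle(column: np.ndarray, member_idx: list[int], tau: float) -> float:
    """Integrated weighted KS walk for one sample and one gene set.

    ``column``: expression values for all genes of one sample.
    ``member_idx``: gene indices belonging to the set.
    """
    n = len(column)
    ranks = rankdata(column)  # 1..n, highest expression -> n, ties averaged
    # walk order: decreasing rank, ties by ascending gene index
    order = sorted(range(n), key=lambda i: (-ranks[i], i))
    in_set = set(member_idx)
    denom = sum(abs(ranks[i]) ** tau for i in in_set)
    n_out = n - len(in_set)
    cum_in = 0.0
    cum_out = 0.0
    es = 0.0
    for i in order:
        if i in in_set:
            cum_in += abs(ranks[i]) ** tau / denom
        else:
            cum_out += 1.0 / n_out
        es += cum_in - cum_out
    return es


def gsva_oracle(
    values: np.ndarray,
    member_idx: list[int],
    tau: float = 1.0,
    max_diff: bool = True,
    bandwidth_floor: float = 1e-8,
) -> np.ndarray:
    """Kernel-CDF GSVA walk for one gene set, straight-line implementation.

    ``values``: genes x samples matrix. Returns one score per sample.
    """
    n_genes, n_samples = values.shape
    z = np.zeros_like(values)
    for i in range(n_genes):
        bw = max(float(np.std(values[i], ddof=1)) / 4.0, bandwidth_floor)
        for j in range(n_samples):
            acc = 0.0
            for k in range(n_samples):
                acc += 0.5 * (1.0 + math.erf((values[i, j] - values[i, k]) / (bw * math.sqrt(2))))
            z[i, j] = acc / n_samples
    in_set = set(member_idx)
    n_out = n_genes - len(in_set)
    out = np.zeros(n_samples)
    for j in range(n_samples):
        r = rankdata(z[:, j])
        stat = [abs(r[i] - n_genes / 2.0) for i in range(n_genes)]
        order = sorted(range(n_genes), key=lambda i: (-r[i], i))
        denom = sum(stat[i] ** tau for i in in_set)
        cum_in = 0.0
        cum_out = 0.0
        vmax = 0.0
        vmin = 0.0
        for i in order:
            if i in in_set:
                cum_in += stat[i] ** tau / denom
            else:
                cum_out += 1.0 / n_out
            v = cum_in - cum_out
            vmax = max(vmax, v)
            vmin = min(vmin, v)
        if max_diff:
            out[j] = vmax + vmin
        else:
            out[j] = vmax if vmax > -vmin else vmin
    return out


def silhouette_oracle(points: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette width from explicit pairwise distances."""
    n = len(points)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            dist[i, j] = math.dist(points[i], points[j])
    widths = []
    for i in range(n):
        same = [j for j in range(n) if j != i and labels[j] == labels[i]]
        if not same:
            widths.append(0.0)
            continue
        a = sum(dist[i, j] for j in same) / len(same)
        b = math.inf
        for other in set(labels.tolist()) - {labels[i]}:
            members = [j for j in range(n) if labels[j] == other]
            b = min(b, sum(dist[i, j] for j in members) / len(members))
        widths.append((b - a) / max(a, b))
    return float(np.mean(widths))
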