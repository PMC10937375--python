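"""Single-sample gene-set scoring.

Two statistics are provided:

* ``ssgsea`` — the integrated (summed) weighted Kolmogorov-Smirnov walk on
  per-sample expression ranks. The enrichment score is the SUM of the
  in-set minus out-of-set cumulative fractions over all gene positions,
  not the maximum deviation. Optional range normalization divides the
  whole score matrix by (global max - global min), and those extremes are
  retained so that new cohorts can be scaled onto the training range.
* ``gsva`` — the kernel-CDF variant: per-gene Gaussian kernel cumulative
  density across samples, symmetric rank statistic within sample, weighted
  KS walk with either max-deviation or max+min ("max diff") summary.

Both are rank-based: any strictly monotone per-sample transform of the
expression values leaves ssGSEA scores unchanged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .formats_io import DataError, ExpressionMatrix, GeneSetCollection

#: bandwidth floor for zero-variance genes in the gsva kernel
BANDWIDTH_FLOOR = 1e-8


@dataclass
class EnrichmentParams:
    method: str = "ssgsea"
    tau: float = 0.25
    normalize: bool = True
    gsva_max_diff: bool = True
    gsva_tau: float = 1.0

    def __post_init__(self) -> None:
        if self.method not in ("ssgsea", "gsva"):
            raise ValueError(f"method must be 'ssgsea' or 'gsva', got {self.method!r}")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")


@dataclass
class ScoreMatrix:
    """Gene sets x samples enrichment scores plus the scoring parameters."""

    set_names: list[str]
    sample_ids: list[str]
    scores: np.ndarray
    params: EnrichmentParams
    norm_min: float | None = None
    norm_max: float | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.set_names), len(self.sample_ids)):
            raise DataError("score matrix shape does not match name lists")

    @property
    def n_sets(self) -> int:
        return len(self.set_names)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.set_names, columns=self.sample_ids)

    def subset_sets(self, names: list[str]) -> "ScoreMatrix":
        idx = {n: i for i, n in enumerate(self.set_names)}
        missing = [n for n in names if n not in idx]
        if missing:
            raise DataError(f"unknown set names: {missing[:5]}")
        rows = [idx[n] for n in names]
        return ScoreMatrix(
            set_names=list(names),
            sample_ids=list(self.sample_ids),
            scores=self.scores[rows, :],
            params=self.params,
            norm_min=self.norm_min,
            norm_max=self.norm_max,
        )

    def write(self, path: str | Path) -> None:
        """TSV of scores plus a JSON sidecar with params and stored extremes."""
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t")
        sidecar = {
            "params": asdict(self.params),
            "norm_min": self.norm_min,
            "norm_max": self.norm_max,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def rank_transform(x: ExpressionMatrix) -> np.ndarray:
    """Column-wise ranks, 1..N with N for the highest expression; ties averaged."""
    return np.apply_along_axis(rankdata, 0, x.values)


def _membership(c: GeneSetCollection, gene_ids: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Boolean sets x genes membership matrix over the matrix's gene universe."""
    index = {g: i for i, g in enumerate(gene_ids)}
    n_genes = len(gene_ids)
    m = np.zeros((len(c.set_names), n_genes), dtype=bool)
    for si, name in enumerate(c.set_names):
        hits = [index[g] for g in c.members[name] if g in index]
        if not hits:
            raise DataError(f"gene set {name!r} has no member in the expression matrix")
        m[si, hits] = True
    sizes = m.sum(axis=1)
    if (sizes >= n_genes).any():
        bad = c.set_names[int(np.argmax(sizes >= n_genes))]
        raise DataError(
            f"gene set {bad!r} covers the whole expression universe; "
            "out-of-set step is undefined"
        )
    return m, sizes


def _ks_walk_sum(values: np.ndarray, member: np.ndarray, sizes: np.ndarray, tau: float) -> np.ndarray:
    """Integrated weighted KS statistic for one sample.

    ``values``: per-gene walk weights (ranks); ``member``: sets x genes.
    Genes are walked in decreasing ``values`` order, ties broken by
    ascending gene index. Returns one score per set.
    """
    n_genes = values.shape[0]
    order = np.lexsort((np.arange(n_genes), -values))
    v_ord = np.abs(values[order]) ** tau
    m_ord = member[:, order]
    in_w = m_ord * v_ord[None, :]
    denom = in_w.sum(axis=1)
    cum_in = np.cumsum(in_w, axis=1) / denom[:, None]
    cum_out = np.cumsum(~m_ord, axis=1) / (n_genes - sizes)[:, None]
    return (cum_in - cum_out).sum(axis=1)


def ssgsea_scores(
    x: ExpressionMatrix, c: GeneSetCollection, p: EnrichmentParams | None = None
) -> ScoreMatrix:
    """ssGSEA enrichment scores for every set and sample.

    With ``p.normalize`` the whole matrix is divided by its global
    (max - min) and those unnormalized extremes are stored on the result.
    """
    p = p or EnrichmentParams()
    if p.method != "ssgsea":
        raise ValueError("ssgsea_scores requires params.method == 'ssgsea'")
    x.require_unique_genes()
    member, sizes = _membership(c, x.gene_ids)
    ranks = rank_transform(x)
    scores = np.empty((len(c.set_names), x.n_samples))
    for j in range(x.n_samples):
        scores[:, j] = _ks_walk_sum(ranks[:, j], member, sizes, p.tau)
    norm_min = norm_max = None
    if p.normalize:
        norm_min = float(scores.min())
        norm_max = float(scores.max())
        if norm_max - norm_min <= 0:
            raise DataError("degenerate score range; cannot range-normalize")
        scores = scores / (norm_max - norm_min)
    return ScoreMatrix(
        set_names=list(c.set_names),
        sample_ids=list(x.sample_ids),
        scores=scores,
        params=p,
        norm_min=norm_min,
        norm_max=norm_max,
    )


def score_with_stored_range(
    x: ExpressionMatrix,
    c: GeneSetCollection,
    p: EnrichmentParams,
    norm_min: float,
    norm_max: float,
) -> ScoreMatrix:
    """ssGSEA scores for new samples scaled by STORED training extremes.

    The new cohort's own range is deliberately not used, so scores are
    directly comparable with the training-time matrix; values outside the
    training range are permitted.
    """
    if not norm_max > norm_min:
        raise DataError("stored range is degenerate (norm_max <= norm_min)")
    raw = ssgsea_scores(
        x, c, EnrichmentParams(method="ssgsea", tau=p.tau, normalize=False)
    )
    return ScoreMatrix(
        set_names=raw.set_names,
        sample_ids=raw.sample_ids,
        scores=raw.scores / (norm_max - norm_min),
        params=EnrichmentParams(method="ssgsea", tau=p.tau, normalize=True),
        norm_min=norm_min,
        norm_max=norm_max,
    )


def _kernel_cdf(values: np.ndarray) -> np.ndarray:
    """Per-gene Gaussian-kernel cumulative density across samples.

    Bandwidth is the per-gene standard deviation / 4, floored for
    zero-variance genes.
    """
    n_genes, n_samples = values.shape
    bw = values.std(axis=1, ddof=1) / 4.0
    bw = np.maximum(bw, BANDWIDTH_FLOOR)
    z = np.empty_like(values)
    for i in range(n_genes):
        diff = (values[i, :, None] - values[i, None, :]) / bw[i]
        z[i] = norm.cdf(diff).mean(axis=1)
    return z


def gsva_scores(
    x: ExpressionMatrix, c: GeneSetCollection, p: EnrichmentParams | None = None
) -> ScoreMatrix:
    """GSVA enrichment scores (Gaussian kernel CDF + weighted KS walk)."""
    p = p or EnrichmentParams(method="gsva")
    if p.method != "gsva":
        raise ValueError("gsva_scores requires params.method == 'gsva'")
    if x.n_samples < 4:
        raise DataError("gsva requires >= 4 samples for the kernel density estimate")
    x.require_unique_genes()
    member, sizes = _membership(c, x.gene_ids)
    z = _kernel_cdf(x.values)
    n_genes = x.n_genes
    scores = np.empty((len(c.set_names), x.n_samples))
    for j in range(x.n_samples):
        r = rankdata(z[:, j])  # ascending, ties averaged
        stat = np.abs(r - n_genes / 2.0)
        order = np.lexsort((np.arange(n_genes), -r))
        w_ord = stat[order] ** p.gsva_tau
        m_ord = member[:, order]
        in_w = m_ord * w_ord[None, :]
        cum_in = np.cumsum(in_w, axis=1) / in_w.sum(axis=1)[:, None]
        cum_out = np.cumsum(~m_ord, axis=1) / (n_genes - sizes)[:, None]
        walk = cum_in - cum_out
        if p.gsva_max_diff:
            scores[:, j] = np.maximum(walk.max(axis=1), 0) + np.minimum(walk.min(axis=1), 0)
        else:
            pos = walk.max(axis=1)
            neg = walk.min(axis=1)
            scores[:, j] = np.where(pos > -neg, pos, neg)
    return ScoreMatrix(
        set_names=list(c.set_names),
        sample_ids=list(x.sample_ids),
        scores=scores,
        params=p,
    )
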