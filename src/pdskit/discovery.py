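"""Unsupervised pathway-level class discovery.

Pipeline: score matrix -> 2-D t-SNE embedding -> per-dimension scaling ->
k-means over a grid of k, with k selected jointly by mean silhouette
width, the elbow (within-cluster SS) curve and bootstrap Jaccard cluster
stability. Clustering operates on the 2-D embedding by default; the full
score matrix can be clustered instead for sensitivity analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from sklearn.cluster import KMeans
from sklearn.manifold import TSNE
from sklearn.metrics import silhouette_score

from .enrichment import EnrichmentParams, ScoreMatrix, ssgsea_scores
from .formats_io import DataError, ExpressionMatrix, GeneSetCollection, filter_sets


@dataclass
class DiscoveryConfig:
    k_grid: tuple[int, ...] = (2, 3, 4, 5, 6, 7, 8)
    perplexity: float = 30.0
    seed: int = 0
    n_bootstrap: int = 100
    stability_floor: float = 0.75
    scale_embedding: bool = True
    tsne_iter: int = 1000
    kmeans_restarts: int = 25
    min_set_size: int = 10
    cluster_on_scores: bool = False  # sensitivity option: cluster the raw score matrix

    def __post_init__(self) -> None:
        if min(self.k_grid) < 2:
            raise ValueError("k_grid must start at k >= 2")
        if not 0 < self.stability_floor < 1:
            raise ValueError("stability_floor must lie in (0, 1)")


@dataclass
class DiscoveryResult:
    embedding: np.ndarray  # samples x 2
    labels: np.ndarray  # per-sample cluster id in 1..chosen_k
    chosen_k: int
    silhouette_by_k: dict[int, float]
    wss_by_k: dict[int, float]
    jaccard_stability_by_k: dict[int, float]
    seed: int
    stability_warning: bool = False
    sample_ids: list[str] = field(default_factory=list)

    def write(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        with open(prefix.with_suffix(".json"), "w") as fh:
            json.dump(
                {
                    "labels": self.labels.tolist(),
                    "sample_ids": self.sample_ids,
                    "chosen_k": self.chosen_k,
                    "silhouette_by_k": {str(k): v for k, v in self.silhouette_by_k.items()},
                    "wss_by_k": {str(k): v for k, v in self.wss_by_k.items()},
                    "jaccard_stability_by_k": {
                        str(k): v for k, v in self.jaccard_stability_by_k.items()
                    },
                    "stability_warning": self.stability_warning,
                    "seed": self.seed,
                },
                fh,
                indent=1,
            )
        with open(prefix.with_suffix(".embedding.tsv"), "w") as fh:
            fh.write("sample_id\tdim1\tdim2\n")
            ids = self.sample_ids or [str(i) for i in range(len(self.embedding))]
            for sid, (d1, d2) in zip(ids, self.embedding):
                fh.write(f"{sid}\t{d1:.8g}\t{d2:.8g}\n")


def embed_scores(s: ScoreMatrix, cfg: DiscoveryConfig) -> np.ndarray:
    """Deterministic 2-D t-SNE embedding of samples, optionally standardized."""
    data = s.scores.T  # samples x sets
    n = data.shape[0]
    if n < 10:
        raise DataError(f"embedding requires >= 10 samples, got {n}")
    bound = (n - 1) / 3.0
    if cfg.perplexity >= bound:
        raise ValueError(
            f"perplexity {cfg.perplexity} too large for {n} samples; must be < {bound:.2f}"
        )
    tsne = TSNE(
        n_components=2,
        perplexity=cfg.perplexity,
        random_state=cfg.seed,
        max_iter=cfg.tsne_iter,
        init="pca",
    )
    emb = np.asarray(tsne.fit_transform(data), dtype=float)
    if cfg.scale_embedding:
        emb = (emb - emb.mean(axis=0)) / emb.std(axis=0, ddof=1)
    return emb


def _canonicalize(labels: np.ndarray, k: int) -> np.ndarray:
    """Relabel clusters 1..k by descending size (ties: first appearance)."""
    sizes = np.bincount(labels, minlength=k)
    first = np.full(k, np.iinfo(np.int64).max)
    for i, lab in enumerate(labels):
        if i < first[lab]:
            first[lab] = min(first[lab], i)
    order = sorted(range(k), key=lambda c: (-sizes[c], first[c]))
    remap = np.empty(k, dtype=int)
    for new, old in enumerate(order):
        remap[old] = new + 1
    return remap[labels]


def kmeans_cluster(embedding: np.ndarray, k: int, seed: int, restarts: int = 25) -> np.ndarray:
    """k-means with restarts; labels canonicalized by descending cluster size."""
    n = embedding.shape[0]
    if k > n:
        raise DataError(f"k={k} exceeds the number of samples ({n})")
    if k == 1:
        return np.ones(n, dtype=int)
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    raw = km.fit_predict(embedding)
    if len(np.unique(raw)) < k:
        raise DataError(f"k-means produced an empty cluster at k={k}")
    return _canonicalize(raw, k)


def _jaccard_stability(
    embedding: np.ndarray, base_labels: np.ndarray, k: int, cfg: DiscoveryConfig
) -> float:
    """Bootstrap cluster-wise Jaccard stability, averaged over clusters and resamples.

    Each resample (with replacement) is re-clustered; every original point
    is then assigned to its nearest bootstrap centroid and each original
    cluster is matched to its best-Jaccard bootstrap cluster.
    """
    rng = np.random.default_rng(cfg.seed + 7919 * k)
    n = embedding.shape[0]
    base_sets = [base_labels == c for c in range(1, k + 1)]
    means = []
    for _ in range(cfg.n_bootstrap):
        idx = rng.integers(0, n, size=n)
        km = KMeans(n_clusters=k, n_init=5, random_state=int(rng.integers(2**31)))
        km.fit(embedding[idx])
        boot_all = km.predict(embedding)
        boot_sets = [boot_all == c for c in range(k)]
        per_cluster = []
        for orig in base_sets:
            best = 0.0
            for boot in boot_sets:
                inter = np.sum(orig & boot)
                union = np.sum(orig | boot)
                if union:
                    best = max(best, inter / union)
            per_cluster.append(best)
        means.append(np.mean(per_cluster))
    return float(np.mean(means))


def select_k(embedding: np.ndarray, cfg: DiscoveryConfig) -> tuple[int, dict]:
    """Choose k by silhouette among k's whose bootstrap stability meets the floor."""
    n = embedding.shape[0]
    sil: dict[int, float] = {}
    wss: dict[int, float] = {}
    stab: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    for k in cfg.k_grid:
        if k > n - 1:
            raise DataError(f"k={k} out of bounds for {n} samples")
        labels = kmeans_cluster(embedding, k, cfg.seed, cfg.kmeans_restarts)
        labels_by_k[k] = labels
        sil[k] = float(silhouette_score(embedding, labels))
        centers = np.vstack([embedding[labels == c].mean(axis=0) for c in range(1, k + 1)])
        wss[k] = float(((embedding - centers[labels - 1]) ** 2).sum())
        stab[k] = _jaccard_stability(embedding, labels, k, cfg)
    stable = [k for k in cfg.k_grid if stab[k] >= cfg.stability_floor]
    warning = not stable
    pool = stable if stable else list(cfg.k_grid)
    chosen = max(pool, key=lambda k: sil[k])
    diagnostics = {
        "silhouette_by_k": sil,
        "wss_by_k": wss,
        "jaccard_stability_by_k": stab,
        "stability_warning": warning,
        "labels_by_k": labels_by_k,
    }
    return chosen, diagnostics


def discover(
    x: ExpressionMatrix, c: GeneSetCollection, cfg: DiscoveryConfig | None = None
) -> DiscoveryResult:
    """End-to-end class discovery from an expression matrix."""
    cfg = cfg or DiscoveryConfig()
    bound = (x.n_samples - 1) / 3.0
    if cfg.perplexity >= bound:  # default perplexity is clipped, not an error
        cfg = replace(cfg, perplexity=0.999 * bound)
    kept = filter_sets(c, x, min_size=cfg.min_set_size)
    scores = ssgsea_scores(x, kept, EnrichmentParams(method="ssgsea", normalize=True))
    emb = embed_scores(scores, cfg)
    space = scores.scores.T if cfg.cluster_on_scores else emb
    chosen_k, diag = select_k(space, cfg)
    labels = diag["labels_by_k"][chosen_k]
    return DiscoveryResult(
        embedding=emb,
        labels=labels,
        chosen_k=chosen_k,
        silhouette_by_k=diag["silhouette_by_k"],
        wss_by_k=diag["wss_by_k"],
        jaccard_stability_by_k=diag["jaccard_stability_by_k"],
        seed=cfg.seed,
        stability_warning=diag["stability_warning"],
        sample_ids=list(x.sample_ids),
    )
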