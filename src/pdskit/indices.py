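"""Derived transcriptomic indices for bulk samples and single cells.

* SMI (stem maturation index): per-sample difference between the
  PRC-target and MYC-target ssGSEA scores, min-max rescaled onto [-1, 1]
  across the supplied cohort. NOTE: the rescale is cohort-relative, so
  SMI values are not comparable across independently scored cohorts.
* Proliferative index: per-sample median (or mean) expression over a
  PCNA-associated gene signature.
* Replication stress: per-sample sum of GSVA scores over a signature
  collection (bulk), or the per-cell sum of ssGSEA scores rescaled onto
  [-1, 1] (single-cell).
* CBC / RSC stem scores: plain ssGSEA on the two stem signatures.
* Tertile-based "targets-high" labels for two competing scores.
"""

from __future__ import annotations

import warnings

import numpy as np

from .enrichment import EnrichmentParams, gsva_scores, ssgsea_scores
from .formats_io import DataError, ExpressionMatrix, GeneSetCollection


def _two_set_collection(name_a: str, genes_a, name_b: str, genes_b) -> GeneSetCollection:
    return GeneSetCollection(
        set_names=[name_a, name_b],
        members={name_a: list(genes_a), name_b: list(genes_b)},
    )


def _rescale_symmetric(v: np.ndarray) -> np.ndarray:
    """Min-max rescale onto [-1, 1]; an all-equal vector maps to zeros."""
    span = v.max() - v.min()
    if span <= 0:
        return np.zeros_like(v)
    return 2.0 * (v - v.min()) / span - 1.0


def smi(
    x: ExpressionMatrix, myc_set, prc_set, tau: float = 0.25
) -> dict[str, np.ndarray]:
    """Stem maturation index.

    Returns per-sample arrays: ``myc`` and ``prc`` ssGSEA scores, their
    difference ``d`` (PRC - MYC) and ``smi`` (d rescaled onto [-1, 1];
    dataset max -> 1, min -> -1). High SMI marks differentiated-like,
    low SMI stem-like states.
    """
    coll = _two_set_collection("MYC_TARGETS", myc_set, "PRC_TARGETS", prc_set)
    scores = ssgsea_scores(
        x, coll, EnrichmentParams(method="ssgsea", tau=tau, normalize=False)
    )
    myc = scores.scores[0]
    prc = scores.scores[1]
    d = prc - myc
    return {"sample_ids": list(x.sample_ids), "myc": myc, "prc": prc, "d": d,
            "smi": _rescale_symmetric(d)}


def proliferative_index(
    x: ExpressionMatrix, pcna_signature, aggregate: str = "median"
) -> np.ndarray:
    """Per-sample median (default) or mean expression over the signature genes present."""
    x.require_unique_genes()
    index = {g: i for i, g in enumerate(x.gene_ids)}
    rows = [index[g] for g in pcna_signature if g in index]
    if not rows:
        raise DataError("proliferation signature has no overlap with the matrix")
    sub = x.values[rows, :]
    if aggregate == "median":
        return np.median(sub, axis=0)
    if aggregate == "mean":
        return sub.mean(axis=0)
    raise ValueError(f"unknown aggregate {aggregate!r}")


def replication_stress(
    x: ExpressionMatrix, signatures: GeneSetCollection, mode: str = "bulk"
) -> np.ndarray:
    """Summed enrichment over the replication-stress signature collection.

    ``bulk``: sum of GSVA scores per sample (left unscaled).
    ``single_cell``: sum of per-cell ssGSEA scores, rescaled onto [-1, 1].
    """
    universe = set(x.gene_ids)
    usable = [n for n in signatures.set_names if any(g in universe for g in signatures.members[n])]
    dropped = [n for n in signatures.set_names if n not in usable]
    if dropped:
        warnings.warn(f"replication_stress: dropped sets with no overlap: {dropped}",
                      stacklevel=2)
    if not usable:
        raise DataError("no replication-stress signature overlaps the matrix")
    coll = signatures.subset(usable)
    if mode == "bulk":
        scores = gsva_scores(x, coll, EnrichmentParams(method="gsva"))
        return scores.scores.sum(axis=0)
    if mode == "single_cell":
        scores = ssgsea_scores(
            x, coll, EnrichmentParams(method="ssgsea", normalize=False)
        )
        return _rescale_symmetric(scores.scores.sum(axis=0))
    raise ValueError(f"unknown mode {mode!r}")


def stem_scores(
    x: ExpressionMatrix, cbc_set, rsc_set, tau: float = 0.25
) -> tuple[np.ndarray, np.ndarray]:
    """Raw (unnormalized) ssGSEA scores for the CBC and RSC stem signatures."""
    coll = _two_set_collection("CBC", cbc_set, "RSC", rsc_set)
    scores = ssgsea_scores(
        x, coll, EnrichmentParams(method="ssgsea", tau=tau, normalize=False)
    )
    return scores.scores[0], scores.scores[1]


def tertile_high_labels(
    scores_a: np.ndarray, scores_b: np.ndarray, names: tuple[str, str] = ("A", "B")
) -> list[str]:
    """Per-sample labels from empirical tertiles of two competing scores.

    ``"<A>-high"`` iff A is in its top tertile AND B in its bottom tertile;
    symmetrically for B; everything else ``"neither"``. The three labels
    are mutually exclusive and exhaustive.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise DataError("score vectors are not aligned")
    if len(a) < 3:
        raise DataError("tertiles are undefined for fewer than 3 samples")

    def bins(v: np.ndarray) -> np.ndarray:
        q1, q2 = np.quantile(v, [1 / 3, 2 / 3])
        out = np.ones(len(v), dtype=int)  # mid
        out[v <= q1] = 0
        out[v > q2] = 2
        return out

    ba, bb = bins(a), bins(b)
    labels = []
    for i in range(len(a)):
        if ba[i] == 2 and bb[i] == 0:
            labels.append(f"{names[0]}-high")
        elif bb[i] == 2 and ba[i] == 0:
            labels.append(f"{names[1]}-high")
        else:
            labels.append("neither")
    return labels
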