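"""Subtype-specific, non-redundant gene-set feature selection.

A set is assigned to the subtype in which its mean score is (a) the
strict maximum across subtypes and (b) above the grand mean; sets
satisfying neither condition for any subtype are dropped. Surviving sets
are then greedily pruned so that no pair exceeds the absolute Pearson
correlation cutoff (default 0.9).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .enrichment import ScoreMatrix
from .formats_io import DataError


@dataclass
class FeatureSelectionConfig:
    correlation_cutoff: float = 0.9
    specificity_rule: str = "max-mean-above-grand-mean"

    def __post_init__(self) -> None:
        if not 0 < self.correlation_cutoff <= 1:
            raise ValueError("correlation_cutoff must lie in (0, 1]")


def subtype_specific_sets(s: ScoreMatrix, labels) -> dict[int, list[str]]:
    """Partition gene sets into subtype-specific lists.

    ``labels`` are per-sample subtype ids aligned with ``s.sample_ids``.
    Returns {subtype: [set names]}; unassignable sets are dropped.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != s.n_samples:
        raise DataError("labels length does not match the score matrix")
    subtypes = sorted(set(labels.tolist()))
    if len(subtypes) < 2:
        raise DataError("need >= 2 subtypes for specificity selection")
    for g in subtypes:
        if np.sum(labels == g) < 2:
            raise DataError(f"subtype {g} has fewer than 2 samples")
    grand = s.scores.mean(axis=1)
    group_means = np.column_stack([s.scores[:, labels == g].mean(axis=1) for g in subtypes])
    result: dict[int, list[str]] = {g: [] for g in subtypes}
    for i, name in enumerate(s.set_names):
        means = group_means[i]
        top = means.max()
        winners = np.flatnonzero(means == top)
        if len(winners) != 1:  # no strict maximum
            continue
        if top <= grand[i]:
            continue
        result[subtypes[winners[0]]].append(name)
    return result


def prune_correlated(
    s: ScoreMatrix, selected: list[str], cutoff: float = 0.9
) -> list[str]:
    """Greedy pruning of highly correlated sets.

    While any surviving pair has |Pearson r| > cutoff, drop from the
    most-correlated pair the member with the larger mean absolute
    correlation to all remaining sets (ties broken by set name, the
    lexicographically later one removed). Constant-score sets have
    undefined correlation and are treated as uncorrelated (retained).
    Output order and content are invariant to the input ordering.
    """
    if len(selected) < 2:
        return list(selected)
    names = sorted(selected)  # internal order fixed by name for determinism
    sub = s.subset_sets(names)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(sub.scores)
    corr = np.abs(np.nan_to_num(corr, nan=0.0))
    np.fill_diagonal(corr, 0.0)
    alive = list(range(len(names)))
    while True:
        sub_corr = corr[np.ix_(alive, alive)]
        if sub_corr.size == 0 or sub_corr.max() <= cutoff:
            break
        a, b = np.unravel_index(np.argmax(sub_corr), sub_corr.shape)
        ia, ib = alive[a], alive[b]
        mean_a = sub_corr[a].mean()
        mean_b = sub_corr[b].mean()
        if mean_a > mean_b:
            drop = ia
        elif mean_b > mean_a:
            drop = ib
        else:  # tie: drop the lexicographically later name
            drop = max(ia, ib, key=lambda i: names[i])
        alive.remove(drop)
    kept = {names[i] for i in alive}
    return [n for n in selected if n in kept]


def select_features(
    s: ScoreMatrix, labels, cfg: FeatureSelectionConfig | None = None
) -> dict[int, list[str]]:
    """Subtype-specific selection followed by per-collection correlation pruning."""
    cfg = cfg or FeatureSelectionConfig()
    assigned = subtype_specific_sets(s, labels)
    all_selected = [n for g in sorted(assigned) for n in assigned[g]]
    kept = set(prune_correlated(s, all_selected, cfg.correlation_cutoff))
    return {g: [n for n in assigned[g] if n in kept] for g in sorted(assigned)}


def write_features(assigned: dict[int, list[str]], path: str | Path) -> None:
    """Two-column TSV: set_name, assigned_subtype."""
    with open(path, "w") as fh:
        fh.write("set_name\tassigned_subtype\n")
        for g in sorted(assigned):
            for name in assigned[g]:
                fh.write(f"{name}\t{g}\n")
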