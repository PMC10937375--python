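"""Synthetic expression cohorts with known ground truth.

The generator plants K latent subtypes as additive activation shifts of
designated gene sets on top of Gaussian background noise (a log-like
scale; downstream scoring is rank-based so only ordering structure
matters). Optional extras: a fraction of "mixed" samples blending two
subtype profiles 50/50, additive per-batch location shifts, and a latent
differentiation axis for stem/differentiation index tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .formats_io import DataError, ExpressionMatrix, GeneSetCollection


@dataclass
class SimulationTruth:
    subtype_labels: list[str]  # "1".."K" or "mixed"
    mixed_flags: list[bool]
    mixed_pairs: list[tuple[int, int] | None]
    set_subtype: dict[str, int | None]  # None = background set
    effect_size: float
    noise_sd: float
    batch_assignments: list[int]
    batch_shifts: list[float]
    seed: int

    def core_labels(self) -> np.ndarray:
        """Integer labels of non-mixed samples (mixed samples -> 0)."""
        return np.array(
            [0 if f else int(lab) for lab, f in zip(self.subtype_labels, self.mixed_flags)]
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "subtype_labels": self.subtype_labels,
                "mixed_flags": self.mixed_flags,
                "mixed_pairs": [list(p) if p else None for p in self.mixed_pairs],
                "set_subtype": self.set_subtype,
                "effect_size": self.effect_size,
                "noise_sd": self.noise_sd,
                "batch_assignments": self.batch_assignments,
                "batch_shifts": self.batch_shifts,
                "seed": self.seed,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "SimulationTruth":
        d = json.loads(text)
        return cls(
            subtype_labels=d["subtype_labels"],
            mixed_flags=d["mixed_flags"],
            mixed_pairs=[tuple(p) if p else None for p in d["mixed_pairs"]],
            set_subtype={k: v for k, v in d["set_subtype"].items()},
            effect_size=d["effect_size"],
            noise_sd=d["noise_sd"],
            batch_assignments=d["batch_assignments"],
            batch_shifts=d["batch_shifts"],
            seed=d["seed"],
        )


def simulate_cohort(
    n_samples: int = 150,
    n_genes: int = 600,
    n_sets: int = 18,
    k: int = 3,
    effect_size: float = 2.0,
    mixed_fraction: float = 0.0,
    noise_sd: float = 1.0,
    set_size: int = 25,
    n_background_sets: int | None = None,
    batch_spec: dict | None = None,
    seed: int = 0,
) -> tuple[ExpressionMatrix, GeneSetCollection, SimulationTruth]:
    """Simulate a gene x sample cohort with planted subtype programs.

    Sets get disjoint member genes. The first ``n_sets - n_background_sets``
    sets are assigned round-robin to subtypes 1..k; their member genes are
    shifted by ``effect_size * noise_sd`` in samples of that subtype.
    Mixed samples receive half the shift from each of two distinct
    subtypes. ``batch_spec = {"n_batches": B, "shift": s}`` adds a
    location shift of ``b * s`` to every gene of samples in batch b.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if n_sets * set_size > n_genes:
        raise DataError(
            f"{n_sets} sets x {set_size} genes exceed the {n_genes}-gene universe"
        )
    if n_background_sets is None:
        n_background_sets = max(0, n_sets - 4 * k) or n_sets % k
    n_signal_sets = n_sets - n_background_sets
    if n_signal_sets < k:
        raise DataError("need at least one signal set per subtype")
    rng = np.random.default_rng(seed)

    gene_ids = [f"g{i:05d}" for i in range(n_genes)]
    sample_ids = [f"s{j:04d}" for j in range(n_samples)]
    set_names = [f"SET{i:03d}" for i in range(n_sets)]
    members = {
        name: gene_ids[i * set_size : (i + 1) * set_size]
        for i, name in enumerate(set_names)
    }
    set_subtype: dict[str, int | None] = {}
    for i, name in enumerate(set_names):
        set_subtype[name] = (i % k) + 1 if i < n_signal_sets else None

    n_mixed = int(round(mixed_fraction * n_samples))
    labels: list[str] = []
    mixed_flags: list[bool] = []
    mixed_pairs: list[tuple[int, int] | None] = []
    for j in range(n_samples):
        if j < n_mixed:
            pair = tuple(sorted(rng.choice(np.arange(1, k + 1), size=2, replace=False)))
            labels.append("mixed")
            mixed_flags.append(True)
            mixed_pairs.append((int(pair[0]), int(pair[1])))
        else:
            labels.append(str((j % k) + 1))
            mixed_flags.append(False)
            mixed_pairs.append(None)
    # shuffle sample order so mixed samples are not a prefix block
    perm = rng.permutation(n_samples)
    labels = [labels[i] for i in perm]
    mixed_flags = [mixed_flags[i] for i in perm]
    mixed_pairs = [mixed_pairs[i] for i in perm]

    values = rng.normal(0.0, noise_sd, size=(n_genes, n_samples))
    shift = effect_size * noise_sd
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    subtype_gene_rows: dict[int, list[int]] = {g: [] for g in range(1, k + 1)}
    for name, g in set_subtype.items():
        if g is not None:
            subtype_gene_rows[g].extend(gene_index[m] for m in members[name])
    for j in range(n_samples):
        if mixed_flags[j]:
            a, b = mixed_pairs[j]
            values[subtype_gene_rows[a], j] += 0.5 * shift
            values[subtype_gene_rows[b], j] += 0.5 * shift
        else:
            values[subtype_gene_rows[int(labels[j])], j] += shift

    if batch_spec:
        n_batches = int(batch_spec.get("n_batches", 1))
        bshift = float(batch_spec.get("shift", 0.0))
        batch_assignments = [j % n_batches for j in range(n_samples)]
        batch_shifts = [b * bshift for b in range(n_batches)]
        for j, b in enumerate(batch_assignments):
            values[:, j] += batch_shifts[b]
    else:
        batch_assignments = [0] * n_samples
        batch_shifts = [0.0]

    x = ExpressionMatrix(gene_ids=gene_ids, sample_ids=sample_ids, values=values)
    c = GeneSetCollection(set_names=set_names, members=members, provenance="simulated")
    truth = SimulationTruth(
        subtype_labels=labels,
        mixed_flags=mixed_flags,
        mixed_pairs=mixed_pairs,
        set_subtype=set_subtype,
        effect_size=effect_size,
        noise_sd=noise_sd,
        batch_assignments=batch_assignments,
        batch_shifts=batch_shifts,
        seed=seed,
    )
    return x, c, truth


def simulate_differentiation_axis(
    n_cells: int,
    myc_set: list[str],
    prc_set: list[str],
    noise_sd: float = 0.5,
    n_background_genes: int = 100,
    amplitude: float = 2.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, np.ndarray]:
    """Cells along a latent differentiation axis t ~ Uniform(0, 1).

    MYC-set genes scale with (1 - t) (stem-like end) and PRC-set genes
    with t (differentiated end), plus Gaussian noise. Signal genes carry
    distinct amplitudes and background genes distinct fixed offsets
    spanning the signal range, so downstream rank-based scores vary
    finely (near-continuously) along t instead of in a few coarse steps.
    Returns the matrix and the truth vector t.
    """
    if set(myc_set) & set(prc_set):
        raise DataError("myc_set and prc_set must not overlap")
    rng = np.random.default_rng(seed)
    t = rng.uniform(0.0, 1.0, size=n_cells)
    background = [f"bg{i:05d}" for i in range(n_background_genes)]
    gene_ids = list(myc_set) + list(prc_set) + background
    values = rng.normal(0.0, noise_sd, size=(len(gene_ids), n_cells))
    n_myc = len(myc_set)
    n_prc = len(prc_set)
    myc_amp = amplitude * np.linspace(0.6, 1.4, n_myc)
    prc_amp = amplitude * np.linspace(0.6, 1.4, n_prc)
    values[:n_myc, :] += myc_amp[:, None] * (1.0 - t)[None, :]
    values[n_myc : n_myc + n_prc, :] += prc_amp[:, None] * t[None, :]
    bg_offsets = amplitude * np.linspace(-0.25, 1.25, max(n_background_genes, 1))
    values[n_myc + n_prc :, :] += bg_offsets[:n_background_genes, None]
    cell_ids = [f"c{j:05d}" for j in range(n_cells)]
    return ExpressionMatrix(gene_ids=gene_ids, sample_ids=cell_ids, values=values), t
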