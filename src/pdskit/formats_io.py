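"""Expression-matrix and gene-set (GMT) input/output.

Expression values are assumed to arrive already log-scale / normalized;
nothing here ever transforms values. Gene identifiers are matched verbatim
(exact string, case-sensitive) between matrices and gene-set collections.
Missing values are an error, never imputed: downstream scoring is
rank-based and ill-defined on NA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


class DataError(ValueError):
    """Raised for malformed or contract-violating input data."""


@dataclass
class ExpressionMatrix:
    """Genes x samples numeric expression matrix.

    ``gene_ids`` may contain duplicates right after loading (microarray
    probes); every other entry point requires them unique. ``sample_ids``
    must always be unique.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise DataError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} gene ids x {len(self.sample_ids)} sample ids"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = _duplicates(self.sample_ids)
            raise DataError(f"duplicate sample ids: {sorted(dupes)[:5]}")
        if np.isnan(self.values).any():
            i, j = np.argwhere(np.isnan(self.values))[0]
            raise DataError(
                f"missing value at gene {self.gene_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def require_unique_genes(self) -> None:
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = _duplicates(self.gene_ids)
            raise DataError(
                f"duplicate gene ids (collapse first): {sorted(dupes)[:5]}"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(
            gene_ids=[str(g) for g in df.index],
            sample_ids=[str(s) for s in df.columns],
            values=df.to_numpy(dtype=float),
        )


@dataclass
class GeneSetCollection:
    """Named gene sets with ordered membership lists (GMT-backed)."""

    set_names: list[str]
    members: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    provenance: str = ""

    def __post_init__(self) -> None:
        if len(set(self.set_names)) != len(self.set_names):
            dupes = _duplicates(self.set_names)
            raise DataError(f"duplicate gene set names: {sorted(dupes)[:5]}")
        for name in self.set_names:
            genes = self.members[name]
            if len(set(genes)) != len(genes):
                raise DataError(f"duplicate gene ids within set {name!r}")
            self.descriptions.setdefault(name, "")

    def __len__(self) -> int:
        return len(self.set_names)

    def __iter__(self):
        return iter(self.set_names)

    def sizes(self) -> dict[str, int]:
        return {n: len(self.members[n]) for n in self.set_names}

    def subset(self, names: list[str]) -> "GeneSetCollection":
        missing = [n for n in names if n not in self.members]
        if missing:
            raise DataError(f"unknown gene set names: {missing[:5]}")
        return GeneSetCollection(
            set_names=list(names),
            members={n: list(self.members[n]) for n in names},
            descriptions={n: self.descriptions.get(n, "") for n in names},
            provenance=self.provenance,
        )


def _duplicates(items: list[str]) -> set[str]:
    seen: set[str] = set()
    dupes: set[str] = set()
    for x in items:
        (dupes if x in seen else seen).add(x)
    return dupes


# ---------------------------------------------------------------------------
# expression matrix IO
# ---------------------------------------------------------------------------

def read_expression(
    path: str | Path,
    dialect: str = "tsv",
    genes_path: str | Path | None = None,
    samples_path: str | Path | None = None,
) -> ExpressionMatrix:
    """Read an expression matrix.

    ``dialect`` is one of ``tsv``, ``csv`` (first column = gene ids, header
    row = sample ids) or ``mtx-triplet`` (MatrixMarket file plus two sidecar
    id files; defaults ``<path>.genes`` and ``<path>.samples``).

    Duplicate gene ids are preserved for later :func:`collapse_features`;
    duplicate sample ids and non-numeric cells are errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect in ("tsv", "csv"):
        sep = "\t" if dialect == "tsv" else ","
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split(sep)[1:]
        dupes = _duplicates(header)
        if dupes:
            raise DataError(f"duplicate sample ids in {path.name}: {sorted(dupes)[:5]}")
        df = pd.read_csv(path, sep=sep, index_col=0, header=0, dtype=str)
        df.columns = header  # undo pandas' duplicate-column mangling

        values = np.empty(df.shape, dtype=float)
        for j, col in enumerate(df.columns):
            try:
                values[:, j] = pd.to_numeric(df[col], errors="raise")
            except (ValueError, TypeError):
                bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
                raise DataError(
                    f"non-numeric value at gene {bad!r}, sample {col!r} in {path.name}"
                ) from None
        return ExpressionMatrix(
            gene_ids=[str(g) for g in df.index],
            sample_ids=[str(c) for c in df.columns],
            values=values,
        )
    if dialect == "mtx-triplet":
        from scipy.io import mmread

        genes_path = Path(genes_path) if genes_path else path.with_suffix(path.suffix + ".genes")
        samples_path = (
            Path(samples_path) if samples_path else path.with_suffix(path.suffix + ".samples")
        )
        mat = mmread(path)
        values = np.asarray(mat.todense() if hasattr(mat, "todense") else mat, dtype=float)
        gene_ids = genes_path.read_text().split()
        sample_ids = samples_path.read_text().split()
        return ExpressionMatrix(gene_ids=gene_ids, sample_ids=sample_ids, values=values)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_expression(x: ExpressionMatrix, path: str | Path, dialect: str = "tsv") -> None:
    sep = {"tsv": "\t", "csv": ","}[dialect]
    x.to_frame().to_csv(path, sep=sep)


def collapse_features(x: ExpressionMatrix, id_map: dict[str, str]) -> ExpressionMatrix:
    """Collapse probe-level rows to one row per gene.

    For each gene the retained row is the probe with the highest
    across-sample mean. Probes absent from ``id_map`` are dropped.
    """
    if not id_map:
        raise DataError("empty probe-to-gene mapping")
    row_means = x.values.mean(axis=1)
    best: dict[str, tuple[float, int]] = {}
    for i, probe in enumerate(x.gene_ids):
        gene = id_map.get(probe)
        if gene is None:
            continue
        cur = best.get(gene)
        if cur is None or row_means[i] > cur[0]:
            best[gene] = (row_means[i], i)
    if not best:
        raise DataError("no probes could be mapped to genes")
    genes = sorted(best)  # deterministic output order
    rows = [best[g][1] for g in genes]
    return ExpressionMatrix(
        gene_ids=genes, sample_ids=list(x.sample_ids), values=x.values[rows, :]
    )


def filter_low_variance(x: ExpressionMatrix, var_cutoff: float = 0.25) -> ExpressionMatrix:
    """Optional pre-filter: drop genes below the ``var_cutoff`` variance quantile."""
    x.require_unique_genes()
    variances = x.values.var(axis=1, ddof=1)
    threshold = np.quantile(variances, var_cutoff)
    keep = variances > threshold
    if not keep.any():
        raise DataError("variance filter removed every gene")
    return ExpressionMatrix(
        gene_ids=[g for g, k in zip(x.gene_ids, keep) if k],
        sample_ids=list(x.sample_ids),
        values=x.values[keep, :],
    )


# ---------------------------------------------------------------------------
# GMT IO
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path, provenance: str | None = None) -> GeneSetCollection:
    """Read a Broad-dialect GMT file: name, description, tab-separated members."""
    path = Path(path)
    set_names: list[str] = []
    members: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataError(
                    f"{path.name}:{lineno}: GMT line has {len(fields)} fields (need >= 3)"
                )
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            if name in members:
                raise DataError(f"{path.name}:{lineno}: duplicate gene set name {name!r}")
            set_names.append(name)
            members[name] = genes
            descriptions[name] = desc
    return GeneSetCollection(
        set_names=set_names,
        members=members,
        descriptions=descriptions,
        provenance=provenance if provenance is not None else str(path),
    )


def write_gmt(c: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in c.set_names:
            fields = [name, c.descriptions.get(name, "")] + list(c.members[name])
            fh.write("\t".join(fields) + "\n")


def filter_sets(
    c: GeneSetCollection, x: ExpressionMatrix, min_size: int = 10
) -> GeneSetCollection:
    """Intersect each set with the expression universe; drop sets below ``min_size``."""
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    universe = set(x.gene_ids)
    kept_names: list[str] = []
    kept_members: dict[str, list[str]] = {}
    for name in c.set_names:
        present = [g for g in c.members[name] if g in universe]
        if len(present) >= min_size:
            kept_names.append(name)
            kept_members[name] = present
    if not kept_names:
        raise DataError(
            "no gene set retains >= min_size members in the expression matrix; "
            "check that gene identifiers use the same namespace"
        )
    if len(kept_names) < len(c.set_names):
        warnings.warn(
            f"filter_sets: kept {len(kept_names)}/{len(c.set_names)} sets "
            f"(min_size={min_size})",
            stacklevel=2,
        )
    return GeneSetCollection(
        set_names=kept_names,
        members=kept_members,
        descriptions={n: c.descriptions.get(n, "") for n in kept_names},
        provenance=c.provenance,
    )
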