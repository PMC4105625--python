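"""Core data containers: expression matrices, partitions, biclusters, and their
delimited-text / JSON round-trip I/O.

Identity is by string identifier throughout; positional indices never cross
module boundaries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "Partition",
    "Bicluster",
    "BiclusterSet",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_biclusters",
    "write_biclusters",
]


def _check_unique(ids, axis_name: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {axis_name} identifier: {x!r}")
        seen.add(x)


@dataclass
class ExpressionMatrix:
    """A genes x samples matrix of expression intensities with identifier axes.

    Parameters
    ----------
    values : (n_genes, n_samples) float array
        Unitless intensities e_ij for gene i in sample j. Must be finite.
    gene_ids, sample_ids : sequences of unique strings
        Row and column labels, in matrix order.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value at gene {self.gene_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index), list(df.columns))

    def gene_index(self, gene_ids) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            return np.array([lookup[g] for g in gene_ids], dtype=int)
        except KeyError as e:
            raise KeyError(f"unknown gene identifier: {e.args[0]!r}") from None

    def sample_index(self, sample_ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([lookup[s] for s in sample_ids], dtype=int)
        except KeyError as e:
            raise KeyError(f"unknown sample identifier: {e.args[0]!r}") from None

    def transpose(self) -> "ExpressionMatrix":
        """Swap the roles of genes and samples (used for orientation swaps)."""
        return ExpressionMatrix(self.values.T.copy(), self.sample_ids, self.gene_ids)


@dataclass
class Partition:
    """A partition of an ordered identifier set into disjoint nonempty blocks."""

    items: list[str]
    blocks: list[frozenset]

    def __post_init__(self) -> None:
        self.items = [str(x) for x in self.items]
        self.blocks = [frozenset(b) for b in self.blocks]
        _check_unique(self.items, "item")
        if any(len(b) == 0 for b in self.blocks):
            raise ValueError("empty block in partition")
        union: set = set()
        total = 0
        for b in self.blocks:
            total += len(b)
            union |= b
        if total != len(union):
            raise ValueError("partition blocks overlap")
        if union != set(self.items):
            raise ValueError("partition blocks do not cover the item set")

    def __len__(self) -> int:
        return len(self.blocks)

    def block_of(self, item: str) -> frozenset:
        for b in self.blocks:
            if item in b:
                return b
        raise KeyError(f"unknown item: {item!r}")

    def as_labels(self) -> dict[str, int]:
        lab: dict[str, int] = {}
        for k, b in enumerate(self.blocks):
            for x in b:
                lab[x] = k
        return lab

    @classmethod
    def from_labels(cls, items, labels) -> "Partition":
        """Build from a parallel label sequence (one label per item)."""
        items = [str(x) for x in items]
        groups: dict = {}
        for x, l in zip(items, labels, strict=True):
            groups.setdefault(l, set()).add(x)
        return cls(items, [frozenset(g) for g in groups.values()])


@dataclass(frozen=True)
class Bicluster:
    """A paired (gene subset, sample subset) — the dual relationship."""

    gene_ids: frozenset
    sample_ids: frozenset
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_ids", frozenset(self.gene_ids))
        object.__setattr__(self, "sample_ids", frozenset(self.sample_ids))
        if not self.gene_ids or not self.sample_ids:
            raise ValueError("bicluster gene and sample sets must be nonempty")

    @property
    def cells(self) -> frozenset:
        return frozenset((g, s) for g in self.gene_ids for s in self.sample_ids)

    def same_sets(self, other: "Bicluster") -> bool:
        return self.gene_ids == other.gene_ids and self.sample_ids == other.sample_ids


@dataclass
class BiclusterSet:
    """A possibly-overlapping collection of biclusters over one source matrix."""

    biclusters: list[Bicluster]
    source_matrix_shape: tuple[int, int] | None = None
    gene_universe: frozenset | None = field(default=None, repr=False)
    sample_universe: frozenset | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.biclusters = list(self.biclusters)
        if self.gene_universe is not None:
            for b in self.biclusters:
                if not b.gene_ids <= self.gene_universe:
                    raise ValueError(f"bicluster {b.label!r} has unknown genes")
        if self.sample_universe is not None:
            for b in self.biclusters:
                if not b.sample_ids <= self.sample_universe:
                    raise ValueError(f"bicluster {b.label!r} has unknown samples")

    def __len__(self) -> int:
        return len(self.biclusters)

    def __iter__(self):
        return iter(self.biclusters)

    def __getitem__(self, i: int) -> Bicluster:
        return self.biclusters[i]

    def validate_against(self, m: ExpressionMatrix) -> None:
        genes, samples = set(m.gene_ids), set(m.sample_ids)
        for b in self.biclusters:
            if not b.gene_ids <= genes or not b.sample_ids <= samples:
                raise ValueError(
                    f"bicluster {b.label!r} refers to identifiers outside the matrix"
                )

    def relabel(self, prefix: str = "B") -> "BiclusterSet":
        out = [
            Bicluster(b.gene_ids, b.sample_ids, f"{prefix}{k:02d}")
            for k, b in enumerate(self.biclusters)
        ]
        return BiclusterSet(out, self.source_matrix_shape)


# ---------------------------------------------------------------------------
# delimited-text matrix I/O


def read_expression_matrix(path, delimiter: str = "\t") -> ExpressionMatrix:
    """Read a header-row/header-column delimited text matrix.

    First row holds sample identifiers, first column gene identifiers,
    body is numeric. Missing or non-numeric cells are rejected.
    """
    df = pd.read_csv(path, sep=delimiter, index_col=0, comment="#")
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no sample columns found")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError):
        for j, col in enumerate(df.columns):
            coerced = pd.to_numeric(df[col], errors="coerce")
            if coerced.isna().any() and not df[col].isna().any():
                i = int(np.argmax(coerced.isna().to_numpy()))
                raise ValueError(
                    f"{path}: non-numeric cell at row {df.index[i]!r}, "
                    f"column {col!r}"
                ) from None
        raise
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise ValueError(
            f"{path}: missing value at row {df.index[i]!r}, column {df.columns[j]!r}"
        )
    return ExpressionMatrix(values, list(df.index.astype(str)), list(df.columns.astype(str)))


def write_expression_matrix(m: ExpressionMatrix, path, delimiter: str = "\t",
                            float_format: str = "%.10g") -> None:
    m.to_frame().to_csv(path, sep=delimiter, float_format=float_format)


# ---------------------------------------------------------------------------
# bicluster report I/O (JSON records)


def write_biclusters(b: BiclusterSet, path) -> None:
    """Write a bicluster set as a JSON report, one record per bicluster."""
    doc = {
        "source_matrix_shape": list(b.source_matrix_shape) if b.source_matrix_shape else None,
        "biclusters": [
            {
                "label": bc.label,
                "genes": sorted(bc.gene_ids),
                "samples": sorted(bc.sample_ids),
            }
            for bc in b.biclusters
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def read_biclusters(path) -> BiclusterSet:
    with open(path) as fh:
        doc = json.load(fh)
    shape = doc.get("source_matrix_shape")
    return BiclusterSet(
        [
            Bicluster(frozenset(r["genes"]), frozenset(r["samples"]), r.get("label", ""))
            for r in doc["biclusters"]
        ],
        tuple(shape) if shape else None,
    )
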