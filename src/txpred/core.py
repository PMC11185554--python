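"""Core data containers and text-table I/O.

The central objects mirror the multiple-regression view of transcriptomic
prediction, ``y = X beta + e``: an :class:`ExpressionMatrix` holds the
``n x m`` matrix of expression levels for inbred lines, a
:class:`PhenotypeVector` holds the per-line trait means, and a
:class:`GeneSetCollection` holds named functional gene sets (GO terms)
defined over the gene universe.

All tables are plain text (TSV by default, GMT for gene sets); identifiers
are treated as opaque strings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "PhenotypeVector",
    "GeneSetCollection",
    "GroupPartition",
    "Dataset",
    "FormatError",
    "read_expression_table",
    "read_phenotype_table",
    "read_gene_sets_gmt",
    "write_expression_table",
    "write_phenotype_table",
    "standardize_columns",
    "train_scaler",
]

_ATOL = 1e-10


class FormatError(ValueError):
    """A file or container violates the expected format or an invariant."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise FormatError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass(frozen=True)
class ExpressionMatrix:
    """Lines-by-genes expression matrix with identifier bookkeeping.

    ``centered``/``standardized`` record whether columns have been put on
    mean 0 (and sample variance 1, n-1 denominator) — the state all the
    regression methods expect.
    """

    line_ids: tuple[str, ...]
    gene_ids: tuple[str, ...]
    values: np.ndarray
    centered: bool = False
    standardized: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "line_ids", tuple(map(str, self.line_ids)))
        object.__setattr__(self, "gene_ids", tuple(map(str, self.gene_ids)))
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        _check_unique(self.line_ids, "line")
        _check_unique(self.gene_ids, "gene")
        if v.shape != (len(self.line_ids), len(self.gene_ids)):
            raise FormatError(
                f"values shape {v.shape} does not match "
                f"({len(self.line_ids)}, {len(self.gene_ids)})"
            )
        if not np.all(np.isfinite(v)):
            raise FormatError("expression values must be finite")
        if self.centered:
            if np.max(np.abs(v.mean(axis=0))) > _ATOL:
                raise FormatError("centered flag set but column means are not 0")
        if self.standardized:
            sv = v.var(axis=0, ddof=1)
            if np.max(np.abs(sv - 1.0)) > 1e-8:
                raise FormatError(
                    "standardized flag set but column sample variances are not 1"
                )

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def gene_index(self, gene_ids: Iterable[str]) -> np.ndarray:
        """Indices of ``gene_ids`` in this matrix; unknown ids raise KeyError."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        return np.array([lookup[g] for g in gene_ids], dtype=int)

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = self.gene_index(gene_ids)
        return ExpressionMatrix(
            self.line_ids,
            tuple(gene_ids),
            self.values[:, idx],
            centered=self.centered,
            standardized=self.standardized,
        )


@dataclass(frozen=True)
class PhenotypeVector:
    """Per-line trait means (the ``y`` of the regression model)."""

    line_ids: tuple[str, ...]
    values: np.ndarray
    centered: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "line_ids", tuple(map(str, self.line_ids)))
        v = np.asarray(self.values, dtype=float).ravel()
        object.__setattr__(self, "values", v)
        _check_unique(self.line_ids, "line")
        if v.shape[0] != len(self.line_ids):
            raise FormatError("phenotype length does not match line_ids")
        if not np.all(np.isfinite(v)):
            raise FormatError("phenotype values must be finite")
        if self.centered and abs(float(v.mean())) > _ATOL:
            raise FormatError("centered flag set but mean is not 0")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)


class GeneSetCollection:
    """Named gene sets (GO terms) over a gene universe.

    Stored as an ordered mapping ``term_id -> (description, frozenset of
    gene ids)``; term ids are unique and sets non-empty.
    """

    def __init__(self, terms: Mapping[str, tuple[str, Iterable[str]]]):
        self._terms: dict[str, tuple[str, frozenset[str]]] = {}
        for term_id, (desc, genes) in terms.items():
            gs = frozenset(map(str, genes))
            if term_id in self._terms:
                raise FormatError(f"duplicate term id: {term_id!r}")
            if not gs:
                raise FormatError(f"empty gene set for term {term_id!r}")
            self._terms[str(term_id)] = (str(desc), gs)

    def __len__(self) -> int:
        return len(self._terms)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self._terms

    def __iter__(self):
        return iter(self._terms)

    @property
    def term_ids(self) -> tuple[str, ...]:
        return tuple(self._terms)

    def genes(self, term_id: str) -> frozenset[str]:
        return self._terms[term_id][1]

    def description(self, term_id: str) -> str:
        return self._terms[term_id][0]

    def items(self):
        return self._terms.items()

    def intersect(self, universe: Iterable[str]) -> "GeneSetCollection":
        """Restrict every set to ``universe``; terms left empty are dropped."""
        uni = set(universe)
        kept = {
            t: (d, g & uni) for t, (d, g) in self._terms.items() if g & uni
        }
        return GeneSetCollection(kept)


@dataclass(frozen=True)
class GroupPartition:
    """Two-group split of gene indices: a focal (GO-term) group and the rest."""

    in_group: np.ndarray
    out_group: np.ndarray
    n_genes: int

    def __post_init__(self) -> None:
        ig = np.asarray(self.in_group, dtype=int)
        og = np.asarray(self.out_group, dtype=int)
        object.__setattr__(self, "in_group", ig)
        object.__setattr__(self, "out_group", og)
        if ig.size == 0:
            raise FormatError("in_group must be non-empty")
        both = np.concatenate([ig, og])
        if np.unique(both).size != both.size:
            raise FormatError("in_group and out_group overlap")
        if not np.array_equal(np.sort(both), np.arange(self.n_genes)):
            raise FormatError("partition does not cover all gene indices")

    @classmethod
    def from_term(
        cls, X: ExpressionMatrix, term_genes: Iterable[str]
    ) -> "GroupPartition":
        genes = set(term_genes) & set(X.gene_ids)
        if not genes:
            raise FormatError("no term genes present in the expression matrix")
        mask = np.array([g in genes for g in X.gene_ids])
        return cls(np.flatnonzero(mask), np.flatnonzero(~mask), X.n_genes)


@dataclass(frozen=True)
class Dataset:
    """Aligned expression + phenotype (+ optional gene sets) for one analysis."""

    expression: ExpressionMatrix
    phenotype: PhenotypeVector
    gene_sets: GeneSetCollection | None = None

    def __post_init__(self) -> None:
        if self.expression.line_ids != self.phenotype.line_ids:
            raise FormatError(
                "expression and phenotype line ids differ (ids or order)"
            )
        if self.gene_sets is not None:
            object.__setattr__(
                self, "gene_sets", self.gene_sets.intersect(self.expression.gene_ids)
            )


# ---------------------------------------------------------------------------
# I/O


def _sep(dialect: str) -> str:
    if dialect == "tsv":
        return "\t"
    if dialect == "csv":
        return ","
    raise ValueError(f"unknown dialect {dialect!r} (use 'tsv' or 'csv')")


def read_expression_table(path: str | Path, dialect: str = "tsv") -> ExpressionMatrix:
    """Read a line-by-gene table: first column line id, header row gene ids."""
    # pandas silently renames duplicate header fields, so check them raw
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split(_sep(dialect))
    _check_unique(header[1:], "gene")
    df = pd.read_csv(path, sep=_sep(dialect), index_col=0, dtype=str)
    if df.shape[1] == 0:
        raise FormatError(f"{path}: no gene columns")
    line_ids = [str(i) for i in df.index]
    gene_ids = [str(c) for c in df.columns]
    _check_unique(line_ids, "line")
    _check_unique(gene_ids, "gene")
    values = np.empty(df.shape, dtype=float)
    raw = df.to_numpy()
    for j in range(raw.shape[1]):
        col = pd.to_numeric(raw[:, j], errors="coerce")
        bad = np.flatnonzero(~np.isfinite(np.asarray(col, dtype=float)))
        if bad.size:
            i = int(bad[0])
            raise FormatError(
                f"{path}: non-numeric cell {raw[i, j]!r} at "
                f"(line {line_ids[i]!r}, gene {gene_ids[j]!r})"
            )
        values[:, j] = col
    return ExpressionMatrix(tuple(line_ids), tuple(gene_ids), values)


def write_expression_table(
    X: ExpressionMatrix, path: str | Path, dialect: str = "tsv"
) -> None:
    df = pd.DataFrame(X.values, index=list(X.line_ids), columns=list(X.gene_ids))
    df.index.name = "line"
    df.to_csv(path, sep=_sep(dialect), float_format="%.17g")


def read_phenotype_table(path: str | Path, dialect: str = "tsv") -> PhenotypeVector:
    """Read a two-column table: line id, trait value."""
    df = pd.read_csv(path, sep=_sep(dialect), dtype=str)
    if df.shape[0] == 0:
        raise FormatError(f"{path}: no records")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected two columns (line id, value)")
    line_ids = [str(v) for v in df.iloc[:, 0]]
    _check_unique(line_ids, "line")
    vals = pd.to_numeric(df.iloc[:, 1], errors="coerce").to_numpy(dtype=float)
    bad = np.flatnonzero(~np.isfinite(vals))
    if bad.size:
        i = int(bad[0])
        raise FormatError(
            f"{path}: missing or non-numeric value for line {line_ids[i]!r}"
        )
    return PhenotypeVector(tuple(line_ids), vals)


def write_phenotype_table(
    y: PhenotypeVector, path: str | Path, dialect: str = "tsv"
) -> None:
    df = pd.DataFrame({"line": list(y.line_ids), "value": y.values})
    df.to_csv(path, sep=_sep(dialect), index=False, float_format="%.17g")


def read_gene_sets_gmt(path: str | Path) -> GeneSetCollection:
    """Read a standard GMT file: term<TAB>description<TAB>gene1<TAB>gene2..."""
    terms: dict[str, tuple[str, list[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated fields"
                )
            term_id, desc = fields[0], fields[1]
            if term_id in terms:
                raise FormatError(f"{path}:{lineno}: duplicate term id {term_id!r}")
            genes = [g for g in fields[2:] if g]
            # duplicates within a line are silently collapsed
            terms[term_id] = (desc, list(dict.fromkeys(genes)))
    return GeneSetCollection(terms)


def write_gene_sets_gmt(sets: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for term_id, (desc, genes) in sets.items():
            fh.write("\t".join([term_id, desc, *sorted(genes)]) + "\n")


# ---------------------------------------------------------------------------
# Standardization


def standardize_columns(X: ExpressionMatrix, mode: str = "center_scale") -> ExpressionMatrix:
    """Center (and optionally variance-scale, n-1 denominator) every column.

    Raises on zero-variance columns, naming the offending genes: a constant
    expression column carries no between-line signal and would divide by 0.
    """
    if mode not in ("center", "center_scale"):
        raise ValueError(f"unknown mode {mode!r}")
    v = X.values
    sd = v.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0.0)
    if zero.size:
        names = [X.gene_ids[i] for i in zero[:10]]
        raise FormatError(f"zero-variance columns: {names}")
    out = v - v.mean(axis=0)
    standardized = False
    if mode == "center_scale":
        out = out / out.std(axis=0, ddof=1)
        standardized = True
    return replace(X, values=out, centered=True, standardized=standardized)


@dataclass(frozen=True)
class train_scaler:
    """Column scaler learned on training rows only, applied to test rows.

    Prevents information leakage in the train/test evaluation: test rows are
    shifted and scaled with the training means and sample standard deviations.
    """

    mean: np.ndarray
    scale: np.ndarray

    @classmethod
    def fit(cls, values: np.ndarray, mode: str = "center_scale") -> "train_scaler":
        mean = values.mean(axis=0)
        if mode == "center_scale":
            sd = values.std(axis=0, ddof=1)
            sd = np.where(sd == 0.0, 1.0, sd)
        elif mode == "center":
            sd = np.ones(values.shape[1])
        else:
            raise ValueError(f"unknown mode {mode!r}")
        return cls(mean=mean, scale=sd)

    def transform(self, values: np.ndarray) -> np.ndarray:
        return (values - self.mean) / self.scale
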