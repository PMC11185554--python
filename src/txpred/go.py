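"""GO-informed prediction pipeline and downstream gene analysis.

Steps: keep GO terms with at least five genes present in the expression
matrix; fit a GO-aware method (two-group spike-and-slab, two-kernel TBLUP
or sparse group LASSO) one term at a time under shared train/test splits;
select the 1% most predictive terms; count how often each gene appears
across those terms; and test the most frequent genes for enrichment of an
annotation class (e.g. protein kinases) with Fisher's exact test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import Dataset, ExpressionMatrix, GeneSetCollection, GroupPartition
from .evaluate import CvResult, Method, SplitPlan, run_cv_benchmark

logger = logging.getLogger(__name__)

__all__ = [
    "TermScanResult",
    "GeneCountTable",
    "EnrichmentResult",
    "filter_terms",
    "run_go_scan",
    "select_top_percent",
    "count_genes_in_top_terms",
    "enrichment_test",
    "auto_count_threshold",
]


@dataclass(frozen=True)
class TermScanResult:
    """Cross-validated accuracy of one GO term under a GO-aware method."""

    term_id: str
    n_genes_in_matrix: int
    per_split_r: np.ndarray
    mean_r: float
    se_r: float
    method: str


@dataclass(frozen=True)
class GeneCountTable:
    """How many of the top terms contain each gene, plus the selected genes."""

    counts: dict
    threshold: int
    selected_genes: tuple[str, ...]


@dataclass(frozen=True)
class EnrichmentResult:
    """Fisher's exact test of selected genes against an annotation set."""

    contingency: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p_value: float
    alternative: str


def filter_terms(
    sets: GeneSetCollection, X: ExpressionMatrix, min_genes: int = 5
) -> GeneSetCollection:
    """Keep terms with >= min_genes genes present in X; store intersections."""
    universe = set(X.gene_ids)
    kept = {}
    for term_id, (desc, genes) in sets.items():
        inter = genes & universe
        if len(inter) >= min_genes:
            kept[term_id] = (desc, inter)
    if not kept:
        logger.warning("no terms passed the %d-gene filter", min_genes)
    return GeneSetCollection(kept)


def run_go_scan(
    dataset: Dataset,
    method_factory,
    plan: SplitPlan,
    terms: GeneSetCollection | None = None,
) -> list[TermScanResult]:
    """Fit a GO-aware method one term at a time under the shared splits.

    ``method_factory()`` must return a fresh partition-accepting
    :class:`Method`; the same ``plan`` is used for every term so per-term
    accuracies are comparable. Terms are processed independently — the
    results do not depend on term order.
    """
    sets = terms if terms is not None else dataset.gene_sets
    if sets is None:
        raise ValueError("dataset has no gene sets")
    out = []
    for term_id in sets.term_ids:
        genes = sets.genes(term_id) & set(dataset.expression.gene_ids)
        if not genes:
            logger.warning("term %s has no genes in the matrix; skipped", term_id)
            continue
        method = method_factory()
        if not method.needs_partition:
            raise ValueError(
                f"method {method.name!r} does not accept a partition"
            )
        partition = GroupPartition.from_term(dataset.expression, genes)
        (res,) = run_cv_benchmark(dataset, [method], plan, partition=partition)
        out.append(
            TermScanResult(
                term_id=term_id,
                n_genes_in_matrix=len(genes),
                per_split_r=res.per_split_r,
                mean_r=res.mean_r,
                se_r=res.se_r,
                method=method.name,
            )
        )
    return out


def select_top_percent(
    results: Sequence[TermScanResult], pct: float = 0.01
) -> list[str]:
    """The floor(pct * n) most predictive terms (at least one).

    Ranked by mean accuracy descending; ties broken by term id ascending
    for determinism.
    """
    if not results:
        raise ValueError("no term results to rank")
    ranked = sorted(results, key=lambda r: (-r.mean_r, r.term_id))
    k = max(1, int(np.floor(pct * len(ranked))))
    return [r.term_id for r in ranked[:k]]


def auto_count_threshold(counts: dict, max_fraction: float = 0.05) -> int:
    """Smallest count threshold keeping at most ``max_fraction`` of genes."""
    values = np.array(sorted(counts.values(), reverse=True))
    n = values.size
    for t in range(1, int(values.max()) + 2):
        if np.sum(values >= t) <= max_fraction * n:
            return t
    return int(values.max()) + 1


def count_genes_in_top_terms(
    top_terms: Sequence[str],
    sets: GeneSetCollection,
    threshold: int | str = "auto",
) -> GeneCountTable:
    """Count term membership of every gene across the selected top terms."""
    counts: dict[str, int] = {}
    for term_id in top_terms:
        if term_id not in sets:
            raise KeyError(f"unknown term id {term_id!r}")
        for g in sets.genes(term_id):
            counts[g] = counts.get(g, 0) + 1
    if threshold == "auto":
        thr = auto_count_threshold(counts) if counts else 1
    else:
        thr = int(threshold)
    selected = sorted(
        (g for g, c in counts.items() if c >= thr),
        key=lambda g: (-counts[g], g),
    )
    return GeneCountTable(counts=counts, threshold=thr, selected_genes=tuple(selected))


def enrichment_test(
    selected_genes: Iterable[str],
    background_genes: Iterable[str],
    annotation_set: Iterable[str],
    alternative: str = "greater",
) -> EnrichmentResult:
    """Fisher's exact test: selected-vs-not against annotated-vs-not.

    One-sided 'greater' (the enrichment direction) uses the exact
    hypergeometric tail; 'two-sided' sums all tables at least as extreme.
    """
    background = set(background_genes)
    if not background:
        raise ValueError("background gene set is empty")
    selected = set(selected_genes)
    annot = set(annotation_set)
    if not selected <= background or not annot <= background:
        raise ValueError("selected and annotation sets must lie in the background")

    a = len(selected & annot)
    b = len(selected - annot)
    c = len(annot - selected)
    d = len(background) - a - b - c
    table = ((a, b), (c, d))

    # zero off-diagonal margin: the ratio is infinite or undefined (0/0);
    # both are reported as the infinity flag
    odds = (a * d) / (b * c) if b * c > 0 else float("inf")

    N, K, n_sel = len(background), len(annot), len(selected)
    if alternative == "greater":
        p = float(stats.hypergeom.sf(a - 1, N, K, n_sel))
    elif alternative == "less":
        p = float(stats.hypergeom.cdf(a, N, K, n_sel))
    elif alternative == "two-sided":
        _, p = stats.fisher_exact(np.array(table), alternative="two-sided")
        p = float(p)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    p = min(p, 1.0)
    if K == N:  # every background gene annotated: the margin is degenerate
        p = 1.0
    return EnrichmentResult(
        contingency=table, odds_ratio=odds, p_value=p, alternative=alternative
    )


def scan_results_table(results: Sequence[TermScanResult]) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "term_id": [r.term_id for r in results],
            "n_genes_in_matrix": [r.n_genes_in_matrix for r in results],
            "mean_r": [r.mean_r for r in results],
            "se_r": [r.se_r for r in results],
            "method": [r.method for r in results],
        }
    )
    return df.sort_values(
        ["mean_r", "term_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
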