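"""Local gene-set enrichment statistics.

A self-contained replacement for web-service functional annotation: for a
query gene set and a GMT-style collection of annotation terms (GO BP/CC/MF
categories and pathways), each overlapping term is scored with the one-sided
hypergeometric upper tail (equivalent to one-sided Fisher), corrected with
Benjamini-Hochberg step-up FDR (the "Q value"), and summarized with the two
bubble-plot quantities:

* rich factor = k / K, the fraction of the term's genes hit by the query;
* gene percentage = 100 k / n, the fraction of the query inside the term.

The test universe defaults to the genes appearing in the collection plus the
query; supplying an explicit universe restricts both and is the reproducible
option.  Significance is gated on the raw p-value (default alpha 0.05), with
Q reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AnnotationTerm",
    "EnrichmentResult",
    "hypergeometric_upper_tail",
    "bh_fdr",
    "enrich",
    "top_by_gene_percentage",
    "bubble_table",
]

CATEGORIES = ("BP", "CC", "MF", "pathway")


@dataclass(frozen=True)
class AnnotationTerm:
    """One annotation term: a named, categorized gene set."""

    term_id: str
    name: str
    category: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"{self.term_id}: empty gene set")
        if self.category not in CATEGORIES:
            raise ValueError(
                f"{self.term_id}: category {self.category!r} not in {CATEGORIES}"
            )


@dataclass(frozen=True)
class EnrichmentResult:
    """Statistics for one term against one query."""

    term: AnnotationTerm
    overlap: int          # k
    term_size: int        # K (restricted to universe)
    query_size: int       # n
    universe_size: int    # N
    p_value: float
    q_value: float
    rich_factor: float    # k / K
    gene_percentage: float  # 100 k / n
    significant: bool
    overlap_genes: tuple[str, ...] = ()


def hypergeometric_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    N is the universe size, K the term size, n the query size, k the
    observed overlap.  Computed via the survival function, numerically
    stable to N ~ 1e5.
    """
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"overlap k={k} outside [0, min(K={K}, n={n})]")
    if K > N or n > N or K < 0 or n < 0:
        raise ValueError(f"inconsistent counts: K={K}, n={n}, N={N}")
    # sf(k-1) = P(X > k-1) = P(X >= k)
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, input order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(
    query: Iterable[str],
    collection: Sequence[AnnotationTerm],
    universe: Iterable[str] | None = None,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Test every overlapping term in ``collection`` against ``query``.

    Terms with zero overlap are omitted.  Results are sorted by ascending
    p-value (ties by term id); Q values are BH-adjusted across the tested
    terms.

    Raises
    ------
    ValueError
        If an explicit universe is empty or does not contain the query.
    """
    query_set = set(query)
    if universe is None:
        uni: set[str] = set(query_set)
        for t in collection:
            uni |= t.genes
    else:
        uni = set(universe)
        if not uni:
            raise ValueError("universe is empty")
        if not query_set <= uni:
            missing = sorted(query_set - uni)[:5]
            raise ValueError(f"query genes outside universe, e.g. {missing}")

    q_in = query_set & uni
    n, N = len(q_in), len(uni)

    rows = []
    for term in collection:
        genes = term.genes & uni
        hit = genes & q_in
        if not genes or not hit:
            continue
        k, K = len(hit), len(genes)
        p = hypergeometric_upper_tail(k, K, n, N)
        rows.append((term, k, K, p, tuple(sorted(hit))))

    if not rows:
        return []
    qvals = bh_fdr([r[3] for r in rows])
    results = [
        EnrichmentResult(
            term=term,
            overlap=k,
            term_size=K,
            query_size=n,
            universe_size=N,
            p_value=p,
            q_value=float(q),
            rich_factor=k / K,
            gene_percentage=100.0 * k / n,
            significant=p < alpha,
            overlap_genes=hit,
        )
        for (term, k, K, p, hit), q in zip(rows, qvals)
    ]
    results.sort(key=lambda r: (r.p_value, r.term.term_id))
    return results


def top_by_gene_percentage(
    results: Sequence[EnrichmentResult],
    m: int = 10,
    category: str | None = None,
) -> list[EnrichmentResult]:
    """Top ``m`` results by gene percentage (descending), ties by ascending
    p-value, optionally restricted to one category."""
    pool = [r for r in results if category is None or r.term.category == category]
    pool.sort(key=lambda r: (-r.gene_percentage, r.p_value, r.term.term_id))
    return pool[:m]


def bubble_table(
    results: Sequence[EnrichmentResult],
    categories: tuple[str, ...] = ("pathway",),
) -> pd.DataFrame:
    """Plot-ready table of significant terms: one row per term with rich
    factor, Q value, and overlap count.  Data only; no graphics."""
    rows = [
        {
            "term_id": r.term.term_id,
            "name": r.term.name,
            "rich_factor": r.rich_factor,
            "q_value": r.q_value,
            "overlap": r.overlap,
            "gene_percentage": r.gene_percentage,
        }
        for r in results
        if r.significant and r.term.category in categories
    ]
    return pd.DataFrame(
        rows,
        columns=["term_id", "name", "rich_factor", "q_value", "overlap", "gene_percentage"],
    )
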