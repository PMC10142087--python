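"""Set algebra over compound-target and disease-gene lists.

Target predictions arrive from two compound-target sources (e.g. similarity-
ensemble and structure-based predictors) and disease genes from three disease
databases; the pipeline intersects the former, unions the latter, and takes
the overlap as the candidate mechanism targets.  Gene identity is the
normalized symbol string: uppercase, stripped, deduplicated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "SourcedTargetSet",
    "VennSummary",
    "normalize_symbols",
    "intersect_compound_sources",
    "union_disease_sources",
    "common_disease_targets",
    "compound_connectivity",
]


def normalize_symbols(raw: Iterable[str]) -> list[str]:
    """Uppercase, strip, deduplicate; drop empties; return sorted list."""
    return sorted({s.strip().upper() for s in raw if s and s.strip()})


@dataclass(frozen=True)
class SourcedTargetSet:
    """A provenance-tagged set of normalized gene symbols."""

    source: str
    genes: frozenset[str]

    @classmethod
    def from_raw(cls, source: str, raw: Iterable[str]) -> "SourcedTargetSet":
        return cls(source, frozenset(normalize_symbols(raw)))

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class VennSummary:
    """Two-set Venn region counts; regions partition the union."""

    label_a: str
    label_b: str
    only_a: int
    only_b: int
    both: int

    @property
    def union_size(self) -> int:
        return self.only_a + self.only_b + self.both

    def as_dict(self) -> dict:
        return {
            "labels": [self.label_a, self.label_b],
            f"{self.label_a}_only": self.only_a,
            f"{self.label_b}_only": self.only_b,
            "intersection": self.both,
            "union": self.union_size,
        }


def intersect_compound_sources(
    a: SourcedTargetSet, b: SourcedTargetSet
) -> tuple[list[str], VennSummary]:
    """Common targets between the two compound-target prediction sources."""
    common = a.genes & b.genes
    summary = VennSummary(
        a.source, b.source,
        only_a=len(a.genes - b.genes),
        only_b=len(b.genes - a.genes),
        both=len(common),
    )
    return sorted(common), summary


def union_disease_sources(*sources: SourcedTargetSet) -> tuple[list[str], dict[str, int]]:
    """Union of disease gene lists, with per-source sizes for reporting."""
    union: set[str] = set()
    per_source: dict[str, int] = {}
    for s in sources:
        union |= s.genes
        per_source[s.source] = len(s.genes)
    return sorted(union), per_source


def common_disease_targets(
    compound_targets: Iterable[str], disease_targets: Iterable[str]
) -> list[str]:
    """Sorted intersection of compound-associated and disease-associated genes."""
    return sorted(set(compound_targets) & set(disease_targets))


def compound_connectivity(
    associations: pd.DataFrame | Iterable[tuple[str, str]],
    common: Iterable[str],
    compounds: Sequence[str] | None = None,
) -> tuple[dict[str, int], list[str]]:
    """Count each compound's distinct links into the common target set.

    Parameters
    ----------
    associations
        (compound_id, gene_symbol) pairs, or a DataFrame with those columns.
        Duplicate pairs (within or across sources) collapse to one link.
    common
        The common target symbols.
    compounds
        The screened compound ids.  When given, every id appears in the
        output (zero-link compounds included) and any association row naming
        an unknown compound raises ``ValueError``.

    Returns
    -------
    counts, orphans
        ``counts`` maps compound id to its number of common-target links;
        ``orphans`` lists compounds with zero links, sorted.
    """
    if isinstance(associations, pd.DataFrame):
        pairs = set(zip(associations["compound_id"], associations["gene_symbol"]))
    else:
        pairs = set(associations)

    if compounds is not None:
        known = set(compounds)
        unknown = sorted({c for c, _ in pairs} - known)
        if unknown:
            raise ValueError(f"association rows reference unknown compounds: {unknown}")
        counts = {c: 0 for c in compounds}
    else:
        counts = {c: 0 for c, _ in pairs}

    common_set = set(common)
    for comp, gene in pairs:
        if gene in common_set:
            counts[comp] += 1
    orphans = sorted(c for c, n in counts.items() if n == 0)
    return counts, orphans
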