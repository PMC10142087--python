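"""Readers and writers for the pipeline's plain-text formats.

CSV/TSV go through pandas; GMT (term <tab> description <tab> genes...) is
read and written directly — the format is line-oriented with a variable
column count, outside what a rectangular-table reader models.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .enrich import AnnotationTerm

__all__ = [
    "read_gmt", "write_gmt",
    "read_compound_csv", "write_compound_csv",
    "read_association_tsv", "read_disease_tsv", "read_string_tsv",
    "read_orbitals_csv", "read_docking_csv",
]


def read_gmt(path: str | Path, category: str = "pathway") -> list[AnnotationTerm]:
    """Parse a GMT file into annotation terms.

    The description field may carry ``category=XX`` (written by
    :func:`write_gmt`); otherwise ``category`` applies to every term.
    """
    terms = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line (need >= 3 fields): {line!r}")
        term_id, desc, genes = fields[0], fields[1], fields[2:]
        cat, name = category, desc
        if desc.startswith("category="):
            head, _, rest = desc.partition(";")
            cat = head.removeprefix("category=")
            name = rest or term_id
        terms.append(AnnotationTerm(term_id, name, cat, frozenset(g for g in genes if g)))
    return terms


def write_gmt(terms: Sequence[AnnotationTerm], path: str | Path) -> None:
    """Write terms as GMT, encoding the category in the description field."""
    lines = [
        "\t".join([t.term_id, f"category={t.category};{t.name}", *sorted(t.genes)])
        for t in terms
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_compound_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"id", "mw", "hba", "hbd", "mlogp", "bioavailability"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"compound CSV missing columns: {sorted(missing)}")
    return df


def write_compound_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_association_tsv(path: str | Path) -> pd.DataFrame:
    """(compound_id, gene_symbol, source) rows."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"compound_id", "gene_symbol"} <= set(df.columns):
        raise ValueError("association TSV needs compound_id and gene_symbol columns")
    return df


def read_disease_tsv(path: str | Path) -> pd.DataFrame:
    """(gene_symbol, source) rows."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "gene_symbol" not in df.columns:
        raise ValueError("disease TSV needs a gene_symbol column")
    return df


def read_string_tsv(path: str | Path) -> pd.DataFrame:
    """(protein1, protein2, combined_score) rows, STRING dialect."""
    df = pd.read_csv(path, sep="\t")
    if not {"protein1", "protein2", "combined_score"} <= set(df.columns):
        raise ValueError("edge TSV needs protein1, protein2, combined_score columns")
    return df


def read_orbitals_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if not {"compound_id", "homo", "lumo"} <= set(df.columns):
        raise ValueError("orbital CSV needs compound_id, homo, lumo columns")
    return df


def read_docking_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if not {"ligand", "target_pdb", "score_kcal_mol"} <= set(df.columns):
        raise ValueError("docking CSV needs ligand, target_pdb, score_kcal_mol columns")
    return df
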