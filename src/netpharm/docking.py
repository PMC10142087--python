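"""Docking-score comparison against reference ligands.

Consumes a pre-computed docking score table (ligand, 4-character PDB target
id, score in kcal/mol, more negative = stronger binding) and classifies each
candidate pose relative to the reference drugs docked on the same target:

* ``stronger_than_all_references`` — score strictly below every reference;
* ``comparable`` — within a tolerance window (default 0.5 kcal/mol) of the
  best (most negative) reference;
* ``weaker`` — otherwise.

Independently, a pose is flagged a *strong binder* when its score is
strictly below the strong-binding threshold (default -8 kcal/mol).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "DockingRecord",
    "compare_docking_scores",
    "EXAMPLE_DOCKING_SCORES",
    "STRONG_BINDING_THRESHOLD",
    "COMPARABLE_WINDOW",
]

STRONG_BINDING_THRESHOLD = -8.0   # kcal/mol, strict
COMPARABLE_WINDOW = 0.5           # kcal/mol around the best reference

_PDB_RE = re.compile(r"[A-Za-z0-9]{4}")


@dataclass(frozen=True)
class DockingRecord:
    """One scored ligand-target pose, optionally with interaction notes."""

    ligand: str
    target: str            # 4-character PDB id
    score: float           # kcal/mol
    bonds: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not _PDB_RE.fullmatch(self.target):
            raise ValueError(f"invalid PDB id {self.target!r} (need 4 alphanumerics)")
        if not math.isfinite(self.score):
            raise ValueError(f"{self.ligand}/{self.target}: non-finite score")


def compare_docking_scores(
    records: Iterable[DockingRecord],
    references: Sequence[str],
    strong_threshold: float = STRONG_BINDING_THRESHOLD,
    comparable_window: float = COMPARABLE_WINDOW,
) -> pd.DataFrame:
    """Classify every candidate (ligand, target) pose against the references.

    Parameters
    ----------
    records
        All scored poses, candidates and references mixed.
    references
        Ligand names to treat as reference drugs.
    strong_threshold
        Strict cutoff below which a pose is a strong binder.
    comparable_window
        Half-width (kcal/mol) of the "comparable to best reference" band.

    Raises
    ------
    ValueError
        If a candidate target has no reference pose.
    """
    recs = list(records)
    ref_names = set(references)
    ref_scores: dict[str, list[float]] = {}
    for r in recs:
        if r.ligand in ref_names:
            ref_scores.setdefault(r.target, []).append(r.score)

    rows = []
    for r in recs:
        if r.ligand in ref_names:
            continue
        refs = ref_scores.get(r.target)
        if not refs:
            raise ValueError(f"no reference scores for target {r.target!r}")
        best_ref = min(refs)
        if r.score < best_ref:
            cls = "stronger_than_all_references"
        elif r.score <= best_ref + comparable_window:
            cls = "comparable"
        else:
            cls = "weaker"
        rows.append({
            "ligand": r.ligand,
            "target": r.target,
            "score_kcal_mol": r.score,
            "best_reference_kcal_mol": best_ref,
            "classification": cls,
            "strong_binder": r.score < strong_threshold,
        })
    return pd.DataFrame(
        rows,
        columns=["ligand", "target", "score_kcal_mol", "best_reference_kcal_mol",
                 "classification", "strong_binder"],
    )


#: Worked-example score table: the candidate metabolite
#: N-(3-chlorophenyl)naphthylcarboxamide versus the reference NSAIDs Aspirin
#: and Indomethacin on five HIF-1 signaling-pathway targets (Glide SP-style
#: scores, kcal/mol).
EXAMPLE_CANDIDATE = "N-(3-chlorophenyl)naphthylcarboxamide"
EXAMPLE_REFERENCES = ("Aspirin", "Indomethacin")
EXAMPLE_DOCKING_SCORES = pd.DataFrame(
    [
        # target protein, PDB id, candidate, aspirin, indomethacin
        (EXAMPLE_CANDIDATE, "1M9J", -7.236),   # NOS3
        ("Aspirin", "1M9J", -5.262),
        ("Indomethacin", "1M9J", -7.451),
        (EXAMPLE_CANDIDATE, "1NSI", -8.85),    # NOS2
        ("Aspirin", "1NSI", -6.467),
        ("Indomethacin", "1NSI", -7.491),
        (EXAMPLE_CANDIDATE, "3HNG", -8.88),    # FLT1
        ("Aspirin", "3HNG", -6.794),
        ("Indomethacin", "3HNG", -5.538),
        (EXAMPLE_CANDIDATE, "3UL7", -4.027),   # TLR4
        ("Aspirin", "3UL7", -4.178),
        ("Indomethacin", "3UL7", -4.168),
        (EXAMPLE_CANDIDATE, "5WB7", -4.123),   # EGFR
        ("Aspirin", "5WB7", -4.182),
        ("Indomethacin", "5WB7", -4.707),
    ],
    columns=["ligand", "target_pdb", "score_kcal_mol"],
)


def records_from_table(df: pd.DataFrame) -> list[DockingRecord]:
    """Build :class:`DockingRecord` objects from a (ligand, target_pdb,
    score_kcal_mol) table."""
    return [
        DockingRecord(str(r.ligand), str(r.target_pdb), float(r.score_kcal_mol))
        for r in df.itertuples(index=False)
    ]
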