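"""Drug-likeness screening of candidate metabolites.

Implements Lipinski's rule of five with the Moriguchi logP (MLOGP) variant and
an Abbott oral-bioavailability gate, as used to filter GC-MS-identified
metabolites before target prediction.  A compound is retained when it violates
at most one of the four descriptor rules *and* its bioavailability score
exceeds 0.50.  All rule boundaries are inclusive: a compound sitting exactly
at MW 500, HBA 10, HBD 5 or MLOGP 4.15 does not violate that rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "LIPINSKI_LIMITS",
    "BIOAVAILABILITY_MIN",
    "COMPOUND_COLUMNS",
    "CompoundRecord",
    "ScreenResult",
    "count_lipinski_violations",
    "is_druglike",
    "screen_table",
    "compute_descriptors",
]

#: Inclusive upper limits of the four rule-of-five descriptors.
LIPINSKI_LIMITS: dict[str, float] = {
    "mw": 500.0,     # molecular weight, Da
    "hba": 10,       # H-bond acceptors
    "hbd": 5,        # H-bond donors
    "mlogp": 4.15,   # Moriguchi octanol-water partition coefficient
}

#: Abbott bioavailability score must strictly exceed this to pass the gate.
BIOAVAILABILITY_MIN: float = 0.50

#: Canonical column order of a compound table.
COMPOUND_COLUMNS = [
    "id", "name", "formula", "rt_min", "area_pct", "smiles",
    "mw", "hba", "hbd", "mlogp", "bioavailability",
]


@dataclass(frozen=True)
class CompoundRecord:
    """One screened metabolite with structure string and descriptors.

    ``rt_min`` and ``area_pct`` carry the chromatographic provenance
    (retention time in minutes, relative peak area in percent); the five
    remaining numeric fields are the screening descriptors.
    """

    id: str
    name: str
    mw: float
    hba: int
    hbd: int
    mlogp: float
    bioavailability: float
    formula: str = ""
    rt_min: float = 0.0
    area_pct: float = 0.0
    smiles: str = ""

    def __post_init__(self) -> None:
        if self.mw <= 0:
            raise ValueError(f"{self.id}: molecular weight must be positive, got {self.mw}")
        if self.hba < 0 or self.hbd < 0:
            raise ValueError(f"{self.id}: H-bond counts must be non-negative")
        if not 0.0 <= self.bioavailability <= 1.0:
            raise ValueError(
                f"{self.id}: bioavailability score must lie in [0, 1], got {self.bioavailability}"
            )


@dataclass
class ScreenResult:
    """Outcome of :func:`screen_table`: the retained rows plus an audit report."""

    retained: pd.DataFrame
    report: dict = field(default_factory=dict)


def count_lipinski_violations(mw: float, hba: int, hbd: int, mlogp: float) -> int:
    """Number of rule-of-five descriptors exceeding their limit (0-4).

    Boundaries are inclusive: equality with a limit is a pass.
    """
    if mw <= 0:
        raise ValueError(f"molecular weight must be positive, got {mw}")
    if hba < 0 or hbd < 0:
        raise ValueError("H-bond counts must be non-negative")
    return sum((
        mw > LIPINSKI_LIMITS["mw"],
        hba > LIPINSKI_LIMITS["hba"],
        hbd > LIPINSKI_LIMITS["hbd"],
        mlogp > LIPINSKI_LIMITS["mlogp"],
    ))


def is_druglike(
    record: CompoundRecord | Mapping,
    bioavailability_min: float = BIOAVAILABILITY_MIN,
) -> bool:
    """True iff the compound has at most one rule violation and its
    bioavailability score strictly exceeds ``bioavailability_min``."""
    get = (lambda k: getattr(record, k)) if isinstance(record, CompoundRecord) else record.__getitem__
    violations = count_lipinski_violations(get("mw"), get("hba"), get("hbd"), get("mlogp"))
    return violations <= 1 and get("bioavailability") > bioavailability_min


def screen_table(
    table: pd.DataFrame | Iterable[CompoundRecord],
    bioavailability_min: float = BIOAVAILABILITY_MIN,
) -> ScreenResult:
    """Apply the drug-likeness gate to a compound table.

    Parameters
    ----------
    table
        DataFrame with at least ``id, mw, hba, hbd, mlogp, bioavailability``
        columns, or an iterable of :class:`CompoundRecord`.
    bioavailability_min
        Abbott-score gate; kept strictly greater-than.

    Returns
    -------
    ScreenResult
        ``retained`` preserves input row order; ``report`` gives per-rule
        violation tallies, the excluded compound ids, and the gate settings.

    Raises
    ------
    ValueError
        On duplicate compound ids.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.DataFrame([vars(r) for r in table])
    if table.empty:
        empty = table.copy()
        return ScreenResult(empty, _empty_report(bioavailability_min))

    ids = table["id"]
    if ids.duplicated().any():
        dupes = sorted(ids[ids.duplicated()].unique())
        raise ValueError(f"duplicate compound ids: {dupes}")

    per_rule = {k: 0 for k in LIPINSKI_LIMITS}
    keep, violations = [], []
    for row in table.itertuples(index=False):
        v = count_lipinski_violations(row.mw, row.hba, row.hbd, row.mlogp)
        violations.append(v)
        for rule, limit in LIPINSKI_LIMITS.items():
            if getattr(row, rule) > limit:
                per_rule[rule] += 1
        keep.append(v <= 1 and row.bioavailability > bioavailability_min)

    retained = table.loc[keep].reset_index(drop=True)
    excluded = table.loc[[not k for k in keep], "id"].tolist()
    n_bio_fail = int((table["bioavailability"] <= bioavailability_min).sum())
    report = {
        "n_input": int(len(table)),
        "n_retained": int(len(retained)),
        "n_excluded": len(excluded),
        "excluded_ids": excluded,
        "rule_violation_counts": per_rule,
        "n_bioavailability_failures": n_bio_fail,
        "violation_counts_per_compound": dict(zip(table["id"], violations)),
        "gate": {
            "max_violations": 1,
            "bioavailability_min": bioavailability_min,
            "limits": dict(LIPINSKI_LIMITS),
        },
    }
    return ScreenResult(retained, report)


def _empty_report(bioavailability_min: float) -> dict:
    return {
        "n_input": 0,
        "n_retained": 0,
        "n_excluded": 0,
        "excluded_ids": [],
        "rule_violation_counts": {k: 0 for k in LIPINSKI_LIMITS},
        "n_bioavailability_failures": 0,
        "violation_counts_per_compound": {},
        "gate": {
            "max_violations": 1,
            "bioavailability_min": bioavailability_min,
            "limits": dict(LIPINSKI_LIMITS),
        },
    }


def compute_descriptors(smiles: str) -> dict[str, float]:
    """Compute screening descriptors from a SMILES string with RDKit.

    Used only when a compound table lacks descriptor columns; supplied values
    always take precedence.  Note: RDKit provides the Wildman-Crippen logP,
    not the Moriguchi MLOGP, so the ``mlogp`` slot is filled with Crippen
    logP and a warning is emitted.
    """
    from rdkit import Chem
    from rdkit.Chem import Crippen, Descriptors, Lipinski

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    warnings.warn(
        "mlogp computed as Wildman-Crippen logP (RDKit has no Moriguchi MLOGP)",
        stacklevel=2,
    )
    return {
        "mw": float(Descriptors.MolWt(mol)),
        "hba": int(Lipinski.NumHAcceptors(mol)),
        "hbd": int(Lipinski.NumHDonors(mol)),
        "mlogp": float(Crippen.MolLogP(mol)),
    }
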