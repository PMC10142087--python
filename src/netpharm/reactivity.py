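"""Frontier-molecular-orbital reactivity descriptors.

From supplied HOMO/LUMO energies (no quantum-chemistry computation is
performed here) the module derives the three global reactivity descriptors:

* gap = |HOMO - LUMO|
* chemical hardness  eta = gap / 2
* chemical softness  S = 1 / eta

A smaller gap means a softer, more reactive molecule.  Hardness is reported
positive regardless of the sign convention of the inputs, and units are
carried through verbatim from the input table — no conversion is attempted.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

__all__ = [
    "OrbitalEnergies",
    "orbital_gap",
    "hardness",
    "softness",
    "reactivity_report",
]


@dataclass(frozen=True)
class OrbitalEnergies:
    """HOMO/LUMO energies of one compound, in the units they arrived in."""

    compound_id: str
    homo: float
    lumo: float
    units: str = "hartree"

    def __post_init__(self) -> None:
        if math.isnan(self.homo) or math.isnan(self.lumo):
            raise ValueError(f"{self.compound_id}: missing orbital energy")
        if self.lumo < self.homo:
            warnings.warn(
                f"{self.compound_id}: LUMO ({self.lumo}) below HOMO ({self.homo}); "
                "check sign convention/units",
                stacklevel=2,
            )


def orbital_gap(e: OrbitalEnergies) -> float:
    """Absolute HOMO-LUMO gap."""
    return abs(e.homo - e.lumo)


def hardness(e: OrbitalEnergies) -> float:
    """Chemical hardness eta = |HOMO - LUMO| / 2, reported positive."""
    return orbital_gap(e) / 2.0


def softness(eta: float) -> float:
    """Chemical softness S = 1/eta; NaN (with a warning) at zero hardness."""
    if eta < 0:
        raise ValueError(f"hardness must be non-negative, got {eta}")
    if eta == 0:
        warnings.warn("zero hardness: softness undefined, reporting NaN", stacklevel=2)
        return math.nan
    return 1.0 / eta


def reactivity_report(
    candidates: Sequence[OrbitalEnergies],
    standards: Sequence[OrbitalEnergies],
) -> pd.DataFrame:
    """Per-compound gap/hardness/softness, candidates flagged when softer
    than every standard.

    A candidate is ``softer_than_all_standards`` when its hardness is
    strictly below the smallest standard hardness (softer means more
    reactive); equality does not flag.

    Raises
    ------
    ValueError
        If either list is empty.
    """
    if not candidates:
        raise ValueError("need at least one candidate")
    if not standards:
        raise ValueError("need at least one standard compound")

    std_hardness = [hardness(s) for s in standards]
    min_std = min(std_hardness)

    rows = []
    for role, group in (("candidate", candidates), ("standard", standards)):
        for e in group:
            eta = hardness(e)
            rows.append({
                "compound_id": e.compound_id,
                "role": role,
                "homo": e.homo,
                "lumo": e.lumo,
                "units": e.units,
                "gap": orbital_gap(e),
                "hardness": eta,
                "softness": softness(eta),
                "softer_than_all_standards": (role == "candidate" and eta < min_std),
            })
    return pd.DataFrame(rows)
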