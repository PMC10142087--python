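"""Frontier-orbital reactivity and docking-score comparison.

Computes HOMO-LUMO gap, chemical hardness and softness for the key
metabolite versus two reference NSAIDs, then classifies its docking scores
on five HIF-1-pathway targets against the same references.
"""

from netpharm.docking import (EXAMPLE_DOCKING_SCORES, EXAMPLE_REFERENCES,
                              compare_docking_scores, records_from_table)
from netpharm.reactivity import OrbitalEnergies, reactivity_report
from netpharm.synth import gen_orbitals

orb = gen_orbitals()
energies = [OrbitalEnergies(r.compound_id, r.homo, r.lumo, r.units)
            for r in orb.itertuples(index=False)]
report = reactivity_report([energies[0]], energies[1:])
print(report[["compound_id", "role", "gap", "hardness", "softness",
              "softer_than_all_standards"]].to_string(index=False))

print()
cls = compare_docking_scores(records_from_table(EXAMPLE_DOCKING_SCORES),
                             list(EXAMPLE_REFERENCES))
print(cls.to_string(index=False))
# Hardness is half the HOMO-LUMO gap; a softer (lower-hardness) molecule is
# more reactive.  Docking scores below the best reference mean stronger
# predicted binding; below -8 kcal/mol is flagged as a strong binder.
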