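"""Drug-likeness screening of a synthetic metabolite table.

Generates 30 GC-MS-style compounds, 30% of them built to violate at least
two rule-of-five descriptors, and applies the screening gate (at most one
violation AND Abbott bioavailability score > 0.50).
"""

from netpharm.screen import screen_table
from netpharm.synth import gen_compounds

table = gen_compounds(n=30, frac_violators=0.3, seed=42)
result = screen_table(table)
rep = result.report

print(f"compounds in           : {rep['n_input']}")
print(f"retained (drug-like)   : {rep['n_retained']}")
print(f"excluded               : {rep['n_excluded']}  ids={rep['excluded_ids']}")
print(f"per-rule violations    : {rep['rule_violation_counts']}")
print(f"bioavailability fails  : {rep['n_bioavailability_failures']}")

# The retained compounds are the ones worth carrying into target prediction:
# each violates at most one of {MW<=500, HBA<=10, HBD<=5, MLOGP<=4.15} and
# has an oral bioavailability score above 0.50.
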