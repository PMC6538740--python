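"""ADME screening of a four-herb compound table.

Generates a synthetic formula table with a planted passer fraction,
applies the OB > 30 % / DL > 0.18 candidate filter and prints per-herb
candidate counts.  Because compounds may belong to several herbs, herb
counts can sum to more than the distinct candidate total.
"""

from netpharm.screen import screen_compounds, union_compound_targets
from netpharm.simulate import SimulationSpec, gen_compound_table, gen_target_map

spec = SimulationSpec(seed=1)
table = gen_compound_table(spec)
result = screen_compounds(table)

print(f"screened {len(table)} compounds -> {len(result.retained)} candidates")
for herb, count in result.herb_counts.items():
    print(f"  {herb}: {count} candidates")

mapping = gen_target_map(spec)
targets, covered = union_compound_targets(result.retained, mapping)
print(f"{covered} candidates map to at least one target; "
      f"{len(targets)} distinct putative targets")
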