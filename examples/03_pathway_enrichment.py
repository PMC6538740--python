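"""Hypergeometric over-representation analysis with BH control.

Generates an annotation collection with three planted enriched terms and
a matching query list, runs the one-sided hypergeometric test per term
and adjusts across tested terms with Benjamini-Hochberg.  Planted terms
should dominate the q < 0.05 calls.
"""

from netpharm.enrich import ora
from netpharm.simulate import SimulationSpec, gen_gene_sets

collection, query, planted = gen_gene_sets(SimulationSpec(seed=1))
result = ora(set(query), collection)

print(f"query of {len(query)} genes against {len(collection)} terms "
      f"(universe {len(collection.universe)})")
print(result.head(5).to_string(index=False,
      formatters={"p": "{:.3g}".format, "q": "{:.3g}".format}))
flagged = set(result.loc[result["enriched"], "term_id"])
print(f"enriched at q<0.05: {sorted(flagged)}; planted: {planted}")
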