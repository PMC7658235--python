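"""Generate a synthetic discovery cohort with planted response modules.

Builds the default study design — 14 azacitidine responders vs 9
non-responders, 5,000 genes with a respiration module and an apoptosis
module up in responders and a Wnt module up in non-responders — and
prints what was planted.
"""

from azasig import SimulationConfig, simulate_discovery_cohort

config = SimulationConfig(seed=1)
cohort = simulate_discovery_cohort(config)

print("expression matrix:", cohort.expression.shape, "(genes x samples)")
print("groups:", cohort.phenotypes.group_counts())
print("planted differential genes:", int(cohort.truth["is_de"].sum()))
for module in config.modules:
    print(f"  {module.name}: {module.n_genes} genes, "
          f"{module.direction}, effect {module.effect_size} log2 units")
print("gene sets (modules + decoys):", len(cohort.gene_sets))
print("regulatory network:", len(cohort.network.nodes), "nodes,",
      cohort.network.n_edges(), "edges")
# The truth table is the oracle every downstream example checks against.
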