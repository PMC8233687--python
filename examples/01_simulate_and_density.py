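"""Simulate a small hypermutator evolution experiment and compute per-gene
mutation densities.

The density statistic counts every mutation ever observed in a gene across
the selected populations and divides by gene length, so long genes do not
look fast merely because they are big targets.
"""

from mutdens import SimulationConfig, mutation_density, simulate_dataset

dataset = simulate_dataset(SimulationConfig(n_genes=500, seed=42))
print(f"simulated {len(dataset.records)} ever-observed mutations "
      f"in {len(dataset.annotations)} genes")

table = mutation_density(
    dataset.records, dataset.annotations,
    populations="hypermutator", scheme="all", cutoff=60_000,
)
top = table.frame.sort_values("density", ascending=False).head(5)
print("\nfive densest genes (hypermutator populations, all classes):")
print(top.to_string())

print(
    "\ncount is the raw number of ever-observed mutations; density is "
    "count/length_nt,\nthe per-nucleotide rate that the correlation "
    "analyses use."
)
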