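"""Simulate a haplogroup tree, a sequence cohort and array manifests.

The study design is one sequence per terminal (five-character) African
haplogroup and two per non-African major (M, N, R), on a reference-length
genome with clade-defining mutations accumulating down the tree.
"""
from mitoarray import simulate_dataset, simulate_haplotree, simulate_manifest
from mitoarray.simulate import ManifestSpec, SimulationConfig

cfg = SimulationConfig(seed=1, genome_length=2000, children_per_node=2)
tree = simulate_haplotree(cfg)
cohort = simulate_dataset(tree, cfg)
rich = simulate_manifest(tree, ManifestSpec("rich", 0.8, 50, seed=1), cfg.genome_length)
poor = simulate_manifest(tree, ManifestSpec("poor", 0.1, 50, seed=1), cfg.genome_length)

print(f"haplogroups in tree:      {len(tree)}")
print(f"clade-defining positions: {len(tree.defining_positions())}")
print(f"cohort size:              {len(cohort.samples)} samples")
print(f"'rich' array manifest:    {len(rich)} positions (80% of defining sites)")
print(f"'poor' array manifest:    {len(poor)} positions (10% of defining sites)")
# Both manifests type a similar number of mtDNA positions; what differs is
# how many of them are informative for haplogroup membership.
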