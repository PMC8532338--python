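"""Build a bootstrapped neighbor-joining tree from array-masked sequences.

Support for each clade is the share of column-resampled replicates that
reproduce its bipartition; only supports >= 50 count toward assignability.
"""
from mitoarray import BootstrapConfig, bootstrap_tree, mask_to_array, simulate_dataset, simulate_haplotree, simulate_manifest
from mitoarray.simulate import ManifestSpec, SimulationConfig

cfg = SimulationConfig(seed=1, genome_length=2000, children_per_node=2)
tree = simulate_haplotree(cfg)
cohort = simulate_dataset(tree, cfg)
manifest = simulate_manifest(tree, ManifestSpec("array", 1.0, 0, seed=1), 2000)

st = bootstrap_tree(
    mask_to_array(cohort, manifest), model="k2p",
    config=BootstrapConfig(replicates=200, seed=1),
)
sup = sorted(st.supports.values())
print(f"leaves: {len(st.leaf_names())}, internal bipartitions: {len(sup)}")
print(f"bootstrap support: min {sup[0]:.0f}, median {sup[len(sup)//2]:.0f}, max {sup[-1]:.0f}")
print(f"clades at support >= 50: {sum(s >= 50 for s in sup)} of {len(sup)}")
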