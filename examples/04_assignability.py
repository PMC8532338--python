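"""Score per-haplogroup assignability of arrays against the full genome.

A haplogroup is assignable when all, or all but one, of its subhaplogroup
leaves cluster under one branch with bootstrap support >= 50 and at most
one intruding leaf.  The full-genome tree is the gold standard.
"""
from mitoarray import (
    BootstrapConfig, assignability_percentages, bootstrap_tree, mask_to_array,
    simulate_dataset, simulate_haplotree, simulate_manifest,
)
from mitoarray.seqio import SiteMatrix
from mitoarray.simulate import ManifestSpec, SimulationConfig

cfg = SimulationConfig(seed=3, genome_length=2000, children_per_node=2)
tree = simulate_haplotree(cfg)
cohort = simulate_dataset(tree, cfg)
labels = {s.id: s.label for s in cohort.samples}

full = bootstrap_tree(SiteMatrix.from_sequences(cohort), config=BootstrapConfig(200, 30))
arrays = {}
for i, frac in enumerate((1.0, 0.5, 0.1)):
    m = simulate_manifest(tree, ManifestSpec(f"array_{int(frac*100)}", frac, 50, seed=3), 2000)
    arrays[m.name] = bootstrap_tree(mask_to_array(cohort, m), config=BootstrapConfig(200, 31 + i))

report = assignability_percentages(full, arrays, labels)
print("percent of gold-standard-assignable African haplogroups preserved:")
print("array        level2  level3  level4")
for name in sorted(arrays):
    row = [report.aggregates[(name, lvl)] for lvl in (2, 3, 4)]
    print(f"{name:12s} {row[0]:6.1f}  {row[1]:6.1f}  {row[2]:6.1f}")
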