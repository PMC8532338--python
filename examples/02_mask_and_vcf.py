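"""Mask a cohort to an array manifest and export the snp-sites-style VCF.

The VCF is haploid, keeps only polymorphic columns, and writes "." for
missing calls -- the format a haplogroup caller consumes.
"""
from pathlib import Path

from mitoarray import mask_to_array, panel_missing_count, sites_to_vcf, simulate_dataset, simulate_haplotree, simulate_manifest
from mitoarray.seqio import ArrayManifest
from mitoarray.simulate import ManifestSpec, SimulationConfig

cfg = SimulationConfig(seed=1, genome_length=2000, children_per_node=2)
tree = simulate_haplotree(cfg)
cohort = simulate_dataset(tree, cfg)
manifest = simulate_manifest(tree, ManifestSpec("array", 0.5, 50, seed=1), 2000)

matrix = mask_to_array(cohort, manifest)
out = Path("scratch_example.vcf")
n_rows = sites_to_vcf(matrix, cohort.reference, out)
print(f"masked matrix: {matrix.n_samples} samples x {matrix.n_sites} positions")
print(f"VCF rows written: {n_rows} (monomorphic-reference columns omitted)")

# a small diagnostic panel, as used by panel-based callers: how many of its
# SNPs does this array actually type?
panel = ArrayManifest("panel", tuple(sorted(tree.defining_positions()))[:54])
missing = panel_missing_count(manifest, panel)
print(f"panel SNPs missing from the array: {missing} of {len(panel)}")
out.unlink()
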