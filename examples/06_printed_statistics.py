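"""The statistical comparisons: Fisher exact, Pearson r, and Fisher's z.

Reproduces the published comparison of the three- versus four-digit
performance correlations across eight arrays (r = 0.9470996 and
r = 0.9698051, n = 8) and shows a Fisher-exact array contrast.
"""
from mitoarray import fisher1925_z, fishers_exact_2x2, pearson_r
from mitoarray.stats import ContingencyTable2x2, pearson_p_from_r

z, p = fisher1925_z(0.9470996, 8, 0.9698051, 8)
print(f"Fisher z comparing the two correlations: z = {z:.4f}, p = {p:.4f}")
print(f"p-value of r = 0.9698051 at n = 8:       {pearson_p_from_r(0.9698051, 8):.3e}")

# e.g. 12 of 15 haplogroups assignable on one array vs 4 of 15 on another
odds, fp = fishers_exact_2x2(ContingencyTable2x2(12, 3, 4, 11))
print(f"Fisher exact on 12/15 vs 4/15 assignable: odds = {odds:.2f}, p = {fp:.4g}")

# correlation between mtDNA SNP count and a (synthetic) performance column
counts = [411, 256, 239, 260, 373, 522, 116, 111]   # published array SNP counts
perf = [55, 41, 37, 27, 62, 81, 4, 11]              # illustrative percentages
res = pearson_r(counts, perf)
print(f"SNP count vs performance: r = {res.r:.3f}, p = {res.p:.4g} (n = {res.n})")
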