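"""Genic-context annotation, SNP spectrum and the gene-related down-sampling test.

Builds a toy gene (two exons, a 5' UTR, 1 kb flanks), classifies a few sites
against it, tabulates the 12 substitution types of a random site set, and
runs the down-sampling test that asks whether one set of sites is depleted
of gene-related contexts relative to random same-size draws from a pool.
"""

import numpy as np
import pandas as pd

from fpfinder import (GeneIndex, GeneModel, classify_site,
                      gene_related_downsample_test, snp_spectrum)

gene = GeneModel(gene_id="toy1", chrom="chr1", strand="+", start=1001, end=3000,
                 exons=[(1001, 1500), (2001, 3000)], utr5=[(1001, 1100)])
index = GeneIndex([gene])

for pos in (1050, 1200, 1502, 1700, 500, 3500, 9999):
    ctx = classify_site("chr1", pos, index)
    print(f"chr1:{pos:>5} -> {ctx.category:>13}  (gene: {ctx.gene_id or '-'})")

rng = np.random.default_rng(0)
ref = rng.choice(list("ACGT"), 200)
alt = [("ACGT".replace(r, ""))[j] for r, j in zip(ref, rng.integers(0, 3, 200))]
spectrum = snp_spectrum(pd.DataFrame({"ref": ref, "alt": alt}))
print(f"\n12-type SNP spectrum of 200 random sites (sums to {spectrum.sum()}):")
print(spectrum.to_string())

# a fingerprint set with 1 of 10 sites gene-related, drawn against a pool
# where 40% are gene-related: is the fingerprint set depleted?
res = gene_related_downsample_test(
    fingerprint_gene_related=[True] + [False] * 9,
    pool_gene_related=rng.random(500) < 0.4,
    set_size=10, n_sets=1000, seed=1)
print(f"\nobserved gene-related count in the fingerprint set: {res.observed}/10")
print(f"mean over 1000 random same-size draws from the pool: "
      f"{res.set_counts.mean():.2f}")
print(f"one-sided empirical p (sets with count <= observed): {res.pvalue:.4f}")
print("a small p says the fingerprint set carries fewer gene-related sites"
      " than chance")
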