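"""Expression and sequence statistics of the redistribution targets.

RPKM = count / (length in kb) / (library size in millions).  Group
comparisons drop zero-RPKM elements before boxplotting and use the
two-tailed Wilcoxon rank-sum test; CpG-dinucleotide density distinguishes
transposons that gain H3K27me3 from those that do not.
"""

import numpy as np

import chromredist as cr
from chromredist.expression import compute_rpkm, group_expression_compare
from chromredist.seqstats import cg_density, extract_sequence, wilcoxon_ranksum

spec = cr.SyntheticSpec(n_chromosomes=2, chromosome_length=100_000,
                        n_genes=40, n_transposons=14, seed=8)
bundle = cr.generate_bundle(spec)
truth, ann = bundle.truth, bundle.annotation

expr = {g: compute_rpkm(bundle.expression[g], genotype=g)
        for g in ("WT", "met1")}
class2 = truth.label_ids("class2")
print("silent fraction of Class II genes in WT:",
      cr.silent_fraction(expr["WT"], class2))

gain, stable = truth.label_ids("te_gain_k27"), truth.label_ids("te_stable")
cmp_ = group_expression_compare(expr["WT"], gain, stable, drop_zero=True)
print(f"WT expression, K27-gaining vs stable TEs: median log2 RPKM "
      f"{cmp_.summary_a.median:.2f} vs {cmp_.summary_b.median:.2f}, "
      f"p = {cmp_.pvalue:.2g} (dropped {cmp_.n_dropped_a + cmp_.n_dropped_b} "
      f"zero-RPKM TEs)")

dens = {}
for name, ids in (("gain", gain), ("stable", stable)):
    rows = ann[ann["id"].isin(ids)]
    dens[name] = [cg_density(extract_sequence(
        bundle.genome, r["chrom"], r["start"], r["end"], r["strand"]))[1]
        for _, r in rows.iterrows()]
_, p = wilcoxon_ranksum(dens["gain"], dens["stable"])
print(f"CpG-dinucleotide density: gain TEs {np.mean(dens['gain']):.3f} vs "
      f"stable TEs {np.mean(dens['stable']):.3f}, Wilcoxon p = {p:.2g}")
# The gaining transposons are lowly expressed in WT and CpG-rich -- the
# proposed recruiting ground for Polycomb once CG methylation is lost.
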