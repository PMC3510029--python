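"""Classify mutant-hypermethylated genes into Class I and Class II.

A gene joins a set when it overlaps the called regions by at least 150 bp
(about one nucleosome).  Class I = H3K9me2-gaining genes already weakly
H3K9me2-marked in wild type; Class II = H3K9me2-gaining genes that are
Polycomb (H3K27me3) targets in wild type.
"""

import chromredist as cr
from chromredist.regions import CallParams, bin_track

spec = cr.SyntheticSpec(n_chromosomes=2, chromosome_length=100_000,
                        n_genes=40, n_transposons=14, seed=8)
bundle = cr.generate_bundle(spec)
norm = {key: cr.log2_ratio_normalize(track, bundle.control)
        for key, track in bundle.tracks.items()}
params = CallParams()
genes = bundle.annotation[bundle.annotation["feature"] == "gene"]
lengths = {c: len(s) for c, s in bundle.genome.items()}

hyper = cr.overlap_genes(cr.call_differential_blocks(
    norm[("H3K9m2", "met1")], norm[("H3K9m2", "WT")], params,
    z_cutoff=params.z_cut_diff_met1), genes)
wt_k9 = cr.overlap_genes(cr.call_blocks(norm[("H3K9m2", "WT")], params), genes)
wt_k27 = cr.overlap_genes(cr.call_enriched_regions(
    bin_track(norm[("H3K27m3", "WT")], 200, 100, lengths), params), genes)

result = cr.classify_hyper_genes(hyper, wt_k9, wt_k27)
print("hypermethylated genes:", len(result.hyper))
print("Class I :", len(result.class1), f"({result.percentages()['class1']}%)")
print("Class II:", len(result.class2), f"({result.percentages()['class2']}%)")
print("planted truth:",
      len(bundle.truth.label_ids("class1")), "Class I,",
      len(bundle.truth.label_ids("class2")), "Class II")
accuracy = cr.classification_accuracy(
    {"class1": result.class1, "class2": result.class2}, bundle.truth.labels)
print(f"label recovery: {100 * accuracy:.1f}%")
# The percentages mirror the published summary style: the share of all
# mutant-hypermethylated genes that fall in each class.
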