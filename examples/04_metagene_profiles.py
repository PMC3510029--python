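"""Metagene profiles: average signal from TSS to TTS with flanks.

Gene bodies are rescaled onto 20 bins, flanks binned at 150 bp; the
met1/WT "log2 ratio" of already-log2 signals is their per-bin difference.
The CHG methylation profile pools methylated/total counts per bin.
"""

import numpy as np

import chromredist as cr
from chromredist.profiles import (ProfileScheme, average_profile,
                                  metagene_matrix, methylation_profile,
                                  ratio_profile)

spec = cr.SyntheticSpec(n_chromosomes=2, chromosome_length=100_000,
                        n_genes=40, n_transposons=14, seed=8)
bundle = cr.generate_bundle(spec)
norm = {key: cr.log2_ratio_normalize(track, bundle.control)
        for key, track in bundle.tracks.items()}
scheme = ProfileScheme(flank=1500, bin_width=150, n_body_bins=20)
nf, nb = scheme.n_flank_bins, scheme.n_body_bins

ann, truth = bundle.annotation, bundle.truth
class2 = ann[ann["id"].isin(truth.label_ids("class2"))]
te_gain = ann[ann["id"].isin(truth.label_ids("te_gain_k27"))]

for name, frame in (("Class II genes", class2), ("K27-gaining TEs", te_gain)):
    profiles = {g: average_profile(
        metagene_matrix(norm[("H3K27m3", g)], frame, scheme), scheme)
        for g in ("WT", "met1")}
    ratio = ratio_profile(profiles["met1"], profiles["WT"])
    body = np.nanmean(ratio.values[nf:nf + nb])
    flank = np.nanmean(np.r_[ratio.values[:3], ratio.values[-3:]])
    print(f"{name}: met1/WT H3K27me3 log2 ratio, body mean {body:+.2f}, "
          f"far-flank mean {flank:+.2f}")

chg = {g: methylation_profile(bundle.methylomes[g], class2, "CHG", scheme,
                              smooth_window=5) for g in ("WT", "met1")}
for g in ("WT", "met1"):
    print(f"CHG methylation over Class II bodies, {g}: "
          f"{np.nanmean(chg[g].values[nf:nf + nb]):.3f}")
# Expected picture: H3K27me3 drops over Class II gene bodies and rises over
# the K27-gaining transposons in met1, while CHG methylation appears over
# the same gene bodies -- the redistribution phenotype.
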