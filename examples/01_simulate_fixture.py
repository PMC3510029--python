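"""Generate a synthetic epigenome fixture with planted mark redistribution.

Builds a two-chromosome genome with annotated genes and transposons, plants
the chromatin-mark swap (Class II genes trade H3K27me3 for H3K9me2 in met1;
CpG-rich transposons trade H3K9me2 for H3K27me3), and writes the full
fixture bundle (FASTA, GFF3, bedGraph tracks, methylation and count tables,
truth JSON) to ./scratch_fixture.
"""

from collections import Counter

import chromredist as cr

spec = cr.SyntheticSpec(n_chromosomes=2, chromosome_length=80_000,
                        n_genes=30, n_transposons=12, seed=4)
bundle = cr.generate_bundle(spec)
files = cr.write_fixture_bundle(bundle, "scratch_fixture")

print(f"wrote {len(files)} files to scratch_fixture/")
print("planted element classes:", dict(Counter(bundle.truth.labels.values())))
print("probes per track:", bundle.tracks[('H3K9m2', 'WT')].n_probes)
# The class counts are the ground truth every downstream stage is scored
# against: class1 = weak wild-type H3K9me2 that strengthens in met1,
# class2 = Polycomb targets that swap H3K27me3 for H3K9me2,
# te_gain_k27 = transposons that gain H3K27me3 once CG methylation is lost.
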