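"""Synthetic-epigenome generator: determinism, planted structure, formats."""

import json

import numpy as np
import pandas as pd
import pytest

import chromredist as cr
from chromredist.simulate import (PackingError, SyntheticSpec,
                                  _cytosine_sites, generate_annotation,
                                  simulate_methylome, simulate_probe_tracks,
                                  simulate_read_counts)
from conftest import small_spec


def _dinucleotide_recount(seq: str) -> float:
    """Independent oracle: direct CpG recount over an emitted sequence."""
    return sum(seq[i:i + 2] == "CG" for i in range(len(seq) - 1)) / (len(seq) - 1)


class TestAnnotation:
    def test_counts_and_determinism(self):
        spec = small_spec(n_genes=10, n_transposons=4, seed=7)
        a1, r1, g1, t1 = generate_annotation(spec)
        a2, r2, g2, t2 = generate_annotation(spec)
        assert (a1["feature"] == "gene").sum() == 10
        assert (a1["feature"] == "transposable_element").sum() == 4
        pd.testing.assert_frame_equal(a1, a2)
        assert g1 == g2 and t1.labels == t2.labels

    def test_zero_pcg_fraction_degenerate(self):
        spec = small_spec(frac_pcg_genes=0.0)
        _, _, _, truth = generate_annotation(spec)
        assert not truth.label_ids("class2", "pcg_stable")

    def test_label_conservation(self, small_bundle):
        truth, spec = small_bundle.truth, small_bundle.spec
        genes = truth.label_ids("class1", "class2", "pcg_stable", "plain_gene")
        assert len(genes) == spec.n_genes
        tes = truth.label_ids("te_gain_k27", "te_stable")
        assert len(tes) == spec.n_transposons

    def test_elements_disjoint_and_planted_inside(self, small_bundle):
        ann = small_bundle.annotation
        for chrom, sub in ann.groupby("chrom"):
            sub = sub.sort_values("start")
            assert (sub["start"].to_numpy()[1:] >=
                    sub["end"].to_numpy()[:-1]).all()
        spans = {row["id"]: (row["chrom"], row["start"], row["end"])
                 for _, row in ann.iterrows()}
        for intervals in small_bundle.truth.planted.values():
            for p in intervals:
                chrom, start, end = spans[p.element_id]
                assert (p.chrom, p.start, p.end) == (chrom, start, end)

    def test_infeasible_packing_raises_named_error(self):
        spec = small_spec(chromosome_length=5000)
        with pytest.raises(PackingError, match="chromosome_length"):
            generate_annotation(spec)

    def test_cpg_density_separation_with_recount_oracle(self):
        spec = cr.SyntheticSpec(
            n_chromosomes=2, chromosome_length=150_000, n_genes=10,
            n_transposons=100, frac_te_gain_k27=0.5,
            high_cpg_density=0.20, low_cpg_density=0.02, seed=3)
        ann, _, genome, truth = generate_annotation(spec)
        dens = {"te_gain_k27": [], "te_stable": []}
        for _, row in ann[ann["feature"] == "transposable_element"].iterrows():
            seq = genome[row["chrom"]][row["start"]:row["end"]]
            recount = _dinucleotide_recount(seq)
            _, from_module = cr.cg_density(seq)
            assert recount == pytest.approx(from_module)
            dens[truth.labels[row["id"]]].append(recount)
        assert len(dens["te_gain_k27"]) == len(dens["te_stable"]) == 50
        assert np.mean(dens["te_gain_k27"]) > 2 * np.mean(dens["te_stable"])


class TestProbeTracks:
    def test_noiseless_values_are_exact_lifts(self, noiseless_bundle):
        delta = noiseless_bundle.spec.enrichment_delta
        allowed = {0.0, delta, 0.5 * delta}
        for track in noiseless_bundle.tracks.values():
            values = set(np.round(track.all_values(), 9))
            assert values <= allowed

    def test_class2_swap_contract(self, noiseless_bundle):
        truth = noiseless_bundle.truth
        ann = noiseless_bundle.annotation
        delta = noiseless_bundle.spec.enrichment_delta
        gene = ann[ann["id"].isin(truth.label_ids("class2"))].iloc[0]

        def probes_in(track):
            p = track.chroms[gene["chrom"]]
            mask = (p.midpoints >= gene["start"]) & (p.midpoints < gene["end"])
            return p.values[mask]

        np.testing.assert_allclose(
            probes_in(noiseless_bundle.tracks[("H3K27m3", "WT")]), delta)
        np.testing.assert_allclose(
            probes_in(noiseless_bundle.tracks[("H3K27m3", "met1")]), 0.0)
        np.testing.assert_allclose(
            probes_in(noiseless_bundle.tracks[("H3K9m2", "WT")]), 0.0)
        np.testing.assert_allclose(
            probes_in(noiseless_bundle.tracks[("H3K9m2", "met1")]), delta)

    def test_interval_means_concentrate(self):
        spec = small_spec(noise_sd=0.2, enrichment_delta=1.5, seed=5)
        ann, _, _, truth = generate_annotation(spec)
        tracks, _ = simulate_probe_tracks(ann, truth, spec)
        checked = 0
        devs = []
        for (mark, genotype), track in tracks.items():
            for p in truth.planted_for(mark, genotype):
                cp = track.chroms[p.chrom]
                mask = (cp.midpoints >= p.start) & (cp.midpoints < p.end)
                vals = cp.values[mask]
                dev = abs(vals.mean() - p.lift) / (spec.noise_sd / np.sqrt(len(vals)))
                devs.append(dev)
                checked += 1
        assert checked > 20
        # per-interval means sit within the normal concentration bound:
        # nearly all within 3 standard errors, none wildly outside
        devs = np.array(devs)
        assert (devs < 3.0).mean() > 0.95
        assert devs.max() < 4.0


class TestMethylome:
    def test_context_assignment_definition(self):
        sites = _cytosine_sites("ACGT", "c")
        plus = sites[sites["strand"] == "+"]
        assert plus["pos"].tolist() == [2]
        assert plus["context"].tolist() == ["CG"]
        minus = sites[sites["strand"] == "-"]
        assert minus["pos"].tolist() == [3]  # G pairs with C on minus strand
        assert minus["context"].tolist() == ["CG"]

    def test_extreme_rates(self):
        spec = small_spec(te_methylation_rate=1.0,
                          background_methylation_rate=0.0,
                          gene_body_cg_rate=0.0, chg_gain_rate=0.0)
        ann, _, genome, truth = generate_annotation(spec)
        tables = simulate_methylome(ann, truth, genome, spec)
        wt = tables["WT"]
        te_rows = np.zeros(len(wt), bool)
        pos0 = wt["pos"].to_numpy() - 1
        for _, row in ann[ann["feature"] == "transposable_element"].iterrows():
            te_rows |= ((wt["chrom"] == row["chrom"]).to_numpy()
                        & (pos0 >= row["start"]) & (pos0 < row["end"]))
        gene_rows = np.zeros(len(wt), bool)
        for _, row in ann[ann["feature"] == "gene"].iterrows():
            gene_rows |= ((wt["chrom"] == row["chrom"]).to_numpy()
                          & (pos0 >= row["start"]) & (pos0 < row["end"]))
        assert (wt.loc[te_rows, "m_count"]
                == wt.loc[te_rows, "t_count"]).all()
        assert (wt.loc[~te_rows & ~gene_rows, "m_count"] == 0).all()

    def test_binomial_concentration(self, small_bundle):
        spec, truth = small_bundle.spec, small_bundle.truth
        wt = small_bundle.methylomes["WT"]
        ann = small_bundle.annotation
        te = ann[ann["feature"] == "transposable_element"].iloc[0]
        sub = wt[(wt["chrom"] == te["chrom"])
                 & (wt["pos"] - 1 >= te["start"]) & (wt["pos"] - 1 < te["end"])]
        assert len(sub) > 200
        pooled = sub["m_count"].sum() / sub["t_count"].sum()
        assert abs(pooled - spec.te_methylation_rate) < 0.05


class TestReadCounts:
    def test_silent_tier_is_exactly_zero(self, small_bundle):
        truth = small_bundle.truth
        wt = small_bundle.expression["WT"].set_index("id")
        for gid in truth.label_ids("class2", "pcg_stable"):
            assert wt.loc[gid, "count"] == 0

    def test_same_seed_identical_tables(self):
        spec = small_spec()
        ann, _, _, truth = generate_annotation(spec)
        e1, s1 = simulate_read_counts(ann, truth, spec)
        e2, s2 = simulate_read_counts(ann, truth, spec)
        for g in ("WT", "met1"):
            pd.testing.assert_frame_equal(e1[g], e2[g])
            pd.testing.assert_frame_equal(s1[g], s2[g])

    def test_tier_means_ordered_and_concentrated(self):
        spec = cr.SyntheticSpec(
            n_chromosomes=3, chromosome_length=250_000, n_genes=300,
            n_transposons=0, frac_pcg_genes=0.34, frac_class1_genes=0.33,
            frac_class2_converted=1.0, seed=9,
            expression_mean_silent=0.0, expression_mean_low=5.0,
            expression_mean_moderate=100.0)
        ann, _, _, truth = generate_annotation(spec)
        expr, _ = simulate_read_counts(ann, truth, spec)
        wt = expr["WT"].set_index("id")["count"]
        means = {}
        for label, target in (("class2", 0.0), ("class1", 5.0),
                              ("plain_gene", 100.0)):
            ids = sorted(truth.label_ids(label))
            vals = wt.loc[ids]
            means[label] = vals.mean()
            var = target + spec.expression_dispersion * target ** 2
            se = np.sqrt(var / len(vals)) if target else 0.0
            # expressed tiers are floored at one read; allow that shift
            slack = 3 * se + 1.0 if target else 0.0
            assert abs(vals.mean() - target) <= slack
        assert means["class2"] < means["class1"] < means["plain_gene"]

    def test_smallrna_concentrates_on_class1_and_rises_in_met1(self, small_bundle):
        truth, ann = small_bundle.truth, small_bundle.annotation
        class1 = ann[ann["id"].isin(truth.label_ids("class1"))]

        def reads_in_class1(table):
            mids = (table["start"] + table["end"]) / 2
            total = 0
            for _, g in class1.iterrows():
                total += int(((table["chrom"] == g["chrom"])
                              & (mids >= g["start"]) & (mids < g["end"])).sum())
            return total

        wt = reads_in_class1(small_bundle.smallrna["WT"])
        met1 = reads_in_class1(small_bundle.smallrna["met1"])
        assert wt > 0.5 * len(small_bundle.smallrna["WT"])
        assert met1 > 2 * wt


class TestFixtureBundle:
    def test_roundtrip_and_checksums(self, tmp_path, small_bundle):
        d1 = tmp_path / "a"
        files1 = cr.write_fixture_bundle(small_bundle, d1)
        back = cr.read_fixture_bundle(d1)
        for key, track in small_bundle.tracks.items():
            for c in track.chrom_names:
                np.testing.assert_allclose(back.tracks[key].chroms[c].values,
                                           track.chroms[c].values, rtol=1e-5)
        pd.testing.assert_frame_equal(
            back.annotation, small_bundle.annotation)
        assert back.truth.labels == small_bundle.truth.labels
        assert back.genome == small_bundle.genome
        # regenerating from the same spec gives identical checksums
        d2 = tmp_path / "b"
        files2 = cr.write_fixture_bundle(
            cr.generate_bundle(small_bundle.spec), d2)
        assert files1 == files2
        manifest = json.loads((d1 / "manifest.json").read_text())
        assert set(manifest["files"]) == {p.name for p in d1.iterdir()} - \
            {"manifest.json"}

    def test_bedgraph_line_count_equals_probe_count(self, tmp_path, small_bundle):
        cr.write_fixture_bundle(small_bundle, tmp_path / "fix")
        lines = (tmp_path / "fix" / "track_H3K9m2_WT.bedGraph").read_text() \
            .strip().split("\n")
        assert len(lines) == small_bundle.tracks[("H3K9m2", "WT")].n_probes
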