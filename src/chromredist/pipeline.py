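"""End-to-end orchestration: normalize -> call -> classify -> profile -> report.

Stage order mirrors the analysis it reimplements: probe tracks are
normalized against the control channel, wild-type H3K9me2/H3K27me3 states
and mutant differential regions are called, mutant-hypermethylated genes
are classified into Class I/II by their wild-type mark, and metagene /
expression / sequence summaries are computed.  The JSON report embeds the
resolved configuration and seed; two runs with the same config and seed
are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path
from typing import Dict, List, Set, Tuple

import numpy as np
import pandas as pd
import yaml

from . import annotations as anno
from .classify import (ClassificationResult, classify_hyper_genes,
                       overlap_genes, percentage)
from .evaluate import classification_accuracy, interval_jaccard
from .expression import compute_rpkm, group_expression_compare, silent_fraction
from .profiles import (MetageneProfile, ProfileScheme, average_profile,
                       metagene_matrix, methylation_profile, profile_to_frame,
                       ratio_profile, read_density_profile)
from .regions import (BinTrack, CallParams, bin_track, call_blocks,
                      call_differential_blocks, call_differential_regions,
                      call_enriched_regions, difference_bins, difference_track,
                      estimate_fdr, regions_to_bed)
from .seqstats import cg_density, extract_sequence, wilcoxon_ranksum
from .simulate import MARKS, SyntheticBundle, read_fixture_bundle
from .tracks import NormalizedTrack, log2_ratio_normalize

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Pipeline configuration failed validation."""


@dataclasses.dataclass
class PipelineConfig:
    fixture_dir: str
    out_dir: str
    seed: int = 0
    params: CallParams = dataclasses.field(default_factory=CallParams)
    scheme: ProfileScheme = dataclasses.field(default_factory=ProfileScheme)
    min_overlap: int = 150
    k27_min_region_len: int = 500   # "> 500 bp" rule for H3K27m3 gains
    run_fdr: bool = True
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return {
            "fixture_dir": str(self.fixture_dir), "out_dir": str(self.out_dir),
            "seed": self.seed, "params": dataclasses.asdict(self.params),
            "scheme": dataclasses.asdict(self.scheme),
            "min_overlap": self.min_overlap,
            "k27_min_region_len": self.k27_min_region_len,
            "run_fdr": self.run_fdr, "log_level": self.log_level,
        }


def config_from_yaml(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    params = CallParams(**raw.pop("params", {}))
    scheme = ProfileScheme(**raw.pop("scheme", {}))
    return PipelineConfig(params=params, scheme=scheme, **raw)


PUBLISHED_DEFAULTS = {
    "bin_size": 200, "step": 100, "z_cut_enriched": 2.0, "z_cut_hypo": -3.0,
    "z_cut_diff_met1": 0.75, "z_cut_diff_ibm1": 0.8, "merge_gap": 200,
}


def validate_config(config: PipelineConfig) -> Tuple[List[str], List[str]]:
    """Returns (errors, warnings); errors block the run."""
    errors: List[str] = []
    warnings_: List[str] = []
    fixture = Path(config.fixture_dir)
    manifest = fixture / "manifest.json"
    if not fixture.is_dir():
        errors.append(f"fixture directory does not exist: {fixture}")
    elif not manifest.is_file():
        errors.append(f"missing manifest.json in {fixture}")
    else:
        listed = json.loads(manifest.read_text()).get("files", {})
        for name in listed:
            if not (fixture / name).is_file():
                errors.append(f"input file listed in manifest is missing: {name}")
    errors.extend(config.params.validate())
    if config.min_overlap < 1:
        errors.append("min_overlap must be >= 1")
    for field, published in PUBLISHED_DEFAULTS.items():
        value = getattr(config.params, field)
        if value != published:
            warnings_.append(
                f"{field}={value} deviates from the published value {published}")
    if config.k27_min_region_len != 500:
        warnings_.append(
            f"k27_min_region_len={config.k27_min_region_len} deviates from the "
            f"published > 500 bp rule")
    return errors, warnings_


def _body_mean(profile: MetageneProfile) -> float:
    s = profile.scheme
    body = profile.values[s.n_flank_bins:s.n_flank_bins + s.n_body_bins]
    return float(np.nanmean(body))


def _gene_frame(annotation: pd.DataFrame, ids: Set[str]) -> pd.DataFrame:
    return annotation[annotation["id"].isin(ids)]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage on a fixture bundle and write the report."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    errors, warnings_ = validate_config(config)
    if errors:
        raise ConfigError("; ".join(errors))
    for w in warnings_:
        logger.warning(w)

    t0 = time.time()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    params = config.params
    scheme = config.scheme

    logger.info("=== stage: load fixture (%s)", config.fixture_dir)
    bundle = read_fixture_bundle(config.fixture_dir)
    annotation = bundle.annotation
    gene_df = annotation[annotation["feature"] == "gene"]
    te_df = annotation[annotation["feature"] == "transposable_element"]
    chrom_lengths = {c: len(s) for c, s in bundle.genome.items()}

    logger.info("=== stage: normalize tracks")
    norm: Dict[Tuple[str, str], NormalizedTrack] = {
        key: log2_ratio_normalize(track, bundle.control)
        for key, track in bundle.tracks.items()
    }

    logger.info("=== stage: region calling")
    wt_k9_blocks = call_blocks(norm[("H3K9m2", "WT")], params)
    k27_bins = {g: bin_track(norm[("H3K27m3", g)], params.bin_size, params.step,
                             chrom_lengths) for g in ("WT", "met1")}
    wt_k27_regions = call_enriched_regions(k27_bins["WT"], params)

    met1_k9_hyper = call_differential_blocks(
        norm[("H3K9m2", "met1")], norm[("H3K9m2", "WT")], params,
        z_cutoff=params.z_cut_diff_met1)
    ibm1_k9_hyper = call_differential_blocks(
        norm[("H3K9m2", "ibm1")], norm[("H3K9m2", "WT")], params,
        z_cutoff=params.z_cut_diff_ibm1)
    met1_k27_hyper = call_differential_regions(
        k27_bins["met1"], k27_bins["WT"], params, "hyper",
        z_cutoff=params.z_cut_enriched, min_region_len=config.k27_min_region_len)
    met1_k27_hypo = call_differential_regions(
        k27_bins["met1"], k27_bins["WT"], params, "hypo",
        z_cutoff=params.z_cut_hypo)
    call_sets = {
        "wt_k9_blocks": wt_k9_blocks, "wt_k27_regions": wt_k27_regions,
        "met1_k9_hyper": met1_k9_hyper, "ibm1_k9_hyper": ibm1_k9_hyper,
        "met1_k27_hyper": met1_k27_hyper, "met1_k27_hypo": met1_k27_hypo,
    }
    for name, regions in call_sets.items():
        logger.info("  %-16s %5d regions", name, len(regions))
        regions_to_bed(regions, out_dir / f"regions_{name}.bed")

    fdr = {}
    if config.run_fdr:
        # the permuted object is the difference signal itself: permuting one
        # raw channel would leave the other channel's planted domains in the
        # difference and contaminate the null
        logger.info("=== stage: permutation FDR (%d rounds)", params.fdr_permutations)
        k9_diff = difference_track(norm[("H3K9m2", "met1")], norm[("H3K9m2", "WT")])
        k9_zero = k9_diff.with_values(
            {c: np.zeros(len(k9_diff.chroms[c])) for c in k9_diff.chrom_names})
        fdr["met1_k9_hyper"] = estimate_fdr(
            lambda diff, zero: call_differential_blocks(
                diff, zero, params, z_cutoff=params.z_cut_diff_met1),
            (k9_diff, k9_zero), params, seed=config.seed)
        k27_diff = difference_bins(k27_bins["met1"], k27_bins["WT"])
        k27_zero = BinTrack(
            {c: dataclasses.replace(cb, scores=np.zeros(len(cb.scores)))
             for c, cb in k27_diff.chroms.items()},
            k27_diff.bin_size, k27_diff.step)
        fdr["met1_k27_hyper"] = estimate_fdr(
            lambda diff, zero: call_differential_regions(
                diff, zero, params, "hyper", z_cutoff=params.z_cut_enriched,
                min_region_len=config.k27_min_region_len),
            (k27_diff, k27_zero), params, seed=config.seed + 1)

    logger.info("=== stage: gene assignment and classification")
    sets: Dict[str, Set[str]] = {
        "hyper_met1": overlap_genes(met1_k9_hyper, gene_df, config.min_overlap),
        "hyper_ibm1": overlap_genes(ibm1_k9_hyper, gene_df, config.min_overlap),
        "wt_k9": overlap_genes(wt_k9_blocks, gene_df, config.min_overlap),
        "wt_k27": overlap_genes(wt_k27_regions, gene_df, config.min_overlap),
        "te_gain_k27": overlap_genes(met1_k27_hyper, te_df, config.min_overlap),
        "te_k27_hypo_genes": overlap_genes(met1_k27_hypo, gene_df,
                                           config.min_overlap),
    }
    classification = classify_hyper_genes(sets["hyper_met1"], sets["wt_k9"],
                                          sets["wt_k27"])
    for name, ids in sets.items():
        pd.Series(sorted(ids)).to_csv(out_dir / f"genes_{name}.tsv",
                                      index=False, header=False)

    logger.info("=== stage: metagene profiles")
    class1_pred = _gene_frame(annotation, classification.class1)
    class2_pred = _gene_frame(annotation, classification.class2)
    profiles: Dict[str, MetageneProfile] = {}
    if len(class1_pred):
        for g in ("WT", "met1"):
            profiles[f"k9_class1_{g}"] = average_profile(
                metagene_matrix(norm[("H3K9m2", g)], class1_pred, scheme), scheme)
        profiles["k9_class1_ratio"] = ratio_profile(
            profiles["k9_class1_met1"], profiles["k9_class1_WT"])
    if len(class2_pred):
        for g in ("WT", "met1"):
            profiles[f"k9_class2_{g}"] = average_profile(
                metagene_matrix(norm[("H3K9m2", g)], class2_pred, scheme), scheme)
            profiles[f"k27_class2_{g}"] = average_profile(
                metagene_matrix(norm[("H3K27m3", g)], class2_pred, scheme), scheme)
        profiles["k27_class2_ratio"] = ratio_profile(
            profiles["k27_class2_met1"], profiles["k27_class2_WT"])
    hyper_genes_df = _gene_frame(annotation, sets["hyper_met1"])
    if len(hyper_genes_df):
        k27_wt_hyper = average_profile(
            metagene_matrix(norm[("H3K27m3", "WT")], hyper_genes_df, scheme), scheme)
        k27_wt_all = average_profile(
            metagene_matrix(norm[("H3K27m3", "WT")], gene_df, scheme), scheme)
        profiles["k27_enrichment_hyper_vs_all"] = ratio_profile(
            k27_wt_hyper, k27_wt_all)
        for context in ("CG", "CHG"):
            for g in ("WT", "met1"):
                profiles[f"meth_{context}_hyper_{g}"] = methylation_profile(
                    bundle.methylomes[g], hyper_genes_df, context, scheme,
                    smooth_window=5)
    if len(te_df):
        for g in ("WT", "met1"):
            profiles[f"k27_te_{g}"] = average_profile(
                metagene_matrix(norm[("H3K27m3", g)], te_df, scheme), scheme)
        profiles["k27_te_ratio"] = ratio_profile(
            profiles["k27_te_met1"], profiles["k27_te_WT"])
    if len(class1_pred):
        for g in ("WT", "met1"):
            profiles[f"smallrna_class1_{g}"] = read_density_profile(
                bundle.smallrna[g], class1_pred, scheme)
    for name, profile in profiles.items():
        profile_to_frame(profile).to_csv(out_dir / f"profile_{name}.tsv",
                                         sep="\t", index=False)

    logger.info("=== stage: expression and sequence statistics")
    expr = {g: compute_rpkm(bundle.expression[g], genotype=g)
            for g in ("WT", "met1")}
    silent_hyper_wt = (silent_fraction(expr["WT"], sets["hyper_met1"])
                       if sets["hyper_met1"] else float("nan"))
    te_gain_ids = sets["te_gain_k27"]
    te_stable_ids = set(te_df["id"]) - te_gain_ids
    te_compare = None
    if te_gain_ids and te_stable_ids:
        te_compare = group_expression_compare(expr["WT"], te_gain_ids,
                                              te_stable_ids, drop_zero=True)
    cpg_stats = None
    if te_gain_ids and te_stable_ids:
        dens = {}
        for name, ids in (("gain", te_gain_ids), ("stable", te_stable_ids)):
            rows = te_df[te_df["id"].isin(ids)]
            dens[name] = [cg_density(extract_sequence(
                bundle.genome, r["chrom"], r["start"], r["end"], r["strand"]))[1]
                for _, r in rows.iterrows()]
        _, p = wilcoxon_ranksum(dens["gain"], dens["stable"])
        cpg_stats = {
            "mean_cpg_gain": float(np.mean(dens["gain"])),
            "mean_cpg_stable": float(np.mean(dens["stable"])),
            "wilcoxon_p": p,
        }

    logger.info("=== stage: truth comparison")
    truth = bundle.truth
    recovery = {
        "k9_hyper_jaccard": interval_jaccard(
            met1_k9_hyper, truth.differential_intervals("H3K9m2", "met1", "hyper")),
        "k27_hyper_jaccard": interval_jaccard(
            met1_k27_hyper, truth.differential_intervals("H3K27m3", "met1", "hyper")),
        "classification_accuracy": classification_accuracy(
            {"class1": classification.class1, "class2": classification.class2},
            truth.labels),
    }

    report = {
        "config": config.to_dict(),
        "validation_warnings": warnings_,
        "region_counts": {k: len(v) for k, v in call_sets.items()},
        "gene_set_sizes": {k: len(v) for k, v in sets.items()},
        "classification": {
            "counts": classification.counts,
            "percentages": classification.percentages(),
            "class1": sorted(classification.class1),
            "class2": sorted(classification.class2),
            "dual": sorted(classification.dual),
        },
        "fdr": {k: {"observed": v.observed_count,
                    "expected_null": v.expected_null_count,
                    "fdr": v.fdr, "significant": v.significant,
                    "zero_observed": v.zero_observed}
                for k, v in fdr.items()},
        "profiles_body_mean": {k: _body_mean(p) for k, p in profiles.items()},
        "expression": {
            "silent_fraction_hyper_met1_wt": silent_hyper_wt,
            "library_size": {g: expr[g].library_size for g in expr},
            "te_gain_vs_stable_wt": None if te_compare is None else {
                "n_gain": te_compare.n_a, "n_stable": te_compare.n_b,
                "dropped_gain": te_compare.n_dropped_a,
                "dropped_stable": te_compare.n_dropped_b,
                "median_log2rpkm_gain": te_compare.summary_a.median,
                "median_log2rpkm_stable": te_compare.summary_b.median,
                "wilcoxon_p": te_compare.pvalue,
            },
        },
        "cpg": cpg_stats,
        "recovery": recovery,
        "runtime_s": round(time.time() - t0, 2),
    }
    # runtime is excluded from the canonical (byte-stable) report on disk
    stable = {k: v for k, v in report.items() if k != "runtime_s"}
    (out_dir / "report.json").write_text(json.dumps(stable, indent=1,
                                                    sort_keys=True))
    _write_markdown(stable, out_dir / "report.md")
    logger.info("pipeline finished in %.1f s", report["runtime_s"])
    return report


def _write_markdown(report: dict, path: Path) -> None:
    lines = ["# Chromatin-mark redistribution report", ""]
    lines.append("## Region counts")
    for k, v in sorted(report["region_counts"].items()):
        lines.append(f"- {k}: {v}")
    lines.append("")
    lines.append("## Gene sets")
    for k, v in sorted(report["gene_set_sizes"].items()):
        lines.append(f"- {k}: {v}")
    lines.append("")
    cls = report["classification"]
    lines.append("## Classification of mutant H3K9m2-hypermethylated genes")
    for k, v in sorted(cls["counts"].items()):
        lines.append(f"- {k}: {v}")
    for k, v in sorted(cls["percentages"].items()):
        lines.append(f"- {k} share: {v}%")
    lines.append("")
    lines.append("## Recovery vs planted truth")
    for k, v in sorted(report["recovery"].items()):
        lines.append(f"- {k}: {v:.4f}")
    path.write_text("\n".join(lines) + "\n")
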