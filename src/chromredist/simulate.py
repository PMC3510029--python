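"""Synthetic epigenome with planted chromatin-mark redistribution.

The generator emulates the structure of a two-mark (H3K9me2, H3K27me3),
three-genotype (wild type, met1, ibm1) tiling-array study of an
Arabidopsis-like genome:

* Class I genes carry weak H3K9me2 in wild type and gain full-strength
  H3K9me2 in met1;
* Class II genes are Polycomb targets: H3K27me3-marked in wild type, they
  lose H3K27me3 and gain H3K9me2 in met1;
* stable Polycomb targets keep H3K27me3 in both genotypes;
* a fraction of transposons loses H3K9me2 and gains H3K27me3 in met1
  (these are built with a high CpG-dinucleotide density, the proposed
  Polycomb recruiting signal), the rest keep their heterochromatic state;
* ibm1 gains H3K9me2 at a separate set of otherwise plain genes.

Probe signal is additive Gaussian on the log2-ratio scale; methylomes are
binomial per-cytosine call tables with sequence-derived CG/CHG/CHH
contexts; read counts follow a negative-binomial (Poisson-Gamma) tier
model.  Everything is deterministic for a fixed seed, and the planted
truth (labels, intervals, tiers) is returned for downstream scoring.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Dict, List, Set, Tuple

import numpy as np
import pandas as pd

from . import annotations as anno
from .tracks import ChromProbes, ProbeTrack, read_bedgraph, write_bedgraph

MARKS = ("H3K9m2", "H3K27m3")
GENOTYPES = ("WT", "met1", "ibm1")

GENE_LABELS = ("class1", "class2", "pcg_stable", "plain_gene")
TE_LABELS = ("te_gain_k27", "te_stable")


class PackingError(ValueError):
    """Elements plus flanks do not fit in the genome."""


@dataclasses.dataclass
class SyntheticSpec:
    """Study conditions of the synthetic epigenome (all lengths in bases)."""

    n_chromosomes: int = 3
    chromosome_length: int = 200_000
    probe_spacing: int = 100
    probe_length: int = 50
    n_genes: int = 120
    n_transposons: int = 40
    frac_pcg_genes: float = 0.25
    frac_class1_genes: float = 0.15
    frac_class2_converted: float = 0.60
    frac_te_gain_k27: float = 0.50
    frac_ibm1_hyper: float = 0.20
    frac_class2_paralog: float = 0.40
    frac_class1_tandem: float = 0.50
    enrichment_delta: float = 1.5
    class1_wt_factor: float = 0.5
    noise_sd: float = 0.30
    high_cpg_density: float = 0.20
    low_cpg_density: float = 0.02
    gene_length_range: Tuple[int, int] = (1000, 2500)
    te_length_range: Tuple[int, int] = (800, 2000)
    flank_min: int = 300
    gene_body_cg_rate: float = 0.70
    te_methylation_rate: float = 0.80
    chg_gain_rate: float = 0.60
    background_methylation_rate: float = 0.02
    methylation_coverage: int = 10
    expression_mean_silent: float = 0.0
    expression_mean_low: float = 5.0
    expression_mean_moderate: float = 100.0
    expression_dispersion: float = 0.2
    library_size: int = 1_000_000
    smallrna_reads_per_class1_wt: float = 20.0
    smallrna_met1_factor: float = 3.0
    smallrna_background_reads: int = 50
    seed: int = 0

    def validate(self) -> None:
        fracs = dict(frac_pcg_genes=self.frac_pcg_genes,
                     frac_class1_genes=self.frac_class1_genes,
                     frac_class2_converted=self.frac_class2_converted,
                     frac_te_gain_k27=self.frac_te_gain_k27,
                     frac_ibm1_hyper=self.frac_ibm1_hyper,
                     frac_class2_paralog=self.frac_class2_paralog,
                     frac_class1_tandem=self.frac_class1_tandem,
                     high_cpg_density=self.high_cpg_density,
                     low_cpg_density=self.low_cpg_density)
        for name, value in fracs.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0,1], got {value}")
        if self.probe_spacing < 1:
            raise ValueError("probe_spacing must be >= 1")
        if self.probe_length > self.probe_spacing:
            raise ValueError("probes must not overlap: probe_length <= probe_spacing")
        if self.frac_pcg_genes + self.frac_class1_genes > 1.0:
            raise ValueError("frac_pcg_genes + frac_class1_genes must be <= 1")
        for lo, hi in (self.gene_length_range, self.te_length_range):
            if not 0 < lo <= hi:
                raise ValueError("length ranges must satisfy 0 < lo <= hi")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclasses.dataclass(frozen=True)
class PlantedInterval:
    chrom: str
    start: int
    end: int
    element_id: str
    lift: float


@dataclasses.dataclass
class SyntheticTruth:
    """Ground truth the generator plants: class labels, per-genotype planted
    mark intervals, CpG densities, expression tiers."""

    labels: Dict[str, str]
    planted: Dict[str, List[PlantedInterval]]  # key "<mark>|<genotype>"
    cpg_density: Dict[str, float]
    expression_tier: Dict[str, Dict[str, str]]  # id -> genotype -> tier
    ibm1_hyper_ids: Set[str]
    paralog_pairs: List[Tuple[str, str]]

    def label_ids(self, *wanted: str) -> Set[str]:
        return {i for i, lab in self.labels.items() if lab in wanted}

    def planted_for(self, mark: str, genotype: str) -> List[PlantedInterval]:
        return self.planted.get(f"{mark}|{genotype}", [])

    def differential_intervals(self, mark: str, mutant: str = "met1",
                               direction: str = "hyper"
                               ) -> List[PlantedInterval]:
        """Element intervals whose planted lift changes mutant vs wild type."""
        wt = {p.element_id: p for p in self.planted_for(mark, "WT")}
        mut = {p.element_id: p for p in self.planted_for(mark, mutant)}
        out = []
        for eid in set(wt) | set(mut):
            lift_wt = wt[eid].lift if eid in wt else 0.0
            lift_mut = mut[eid].lift if eid in mut else 0.0
            delta = lift_mut - lift_wt
            ref = mut.get(eid, wt.get(eid))
            if direction == "hyper" and delta > 0:
                out.append(dataclasses.replace(ref, lift=delta))
            elif direction == "hypo" and delta < 0:
                out.append(dataclasses.replace(ref, lift=delta))
        return sorted(out, key=lambda p: (p.chrom, p.start))


@dataclasses.dataclass
class SyntheticBundle:
    spec: SyntheticSpec
    annotation: pd.DataFrame
    repeats: pd.DataFrame
    genome: Dict[str, str]
    truth: SyntheticTruth
    tracks: Dict[Tuple[str, str], ProbeTrack]  # (mark, genotype) -> chip track
    control: ProbeTrack
    methylomes: Dict[str, pd.DataFrame]        # genotype -> call table
    expression: Dict[str, pd.DataFrame]        # genotype -> (id,length,count)
    smallrna: Dict[str, pd.DataFrame]          # genotype -> read intervals


def _chrom_name(i: int) -> str:
    return f"chr{i + 1}"


def _random_seq(rng: np.random.Generator, length: int) -> str:
    # mildly AT-rich background, as in plant euchromatin
    bases = rng.choice(list("ACGT"), size=length, p=[0.3, 0.2, 0.2, 0.3])
    return "".join(bases)


def _cpg_seq(rng: np.random.Generator, length: int, cpg_rate: float) -> str:
    """Sequence whose CpG-dinucleotide rate tracks ``cpg_rate``."""
    out: List[str] = []
    while len(out) < length:
        if len(out) + 2 <= length and rng.random() < cpg_rate:
            out.extend("CG")
        else:
            out.append(str(rng.choice(list("ACGT"), p=[0.3, 0.2, 0.2, 0.3])))
    return "".join(out[:length])


def _counts_from_fracs(n: int, fracs: Dict[str, float]) -> Dict[str, int]:
    counts = {k: int(round(v * n)) for k, v in fracs.items()}
    return counts


def generate_annotation(spec: SyntheticSpec
                        ) -> Tuple[pd.DataFrame, pd.DataFrame,
                                   Dict[str, str], SyntheticTruth]:
    """Lay out non-overlapping genes/TEs, emit sequence, assign labels.

    Returns (annotation, repeats, genome, truth).  Raises
    :class:`PackingError` when the element footprint plus minimum flanks
    exceeds the genome.
    """
    spec.validate()
    rng = np.random.default_rng([spec.seed, 0])

    n_pcg = int(round(spec.frac_pcg_genes * spec.n_genes))
    n_class2 = int(round(spec.frac_class2_converted * n_pcg))
    n_pcg_stable = n_pcg - n_class2
    n_class1 = int(round(spec.frac_class1_genes * spec.n_genes))
    n_plain = spec.n_genes - n_pcg - n_class1
    if n_plain < 0:
        raise ValueError("class fractions exceed the gene count")
    n_te_gain = int(round(spec.frac_te_gain_k27 * spec.n_transposons))

    gene_labels = (["class2"] * n_class2 + ["pcg_stable"] * n_pcg_stable
                   + ["class1"] * n_class1 + ["plain_gene"] * n_plain)
    te_labels = (["te_gain_k27"] * n_te_gain
                 + ["te_stable"] * (spec.n_transposons - n_te_gain))
    rng.shuffle(gene_labels)
    rng.shuffle(te_labels)

    elements = []
    for i, label in enumerate(gene_labels):
        length = int(rng.integers(spec.gene_length_range[0],
                                  spec.gene_length_range[1] + 1))
        elements.append({"id": f"gene{i + 1:04d}", "feature": "gene",
                         "label": label, "length": length})
    for i, label in enumerate(te_labels):
        length = int(rng.integers(spec.te_length_range[0],
                                  spec.te_length_range[1] + 1))
        elements.append({"id": f"te{i + 1:04d}", "feature": "transposable_element",
                         "label": label, "length": length})
    order = rng.permutation(len(elements))
    elements = [elements[i] for i in order]

    # greedy balance of total element length across chromosomes
    chrom_elems: List[List[dict]] = [[] for _ in range(spec.n_chromosomes)]
    chrom_load = np.zeros(spec.n_chromosomes)
    for el in elements:
        c = int(np.argmin(chrom_load))
        chrom_elems[c].append(el)
        chrom_load[c] += el["length"]

    rows = []
    genome: Dict[str, str] = {}
    for ci in range(spec.n_chromosomes):
        chrom = _chrom_name(ci)
        els = chrom_elems[ci]
        total = sum(e["length"] for e in els)
        needed = total + (len(els) + 1) * spec.flank_min
        if needed > spec.chromosome_length:
            raise PackingError(
                f"{chrom}: {len(els)} elements spanning {total} bp plus "
                f"{len(els) + 1} flanks of {spec.flank_min} bp need {needed} bp "
                f"but chromosome_length is {spec.chromosome_length}")
        slack = spec.chromosome_length - needed
        extras = rng.multinomial(slack, np.full(len(els) + 1, 1.0 / (len(els) + 1))) \
            if len(els) >= 0 else []
        seq = list(_random_seq(rng, spec.chromosome_length))
        pos = 0
        for gi, el in enumerate(els):
            pos += spec.flank_min + int(extras[gi])
            start, end = pos, pos + el["length"]
            strand = str(rng.choice(["+", "-"]))
            rows.append({"id": el["id"], "chrom": chrom, "start": start,
                         "end": end, "strand": strand, "feature": el["feature"],
                         "label": el["label"]})
            if el["feature"] == "transposable_element":
                rate = (spec.high_cpg_density if el["label"] == "te_gain_k27"
                        else spec.low_cpg_density)
                seq[start:end] = _cpg_seq(rng, el["length"], rate)
            pos = end
        genome[chrom] = "".join(seq)

    frame = pd.DataFrame(rows)
    labels = dict(zip(frame["id"], frame["label"]))

    # paralog pairs among Class II genes: shared, lightly mutated 300 bp core
    repeats_rows = []
    class2_ids = sorted(frame.loc[frame["label"] == "class2", "id"])
    n_pairs = int(round(spec.frac_class2_paralog * len(class2_ids) / 2))
    paralog_pairs: List[Tuple[str, str]] = []
    flagged_dispersed: Set[str] = set()
    core_len, core_off = 300, 100
    for k in range(n_pairs):
        a, b = class2_ids[2 * k], class2_ids[2 * k + 1]
        ra = frame.loc[frame["id"] == a].iloc[0]
        rb = frame.loc[frame["id"] == b].iloc[0]
        core = genome[ra["chrom"]][ra["start"] + core_off:ra["start"] + core_off + core_len]
        mutated = list(core)
        n_mut = int(0.2 * core_len)
        sites = rng.choice(core_len, size=n_mut, replace=False)
        for s in sites:
            mutated[s] = str(rng.choice([c for c in "ACGT" if c != mutated[s]]))
        gb = genome[rb["chrom"]]
        genome[rb["chrom"]] = (gb[:rb["start"] + core_off] + "".join(mutated)
                               + gb[rb["start"] + core_off + core_len:])
        paralog_pairs.append((a, b))
        flagged_dispersed.update((a, b))
        for r in (ra, rb):
            repeats_rows.append({"chrom": r["chrom"],
                                 "start": int(r["start"]) + core_off,
                                 "end": int(r["start"]) + core_off + core_len,
                                 "name": f"dispersed_{a}_{b}", "kind": "dispersed"})

    # tandem repeats inside a fraction of Class I genes
    class1_ids = sorted(frame.loc[frame["label"] == "class1", "id"])
    n_tandem = int(round(spec.frac_class1_tandem * len(class1_ids)))
    flagged_tandem: Set[str] = set(class1_ids[:n_tandem])
    for gid in sorted(flagged_tandem):
        r = frame.loc[frame["id"] == gid].iloc[0]
        unit = _random_seq(rng, 60)
        g = genome[r["chrom"]]
        s0 = int(r["start"]) + 200
        genome[r["chrom"]] = g[:s0] + unit * 2 + g[s0 + 120:]
        repeats_rows.append({"chrom": r["chrom"], "start": s0, "end": s0 + 120,
                             "name": f"tandem_{gid}", "kind": "tandem"})

    plain_ids = sorted(frame.loc[frame["label"] == "plain_gene", "id"])
    n_ibm1 = int(round(spec.frac_ibm1_hyper * len(plain_ids)))
    ibm1_hyper = set(rng.choice(plain_ids, size=n_ibm1, replace=False)) \
        if n_ibm1 else set()

    annotation = anno.make_annotation(
        {**{k: row[k] for k in ("id", "chrom", "start", "end", "strand", "feature")},
         "contains_dispersed_repeat": row["id"] in flagged_dispersed,
         "contains_tandem_repeat": row["id"] in flagged_tandem,
         "contains_te": False}
        for _, row in frame.iterrows())
    repeats = pd.DataFrame(repeats_rows,
                           columns=["chrom", "start", "end", "name", "kind"])

    truth = SyntheticTruth(
        labels=labels,
        planted=_plant_marks(annotation, labels, ibm1_hyper, spec),
        cpg_density={eid: (spec.high_cpg_density if labels[eid] == "te_gain_k27"
                           else spec.low_cpg_density)
                     for eid in labels if labels[eid] in TE_LABELS},
        expression_tier=_expression_tiers(labels, ibm1_hyper),
        ibm1_hyper_ids=ibm1_hyper,
        paralog_pairs=paralog_pairs,
    )
    return annotation, repeats, genome, truth


def _plant_marks(annotation: pd.DataFrame, labels: Dict[str, str],
                 ibm1_hyper: Set[str], spec: SyntheticSpec
                 ) -> Dict[str, List[PlantedInterval]]:
    """Planted mark intervals per (mark, genotype); the interval is the
    element's own span and the lift is in log2-ratio units."""
    d = spec.enrichment_delta
    half = spec.class1_wt_factor * d
    lift_rules = {
        ("H3K9m2", "WT"): {"class1": half, "te_gain_k27": d, "te_stable": d},
        ("H3K9m2", "met1"): {"class1": d, "class2": d, "te_stable": d},
        ("H3K9m2", "ibm1"): {"class1": half, "te_gain_k27": d, "te_stable": d},
        ("H3K27m3", "WT"): {"class2": d, "pcg_stable": d},
        ("H3K27m3", "met1"): {"pcg_stable": d, "te_gain_k27": d},
        ("H3K27m3", "ibm1"): {"class2": d, "pcg_stable": d},
    }
    planted: Dict[str, List[PlantedInterval]] = {}
    for (mark, genotype), rules in lift_rules.items():
        intervals = []
        for _, row in annotation.iterrows():
            lift = rules.get(labels[row["id"]], 0.0)
            if genotype == "ibm1" and mark == "H3K9m2" and row["id"] in ibm1_hyper:
                lift = d
            if lift != 0.0:
                intervals.append(PlantedInterval(row["chrom"], int(row["start"]),
                                                 int(row["end"]), row["id"], lift))
        planted[f"{mark}|{genotype}"] = intervals
    return planted


def _expression_tiers(labels: Dict[str, str], ibm1_hyper: Set[str]
                      ) -> Dict[str, Dict[str, str]]:
    tiers = {}
    for eid, label in labels.items():
        if label == "plain_gene":
            t = {"WT": "moderate", "met1": "moderate"}
        elif label == "class1":
            t = {"WT": "low", "met1": "low"}
        elif label in ("class2", "pcg_stable"):
            t = {"WT": "silent", "met1": "silent"}
        elif label == "te_gain_k27":
            t = {"WT": "low", "met1": "moderate"}  # reactivated despite H3K27m3
        else:  # te_stable: half silent/half moderate in WT, reactivated in met1
            t = {"WT": "silent" if int(eid[2:]) % 2 else "moderate",
                 "met1": "moderate"}
        tiers[eid] = t
    return tiers


def probe_grid(spec: SyntheticSpec) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
    starts = np.arange(0, spec.chromosome_length - spec.probe_length + 1,
                       spec.probe_spacing, dtype=np.int64)
    return {_chrom_name(i): (starts.copy(), starts + spec.probe_length)
            for i in range(spec.n_chromosomes)}


def simulate_probe_tracks(annotation: pd.DataFrame, truth: SyntheticTruth,
                          spec: SyntheticSpec
                          ) -> Tuple[Dict[Tuple[str, str], ProbeTrack], ProbeTrack]:
    """Gaussian log2-ratio probe tracks per mark x genotype, plus a zero
    control channel.  A probe picks up every planted lift whose interval
    contains its midpoint."""
    grid = probe_grid(spec)
    tracks: Dict[Tuple[str, str], ProbeTrack] = {}
    for ti, (mark, genotype) in enumerate(
            (m, g) for m in MARKS for g in GENOTYPES):
        rng = np.random.default_rng([spec.seed, 1, ti])
        chroms = {}
        for chrom, (starts, ends) in grid.items():
            mids = (starts + ends) / 2.0
            values = (rng.normal(0.0, spec.noise_sd, len(starts))
                      if spec.noise_sd > 0 else np.zeros(len(starts)))
            for p in truth.planted_for(mark, genotype):
                if p.chrom != chrom:
                    continue
                lo = np.searchsorted(mids, p.start, side="left")
                hi = np.searchsorted(mids, p.end, side="left")
                values[lo:hi] += p.lift
            chroms[chrom] = ChromProbes(starts.copy(), ends.copy(), values)
        tracks[(mark, genotype)] = ProbeTrack(chroms, mark=mark, genotype=genotype,
                                              channel="chip", already_log=True)
    control = ProbeTrack(
        {c: ChromProbes(s.copy(), e.copy(), np.zeros(len(s)))
         for c, (s, e) in grid.items()},
        mark="", genotype="", channel="control", already_log=True)
    return tracks, control


# ---------------------------------------------------------------------------
# Methylome
# ---------------------------------------------------------------------------

def _cytosine_sites(seq: str, chrom: str) -> pd.DataFrame:
    """All cytosines on both strands with CG/CHG/CHH context (1-based pos)."""
    arr = np.frombuffer(seq.encode(), dtype="S1")
    out = []
    # plus strand: C at i; context from i+1, i+2
    idx = np.nonzero(arr == b"C")[0]
    nxt1 = np.full(len(idx), b"N", dtype="S1")
    nxt2 = np.full(len(idx), b"N", dtype="S1")
    ok1 = idx + 1 < len(arr)
    ok2 = idx + 2 < len(arr)
    nxt1[ok1] = arr[idx[ok1] + 1]
    nxt2[ok2] = arr[idx[ok2] + 2]
    ctx = np.where(nxt1 == b"G", "CG", np.where(nxt2 == b"G", "CHG", "CHH"))
    out.append(pd.DataFrame({"chrom": chrom, "pos": idx + 1, "strand": "+",
                             "context": ctx}))
    # minus strand: G at i is a C on the reverse strand; context from i-1, i-2
    idx = np.nonzero(arr == b"G")[0]
    prv1 = np.full(len(idx), b"N", dtype="S1")
    prv2 = np.full(len(idx), b"N", dtype="S1")
    ok1 = idx - 1 >= 0
    ok2 = idx - 2 >= 0
    prv1[ok1] = arr[idx[ok1] - 1]
    prv2[ok2] = arr[idx[ok2] - 2]
    ctx = np.where(prv1 == b"C", "CG", np.where(prv2 == b"C", "CHG", "CHH"))
    out.append(pd.DataFrame({"chrom": chrom, "pos": idx + 1, "strand": "-",
                             "context": ctx}))
    return pd.concat(out).sort_values("pos", kind="stable").reset_index(drop=True)


def _element_lookup(annotation: pd.DataFrame, chrom: str):
    sub = annotation[annotation["chrom"] == chrom].sort_values("start")
    return (sub["start"].to_numpy(), sub["end"].to_numpy(),
            sub["id"].to_numpy(), sub["feature"].to_numpy())


def simulate_methylome(annotation: pd.DataFrame, truth: SyntheticTruth,
                       genome: Dict[str, str], spec: SyntheticSpec
                       ) -> Dict[str, pd.DataFrame]:
    """Binomial per-cytosine call tables for WT and met1.

    WT: gene-body CG methylation, all-context methylation at TEs; met1: CG
    methylation lost genome-wide, CHG elevated in Class I/II gene bodies.
    """
    tables: Dict[str, pd.DataFrame] = {}
    for gi, genotype in enumerate(("WT", "met1")):
        rng = np.random.default_rng([spec.seed, 2, gi])
        frames = []
        for chrom in sorted(genome):
            sites = _cytosine_sites(genome[chrom], chrom)
            starts, ends, ids, features = _element_lookup(annotation, chrom)
            pos0 = sites["pos"].to_numpy() - 1
            if len(starts):
                # elements are non-overlapping and sorted: one searchsorted
                ei = np.searchsorted(starts, pos0, side="right") - 1
                valid = (ei >= 0) & (pos0 < ends[np.maximum(ei, 0)])
                labels = np.array([truth.labels.get(i, "") for i in ids])
                in_te = valid & (features[np.maximum(ei, 0)] == "transposable_element")
                in_gene = valid & (features[np.maximum(ei, 0)] == "gene")
                lab = np.where(valid, labels[np.maximum(ei, 0)], "")
            else:
                in_te = in_gene = np.zeros(len(sites), dtype=bool)
                lab = np.full(len(sites), "")
            ctx = sites["context"].to_numpy()
            rate = np.full(len(sites), spec.background_methylation_rate)
            if genotype == "WT":
                rate[in_gene & (ctx == "CG")] = spec.gene_body_cg_rate
                rate[in_te] = spec.te_methylation_rate
            else:  # met1
                rate[in_te] = spec.te_methylation_rate
                hyper = in_gene & np.isin(lab, ["class1", "class2"]) & (ctx == "CHG")
                rate[hyper] = spec.chg_gain_rate
                rate[ctx == "CG"] = 0.0  # CG maintenance lost
            total = np.full(len(sites), spec.methylation_coverage)
            m = rng.binomial(total, rate)
            frame = sites.copy()
            frame["m_count"] = m
            frame["t_count"] = total
            frames.append(frame)
        tables[genotype] = pd.concat(frames, ignore_index=True)
    return tables


# ---------------------------------------------------------------------------
# Read counts
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float,
             size: int) -> np.ndarray:
    if mean <= 0:
        return np.zeros(size, dtype=np.int64)
    if dispersion <= 0:
        return rng.poisson(mean, size)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p, size)


def simulate_read_counts(annotation: pd.DataFrame, truth: SyntheticTruth,
                         spec: SyntheticSpec
                         ) -> Tuple[Dict[str, pd.DataFrame], Dict[str, pd.DataFrame]]:
    """mRNA count tables per genotype plus small-RNA read intervals.

    Counts follow the planted tier (silent / low / moderate) with a
    negative-binomial model; non-silent tiers are floored at one read so
    the planted silent set is exactly the zero-count set.  Small RNAs
    concentrate on Class I genes and increase in met1.
    """
    tier_means = {"silent": spec.expression_mean_silent,
                  "low": spec.expression_mean_low,
                  "moderate": spec.expression_mean_moderate}
    expression: Dict[str, pd.DataFrame] = {}
    for gi, genotype in enumerate(("WT", "met1")):
        rng = np.random.default_rng([spec.seed, 3, gi])
        rows = []
        for _, row in annotation.iterrows():
            tier = truth.expression_tier[row["id"]][genotype]
            mean = tier_means[tier]
            count = int(_nb_draw(rng, mean, spec.expression_dispersion, 1)[0])
            if mean > 0:
                count = max(count, 1)  # expressed tiers stay detectable
            rows.append({"id": row["id"], "length": int(row["end"] - row["start"]),
                         "count": count})
        expression[genotype] = pd.DataFrame(rows)

    smallrna: Dict[str, pd.DataFrame] = {}
    read_len = 24
    class1 = truth.label_ids("class1")
    for gi, genotype in enumerate(("WT", "met1")):
        rng = np.random.default_rng([spec.seed, 4, gi])
        rows = []
        mean = spec.smallrna_reads_per_class1_wt * (
            spec.smallrna_met1_factor if genotype == "met1" else 1.0)
        for _, row in annotation.iterrows():
            if row["id"] not in class1:
                continue
            n = int(rng.poisson(mean))
            if n == 0:
                continue
            starts = rng.integers(row["start"], max(row["end"] - read_len,
                                                    row["start"] + 1), size=n)
            for s in starts:
                rows.append({"chrom": row["chrom"], "start": int(s),
                             "end": int(s) + read_len})
        for _ in range(spec.smallrna_background_reads):
            ci = int(rng.integers(0, spec.n_chromosomes))
            s = int(rng.integers(0, spec.chromosome_length - read_len))
            rows.append({"chrom": _chrom_name(ci), "start": s, "end": s + read_len})
        smallrna[genotype] = pd.DataFrame(rows, columns=["chrom", "start", "end"]) \
            .sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    return expression, smallrna


def generate_bundle(spec: SyntheticSpec) -> SyntheticBundle:
    """Run every generator stage for one spec."""
    annotation, repeats, genome, truth = generate_annotation(spec)
    tracks, control = simulate_probe_tracks(annotation, truth, spec)
    methylomes = simulate_methylome(annotation, truth, genome, spec)
    expression, smallrna = simulate_read_counts(annotation, truth, spec)
    return SyntheticBundle(spec, annotation, repeats, genome, truth, tracks,
                           control, methylomes, expression, smallrna)


# ---------------------------------------------------------------------------
# Fixture bundle on disk
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_fixture_bundle(bundle: SyntheticBundle, directory: str | Path
                         ) -> Dict[str, str]:
    """Write the full fixture (FASTA/GFF3/BED/bedGraph/TSV/JSON) and return
    the manifest mapping file name to SHA-256 checksum."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    records = [SeqRecord(Seq(seq), id=chrom, description="")
               for chrom, seq in sorted(bundle.genome.items())]
    SeqIO.write(records, directory / "genome.fa", "fasta")
    anno.write_gff3(bundle.annotation, directory / "annotation.gff3")
    anno.write_bed(bundle.repeats.assign(score=0, strand="."),
                   directory / "repeats.bed")
    for (mark, genotype), track in sorted(bundle.tracks.items()):
        write_bedgraph(track, directory / f"track_{mark}_{genotype}.bedGraph")
    write_bedgraph(bundle.control, directory / "track_control.bedGraph")
    for genotype, table in sorted(bundle.methylomes.items()):
        anno.write_methylation_tsv(table, directory / f"methylation_{genotype}.tsv")
    for genotype, table in sorted(bundle.expression.items()):
        anno.write_counts_tsv(table, directory / f"expression_{genotype}.tsv")
    for genotype, table in sorted(bundle.smallrna.items()):
        table.to_csv(directory / f"smallrna_{genotype}.tsv", sep="\t", index=False)
    for key, intervals in sorted(bundle.truth.planted.items()):
        mark, genotype = key.split("|")
        frame = pd.DataFrame([{"chrom": p.chrom, "start": p.start, "end": p.end,
                               "name": p.element_id, "score": p.lift,
                               "strand": "."} for p in intervals])
        if frame.empty:
            frame = pd.DataFrame(columns=["chrom", "start", "end", "name",
                                          "score", "strand"])
        anno.write_bed(frame, directory / f"planted_{mark}_{genotype}.bed")

    truth_json = {
        "labels": bundle.truth.labels,
        "planted": {k: [dataclasses.asdict(p) for p in v]
                    for k, v in bundle.truth.planted.items()},
        "cpg_density": bundle.truth.cpg_density,
        "expression_tier": bundle.truth.expression_tier,
        "ibm1_hyper_ids": sorted(bundle.truth.ibm1_hyper_ids),
        "paralog_pairs": bundle.truth.paralog_pairs,
    }
    (directory / "truth.json").write_text(
        json.dumps(truth_json, indent=1, sort_keys=True))

    files = sorted(p.name for p in directory.iterdir()
                   if p.name != "manifest.json")
    manifest = {
        "seed": bundle.spec.seed,
        "spec": dataclasses.asdict(bundle.spec),
        "files": {name: _sha256(directory / name) for name in files},
    }
    (directory / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True))
    return manifest["files"]


def read_fixture_bundle(directory: str | Path) -> SyntheticBundle:
    """Load a written fixture bundle back into memory."""
    from Bio import SeqIO

    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    spec_dict = manifest["spec"]
    for key in ("gene_length_range", "te_length_range"):
        spec_dict[key] = tuple(spec_dict[key])
    spec = SyntheticSpec(**spec_dict)

    genome = {rec.id: str(rec.seq)
              for rec in SeqIO.parse(directory / "genome.fa", "fasta")}
    annotation = anno.read_gff3(directory / "annotation.gff3")
    repeats = anno.read_bed(directory / "repeats.bed")
    if "name" in repeats.columns and len(repeats):
        repeats["kind"] = repeats["name"].str.split("_").str[0]
    tracks = {}
    for mark in MARKS:
        for genotype in GENOTYPES:
            path = directory / f"track_{mark}_{genotype}.bedGraph"
            tracks[(mark, genotype)] = read_bedgraph(
                path, mark=mark, genotype=genotype, channel="chip",
                already_log=True)
    control = read_bedgraph(directory / "track_control.bedGraph",
                            channel="control", already_log=True)
    methylomes = {g: anno.read_methylation_tsv(directory / f"methylation_{g}.tsv")
                  for g in ("WT", "met1")}
    expression = {g: anno.read_counts_tsv(directory / f"expression_{g}.tsv")
                  for g in ("WT", "met1")}
    smallrna = {g: pd.read_csv(directory / f"smallrna_{g}.tsv", sep="\t")
                for g in ("WT", "met1")}

    tj = json.loads((directory / "truth.json").read_text())
    truth = SyntheticTruth(
        labels=tj["labels"],
        planted={k: [PlantedInterval(**p) for p in v]
                 for k, v in tj["planted"].items()},
        cpg_density=tj["cpg_density"],
        expression_tier=tj["expression_tier"],
        ibm1_hyper_ids=set(tj["ibm1_hyper_ids"]),
        paralog_pairs=[tuple(p) for p in tj["paralog_pairs"]],
    )
    return SyntheticBundle(spec, annotation, repeats, genome, truth, tracks,
                           control, methylomes, expression, smallrna)
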