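"""Gene-level assignment of called regions and Class I / Class II labels.

A gene counts as overlapping a region set when its total overlap with the
union of regions reaches ``min_overlap`` bases (150 bp by default, roughly
one nucleosome of DNA).  Genes hypermethylated for H3K9me2 in the mutant
are classified by their wild-type state: Class I genes were already weakly
H3K9me2-marked in wild type; Class II genes are Polycomb targets that carry
H3K27me3 in wild type and trade it for H3K9me2 in the mutant.
"""

from __future__ import annotations

import dataclasses
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, Iterable, Sequence, Set, Tuple

import pandas as pd

from .regions import Region, merge_intervals


def overlap_genes(regions: Sequence[Region], genes: pd.DataFrame,
                  min_overlap: int = 150, mode: str = "union") -> Set[str]:
    """IDs of genes overlapping the region set by >= ``min_overlap`` bases.

    ``mode='union'`` (default) sums a gene's overlap with the union of all
    regions, so several short overlaps can jointly reach the threshold;
    ``mode='single'`` requires a single region to provide the full overlap.
    """
    if mode not in ("union", "single"):
        raise ValueError(f"unknown overlap mode {mode!r}")
    by_chrom: Dict[str, list] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
    if mode == "union":
        by_chrom = {c: merge_intervals(iv) for c, iv in by_chrom.items()}
    hits: Set[str] = set()
    for _, g in genes.iterrows():
        spans = by_chrom.get(g["chrom"], [])
        overlaps = [min(g["end"], e) - max(g["start"], s)
                    for s, e in spans if min(g["end"], e) > max(g["start"], s)]
        if not overlaps:
            continue
        if mode == "union":
            if sum(overlaps) >= min_overlap:
                hits.add(g["id"])
        elif max(overlaps) >= min_overlap:
            hits.add(g["id"])
    return hits


@dataclasses.dataclass
class ClassificationResult:
    hyper: Set[str]
    class1: Set[str]
    class2: Set[str]
    dual: Set[str]          # hyper genes carrying both WT marks
    unclassified: Set[str]

    @property
    def counts(self) -> Dict[str, int]:
        return {
            "hyper": len(self.hyper), "class1": len(self.class1),
            "class2": len(self.class2), "dual": len(self.dual),
            "unclassified": len(self.unclassified),
        }

    def percentages(self, decimals: int = 1) -> Dict[str, float]:
        if not self.hyper:
            return {"class1": 0.0, "class2": 0.0}
        return {
            "class1": percentage(len(self.class1), len(self.hyper), decimals),
            "class2": percentage(len(self.class2), len(self.hyper), decimals),
        }


def classify_hyper_genes(hyper: Iterable[str], wt_k9: Iterable[str],
                         wt_k27: Iterable[str]) -> ClassificationResult:
    """Split mutant-hypermethylated genes by wild-type mark state.

    Genes carrying both wild-type marks are reported under both classes and
    tallied separately as ``dual``; the remainder is ``unclassified``.
    """
    hyper, wt_k9, wt_k27 = set(hyper), set(wt_k9), set(wt_k27)
    class1 = hyper & wt_k9
    class2 = hyper & wt_k27
    dual = class1 & class2
    return ClassificationResult(
        hyper=hyper, class1=class1, class2=class2, dual=dual,
        unclassified=hyper - class1 - class2)


def set_overlap(a: Iterable[str], b: Iterable[str]) -> Tuple[int, int, int]:
    a, b = set(a), set(b)
    return len(a), len(b), len(a & b)


def percentage(part: int, whole: int, decimals: int = 1) -> float:
    """100*part/whole, rounded half-up to ``decimals`` places."""
    if whole <= 0:
        raise ValueError("whole must be > 0")
    if not 0 <= part <= whole:
        raise ValueError("part must lie in [0, whole]")
    q = (Decimal(part) * 100) / Decimal(whole)
    return float(q.quantize(Decimal(1).scaleb(-decimals), rounding=ROUND_HALF_UP))


def repeat_content_fraction(gene_ids: Iterable[str], annotation: pd.DataFrame,
                            flag: str = "contains_dispersed_repeat",
                            exclude: Iterable[str] | None = None) -> float:
    """Fraction of the gene set whose annotation row carries ``flag``.

    ``exclude`` restricts the numerator to flagged genes *not* in the given
    set (e.g. flagged genes without a wild-type H3K9me2 region).
    """
    ids = set(gene_ids)
    if not ids:
        raise ValueError("empty gene set")
    if flag not in annotation.columns:
        raise KeyError(f"unknown flag column {flag!r}")
    sub = annotation[annotation["id"].isin(ids)]
    flagged = set(sub.loc[sub[flag].astype(bool), "id"])
    if exclude is not None:
        flagged -= set(exclude)
    return len(flagged) / len(ids)


def flag_elements_by_overlap(annotation: pd.DataFrame, intervals: pd.DataFrame,
                             flag: str) -> pd.DataFrame:
    """Set ``flag`` on elements overlapping any interval by >= 1 bp."""
    out = annotation.copy()
    for i, row in out.iterrows():
        sub = intervals[(intervals["chrom"] == row["chrom"])
                        & (intervals["start"] < row["end"])
                        & (intervals["end"] > row["start"])]
        if len(sub):
            out.at[i, flag] = True
    return out
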