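"""RPKM expression tables, silent fractions, and genotype comparisons.

RPKM = count / (length/1000) / (library_size/1e6).  Group comparisons of
log2 RPKM drop zero-RPKM elements first (boxplot convention of the source
analyses) and use the two-tailed Wilcoxon rank-sum test.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, Iterable, Set, Tuple

import numpy as np
import pandas as pd

from .seqstats import BoxplotSummary, boxplot_summary, wilcoxon_ranksum


@dataclasses.dataclass
class ExpressionTable:
    """Per-element counts and RPKM for one genotype."""

    table: pd.DataFrame  # columns: id, length, count, rpkm
    library_size: int
    genotype: str = ""

    def rpkm(self, element_id: str) -> float:
        row = self.table.loc[self.table["id"] == element_id]
        if row.empty:
            raise KeyError(f"unknown element {element_id!r}")
        return float(row["rpkm"].iloc[0])

    def count(self, element_id: str) -> int:
        row = self.table.loc[self.table["id"] == element_id]
        if row.empty:
            raise KeyError(f"unknown element {element_id!r}")
        return int(row["count"].iloc[0])


def compute_rpkm(counts: pd.DataFrame, library_size: int | None = None,
                 genotype: str = "") -> ExpressionTable:
    """Build an :class:`ExpressionTable` from an (id, length, count) frame.

    ``library_size`` defaults to the summed counts (all reads assigned).
    """
    df = counts[["id", "length", "count"]].copy()
    if (df["length"] <= 0).any():
        raise ValueError("all element lengths must be > 0")
    if library_size is None:
        library_size = int(df["count"].sum())
    if library_size <= 0:
        raise ValueError("library_size must be > 0")
    df["rpkm"] = df["count"] / (df["length"] / 1000.0) / (library_size / 1e6)
    return ExpressionTable(df.reset_index(drop=True), library_size, genotype)


def silent_fraction(table: ExpressionTable, gene_ids: Iterable[str]) -> float:
    """Fraction of the gene set with zero reads."""
    ids = set(gene_ids)
    if not ids:
        raise ValueError("empty gene set")
    sub = table.table[table.table["id"].isin(ids)]
    missing = ids - set(sub["id"])
    if missing:
        raise KeyError(f"ids absent from expression table: {sorted(missing)[:3]}...")
    return float((sub["count"] == 0).sum() / len(sub))


@dataclasses.dataclass
class PercentChange:
    percent: float | None  # None when WT RPKM is zero (undefined change)
    pvalue: float
    rpkm_wt: float
    rpkm_mut: float


def percent_change(wt: ExpressionTable, mut: ExpressionTable,
                   element_id: str) -> PercentChange:
    """Percent RPKM change mutant vs wild type for one element.

    Significance comes from an exact conditional two-proportion test: given
    the combined read count of the element, its split between genotypes is
    binomial with success probability set by the library-size ratio.  (The
    design has no replicates, so a proportion test on counts is the
    available option; flagged as a stand-in.)
    """
    from scipy.stats import binomtest

    rw, rm = wt.rpkm(element_id), mut.rpkm(element_id)
    cw, cm = wt.count(element_id), mut.count(element_id)
    total = cw + cm
    p0 = mut.library_size / (mut.library_size + wt.library_size)
    pvalue = binomtest(cm, total, p0, alternative="two-sided").pvalue if total > 0 else 1.0
    pct = None if rw == 0 else 100.0 * (rm - rw) / rw
    return PercentChange(pct, float(pvalue), rw, rm)


@dataclasses.dataclass
class GroupComparison:
    summary_a: BoxplotSummary
    summary_b: BoxplotSummary
    n_a: int
    n_b: int
    n_dropped_a: int
    n_dropped_b: int
    pvalue: float


def group_expression_compare(table: ExpressionTable, set_a: Iterable[str],
                             set_b: Iterable[str], drop_zero: bool = True
                             ) -> GroupComparison:
    """Boxplot summaries and rank-sum p on log2 RPKM of two element sets."""
    def _values(ids: Set[str], name: str) -> Tuple[np.ndarray, int]:
        sub = table.table[table.table["id"].isin(ids)]
        vals = sub["rpkm"].to_numpy()
        dropped = 0
        if drop_zero:
            dropped = int((vals == 0).sum())
            vals = vals[vals > 0]
        if len(vals) == 0:
            raise ValueError(f"set {name!r} is empty after zero-RPKM removal")
        return np.log2(vals), dropped

    a, da = _values(set(set_a), "a")
    b, db = _values(set(set_b), "b")
    _, p = wilcoxon_ranksum(a, b)
    return GroupComparison(boxplot_summary(a), boxplot_summary(b),
                           len(a), len(b), da, db, p)
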