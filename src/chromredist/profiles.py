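"""Metagene (TSS-to-TTS) profiles with fixed-width flanks.

Gene bodies are rescaled onto ``n_body_bins`` equal-fraction bins; the
upstream and downstream flanks are binned at fixed ``bin_width`` anchored at
the TSS and TTS.  Probes (and reads, and cytosines) are assigned to the bin
containing their midpoint, which avoids double counting; minus-strand genes
are flipped so bin 0 is always 5'-most.  Profiles average over genes and may
be smoothed with a centered moving average (truncated at the edges).
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Dict, Sequence

import numpy as np
import pandas as pd

from .tracks import ProbeTrack


@dataclasses.dataclass(frozen=True)
class ProfileScheme:
    flank: int = 3000
    bin_width: int = 150
    n_body_bins: int = 20

    def __post_init__(self) -> None:
        if self.flank % self.bin_width != 0:
            raise ValueError("flank must be a multiple of bin_width")
        if self.n_body_bins < 1:
            raise ValueError("need at least one body bin")

    @property
    def n_flank_bins(self) -> int:
        return self.flank // self.bin_width

    @property
    def total_bins(self) -> int:
        return 2 * self.n_flank_bins + self.n_body_bins

    def bin_labels(self) -> list[str]:
        nf, nb = self.n_flank_bins, self.n_body_bins
        return ([f"up{(nf - i) * self.bin_width}" for i in range(nf)]
                + [f"body{i}" for i in range(nb)]
                + [f"down{(i + 1) * self.bin_width}" for i in range(nf)])


@dataclasses.dataclass
class MetageneProfile:
    values: np.ndarray           # one value per bin; NaN where no contributors
    n_contributing: np.ndarray   # genes (or sites/reads) per bin
    scheme: ProfileScheme
    smooth_window: int = 1
    mode: str = "mean"           # how values were aggregated


def _assign_bins(positions: np.ndarray, start: int, end: int,
                 scheme: ProfileScheme) -> np.ndarray:
    """Bin index (plus-strand orientation) per position; -1 = outside."""
    nf, nb = scheme.n_flank_bins, scheme.n_body_bins
    length = end - start
    idx = np.full(len(positions), -1, dtype=np.int64)
    up = (positions >= start - scheme.flank) & (positions < start)
    idx[up] = ((positions[up] - (start - scheme.flank)) // scheme.bin_width)
    body = (positions >= start) & (positions < end)
    frac = (positions[body] - start) / length
    idx[body] = nf + np.minimum((frac * nb).astype(np.int64), nb - 1)
    down = (positions >= end) & (positions < end + scheme.flank)
    idx[down] = nf + nb + ((positions[down] - end) // scheme.bin_width).astype(np.int64)
    return idx


def _iter_genes(genes: pd.DataFrame, scheme: ProfileScheme):
    for _, g in genes.iterrows():
        if g["end"] - g["start"] < scheme.n_body_bins:
            warnings.warn(f"gene {g['id']} shorter than n_body_bins bases; skipped")
            continue
        yield g


def metagene_matrix(track: ProbeTrack, genes: pd.DataFrame,
                    scheme: ProfileScheme = ProfileScheme()) -> np.ndarray:
    """Per-gene x per-bin matrix of mean probe values (NaN for empty bins)."""
    rows = []
    for g in _iter_genes(genes, scheme):
        row = np.full(scheme.total_bins, np.nan)
        if g["chrom"] in track.chroms:
            p = track.chroms[g["chrom"]]
            idx = _assign_bins(p.midpoints, int(g["start"]), int(g["end"]), scheme)
            keep = idx >= 0
            if keep.any():
                sums = np.zeros(scheme.total_bins)
                counts = np.zeros(scheme.total_bins)
                np.add.at(sums, idx[keep], p.values[keep])
                np.add.at(counts, idx[keep], 1.0)
                with np.errstate(invalid="ignore"):
                    row = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        if g["strand"] == "-":
            row = row[::-1]
        rows.append(row)
    if not rows:
        raise ValueError("no usable genes for metagene matrix")
    return np.vstack(rows)


def moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average, truncated windows at the edges, NaN-aware."""
    if window <= 1:
        return values.copy()
    half = window // 2
    out = np.empty_like(values, dtype=float)
    for i in range(len(values)):
        seg = values[max(0, i - half):min(len(values), i + half + 1)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out[i] = np.nanmean(seg) if np.isfinite(seg).any() else np.nan
    return out


def average_profile(matrix: np.ndarray, scheme: ProfileScheme = ProfileScheme(),
                    smooth_window: int = 5, linearize: bool = False
                    ) -> MetageneProfile:
    """Column means over genes (NaN-ignoring), then moving-average smoothing.

    ``linearize=True`` averages 2**value before returning to log2 scale,
    for the ratio-of-linear-means reading of "log2 ratio of averages".
    Bins with zero contributing genes stay NaN even after smoothing.
    """
    if matrix.size == 0:
        raise ValueError("empty matrix")
    n_contrib = np.isfinite(matrix).sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        if linearize:
            means = np.log2(np.nanmean(np.exp2(matrix), axis=0))
        else:
            means = np.nanmean(matrix, axis=0)
    smoothed = moving_average(means, smooth_window)
    smoothed[n_contrib == 0] = np.nan
    return MetageneProfile(smoothed, n_contrib, scheme, smooth_window,
                           mode="linear_mean" if linearize else "mean")


def ratio_profile(a: MetageneProfile, b: MetageneProfile) -> MetageneProfile:
    """Per-bin a - b.  Signals are already log2-scale, so the difference of
    (log) profiles is the log2 ratio; build the inputs with
    ``linearize=True`` for the linearize-then-ratio reading."""
    if a.scheme != b.scheme:
        raise ValueError("profiles have different bin schemes")
    if a.mode != b.mode:
        raise ValueError(f"profiles were aggregated differently: {a.mode} vs {b.mode}")
    return MetageneProfile(a.values - b.values,
                           np.minimum(a.n_contributing, b.n_contributing),
                           a.scheme, max(a.smooth_window, b.smooth_window),
                           mode=f"difference[{a.mode}]")


VALID_CONTEXTS = ("CG", "CHG", "CHH")


def methylation_profile(calls: pd.DataFrame, genes: pd.DataFrame,
                        context: str, scheme: ProfileScheme = ProfileScheme(),
                        smooth_window: int = 1) -> MetageneProfile:
    """Pooled per-bin methylation ratio for one cytosine context.

    Ratio = sum(methylated) / sum(total) over all cytosines of the context
    falling in the bin, pooled across genes (not averaged per site); bins
    with no cytosines are NaN.  ``calls`` uses 1-based positions.
    """
    if context not in VALID_CONTEXTS:
        raise ValueError(f"unknown context {context!r}; expected one of {VALID_CONTEXTS}")
    sub = calls[calls["context"] == context]
    m_sums = np.zeros(scheme.total_bins)
    t_sums = np.zeros(scheme.total_bins)
    site_counts = np.zeros(scheme.total_bins)
    by_chrom = {c: g.sort_values("pos") for c, g in sub.groupby("chrom")}
    for g in _iter_genes(genes, scheme):
        tab = by_chrom.get(g["chrom"])
        if tab is None:
            continue
        pos0 = tab["pos"].to_numpy() - 1  # to 0-based
        idx = _assign_bins(pos0, int(g["start"]), int(g["end"]), scheme)
        keep = idx >= 0
        if not keep.any():
            continue
        bidx = idx[keep]
        if g["strand"] == "-":
            bidx = scheme.total_bins - 1 - bidx
        np.add.at(m_sums, bidx, tab["m_count"].to_numpy(float)[keep])
        np.add.at(t_sums, bidx, tab["t_count"].to_numpy(float)[keep])
        np.add.at(site_counts, bidx, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(t_sums > 0, m_sums / np.maximum(t_sums, 1), np.nan)
    smoothed = moving_average(ratio, smooth_window)
    smoothed[t_sums == 0] = np.nan
    return MetageneProfile(smoothed, site_counts.astype(int), scheme,
                           smooth_window, mode="pooled_ratio")


def read_density_profile(reads: pd.DataFrame, genes: pd.DataFrame,
                         scheme: ProfileScheme = ProfileScheme(),
                         total_reads: int | None = None,
                         normalize: bool = True) -> MetageneProfile:
    """Average density of read midpoints across the gene set.

    Per gene, read-midpoint counts per bin are divided by bin length in kb
    (body bins scale with gene length) and by total reads in millions, then
    averaged over genes.  ``normalize=False`` returns raw mean counts.
    """
    if total_reads is None:
        total_reads = len(reads)
    by_chrom = {c: g for c, g in reads.groupby("chrom")}
    rows = []
    nf, nb = scheme.n_flank_bins, scheme.n_body_bins
    for g in _iter_genes(genes, scheme):
        counts = np.zeros(scheme.total_bins)
        tab = by_chrom.get(g["chrom"])
        if tab is not None:
            mids = ((tab["start"].to_numpy() + tab["end"].to_numpy()) / 2.0)
            idx = _assign_bins(mids, int(g["start"]), int(g["end"]), scheme)
            keep = idx >= 0
            np.add.at(counts, idx[keep], 1.0)
        if g["strand"] == "-":
            counts = counts[::-1]
        if normalize and total_reads > 0:
            body_kb = (g["end"] - g["start"]) / nb / 1000.0
            widths = np.concatenate([
                np.full(nf, scheme.bin_width / 1000.0),
                np.full(nb, body_kb),
                np.full(nf, scheme.bin_width / 1000.0)])
            counts = counts / widths / (total_reads / 1e6)
        rows.append(counts)
    if not rows:
        raise ValueError("no usable genes for read density profile")
    matrix = np.vstack(rows)
    return MetageneProfile(matrix.mean(axis=0),
                           np.full(scheme.total_bins, len(rows)),
                           scheme, 1, mode="read_density" if normalize else "read_count")


def profile_to_frame(profile: MetageneProfile) -> pd.DataFrame:
    return pd.DataFrame({
        "bin": np.arange(profile.scheme.total_bins),
        "label": profile.scheme.bin_labels(),
        "value": profile.values,
        "n": profile.n_contributing,
    })
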