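"""Enriched and differential chromatin-domain calling.

The procedure follows the tiling-array analysis it re-implements:

* the genome is tiled into overlapping bins (200 bp bins, 100 bp step),
  each bin scored as the mean of the probes whose midpoint falls inside it;
* bin (or probe) scores are z-transformed genome-wide;
* bins/probes above a z cutoff become candidate intervals, which are
  unioned and then merged across gaps of at most ``merge_gap`` bases;
* optionally only regions strictly longer than ``min_region_len`` survive
  (the H3K27me3 differential-gain rule: regions > 500 bp);
* differential calls score mutant minus wild-type on a shared grid before
  z-transforming, with direction-specific cutoffs (z > 0.75 for met1 and
  z > 0.8 for ibm1 H3K9me2 gains; z > 2 for H3K27me3 gains; z < -3 for
  losses).

For probe-resolution H3K9me2 calls, :func:`call_blocks` provides a
transparent broad-block heuristic (seed at passing probes, bridge short
runs of failing probes, drop short blocks) standing in for the published
block-finding algorithm whose internals are not part of this package.

Significance of a call set is assessed by a circular-permutation null that
rotates the signal vector per chromosome, preserving autocorrelation.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Callable, Dict, List, Sequence, Tuple

import numpy as np

from .tracks import ChromProbes, ProbeTrack, zscore_transform

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class CallParams:
    """Thresholds and geometry of the region callers.

    Defaults are the published values: 200 bp bins with 100 bp step,
    enrichment cutoff z > 2, loss cutoff z < -3, differential H3K9me2
    cutoffs 0.75 (met1) / 0.8 (ibm1), merge gap 200 bp, and a > 500 bp
    minimum for H3K27me3 differential gains (set via ``min_region_len``).
    Block-caller knobs (``block_*``) parameterize the broad-block stand-in.
    """

    bin_size: int = 200
    step: int = 100
    z_cut_enriched: float = 2.0
    z_cut_hypo: float = -3.0
    z_cut_diff_met1: float = 0.75
    z_cut_diff_ibm1: float = 0.8
    merge_gap: int = 200
    min_region_len: int = 0
    block_z_cutoff: float = 0.5
    block_max_gap_probes: int = 2
    block_min_probes: int = 4
    block_smooth_probes: int = 5
    block_diff_min_probes: int = 6
    block_refine_pad: int = 8
    fdr_permutations: int = 100
    fdr_alpha: float = 0.01
    seed: int = 0

    def validate(self) -> List[str]:
        errors = []
        if not (self.bin_size >= self.step > 0):
            errors.append(f"require bin_size >= step > 0, got {self.bin_size}/{self.step}")
        if self.merge_gap < 0:
            errors.append(f"merge_gap must be >= 0, got {self.merge_gap}")
        if not 0 < self.fdr_alpha < 1:
            errors.append(f"fdr_alpha must lie in (0,1), got {self.fdr_alpha}")
        if self.fdr_permutations < 1:
            errors.append("fdr_permutations must be >= 1")
        if self.block_min_probes < 1 or self.block_max_gap_probes < 0:
            errors.append("block_min_probes >= 1 and block_max_gap_probes >= 0 required")
        return errors


@dataclasses.dataclass(frozen=True)
class Region:
    """A called genomic interval (0-based, half-open)."""

    chrom: str
    start: int
    end: int
    mean_z: float = float("nan")
    n_support: int = 0
    direction: str = "enriched"

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclasses.dataclass
class ChromBins:
    starts: np.ndarray
    ends: np.ndarray
    scores: np.ndarray  # NaN where no probe midpoint fell in the bin


@dataclasses.dataclass
class BinTrack:
    """Sliding-bin aggregated scores; z-statistics are computed genome-wide
    over non-empty bins at call time."""

    chroms: Dict[str, ChromBins]
    bin_size: int
    step: int

    @property
    def chrom_names(self) -> list[str]:
        return sorted(self.chroms)

    def all_scores(self) -> np.ndarray:
        return np.concatenate([self.chroms[c].scores for c in self.chrom_names])


def bin_track(track: ProbeTrack, bin_size: int = 200, step: int = 100,
              chrom_lengths: Dict[str, int] | None = None) -> BinTrack:
    """Tile each chromosome into overlapping bins and average probe values.

    A probe contributes to every bin containing its midpoint.  Bins cover
    [0, chrom_length) with a trailing partial bin; chromosome length
    defaults to the last probe end.  Empty bins carry NaN and are excluded
    from downstream z statistics.
    """
    if track.n_probes == 0:
        raise ValueError("cannot bin an empty track")
    chroms: Dict[str, ChromBins] = {}
    for chrom in track.chrom_names:
        p = track.chroms[chrom]
        length = (chrom_lengths or {}).get(chrom, int(p.ends[-1]))
        starts = np.arange(0, length, step, dtype=np.int64)
        ends = np.minimum(starts + bin_size, length)
        mids = p.midpoints  # sorted because probes are sorted, uniform length
        csum = np.concatenate([[0.0], np.cumsum(p.values)])
        left = np.searchsorted(mids, starts, side="left")
        right = np.searchsorted(mids, ends, side="left")
        n = right - left
        with np.errstate(invalid="ignore"):
            scores = np.where(n > 0, (csum[right] - csum[left]) / np.maximum(n, 1), np.nan)
        chroms[chrom] = ChromBins(starts, ends, scores)
    return BinTrack(chroms, bin_size=bin_size, step=step)


# ---------------------------------------------------------------------------
# Interval arithmetic
# ---------------------------------------------------------------------------

def merge_intervals(intervals: Sequence[Tuple[int, int]], gap: int = 0
                    ) -> List[Tuple[int, int]]:
    """Union of intervals, additionally merging neighbours whose gap
    (next.start - prev.end) is <= ``gap``.  Output sorted, non-overlapping."""
    if not intervals:
        return []
    ordered = sorted(intervals)
    merged = [list(ordered[0])]
    for s, e in ordered[1:]:
        if s - merged[-1][1] <= gap:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _regions_from_mask(chrom: str, starts: np.ndarray, ends: np.ndarray,
                       z: np.ndarray, mask: np.ndarray, merge_gap: int,
                       min_region_len: int, direction: str) -> List[Region]:
    idx = np.nonzero(mask)[0]
    if len(idx) == 0:
        return []
    merged = merge_intervals(
        [(int(starts[i]), int(ends[i])) for i in idx], gap=merge_gap)
    regions = []
    for s, e in merged:
        if min_region_len > 0 and (e - s) <= min_region_len:
            continue  # strictly-greater length rule ("> 500 bp")
        sel = idx[(starts[idx] < e) & (ends[idx] > s)]
        regions.append(Region(chrom, s, e, mean_z=float(np.mean(z[sel])),
                              n_support=len(sel), direction=direction))
    return regions


def call_enriched_regions(bins: BinTrack, params: CallParams,
                          z_cutoff: float | None = None,
                          min_region_len: int | None = None) -> List[Region]:
    """Single-condition enrichment: bins with z strictly above the cutoff,
    unioned and gap-merged."""
    cutoff = params.z_cut_enriched if z_cutoff is None else z_cutoff
    min_len = params.min_region_len if min_region_len is None else min_region_len
    z_all = zscore_transform(bins.all_scores())
    out: List[Region] = []
    offset = 0
    for chrom in bins.chrom_names:
        cb = bins.chroms[chrom]
        z = z_all[offset:offset + len(cb.starts)]
        offset += len(cb.starts)
        mask = np.isfinite(z) & (z > cutoff)
        out.extend(_regions_from_mask(chrom, cb.starts, cb.ends, z, mask,
                                      params.merge_gap, min_len, "enriched"))
    return out


def difference_bins(mut: BinTrack, wt: BinTrack) -> BinTrack:
    """Mutant minus wild-type bin scores on a shared grid."""
    if mut.chrom_names != wt.chrom_names or mut.bin_size != wt.bin_size \
            or mut.step != wt.step:
        raise ValueError("bin grids differ between mutant and wild type")
    chroms = {}
    for chrom in mut.chrom_names:
        a, b = mut.chroms[chrom], wt.chroms[chrom]
        if len(a.starts) != len(b.starts) or np.any(a.starts != b.starts):
            raise ValueError(f"bin grids differ on {chrom}")
        chroms[chrom] = ChromBins(a.starts.copy(), a.ends.copy(), a.scores - b.scores)
    return BinTrack(chroms, mut.bin_size, mut.step)


def difference_track(mut: ProbeTrack, wt: ProbeTrack) -> ProbeTrack:
    """Mutant minus wild-type probe values on a shared grid (both log2-scale)."""
    from .tracks import _assert_same_grid
    _assert_same_grid(mut, wt)
    diff = {c: mut.chroms[c].values - wt.chroms[c].values for c in mut.chrom_names}
    return mut.with_values(diff, channel="difference")


def call_differential_regions(mut, wt, params: CallParams,
                              direction: str = "hyper",
                              z_cutoff: float | None = None,
                              min_region_len: int | None = None) -> List[Region]:
    """Differential (hyper/hypo) regions from matched mutant/WT tracks.

    Accepts a pair of :class:`BinTrack` (bin resolution, the H3K27me3 path)
    or :class:`ProbeTrack` (probe resolution).  The per-unit difference is
    z-transformed genome-wide; units strictly beyond the direction cutoff
    are unioned and gap-merged.  Identical tracks (zero-variance difference)
    yield an empty call with a warning rather than an exception.
    """
    if direction not in ("hyper", "hypo"):
        raise ValueError(f"direction must be 'hyper' or 'hypo', got {direction!r}")
    if isinstance(mut, BinTrack):
        diff = difference_bins(mut, wt)
        per_chrom = {c: (diff.chroms[c].starts, diff.chroms[c].ends,
                         diff.chroms[c].scores) for c in diff.chrom_names}
    else:
        diff = difference_track(mut, wt)
        per_chrom = {c: (diff.chroms[c].starts, diff.chroms[c].ends,
                         diff.chroms[c].values) for c in diff.chrom_names}
    names = sorted(per_chrom)
    scores = np.concatenate([per_chrom[c][2] for c in names])
    finite = scores[np.isfinite(scores)]
    if len(finite) < 2 or float(finite.std()) == 0.0:
        warnings.warn("zero-variance difference (identical tracks?); no regions called")
        return []
    z_all = zscore_transform(scores)
    if z_cutoff is None:
        z_cutoff = params.z_cut_enriched if direction == "hyper" else params.z_cut_hypo
    min_len = params.min_region_len if min_region_len is None else min_region_len
    out: List[Region] = []
    offset = 0
    for chrom in names:
        starts, ends, _ = per_chrom[chrom]
        z = z_all[offset:offset + len(starts)]
        offset += len(starts)
        if direction == "hyper":
            mask = np.isfinite(z) & (z > z_cutoff)
        else:
            mask = np.isfinite(z) & (z < z_cutoff)
        out.extend(_regions_from_mask(chrom, starts, ends, z, mask,
                                      params.merge_gap, min_len, direction))
    return out


def call_blocks(track: ProbeTrack, params: CallParams,
                z_cutoff: float | None = None,
                direction: str = "hyper") -> List[Region]:
    """Broad-block stand-in for probe-level H3K9me2 domain calling.

    Probes with z strictly beyond the cutoff seed blocks; a block extends
    across runs of at most ``block_max_gap_probes`` failing probes; blocks
    spanning fewer than ``block_min_probes`` probes (passing plus bridged)
    are dropped.
    """
    cutoff = params.block_z_cutoff if z_cutoff is None else z_cutoff
    values = track.all_values()
    finite = values[np.isfinite(values)]
    if len(finite) < 2 or float(finite.std()) == 0.0:
        warnings.warn("zero-variance track; no blocks called")
        return []
    z_all = zscore_transform(values)
    out: List[Region] = []
    offset = 0
    for chrom in track.chrom_names:
        p = track.chroms[chrom]
        z = z_all[offset:offset + len(p)]
        offset += len(p)
        if direction == "hyper":
            passing = np.isfinite(z) & (z > cutoff)
        else:
            passing = np.isfinite(z) & (z < cutoff)
        idx = np.nonzero(passing)[0]
        if len(idx) == 0:
            continue
        block_start = prev = idx[0]
        spans: List[Tuple[int, int]] = []
        for i in idx[1:]:
            if i - prev - 1 <= params.block_max_gap_probes:
                prev = i
            else:
                spans.append((block_start, prev))
                block_start = prev = i
        spans.append((block_start, prev))
        for i0, i1 in spans:
            if (i1 - i0 + 1) < params.block_min_probes:
                continue
            sel = np.arange(i0, i1 + 1)
            zsel = z[sel][passing[sel]]
            out.append(Region(chrom, int(p.starts[i0]), int(p.ends[i1]),
                              mean_z=float(np.mean(zsel)),
                              n_support=int(passing[sel].sum()),
                              direction=direction))
    return out


def _max_subarray(score: np.ndarray) -> Tuple[int, int]:
    """Kadane's maximum-scoring contiguous segment (indices inclusive)."""
    best = (-np.inf, 0, 0)
    cur, start = 0.0, 0
    for i, s in enumerate(score):
        if cur <= 0:
            cur, start = float(s), i
        else:
            cur += float(s)
        if cur > best[0]:
            best = (cur, start, i)
    return best[1], best[2]


def _smoothed(track: ProbeTrack, window: int) -> ProbeTrack:
    if window <= 1:
        return track
    half = window // 2
    kernel = np.ones(window) / window
    out = {}
    for c in track.chrom_names:
        v = track.chroms[c].values
        if len(v) >= window:
            sm = np.convolve(v, kernel, mode="same")
            # truncated windows at the edges (same as a centered moving average)
            for i in range(half):
                sm[i] = v[:i + half + 1].mean()
                sm[-(i + 1)] = v[-(i + half + 1):].mean()
            out[c] = sm
        else:
            out[c] = np.full(len(v), v.mean()) if len(v) else v
    return track.with_values(out)


def call_differential_blocks(mut: ProbeTrack, wt: ProbeTrack, params: CallParams,
                             z_cutoff: float | None = None,
                             direction: str = "hyper") -> List[Region]:
    """Probe-resolution differential domains with step-fit boundaries.

    The mutant-minus-wild-type probe differences are smoothed with a
    ``block_smooth_probes`` moving average for detection (z strictly beyond
    the cutoff, gap bridging as in :func:`call_blocks`, at least
    ``block_diff_min_probes`` probes).  Each detected block's boundaries are
    then refit on the unsmoothed differences as the maximum-scoring segment
    of (value - baseline) - lift/2 -- the maximum-likelihood extent of a
    step of the block's (median-estimated) height -- within the block plus
    ``block_refine_pad`` probes.  Blocks whose refined probes average below
    the z cutoff are discarded, and boundaries extend to the midpoint of
    the neighbouring inter-probe gaps.
    """
    if z_cutoff is None:
        z_cutoff = (params.z_cut_diff_met1 if direction == "hyper"
                    else params.z_cut_hypo)
    diff = difference_track(mut, wt)
    values = diff.all_values()
    finite = values[np.isfinite(values)]
    if len(finite) < 2 or float(finite.std()) == 0.0:
        warnings.warn("zero-variance difference (identical tracks?); no blocks called")
        return []
    detect_params = dataclasses.replace(params,
                                        block_min_probes=params.block_diff_min_probes)
    blocks = call_blocks(_smoothed(diff, params.block_smooth_probes),
                         detect_params, z_cutoff=z_cutoff, direction=direction)
    base = float(np.median(values))
    z_all = zscore_transform(values)
    z_by_chrom: Dict[str, np.ndarray] = {}
    offset = 0
    for c in diff.chrom_names:
        n = len(diff.chroms[c])
        z_by_chrom[c] = z_all[offset:offset + n]
        offset += n
    sign = 1.0 if direction == "hyper" else -1.0
    out: List[Region] = []
    for r in blocks:
        p = diff.chroms[r.chrom]
        b0 = int(np.searchsorted(p.starts, r.start))
        b1 = int(np.searchsorted(p.ends, r.end, side="right")) - 1
        lift = abs(float(np.median(p.values[b0:b1 + 1])) - base)
        i0 = max(0, b0 - params.block_refine_pad)
        i1 = min(len(p) - 1, b1 + params.block_refine_pad)
        score = sign * (p.values[i0:i1 + 1] - base) - lift / 2.0
        j0, j1 = _max_subarray(score)
        g0, g1 = i0 + j0, i0 + j1
        if g1 - g0 + 1 < params.block_diff_min_probes:
            continue
        zseg = z_by_chrom[r.chrom][g0:g1 + 1]
        if sign * float(np.mean(zseg)) <= sign * z_cutoff:
            continue
        start, end = int(p.starts[g0]), int(p.ends[g1])
        if g0 > 0:
            start -= int(p.starts[g0] - p.ends[g0 - 1]) // 2
        if g1 + 1 < len(p):
            end += int(p.starts[g1 + 1] - p.ends[g1]) // 2
        out.append(Region(r.chrom, start, end, mean_z=float(np.mean(zseg)),
                          n_support=g1 - g0 + 1, direction=direction))
    return sorted(out, key=lambda r: (r.chrom, r.start))


# ---------------------------------------------------------------------------
# Permutation FDR
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class FdrResult:
    observed_count: int
    expected_null_count: float
    fdr: float
    alpha: float
    zero_observed: bool = False

    @property
    def significant(self) -> bool:
        return self.observed_count > 0 and self.fdr < self.alpha


def rotate_track(track, offsets: Dict[str, int]):
    """Circularly rotate the value/score vector of each chromosome."""
    if isinstance(track, BinTrack):
        chroms = {
            c: ChromBins(cb.starts.copy(), cb.ends.copy(),
                         np.roll(cb.scores, offsets.get(c, 0)))
            for c, cb in track.chroms.items()
        }
        return BinTrack(chroms, track.bin_size, track.step)
    rolled = {c: np.roll(track.chroms[c].values, offsets.get(c, 0))
              for c in track.chrom_names}
    return track.with_values(rolled)


def shuffle_track(track, rng: np.random.Generator):
    """Permute the value/score vector within each chromosome."""
    if isinstance(track, BinTrack):
        chroms = {
            c: ChromBins(cb.starts.copy(), cb.ends.copy(),
                         rng.permutation(cb.scores))
            for c, cb in track.chroms.items()
        }
        return BinTrack(chroms, track.bin_size, track.step)
    shuffled = {c: rng.permutation(track.chroms[c].values)
                for c in track.chrom_names}
    return track.with_values(shuffled)


def estimate_fdr(call_fn: Callable[..., List[Region]], tracks: Sequence,
                 params: CallParams, seed: int | None = None,
                 method: str = "shuffle") -> FdrResult:
    """Permutation FDR for a calling function.

    ``call_fn(*tracks)`` must return the observed region list.  For each of
    ``params.fdr_permutations`` rounds, the first track's value vector is
    permuted per chromosome and the caller re-run; the FDR is the mean null
    region count divided by the observed count.

    ``method='shuffle'`` (default) randomly permutes values, destroying the
    spatial clustering that region callers key on -- contiguous planted
    signal therefore drives the FDR down, which is the intended behaviour
    for these domain callers.  ``method='rotate'`` applies a circular shift
    instead; it preserves autocorrelation but also preserves contiguous
    signal blocks, so it is only a meaningful null for position-anchored
    questions, not for "more domains than chance" -- it is kept for
    comparison.
    """
    if method not in ("shuffle", "rotate"):
        raise ValueError(f"unknown permutation method {method!r}")
    observed = call_fn(*tracks)
    n_obs = len(observed)
    rng = np.random.default_rng(params.seed if seed is None else seed)
    first = tracks[0]
    names = first.chrom_names
    sizes = {c: (len(first.chroms[c].scores) if isinstance(first, BinTrack)
                 else len(first.chroms[c])) for c in names}
    null_counts = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(params.fdr_permutations):
            if method == "shuffle":
                null = shuffle_track(first, rng)
            else:
                offsets = {c: int(rng.integers(0, max(sizes[c], 1)))
                           for c in names}
                null = rotate_track(first, offsets)
            null_counts.append(len(call_fn(null, *tracks[1:])))
    expected_null = float(np.mean(null_counts))
    fdr = expected_null / max(n_obs, 1)
    if n_obs == 0:
        logger.info("no observed regions; FDR reported as 0 with zero_observed flag")
        return FdrResult(0, expected_null, 0.0, params.fdr_alpha, zero_observed=True)
    return FdrResult(n_obs, expected_null, fdr, params.fdr_alpha)


def total_called_bases(regions: Sequence[Region]) -> int:
    return sum(r.length for r in regions)


def regions_to_bed(regions: Sequence[Region], path) -> None:
    """BED6; score = mean z clipped/scaled to 0-1000."""
    with open(path, "w") as fh:
        for i, r in enumerate(sorted(regions, key=lambda r: (r.chrom, r.start))):
            score = int(np.clip(abs(r.mean_z) * 100, 0, 1000)) if np.isfinite(r.mean_z) else 0
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.direction}_{i}\t{score}\t.\n")
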