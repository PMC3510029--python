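"""Probe-level signal tracks: containers, bedGraph/WIG I/O, normalization.

Tiling-array ChIP signal is represented as per-chromosome arrays of
non-overlapping probes (0-based, half-open coordinates) carrying one float
value each.  Raw chip/control channel pairs are normalized by taking the
log2 ratio and re-centering so the genome-wide average log2 ratio is zero;
tracks that are already on a log2 scale are combined by subtraction instead.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Dict, Iterable, Iterator, Tuple

import numpy as np


class TrackError(ValueError):
    """Malformed or incompatible probe track."""


@dataclasses.dataclass
class ChromProbes:
    """Sorted, non-overlapping probes of one chromosome."""

    starts: np.ndarray
    ends: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if not (len(self.starts) == len(self.ends) == len(self.values)):
            raise TrackError("starts, ends and values must have equal length")

    def __len__(self) -> int:
        return len(self.starts)

    @property
    def midpoints(self) -> np.ndarray:
        return (self.starts + self.ends) / 2.0


@dataclasses.dataclass
class ProbeTrack:
    """Per-probe genomic signal for one mark/genotype/channel.

    ``already_log`` marks values that are on a log2 scale (e.g. simulated
    log-ratio signal); it controls how :func:`log2_ratio_normalize` combines
    the chip and control channels.
    """

    chroms: Dict[str, ChromProbes]
    mark: str = ""
    genotype: str = ""
    channel: str = "chip"
    already_log: bool = False

    def __post_init__(self) -> None:
        for chrom, probes in self.chroms.items():
            order = np.argsort(probes.starts, kind="stable")
            probes.starts = probes.starts[order]
            probes.ends = probes.ends[order]
            probes.values = probes.values[order]
            if np.any(probes.ends <= probes.starts):
                i = int(np.argmax(probes.ends <= probes.starts))
                raise TrackError(
                    f"probe with end <= start on {chrom}: "
                    f"[{probes.starts[i]}, {probes.ends[i]})"
                )
            if len(probes) > 1:
                overlap = probes.starts[1:] < probes.ends[:-1]
                if np.any(overlap):
                    i = int(np.argmax(overlap))
                    raise TrackError(
                        f"overlapping probes on {chrom}: "
                        f"[{probes.starts[i]}, {probes.ends[i]}) and "
                        f"[{probes.starts[i + 1]}, {probes.ends[i + 1]})"
                    )

    @property
    def chrom_names(self) -> list[str]:
        return sorted(self.chroms)

    @property
    def n_probes(self) -> int:
        return sum(len(p) for p in self.chroms.values())

    def all_values(self) -> np.ndarray:
        """Concatenated values in chromosome-name order."""
        return np.concatenate(
            [self.chroms[c].values for c in self.chrom_names]
        ) if self.chroms else np.empty(0)

    def with_values(self, per_chrom: Dict[str, np.ndarray], **meta) -> "ProbeTrack":
        """Copy of this track's grid carrying new values."""
        chroms = {
            c: ChromProbes(p.starts.copy(), p.ends.copy(), np.asarray(per_chrom[c], float))
            for c, p in self.chroms.items()
        }
        fields = dict(mark=self.mark, genotype=self.genotype,
                      channel=self.channel, already_log=self.already_log)
        fields.update(meta)
        return ProbeTrack(chroms, **fields)

    def iter_probes(self) -> Iterator[Tuple[str, int, int, float]]:
        for chrom in self.chrom_names:
            p = self.chroms[chrom]
            for s, e, v in zip(p.starts, p.ends, p.values):
                yield chrom, int(s), int(e), float(v)


@dataclasses.dataclass
class NormalizedTrack(ProbeTrack):
    """Centered log2-ratio track; ``genome_mean`` is the post-centering mean."""

    genome_mean: float = 0.0
    control_channel: str = "control"


def _assert_same_grid(a: ProbeTrack, b: ProbeTrack) -> None:
    if a.chrom_names != b.chrom_names:
        raise TrackError(
            f"chromosome sets differ: {a.chrom_names} vs {b.chrom_names}"
        )
    for chrom in a.chrom_names:
        pa, pb = a.chroms[chrom], b.chroms[chrom]
        if len(pa) != len(pb) or np.any(pa.starts != pb.starts) or np.any(pa.ends != pb.ends):
            n = min(len(pa), len(pb))
            bad = np.nonzero((pa.starts[:n] != pb.starts[:n]) | (pa.ends[:n] != pb.ends[:n]))[0]
            where = (f"probe {bad[0]} ([{pa.starts[bad[0]]},{pa.ends[bad[0]]}) vs "
                     f"[{pb.starts[bad[0]]},{pb.ends[bad[0]]}))") if len(bad) else \
                    f"probe counts {len(pa)} vs {len(pb)}"
            raise TrackError(f"probe grids differ on {chrom}: {where}")


def log2_ratio_normalize(chip: ProbeTrack, control: ProbeTrack) -> NormalizedTrack:
    """log2(chip/control) per probe, centered to genome-wide mean zero.

    If both channels are flagged ``already_log`` the ratio is a subtraction.
    The centering mean is unweighted over probes (uniform probe length in the
    designs handled here).
    """
    _assert_same_grid(chip, control)
    already_log = chip.already_log and control.already_log
    ratios: Dict[str, np.ndarray] = {}
    for chrom in chip.chrom_names:
        cv, kv = chip.chroms[chrom].values, control.chroms[chrom].values
        if already_log:
            ratios[chrom] = cv - kv
        else:
            bad = (cv <= 0) | (kv <= 0)
            if np.any(bad):
                i = int(np.argmax(bad))
                s = chip.chroms[chrom].starts[i]
                raise TrackError(
                    f"nonpositive intensity at {chrom}:{s} "
                    f"(chip={cv[i]}, control={kv[i]}); raw channels must be > 0"
                )
            ratios[chrom] = np.log2(cv / kv)
    grand_mean = float(np.mean(np.concatenate(
        [ratios[c] for c in chip.chrom_names]))) if ratios else 0.0
    chroms = {
        c: ChromProbes(chip.chroms[c].starts.copy(), chip.chroms[c].ends.copy(),
                       ratios[c] - grand_mean)
        for c in chip.chrom_names
    }
    out = NormalizedTrack(chroms, mark=chip.mark, genotype=chip.genotype,
                          channel="normalized", already_log=True,
                          control_channel=control.channel or "control")
    out.genome_mean = float(np.mean(out.all_values())) if out.n_probes else 0.0
    return out


def zscore_transform(values: np.ndarray) -> np.ndarray:
    """Population z-scores; NaNs are ignored in the statistics and propagated.

    Raises on fewer than two finite values or zero variance -- a degenerate
    (constant) track must fail loudly rather than return silent zeros.
    """
    values = np.asarray(values, dtype=np.float64)
    finite = np.isfinite(values)
    if finite.sum() < 2:
        raise ValueError("z-score transform requires at least 2 finite values")
    mean = float(values[finite].mean())
    sd = float(values[finite].std())  # population (ddof=0)
    if sd == 0.0:
        raise ValueError("z-score transform undefined for constant input (sd = 0)")
    out = np.full_like(values, np.nan)
    out[finite] = (values[finite] - mean) / sd
    return out


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

def read_track(path: str | Path, format: str | None = None, **meta) -> ProbeTrack:
    """Read a bedGraph or WIG (fixedStep/variableStep) file.

    ``format`` is inferred from the file extension when omitted.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        if suffix in (".bedgraph", ".bg"):
            format = "bedGraph"
        elif suffix in (".wig", ".wiggle"):
            format = "wig"
        else:
            raise TrackError(f"cannot infer track format from {path.name}")
    if format.lower() == "bedgraph":
        return read_bedgraph(path, **meta)
    if format.lower() == "wig":
        return read_wig(path, **meta)
    raise TrackError(f"unknown track format: {format!r}")


def read_bedgraph(path: str | Path, **meta) -> ProbeTrack:
    data: Dict[str, list] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            chrom, start, end, value = line.split()[:4]
            data.setdefault(chrom, []).append((int(start), int(end), float(value)))
    return _build(data, **meta)


def read_wig(path: str | Path, **meta) -> ProbeTrack:
    data: Dict[str, list] = {}
    mode = None
    chrom, start, step, span = None, 0, 1, 1
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            if line.startswith("fixedStep"):
                fields = dict(kv.split("=") for kv in line.split()[1:])
                mode = "fixed"
                chrom = fields["chrom"]
                start = int(fields["start"]) - 1  # WIG is 1-based
                step = int(fields.get("step", 1))
                span = int(fields.get("span", 1))
            elif line.startswith("variableStep"):
                fields = dict(kv.split("=") for kv in line.split()[1:])
                mode = "variable"
                chrom = fields["chrom"]
                span = int(fields.get("span", 1))
            elif mode == "fixed":
                data.setdefault(chrom, []).append((start, start + span, float(line)))
                start += step
            elif mode == "variable":
                pos, value = line.split()[:2]
                s = int(pos) - 1
                data.setdefault(chrom, []).append((s, s + span, float(value)))
            else:
                raise TrackError(f"WIG data line before any step declaration: {line!r}")
    return _build(data, **meta)


def _build(data: Dict[str, list], **meta) -> ProbeTrack:
    chroms = {}
    for chrom, rows in data.items():
        rows.sort()
        arr = np.asarray(rows, dtype=np.float64).reshape(-1, 3)
        chroms[chrom] = ChromProbes(arr[:, 0].astype(np.int64),
                                    arr[:, 1].astype(np.int64), arr[:, 2])
    return ProbeTrack(chroms, **meta)


def write_bedgraph(track: ProbeTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in track.iter_probes():
            fh.write(f"{chrom}\t{start}\t{end}\t{value:.6g}\n")


def write_wig_fixedstep(track: ProbeTrack, path: str | Path) -> None:
    """Write as fixedStep WIG; requires a regular grid per chromosome."""
    with open(path, "w") as fh:
        for chrom in track.chrom_names:
            p = track.chroms[chrom]
            if len(p) == 0:
                continue
            span = int(p.ends[0] - p.starts[0])
            step = int(p.starts[1] - p.starts[0]) if len(p) > 1 else span
            if np.any(np.diff(p.starts) != step) or np.any(p.ends - p.starts != span):
                raise TrackError(f"irregular probe grid on {chrom}; cannot use fixedStep")
            fh.write(f"fixedStep chrom={chrom} start={int(p.starts[0]) + 1} "
                     f"step={step} span={span}\n")
            for v in p.values:
                fh.write(f"{v:.6g}\n")
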