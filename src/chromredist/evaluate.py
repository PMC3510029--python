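"""Recovery metrics scoring called regions and classes against planted truth."""

from __future__ import annotations

from typing import Dict, Iterable, List, Sequence, Tuple

from .regions import Region, merge_intervals


def _by_chrom(intervals) -> Dict[str, List[Tuple[int, int]]]:
    out: Dict[str, List[Tuple[int, int]]] = {}
    for iv in intervals:
        chrom, start, end = iv.chrom, iv.start, iv.end
        out.setdefault(chrom, []).append((int(start), int(end)))
    return {c: merge_intervals(v) for c, v in out.items()}


def _overlap_bases(a: List[Tuple[int, int]], b: List[Tuple[int, int]]) -> int:
    total, j = 0, 0
    for s, e in a:
        while j < len(b) and b[j][1] <= s:
            j += 1
        k = j
        while k < len(b) and b[k][0] < e:
            total += min(e, b[k][1]) - max(s, b[k][0])
            k += 1
    return total


def interval_jaccard(called: Sequence, truth: Sequence) -> float:
    """Base-pair Jaccard index between two interval sets (any objects with
    chrom/start/end attributes)."""
    a, b = _by_chrom(called), _by_chrom(truth)
    inter = sum(_overlap_bases(a.get(c, []), b.get(c, []))
                for c in set(a) | set(b))
    len_a = sum(e - s for ivs in a.values() for s, e in ivs)
    len_b = sum(e - s for ivs in b.values() for s, e in ivs)
    union = len_a + len_b - inter
    return inter / union if union else 1.0


def boundary_errors(called: Sequence[Region], truth: Sequence) -> List[int]:
    """For every truth interval, the worst boundary offset (bp) of the best
    matching called region; unmatched truth intervals get -1."""
    by_chrom: Dict[str, List[Region]] = {}
    for r in called:
        by_chrom.setdefault(r.chrom, []).append(r)
    errors = []
    for t in truth:
        best = None
        for r in by_chrom.get(t.chrom, []):
            ov = min(t.end, r.end) - max(t.start, r.start)
            if ov > 0 and (best is None or ov > best[0]):
                best = (ov, r)
        if best is None:
            errors.append(-1)
        else:
            r = best[1]
            errors.append(max(abs(r.start - t.start), abs(r.end - t.end)))
    return errors


def classification_accuracy(predicted: Dict[str, set],
                            truth_labels: Dict[str, str],
                            wanted: Iterable[str] = ("class1", "class2")
                            ) -> float:
    """Fraction of planted Class I/II genes assigned their planted class."""
    total = correct = 0
    for label in wanted:
        planted = {i for i, lab in truth_labels.items() if lab == label}
        total += len(planted)
        correct += len(planted & predicted.get(label, set()))
    if total == 0:
        raise ValueError("no planted genes with the wanted labels")
    return correct / total
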