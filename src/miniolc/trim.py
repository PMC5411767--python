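"""Overlap-based trimming of corrected reads.

Each read is trimmed to the largest interval covered to depth >= C by
overlaps of error <= E and length >= L (gapped alignments make the trim
points precise). A second pass flags technology artifacts: hairpin
adapters (several partners overlapping in both orientations around a
common pivot with few reads spanning it) and chimeric junctions (interior
positions spanned by almost no overlap). In both cases the read keeps its
largest supported side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .config import PipelineConfig
from .overlap import Overlap

log = logging.getLogger("miniolc.trim")


@dataclass
class Flaw:
    kind: str                 # 'hairpin' | 'chimera'
    interval: tuple[int, int]


@dataclass
class ClearRange:
    read_id: str
    begin: int
    end: int
    status: str               # 'trimmed' | 'split' | 'discarded'
    flaws: list[Flaw] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.begin > self.end:
            raise ValueError("empty clear range must use begin == end")


def _qualifying(overlaps: list[Overlap], E: float, L: int) -> list[Overlap]:
    return [o for o in overlaps if o.error <= E and o.length >= L]


def _coverage(read_len: int, intervals: list[tuple[int, int]]) -> np.ndarray:
    cov = np.zeros(read_len + 1, dtype=np.int32)
    for s, e in intervals:
        cov[max(0, s)] += 1
        cov[min(read_len, e)] -= 1
    return np.cumsum(cov)[:read_len]


def _longest_run(mask: np.ndarray) -> tuple[int, int]:
    """Longest True run as (start, end); (0, 0) when mask is all False."""
    if not mask.any():
        return 0, 0
    padded = np.concatenate(([False], mask, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    i = int(np.argmax(ends - starts))
    return int(starts[i]), int(ends[i])


def compute_clear_range(
    read_id: str,
    read_len: int,
    overlaps: list[Overlap],
    C: int = 2,
    E: float = 0.045,
    L: int = 500,
) -> ClearRange:
    """Largest interval with qualifying overlap depth >= C.

    `overlaps` must have a_id == read_id (the read's own store slice).
    Reads whose best interval is shorter than L are discarded.
    """
    quals = _qualifying(overlaps, E, L)
    if not quals:
        return ClearRange(read_id, 0, 0, "discarded")
    cov = _coverage(read_len, [(o.a_start, o.a_end) for o in quals])
    s, e = _longest_run(cov >= C)
    if e - s < L:
        return ClearRange(read_id, 0, 0, "discarded")
    return ClearRange(read_id, s, e, "trimmed")


def _spanning_count(overlaps: list[Overlap], pos: int, margin: int) -> int:
    return sum(1 for o in overlaps
               if o.a_start <= pos - margin and o.a_end >= pos + margin)


def detect_hairpin(
    read_id: str,
    read_len: int,
    overlaps: list[Overlap],
    min_partners: int = 5,
    max_spanning: int = 2,
    span_margin: int = 100,
) -> Flaw | None:
    """Unremoved hairpin adapter: the same partners overlap the read in
    both orientations around a common pivot which few overlaps span."""
    by_partner: dict[str, dict[str, list[Overlap]]] = {}
    for o in overlaps:
        by_partner.setdefault(o.b_id, {}).setdefault(o.orient, []).append(o)
    pivots = []
    for partner, by_or in by_partner.items():
        if "+" not in by_or or "-" not in by_or:
            continue
        for of in by_or["+"]:
            for orv in by_or["-"]:
                lo = max(min(of.a_end, orv.a_end) - 50, 0)
                hi = min(max(of.a_start, orv.a_start) + 50, read_len)
                mid = (min(of.a_end, orv.a_end) + max(of.a_start, orv.a_start)) // 2
                if 0 < mid < read_len:
                    pivots.append(mid)
    if len(pivots) < min_partners:
        return None
    pivot = int(np.median(pivots))
    if _spanning_count(overlaps, pivot, span_margin) > max_spanning:
        return None  # true inverted repeat: plenty of spanning evidence
    lo = max(0, pivot - 100)
    hi = min(read_len, pivot + 100)
    return Flaw("hairpin", (lo, hi))


def detect_chimera(
    read_id: str,
    read_len: int,
    overlaps: list[Overlap],
    clear: tuple[int, int],
    max_spanning: int = 1,
    span_margin: int = 100,
) -> list[int]:
    """Interior clear-range positions spanned by <= max_spanning overlaps."""
    s, e = clear
    interior = range(s + 2 * span_margin, e - 2 * span_margin)
    if not len(interior) or not overlaps:
        return []
    # spanning profile via difference array: overlap spans pos iff
    # a_start <= pos - margin and a_end >= pos + margin
    cov = np.zeros(read_len + 1, dtype=np.int32)
    for o in overlaps:
        lo = o.a_start + span_margin
        hi = o.a_end - span_margin
        if hi > lo:
            cov[lo] += 1
            cov[min(read_len, hi)] -= 1
    prof = np.cumsum(cov)[:read_len]
    weak = np.flatnonzero(prof[interior.start : interior.stop] <= max_spanning)
    if len(weak) == 0:
        return []
    # merge consecutive weak positions into junction midpoints
    junctions = []
    run_start = weak[0]
    prev = weak[0]
    for w in weak[1:]:
        if w > prev + 1:
            junctions.append(interior.start + (run_start + prev) // 2)
            run_start = w
        prev = w
    junctions.append(interior.start + (run_start + prev) // 2)
    return junctions


def trim_read(
    read_id: str,
    read_len: int,
    overlaps: list[Overlap],
    cfg: PipelineConfig,
) -> ClearRange:
    """Full trim decision for one read: depth rule, then hairpin/chimera."""
    cr = compute_clear_range(read_id, read_len, overlaps,
                             cfg.trim_depth, cfg.trim_error, cfg.trim_min_len)
    if cr.status == "discarded":
        return cr
    hp = detect_hairpin(read_id, read_len, overlaps,
                        cfg.hairpin_min_partners, cfg.hairpin_max_spanning,
                        cfg.span_margin)
    if hp is not None:
        cr.flaws.append(hp)
        lo, hi = hp.interval
        # keep the larger side of the pivot
        if lo - cr.begin >= cr.end - hi:
            cr = ClearRange(read_id, cr.begin, max(cr.begin, lo), "split", cr.flaws)
        else:
            cr = ClearRange(read_id, min(hi, cr.end), cr.end, "split", cr.flaws)
        if cr.end - cr.begin < cfg.trim_min_len:
            return ClearRange(read_id, 0, 0, "discarded", cr.flaws)
    juncs = detect_chimera(read_id, read_len, overlaps, (cr.begin, cr.end),
                           cfg.chimera_max_spanning, cfg.span_margin)
    if juncs:
        cr.flaws.extend(Flaw("chimera", (j, j)) for j in juncs)
        # largest supported region between junctions
        bounds = [cr.begin] + juncs + [cr.end]
        best = max(range(len(bounds) - 1), key=lambda i: bounds[i + 1] - bounds[i])
        cr = ClearRange(read_id, bounds[best], bounds[best + 1], "split", cr.flaws)
        if cr.end - cr.begin < cfg.trim_min_len:
            return ClearRange(read_id, 0, 0, "discarded", cr.flaws)
    return cr


def trim_reads(
    reads: list[tuple[str, str]],
    store,
    cfg: PipelineConfig,
) -> tuple[list[tuple[str, str]], dict[str, ClearRange]]:
    """Trim every read; returns surviving (id, clipped sequence) and ranges."""
    out = []
    ranges = {}
    for rid, seq in reads:
        cr = trim_read(rid, len(seq), store.get(rid), cfg)
        ranges[rid] = cr
        if cr.status != "discarded" and cr.end - cr.begin >= cfg.trim_min_len:
            out.append((rid, seq[cr.begin : cr.end]))
    n_disc = sum(1 for c in ranges.values() if c.status == "discarded")
    log.info("trimming: %d reads in, %d out, %d discarded", len(reads), len(out), n_disc)
    return out, ranges


def write_clear_ranges(path, ranges: dict[str, ClearRange]) -> None:
    with open(path, "w") as fh:
        for rid in sorted(ranges):
            c = ranges[rid]
            fh.write(f"{rid}\t{c.begin}\t{c.end}\t{c.status}\n")
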