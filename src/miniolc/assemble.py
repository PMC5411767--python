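"""Sparse best-overlap-graph assembly.

The graph keeps, per read end (5' and 3'), only the longest dovetail
overlap whose error rate passes an automatically estimated cutoff:
median + 6 MAD of the best-edge error distribution (the residual error
left after correction, trimming and overlap error adjustment). Contigs
are maximal mutual-best chains; each gets a per-window error profile
(median, MAD) used to place contained and filtered reads, absorb or label
bubbles, and — where conflicting external reads annotate a possible
repeat that no read spans and no clearly better internal overlap joins —
split the contig into flanks plus a repeat-labeled middle. The final
graph is emitted as GFA 1.0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .config import PipelineConfig
from .overlap import Overlap, end_slop
from .store import OverlapStore

log = logging.getLogger("miniolc.assemble")


# ---------------------------------------------------------------- error model

@dataclass
class ErrorModel:
    median: float
    mad: float
    cutoff: float


def estimate_error_model(
    errors: list[float], mad_multiplier: float = 6.0, floor: float = 0.005
) -> ErrorModel:
    """Global overlap error cutoff: median + 6 MAD, floored when the
    distribution degenerates (MAD ~ 0)."""
    if not len(errors):
        raise ValueError("no best edges: cannot estimate an error model")
    e = np.asarray(errors, dtype=np.float64)
    med = float(np.median(e))
    mad = float(np.median(np.abs(e - med)))
    cutoff = max(med + mad_multiplier * mad, floor)
    return ErrorModel(median=med, mad=mad, cutoff=cutoff)


# ------------------------------------------------------------------ best edges

@dataclass
class BestEdgeSet:
    five: dict[str, Overlap | None] = field(default_factory=dict)
    three: dict[str, Overlap | None] = field(default_factory=dict)
    contained: set[str] = field(default_factory=set)
    chimeric_suspect: set[str] = field(default_factory=set)
    nonmutual_suspect: set[str] = field(default_factory=set)
    unplaced: set[str] = field(default_factory=set)

    def edge(self, rid: str, end: str) -> Overlap | None:
        return (self.five if end == "5" else self.three).get(rid)

    def excluded(self) -> set[str]:
        return self.contained | self.chimeric_suspect | self.nonmutual_suspect


def _touches(o: Overlap, end: str) -> bool:
    """Does the overlap involve this end of read A?"""
    slop = end_slop(o.a_len, o.b_len)
    return o.a_start <= slop if end == "5" else o.a_end >= o.a_len - slop


def partner_end(o: Overlap, end: str) -> str:
    """The end of read B facing read A's `end` in this overlap."""
    if o.orient == "+":
        return "3" if end == "5" else "5"
    return end  # flipped alignment joins like ends


def _a_contained(o: Overlap) -> bool:
    slop = end_slop(o.a_len, o.b_len)
    return o.a_start <= slop and o.a_end >= o.a_len - slop


def find_contained(store: OverlapStore, max_error: float = 1.0) -> set[str]:
    contained = set()
    for rid in store.read_ids:
        for o in store.get(rid):
            if o.kind == "containment" and o.error <= max_error and _a_contained(o):
                # containment is mutual only for equal reads; prefer keeping
                # the longer read as container
                if o.a_len < o.b_len or (o.a_len == o.b_len and o.a_id > o.b_id):
                    contained.add(rid)
                    break
    return contained


def _best_for_end(ovs: list[Overlap], end: str, cutoff: float,
                  excluded: set[str]) -> Overlap | None:
    best = None
    for o in ovs:
        if o.kind != "dovetail" or o.error > cutoff or o.b_id in excluded:
            continue
        if not _touches(o, end):
            continue
        # longest wins; ties: lower error, then lower partner id
        if best is None or o.length > best.length or (
            o.length == best.length and (o.error, o.b_id) < (best.error, best.b_id)
        ):
            best = o
    return best


def pick_best_edges(
    store: OverlapStore,
    cutoff: float = 1.0,
    contained: set[str] | None = None,
    flagged: set[str] | None = None,
) -> BestEdgeSet:
    """Per read end, the longest qualifying dovetail overlap."""
    contained = contained or set()
    flagged = flagged or set()
    excluded = contained | flagged
    bes = BestEdgeSet(contained=set(contained))
    for rid in store.read_ids:
        if rid in excluded:
            bes.five[rid] = bes.three[rid] = None
            continue
        ovs = store.get(rid)
        bes.five[rid] = _best_for_end(ovs, "5", cutoff, excluded)
        bes.three[rid] = _best_for_end(ovs, "3", cutoff, excluded)
    return bes


def filter_suspicious_reads(
    store: OverlapStore,
    model: ErrorModel,
    read_lengths: dict[str, int],
    contained: set[str],
    nonmutual_tolerance: int = 500,
) -> tuple[set[str], set[str]]:
    """Chimeric suspects (not fully covered by sub-cutoff overlaps) and
    nonmutual suspects (best edge whose reciprocal best differs in implied
    overlap length beyond tolerance)."""
    chimeric: set[str] = set()
    for rid, ln in read_lengths.items():
        if rid in contained:
            continue
        ivals = sorted(
            (o.a_start, o.a_end) for o in store.get(rid) if o.error <= model.cutoff
        )
        slop = max(100, int(0.03 * ln))
        reach = 0
        ok = True
        for s, e in ivals:
            if s > reach + slop:
                ok = False
                break
            reach = max(reach, e)
        if not ok or reach < ln - slop or (ivals and ivals[0][0] > slop) or not ivals:
            chimeric.add(rid)

    prelim = pick_best_edges(store, model.cutoff, contained, chimeric)
    nonmutual: set[str] = set()
    for rid in store.read_ids:
        if rid in contained or rid in chimeric:
            continue
        for end in ("5", "3"):
            o = prelim.edge(rid, end)
            if o is None:
                continue
            back = prelim.edge(o.b_id, partner_end(o, end))
            if back is None:
                continue
            if back.b_id != rid and abs(back.length - o.length) > nonmutual_tolerance:
                nonmutual.add(rid)
    return chimeric, nonmutual


# -------------------------------------------------------------------- contigs

@dataclass
class LayoutRead:
    rid: str
    orient: str   # '+'/'-' in contig frame
    begin: int
    end: int
    contained: bool = False


@dataclass
class Contig:
    name: str
    layout: list[LayoutRead]
    length: int
    cls: str = "contig"                 # contig | bubble | repeat | unassembled
    repeat_intervals: list[tuple[int, int]] = field(default_factory=list)
    circular: bool = False
    consensus: str | None = None

    def read_ids(self) -> set[str]:
        return {lr.rid for lr in self.layout}


def place_partner(offA: int, orientA: str, o: Overlap) -> tuple[int, str]:
    """Contig placement (offset, orient) of read B given read A's placement
    and their overlap (a=A, b=B)."""
    orientB = o.orient if orientA == "+" else ("-" if o.orient == "+" else "+")
    if orientA == "+":
        c0 = offA + o.a_start
    else:
        c0 = offA + (o.a_len - o.a_end)
    # c0 is the contig coordinate where the overlap region starts
    if orientA == "+":
        b_lo, b_hi = (o.b_start, o.b_end) if o.orient == "+" else \
                     (o.b_len - o.b_end, o.b_len - o.b_start)
    else:
        b_lo, b_hi = (o.b_len - o.b_end, o.b_len - o.b_start) if o.orient == "+" else \
                     (o.b_start, o.b_end)
    # b_lo is the offset of the overlap start within B *as oriented in the contig*
    return c0 - b_lo, orientB


def build_contigs(best: BestEdgeSet, read_lengths: dict[str, int]) -> list[Contig]:
    """Greedy mutual-best chains, extended from each seed in both the 5'
    and 3' directions until a branch, a flagged read, or an already-used
    read stops the walk."""
    used: set[str] = set()
    contigs: list[Contig] = []
    excluded = best.excluded()

    def facing_end(orient: str, direction: str) -> str:
        # the read end pointing in `direction` ('R'ight/'L'eft) of the contig
        if direction == "R":
            return "3" if orient == "+" else "5"
        return "5" if orient == "+" else "3"

    for seed in sorted(read_lengths):
        if seed in used or seed in excluded:
            continue
        placements: dict[str, tuple[int, str]] = {seed: (0, "+")}
        order: list[str] = [seed]
        used.add(seed)
        circular = False
        for direction in ("R", "L"):
            cur = seed
            while True:
                off, orient = placements[cur]
                end = facing_end(orient, direction)
                o = best.edge(cur, end)
                if o is None:
                    break
                back = best.edge(o.b_id, partner_end(o, end))
                if back is None or back.b_id != cur:
                    break  # not mutual: branch point
                if o.b_id in placements:
                    if o.b_id == seed:
                        circular = True
                    break
                noff, norient = place_partner(off, orient, o)
                placements[o.b_id] = (noff, norient)
                used.add(o.b_id)
                order.append(o.b_id)
                cur = o.b_id
        lo = min(off for off, _ in placements.values())
        layout = [
            LayoutRead(rid, orient, off - lo, off - lo + read_lengths[rid])
            for rid, (off, orient) in placements.items()
        ]
        layout.sort(key=lambda lr: (lr.begin, lr.rid))
        length = max(lr.end for lr in layout)
        contigs.append(Contig(name="", layout=layout, length=length,
                              circular=circular))
    contigs.sort(key=lambda c: (-c.length, c.layout[0].rid))
    for i, c in enumerate(contigs):
        c.name = f"ctg{i + 1:04d}"
    return contigs


# -------------------------------------------------------------- error profiles

@dataclass
class ErrorProfile:
    window: int
    medians: np.ndarray
    mads: np.ndarray

    def tolerance(self, lo: int, hi: int, n_mads: float) -> float:
        """Max acceptable error over contig interval [lo, hi)."""
        w0 = max(0, lo // self.window)
        w1 = min(len(self.medians), hi // self.window + 1)
        if w1 <= w0:
            w0, w1 = 0, len(self.medians)
        meds = self.medians[w0:w1]
        mads = self.mads[w0:w1]
        return float(np.max(meds + n_mads * mads))


def project_interval(lr: LayoutRead, a0: int, a1: int) -> tuple[int, int]:
    """Read-forward interval [a0, a1) -> contig coordinates."""
    ln = lr.end - lr.begin
    if lr.orient == "+":
        return lr.begin + a0, lr.begin + a1
    return lr.begin + ln - a1, lr.begin + ln - a0


def compute_error_profile(
    contig: Contig, store: OverlapStore, window: int = 1000
) -> ErrorProfile:
    """Per-window (median, MAD) of the error of overlaps internal to the
    contig; empty windows inherit their nearest computed neighbor."""
    n_win = max(1, -(-contig.length // window))
    samples: list[list[float]] = [[] for _ in range(n_win)]
    by_id = {lr.rid: lr for lr in contig.layout}
    for lr in contig.layout:
        for o in store.get(lr.rid):
            if o.b_id not in by_id or o.b_id < lr.rid:
                continue
            c0, c1 = project_interval(lr, o.a_start, o.a_end)
            for w in range(max(0, c0 // window), min(n_win, c1 // window + 1)):
                samples[w].append(o.error)
    meds = np.full(n_win, np.nan)
    mads = np.full(n_win, np.nan)
    for w, vals in enumerate(samples):
        if vals:
            v = np.asarray(vals)
            meds[w] = np.median(v)
            mads[w] = np.median(np.abs(v - meds[w]))
    # inherit neighbors: forward then backward fill
    for arr in (meds, mads):
        last = np.nan
        for i in range(n_win):
            if np.isnan(arr[i]):
                arr[i] = last
            else:
                last = arr[i]
        last = np.nan
        for i in range(n_win - 1, -1, -1):
            if np.isnan(arr[i]):
                arr[i] = last
            else:
                last = arr[i]
    meds = np.nan_to_num(meds, nan=0.0)
    mads = np.nan_to_num(mads, nan=0.0)
    return ErrorProfile(window=window, medians=meds, mads=mads)


def normalize_layout(contig: Contig) -> None:
    """Shift offsets so the leftmost read starts at 0; refresh length."""
    if not contig.layout:
        return
    shift = min(lr.begin for lr in contig.layout)
    if shift:
        for lr in contig.layout:
            lr.begin -= shift
            lr.end -= shift
    contig.layout.sort(key=lambda lr: (lr.begin, lr.rid))
    contig.length = max(lr.end for lr in contig.layout)


# -------------------------------------------------------- contained placement

@dataclass
class Placement:
    contig: str
    begin: int
    end: int
    orient: str
    mean_error: float
    n_overlaps: int


def candidate_placements(
    rid: str,
    read_len: int,
    store: OverlapStore,
    contigs: list[Contig],
    exclude_contigs: set[str] = frozenset(),
) -> list[Placement]:
    """All contig placements of a read implied by its overlaps to layout
    reads, clustered by position, scored by mean overlap error."""
    layout_of: dict[str, tuple[Contig, LayoutRead]] = {}
    for c in contigs:
        if c.name in exclude_contigs:
            continue
        for lr in c.layout:
            layout_of[lr.rid] = (c, lr)
    by_contig: dict[str, list[tuple[int, str, float]]] = {}
    for o in store.get(rid):
        hit = layout_of.get(o.b_id)
        if hit is None:
            continue
        c, lr = hit
        off, orient = place_partner(lr.begin, lr.orient, o.flipped())
        by_contig.setdefault(c.name, []).append((off, orient, o.error))
    placements = []
    for cname, cands in by_contig.items():
        cands.sort()
        cluster: list[tuple[int, str, float]] = []
        for cand in cands + [(10**12, "+", 0.0)]:
            if cluster and cand[0] - cluster[-1][0] > 200:
                offs = [c[0] for c in cluster]
                errs = [c[2] for c in cluster]
                orients = [c[1] for c in cluster]
                begin = int(np.median(offs))
                placements.append(Placement(
                    contig=cname, begin=begin, end=begin + read_len,
                    orient=max(set(orients), key=orients.count),
                    mean_error=float(np.mean(errs)), n_overlaps=len(cluster),
                ))
                cluster = []
            if cand[0] < 10**12:
                cluster.append(cand)
    placements.sort(key=lambda p: (p.mean_error, p.contig, p.begin))
    return placements


def place_contained_reads(
    contigs: list[Contig],
    store: OverlapStore,
    profiles: dict[str, ErrorProfile],
    unplaced: set[str],
    read_lengths: dict[str, int],
    profile_mads: float = 5.0,
    floor: float = 0.005,
) -> tuple[list[Contig], set[str]]:
    """Place contained/filtered reads at their lowest-error accepted
    placement; placements whose mean error exceeds the local profile
    tolerance are rejected (diverged repeat or haplotype kept out)."""
    unassembled: set[str] = set()
    for rid in sorted(unplaced):
        cands = candidate_placements(rid, read_lengths[rid], store, contigs)
        placed = False
        for p in cands:
            prof = profiles.get(p.contig)
            if prof is None:
                continue
            tol = prof.tolerance(max(0, p.begin), p.end, profile_mads)
            if p.mean_error <= max(tol, floor):
                contig = next(c for c in contigs if c.name == p.contig)
                contig.layout.append(LayoutRead(
                    rid, p.orient, p.begin, p.begin + read_lengths[rid],
                    contained=True))
                placed = True
                break
        if not placed:
            unassembled.add(rid)
    for c in contigs:
        normalize_layout(c)
    return contigs, unassembled


# -------------------------------------------------------------------- bubbles

def handle_bubbles(
    contigs: list[Contig],
    store: OverlapStore,
    profiles: dict[str, ErrorProfile],
    read_lengths: dict[str, int],
    min_reads: int = 3,
    profile_mads: float = 5.0,
    floor: float = 0.005,
) -> list[Contig]:
    """Small contigs, or contigs whose reads mostly overlap another
    contig, are re-placed read-by-read; fully absorbed ones disappear,
    unplaceable ones stay labeled 'bubble'."""
    main = [c for c in contigs if c.cls == "contig"]
    out: list[Contig] = []
    for c in contigs:
        if c.cls != "contig" or len(contigs) == 1:
            out.append(c)
            continue
        rids = c.read_ids()
        other_reads = {lr.rid for k in main if k.name != c.name for lr in k.layout}
        n_external = 0
        for rid in rids:
            if any(o.b_id in other_reads for o in store.get(rid)):
                n_external += 1
        is_candidate = len(rids) < min_reads or (n_external / max(len(rids), 1)) > 0.75
        if not is_candidate:
            out.append(c)
            continue
        moved = []
        for rid in sorted(rids):
            cands = candidate_placements(rid, read_lengths[rid], store, contigs,
                                         exclude_contigs={c.name})
            accepted = None
            for p in cands:
                prof = profiles.get(p.contig)
                if prof is None:
                    continue
                if p.mean_error <= max(prof.tolerance(max(0, p.begin), p.end,
                                                      profile_mads), floor):
                    accepted = p
                    break
            if accepted is None:
                break
            moved.append((rid, accepted))
        if len(moved) == len(rids):
            for rid, p in moved:
                tgt = next(k for k in contigs if k.name == p.contig)
                tgt.layout.append(LayoutRead(rid, p.orient, p.begin,
                                             p.begin + read_lengths[rid],
                                             contained=True))
                normalize_layout(tgt)
            log.info("bubble %s absorbed (%d reads)", c.name, len(rids))
        else:
            out.append(replace(c, cls="bubble"))
    return out


# -------------------------------------------------------------- repeat splits

def _conflicting_regions(
    contig: Contig, store: OverlapStore, model: ErrorModel,
    profile: ErrorProfile, profile_mads: float,
    layout_ids: set[str],
) -> list[tuple[int, int, float]]:
    """Merged contig intervals annotated by conflicting reads.

    Two signals mark a possible collapsed or misjoined repeat:

    * a qualifying *partial* overlap from any read — the alignment ends
      interior to both the contig and the read, i.e. the read matches
      the contig over the region but indicates different boundary
      sequence; and
    * a qualifying overlap between two *layout* reads whose implied
      relative placement contradicts their actual layout positions
      (identical repeat copies collapsed at different loci).

    Returns (lo, hi, best_conflict_error) per merged region.
    """
    by_id = {lr.rid: lr for lr in contig.layout}
    raw: list[tuple[int, int, float]] = []
    for lr in contig.layout:
        for o in store.get(lr.rid):
            if o.error > model.cutoff:
                continue
            c0, c1 = project_interval(lr, o.a_start, o.a_end)
            c0, c1 = max(0, min(c0, c1)), min(contig.length, max(c0, c1))
            if c1 - c0 < 100:
                continue
            if o.error > profile.tolerance(c0, c1, profile_mads):
                continue
            partner = by_id.get(o.b_id)
            if partner is None:
                if o.kind == "partial" and (c0 > 200 or c1 < contig.length - 200):
                    raw.append((c0, c1, o.error))
            else:
                off, _ = place_partner(lr.begin, lr.orient, o)
                diff = abs(off - partner.begin)
                if contig.circular and diff > 0.6 * contig.length:
                    continue  # the closing overlap of a circular contig
                if diff > 1000:
                    raw.append((c0, c1, o.error))
    if not raw:
        return []
    raw.sort()
    merged: list[tuple[int, int, float]] = []
    lo, hi, err = raw[0]
    for s, e, x in raw[1:]:
        if s <= hi:
            hi = max(hi, e)
            err = min(err, x)
        else:
            merged.append((lo, hi, err))
            lo, hi, err = s, e, x
    merged.append((lo, hi, err))
    return merged


def split_repeats(
    contig: Contig,
    store: OverlapStore,
    model: ErrorModel,
    profile: ErrorProfile,
    repeat_margin_mads: float = 3.0,
    profile_mads: float = 5.0,
) -> list[Contig]:
    """Confirm or split candidate repeat regions.

    A region is confirmed when a layout read spans it, or when the
    internal overlap joining the layout across it has error lower than
    the best conflicting overlap by at least `repeat_margin_mads` local
    MADs. Otherwise the contig splits into left flank, repeat-labeled
    middle, and right flank.
    """
    layout_ids = contig.read_ids()
    regions = _conflicting_regions(contig, store, model, profile,
                                   profile_mads, layout_ids)
    to_split: list[tuple[int, int]] = []
    for lo, hi, conflict_err in regions:
        spanned = any(lr.begin <= lo - 50 and lr.end >= hi + 50
                      for lr in contig.layout)
        if spanned:
            continue
        # best internal join across the region
        by_id = {lr.rid: lr for lr in contig.layout}
        internal_best = None
        for lr in contig.layout:
            if lr.end <= lo or lr.begin >= hi:
                continue
            for o in store.get(lr.rid):
                if o.b_id not in by_id:
                    continue
                c0, c1 = project_interval(lr, o.a_start, o.a_end)
                if min(c1, hi) - max(c0, lo) > 0:
                    if internal_best is None or o.error < internal_best:
                        internal_best = o.error
        w_mad = float(np.median(profile.mads)) or model.mad
        margin = repeat_margin_mads * max(w_mad, 1e-4)
        if internal_best is not None and internal_best <= conflict_err - margin:
            continue  # internal join significantly better: confirmed
        to_split.append((lo, hi))
    if not to_split:
        if regions:
            contig.repeat_intervals = [(lo, hi) for lo, hi, _ in regions]
        return [contig]

    pieces: list[Contig] = []
    bounds = sorted(to_split)
    cuts: list[tuple[int, int, str]] = []
    prev = 0
    for lo, hi in bounds:
        if lo > prev:
            cuts.append((prev, lo, "contig"))
        cuts.append((lo, hi, "repeat"))
        prev = hi
    if prev < contig.length:
        cuts.append((prev, contig.length, "contig"))
    for i, (lo, hi, cls) in enumerate(cuts):
        sub = [lr for lr in contig.layout
               if min(lr.end, hi) - max(lr.begin, lo) > (lr.end - lr.begin) * 0.5
               or (lo <= lr.begin and lr.end <= hi)]
        if not sub:
            continue
        shift = min(lr.begin for lr in sub)
        layout = [LayoutRead(lr.rid, lr.orient, lr.begin - shift,
                             lr.end - shift, lr.contained) for lr in sub]
        pieces.append(Contig(
            name=f"{contig.name}.{i}", layout=layout,
            length=max(lr.end for lr in layout), cls=cls,
        ))
    log.info("%s split into %d pieces (%d repeat region(s))",
             contig.name, len(pieces), len(bounds))
    return pieces if len(pieces) >= 2 else [contig]


# ------------------------------------------------------------------------ GFA

def contig_end_links(
    contigs: list[Contig], store: OverlapStore, cutoff: float
) -> list[tuple[str, str, str, str, int]]:
    """Graph edges between contig ends from unused qualifying dovetail
    overlaps: (contig_a, ori_a, contig_b, ori_b, overlap_len)."""
    end_reads: dict[str, tuple[str, str, str]] = {}
    # read id -> (contig, which end of contig it terminates, read orient)
    for c in contigs:
        if not c.layout:
            continue
        first = c.layout[0]
        last = max(c.layout, key=lambda lr: lr.end)
        end_reads.setdefault(first.rid, (c.name, "L", first.orient))
        end_reads.setdefault(last.rid, (c.name, "R", last.orient))
    links: set[tuple[str, str, str, str, int]] = set()
    in_contig: dict[str, str] = {lr.rid: c.name for c in contigs for lr in c.layout}
    for rid, (cname, side, orient) in end_reads.items():
        for o in store.get(rid):
            if o.kind != "dovetail" or o.error > cutoff:
                continue
            tgt = end_reads.get(o.b_id)
            if tgt is None:
                continue
            cname2, side2, orient2 = tgt
            if cname2 == cname and rid == o.b_id:
                continue
            # orientation of the link ends: leaving via the Right end keeps
            # contig orientation '+', via the Left end means '-'
            ori_a = "+" if side == "R" else "-"
            ori_b = "+" if side2 == "L" else "-"
            key = (cname, ori_a, cname2, ori_b, o.length)
            rkey = (cname2, "-" if ori_b == "+" else "+",
                    cname, "-" if ori_a == "+" else "+", o.length)
            if rkey not in links and in_contig.get(rid) != in_contig.get(o.b_id, ""):
                links.add(key)
    for c in contigs:
        if c.circular:
            links.add((c.name, "+", c.name, "+", 0))
    return sorted(links)


def emit_gfa(contigs: list[Contig],
             links: list[tuple[str, str, str, str, int]]) -> str:
    """GFA 1.0 document: one S record per contig, one L per graph edge."""
    lines = ["H\tVN:Z:1.0"]
    for c in contigs:
        seq = c.consensus if c.consensus else "*"
        ln = len(c.consensus) if c.consensus else c.length
        lines.append(f"S\t{c.name}\t{seq}\tLN:i:{ln}")
    for a, oa, b, ob, olen in links:
        lines.append(f"L\t{a}\t{oa}\t{b}\t{ob}\t{olen}M")
    return "\n".join(lines) + "\n"


# ------------------------------------------------------------------- pipeline

@dataclass
class AssemblyResult:
    contigs: list[Contig]
    model: ErrorModel
    best: BestEdgeSet
    links: list[tuple[str, str, str, str, int]]
    unassembled: set[str]


def assemble(
    reads: list[tuple[str, str]],
    store: OverlapStore,
    cfg: PipelineConfig,
) -> AssemblyResult:
    """Full graph stage: error model, filters, best edges, contigs,
    profiles, contained placement, bubbles, repeat splitting, graph edges."""
    read_lengths = {r: len(s) for r, s in reads}

    contained = find_contained(store)
    initial = pick_best_edges(store, 1.0, contained)
    init_errors = [o.error for d in (initial.five, initial.three)
                   for o in d.values() if o is not None]
    model = estimate_error_model(init_errors, cfg.mad_multiplier, cfg.error_floor)
    log.info("error model: median %.4f MAD %.4f cutoff %.4f",
             model.median, model.mad, model.cutoff)

    chimeric, nonmutual = filter_suspicious_reads(
        store, model, read_lengths, contained, cfg.nonmutual_tolerance)
    best = pick_best_edges(store, model.cutoff, contained, chimeric | nonmutual)
    best.chimeric_suspect = chimeric
    best.nonmutual_suspect = nonmutual
    # final model from the filtered best edges
    errors = [o.error for d in (best.five, best.three)
              for o in d.values() if o is not None]
    if errors:
        model = estimate_error_model(errors, cfg.mad_multiplier, cfg.error_floor)

    placed_ids = set(read_lengths) - best.excluded()
    contigs = build_contigs(best, {r: read_lengths[r] for r in placed_ids})
    profiles = {c.name: compute_error_profile(c, store, cfg.window_size)
                for c in contigs}

    unplaced = contained | chimeric | nonmutual
    contigs, unassembled = place_contained_reads(
        contigs, store, profiles, unplaced, read_lengths, cfg.profile_mads,
        cfg.error_floor)
    profiles = {c.name: compute_error_profile(c, store, cfg.window_size)
                for c in contigs}

    contigs = handle_bubbles(contigs, store, profiles, read_lengths,
                             cfg.bubble_min_reads, cfg.profile_mads,
                             cfg.error_floor)

    final: list[Contig] = []
    for c in contigs:
        if c.cls != "contig":
            final.append(c)
            continue
        prof = profiles.get(c.name) or compute_error_profile(c, store, cfg.window_size)
        final.extend(split_repeats(c, store, model, prof,
                                   cfg.repeat_margin_mads, cfg.profile_mads))
    for u in sorted(unassembled):
        final.append(Contig(name=f"unasm_{u}", cls="unassembled",
                            layout=[LayoutRead(u, "+", 0, read_lengths[u])],
                            length=read_lengths[u]))
    links = contig_end_links([c for c in final if c.cls in ("contig", "repeat", "bubble")],
                             store, model.cutoff)
    return AssemblyResult(contigs=final, model=model, best=best,
                          links=links, unassembled=unassembled)


def write_layout(path, contigs: list[Contig]) -> None:
    with open(path, "w") as fh:
        for c in contigs:
            for lr in c.layout:
                fh.write(f"{c.name}\t{lr.rid}\t{lr.orient}\t{lr.begin}\t{lr.end}"
                         f"\t{c.cls}\n")
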