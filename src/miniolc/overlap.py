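"""Two-stage overlap detection.

Stage one compares weighted MinHash sketches and keeps read pairs with at
least `min_slot_matches` matching slots. Stage two merges the two reads'
bottom sketches to estimate the Jaccard similarity of the shared region,
converts it to an error rate with the Mash distance
d = -ln(2j/(1+j))/k, and estimates overlap extent and relative
orientation from the positions of shared min-mers. A banded edit-distance
overlapper (edlib) confirms candidates exactly where the downstream stage
needs true alignments (trimming, error adjustment, graph construction).

Overlap intervals are 0-based half-open on each read's forward strand
(PAF convention); orientation "-" means read B aligns reverse-complemented.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, replace

import edlib
import numpy as np

from .hashing import revcomp
from .sketch import BottomSketch, Sketch, build_bottom_sketch


@dataclass
class Overlap:
    a_id: str
    b_id: str
    a_len: int
    b_len: int
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    orient: str          # '+' same, '-' flipped
    error: float         # edit distance / alignment length
    kind: str            # 'dovetail' | 'containment'
    evidence: str        # 'sketch' | 'dp'
    align_len: int = 0

    @property
    def length(self) -> int:
        return max(self.a_end - self.a_start, self.b_end - self.b_start)

    def flipped(self) -> "Overlap":
        """The same alignment seen from read B's side."""
        return replace(
            self,
            a_id=self.b_id, b_id=self.a_id,
            a_len=self.b_len, b_len=self.a_len,
            a_start=self.b_start, a_end=self.b_end,
            b_start=self.a_start, b_end=self.a_end,
        )

    def key(self) -> tuple:
        return tuple(sorted((self.a_id, self.b_id)))


def end_slop(a_len: int, b_len: int, slop_bp: int = 100, slop_frac: float = 0.03) -> int:
    return max(slop_bp, int(slop_frac * min(a_len, b_len)))


def classify(a_len, b_len, a_start, a_end, b_start, b_end, slop,
             orient: str = "+") -> str:
    """containment: one read fully aligned; dovetail: both alignment ends
    at read ends; partial: an end interior to both reads (branching
    alignment, e.g. at a repeat boundary)."""
    a_full = a_start <= slop and a_end >= a_len - slop
    b_full = b_start <= slop and b_end >= b_len - slop
    if a_full or b_full:
        return "containment"
    # the alignment's left end (on A) pairs with B's left end for '+',
    # with B's right (forward-coordinate) end for '-'
    b_left = b_start <= slop if orient == "+" else b_end >= b_len - slop
    b_right = b_end >= b_len - slop if orient == "+" else b_start <= slop
    left_ok = a_start <= slop or b_left
    right_ok = a_end >= a_len - slop or b_right
    return "dovetail" if (left_ok and right_ok) else "partial"


def mash_distance(j: float, k: int) -> float:
    """Error-rate estimate from a Jaccard similarity (clamped to [0, 1])."""
    if j <= 0.0:
        return 1.0
    if j >= 1.0:
        return 0.0
    d = -math.log(2.0 * j / (1.0 + j)) / k
    return min(max(d, 0.0), 1.0)


def find_candidates(sketches: list[Sketch], min_slot_matches: int = 2) -> dict[tuple, int]:
    """Read-id pairs whose sketches agree in >= min_slot_matches slots.

    Returns {(id_a, id_b): n_matching_slots} with id_a < id_b. Symmetric by
    construction; self-pairs excluded.
    """
    if not sketches:
        return {}
    ref = (sketches[0].s, sketches[0].k, sketches[0].seed)
    for sk in sketches:
        if (sk.s, sk.k, sk.seed) != ref:
            raise ValueError("sketches built with mixed parameters")
    entries = np.stack([sk.entries for sk in sketches])  # (n, s)
    ids = [sk.read_id for sk in sketches]
    counts: Counter = Counter()
    n, s = entries.shape
    for slot in range(s):
        col = entries[:, slot]
        order = np.argsort(col, kind="stable")
        vals = col[order]
        boundaries = np.flatnonzero(np.diff(vals)) + 1
        start = 0
        for stop in list(boundaries) + [n]:
            if stop - start > 1:
                grp = sorted(order[start:stop])
                for i in range(len(grp)):
                    for j in range(i + 1, len(grp)):
                        counts[(ids[grp[i]], ids[grp[j]])] += 1
            start = stop
    return {
        tuple(sorted(p)): c for p, c in counts.items() if c >= min_slot_matches
    }


def estimate_overlap(a: BottomSketch, b: BottomSketch, k: int,
                     min_shared: int = 3, min_overlap: int = 500) -> Overlap | None:
    """Sketch-estimated overlap from two bottom sketches.

    Orientation comes from the sign of the position trend of shared
    min-mers; the extent from the median alignment diagonal; the error
    rate from the Mash distance of the Jaccard estimated over min-mers
    restricted to the shared region.
    """
    if a.k != b.k or a.k != k:
        raise ValueError("bottom sketches built with different k")
    shared = np.intersect1d(a.values, b.values, assume_unique=True)
    if len(shared) < min_shared:
        return None
    pa = a.positions[np.searchsorted(a.values, shared)].astype(np.float64)
    pb = b.positions[np.searchsorted(b.values, shared)].astype(np.float64)
    if len(shared) >= 2 and np.std(pa) > 0 and np.std(pb) > 0:
        orient = "+" if np.corrcoef(pa, pb)[0, 1] >= 0 else "-"
    else:
        orient = "+"
    # work in the frame where B is oriented like A
    pb2 = pb if orient == "+" else (b.length - k) - pb
    diag = float(np.median(pa - pb2))
    a0 = int(max(0, round(diag)))
    a1 = int(min(a.length, b.length + round(diag)))
    if a1 - a0 < min_overlap:
        return None
    b0o, b1o = a0 - int(round(diag)), a1 - int(round(diag))
    # local Jaccard: min-mers restricted to the estimated shared region
    in_a = (a.positions >= a0) & (a.positions < a1)
    posb_all = b.positions if orient == "+" else (b.length - k) - b.positions
    in_b = (posb_all >= b0o) & (posb_all < b1o)
    va, vb = a.values[in_a], b.values[in_b]
    s = min(len(va), len(vb))
    if s < min_shared:
        return None
    union = np.union1d(va, vb)[:s]
    sh = np.intersect1d(va, vb, assume_unique=False)
    j = len(np.intersect1d(sh, union, assume_unique=False)) / s
    err = mash_distance(j, k)
    if orient == "+":
        b0, b1 = b0o, b1o
    else:
        b0, b1 = b.length - b1o, b.length - b0o
    slop = end_slop(a.length, b.length)
    kind = classify(a.length, b.length, a0, a1, b0, b1, slop, orient)
    return Overlap(a.read_id, b.read_id, a.length, b.length,
                   a0, a1, b0, b1, orient, err, kind, "sketch",
                   align_len=a1 - a0)


def _refine_diag(a_seq: str, b_or: str, a0: int, a1: int, diag: int) -> int:
    """Refine the alignment diagonal with a small anchored HW alignment."""
    mid = (a0 + a1) // 2
    half = min(300, (a1 - a0) // 2)
    qa = a_seq[mid - half : mid + half]
    pad = max(200, int(0.2 * (a1 - a0)))
    t0 = max(0, mid - half - diag - pad)
    t1 = min(len(b_or), mid + half - diag + pad)
    if len(qa) < 50 or t1 - t0 < len(qa):
        return diag
    res = edlib.align(qa, b_or[t0:t1], mode="HW", task="locations")
    if res["editDistance"] < 0 or not res["locations"]:
        return diag
    loc = res["locations"][0]
    return (mid - half) - (t0 + loc[0])


_TRIM_WINDOW = 200   # alignment columns per trimming window
_TRIM_STRIDE = 50
_TRIM_MAX_ERR = 0.30  # windows above this are alignment overhang, not overlap


def _trim_threshold(expected_error: float) -> float:
    """Window-error threshold separating genuine (noisy) overlap from
    alignment overhang (random sequence: ~0.5 error/column). Scales with
    the expected pairwise error so that low-error overlaps are clipped
    tightly (a window half across a chimeric junction must not pass) while
    raw-read overlaps at ~20% pairwise error still qualify."""
    return min(0.45, 0.08 + 1.5 * expected_error)


def _trim_alignment(cigar: str, max_err: float = _TRIM_MAX_ERR):
    """Clip terminal low-identity stretches off a global alignment.

    A true overlap that ends inside both reads (e.g. at a repeat
    boundary) appears as a diagonal alignment whose flanks degrade to
    random-sequence identity (~50% error per column); windows above
    _TRIM_MAX_ERR are clipped. Returns query/target offsets of the kept
    core, its edit distance and its length — or None if nothing survives.
    """
    from .dagcon import _parse_cigar  # shared CIGAR machinery

    ops, lens = _parse_cigar(cigar)
    op_arr = np.repeat(ops, lens)
    n = len(op_arr)
    mism = (op_arr != 0).astype(np.int32)
    if n <= _TRIM_WINDOW:
        starts = np.array([0])
        win_err = np.array([mism.mean()])
    else:
        cum = np.concatenate(([0], np.cumsum(mism)))
        starts = np.arange(0, n - _TRIM_WINDOW + 1, _TRIM_STRIDE)
        win_err = (cum[starts + _TRIM_WINDOW] - cum[starts]) / _TRIM_WINDOW
    good = win_err <= max_err
    if not good.any():
        return None
    # longest run of good windows
    padded = np.concatenate(([False], good, [False]))
    d = np.diff(padded.astype(np.int8))
    runs = list(zip(np.flatnonzero(d == 1), np.flatnonzero(d == -1)))
    r0, r1 = max(runs, key=lambda r: r[1] - r[0])
    c0 = int(starts[r0])
    c1 = int(min(n, starts[r1 - 1] + _TRIM_WINDOW))
    q_cons = ((op_arr == 0) | (op_arr == 1) | (op_arr == 2)).astype(np.int64)
    t_cons = ((op_arr == 0) | (op_arr == 1) | (op_arr == 3)).astype(np.int64)
    qc = np.concatenate(([0], np.cumsum(q_cons)))
    tc = np.concatenate(([0], np.cumsum(t_cons)))
    dist = int(mism[c0:c1].sum())
    return int(qc[c0]), int(qc[c1]), int(tc[c0]), int(tc[c1]), dist, c1 - c0


def dp_overlap(a_id: str, a_seq: str, b_id: str, b_seq: str,
               hint: Overlap | None = None, k: int = 16,
               min_overlap: int = 500, max_error: float = 0.5,
               slop_bp: int = 100, slop_frac: float = 0.03) -> Overlap | None:
    """Gapped-alignment-confirmed overlap.

    Uses the sketch-estimated overlap (or computes one if absent) as a
    seed, refines the diagonal with an anchored alignment, extends to the
    maximal extent that the diagonal permits, and reports the exact
    edit-distance error over a global alignment of the shared region.
    """
    if hint is None:
        ba = build_bottom_sketch(a_id, a_seq, k)
        bb = build_bottom_sketch(b_id, b_seq, k)
        hint = estimate_overlap(ba, bb, k, min_overlap=min_overlap)
        if hint is None:
            return None
    if hint.a_id != a_id:  # hint given from B's perspective
        hint = hint.flipped()
    la, lb = len(a_seq), len(b_seq)
    orient = hint.orient
    b_or = b_seq if orient == "+" else revcomp(b_seq)
    if orient == "+":
        diag = hint.a_start - hint.b_start
    else:
        diag = hint.a_start - (lb - hint.b_end)
    diag = _refine_diag(a_seq, b_or, max(0, diag), min(la, lb + diag), diag)
    a0 = max(0, diag)
    a1 = min(la, lb + diag)
    if a1 - a0 < min_overlap:
        return None
    b0o, b1o = a0 - diag, a1 - diag
    res = edlib.align(a_seq[a0:a1], b_or[b0o:b1o], mode="NW", task="path")
    if res["editDistance"] < 0:
        return None
    trimmed = _trim_alignment(res["cigar"], _trim_threshold(hint.error))
    if trimmed is None:
        return None
    q_off0, q_off1, t_off0, t_off1, dist, align_len = trimmed
    a0t, a1t = a0 + q_off0, a0 + q_off1
    b0t, b1t = b0o + t_off0, b0o + t_off1
    if min(a1t - a0t, b1t - b0t) < min_overlap:
        return None
    err = dist / max(align_len, 1)
    if err > max_error:
        return None
    if orient == "+":
        b0, b1 = b0t, b1t
    else:
        b0, b1 = lb - b1t, lb - b0t
    slop = end_slop(la, lb, slop_bp, slop_frac)
    kind = classify(la, lb, a0t, a1t, b0, b1, slop, orient)
    return Overlap(a_id, b_id, la, lb, a0t, a1t, b0, b1, orient, err, kind, "dp",
                   align_len=align_len)


# ------------------------------------------------------------------- PAF I/O

def write_paf(path, overlaps: list[Overlap]) -> None:
    with open(path, "w") as fh:
        for o in overlaps:
            nmatch = int(round((1.0 - o.error) * o.align_len))
            fh.write(
                f"{o.a_id}\t{o.a_len}\t{o.a_start}\t{o.a_end}\t{o.orient}\t"
                f"{o.b_id}\t{o.b_len}\t{o.b_start}\t{o.b_end}\t"
                f"{nmatch}\t{o.align_len}\t255\t"
                f"er:f:{o.error:.6f}\tkd:Z:{o.kind}\tev:Z:{o.evidence}\n"
            )


def read_paf(path) -> list[Overlap]:
    out = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            tags = dict(t.split(":", 2)[::2] for t in f[12:])
            out.append(Overlap(
                a_id=f[0], a_len=int(f[1]), a_start=int(f[2]), a_end=int(f[3]),
                orient=f[4], b_id=f[5], b_len=int(f[6]),
                b_start=int(f[7]), b_end=int(f[8]),
                error=float(tags.get("er", 0.0)),
                kind=tags.get("kd", "dovetail"),
                evidence=tags.get("ev", "dp"),
                align_len=int(f[10]),
            ))
    return out


# ------------------------------------------------------ convenience pipeline

def overlap_read_set(
    reads: list[tuple[str, str]],
    spectrum,
    params,
    s: int = 512,
    k: int = 16,
    seed: int = 1,
    bottom_size: int = 1500,
    min_slot_matches: int = 2,
    min_overlap: int = 500,
    confirm: bool = False,
    weighting: str = "tfidf",
    max_kmer_count: int = 0,
    max_error: float = 0.5,
) -> list[Overlap]:
    """All-vs-all overlaps of a read set (one record per unordered pair)."""
    from .sketch import build_sketch  # local import to avoid cycle at module load

    seqs = dict(reads)
    sketches = [
        build_sketch(r, q, s, spectrum, params, seed=seed, k=k,
                     weighting=weighting, max_kmer_count=max_kmer_count)
        for r, q in reads if len(q) >= k
    ]
    cands = find_candidates(sketches, min_slot_matches)
    bottoms = {r: build_bottom_sketch(r, q, k, bottom_size)
               for r, q in reads if len(q) >= k}
    out = []
    for (ra, rb) in sorted(cands):
        est = estimate_overlap(bottoms[ra], bottoms[rb], k, min_overlap=min_overlap)
        if est is None:
            continue
        if confirm:
            ov = dp_overlap(ra, seqs[ra], rb, seqs[rb], hint=est, k=k,
                            min_overlap=min_overlap, max_error=max_error)
            if ov is None:
                continue
            out.append(ov)
        else:
            out.append(est)
    return out
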