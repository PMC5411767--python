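"""Overlap error adjustment.

A two-pass majority vote that separates residual sequencing errors from
true sequence differences (diverged repeat copies, haplotypes). Pass one
aligns every partner to each read and proposes base edits where the
read disagrees with a strict majority of covering partners *and* fewer
than a support fraction agree with the read — so a genuine variant shared
by a subpopulation of partners (e.g. same-repeat-copy reads) is
preserved. The read sequences themselves are never rewritten: pass two
applies the edits to temporary copies of both reads of each overlap,
realigns, and replaces the stored error rate with the error the overlap
would have had were the sequencing errors resolved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import edlib
import numpy as np

from .config import PipelineConfig
from .dagcon import VoteAccumulator
from .hashing import revcomp
from .overlap import Overlap
from .store import OverlapStore, build_store_from_overlaps

log = logging.getLogger("miniolc.adjust")


@dataclass(frozen=True)
class Edit:
    read_id: str
    pos: int        # position on the read's forward strand
    src: str        # read base, or '-' for a missing base (insertion edit)
    dst: str        # replacement base, or '-' for a deletion edit


def _oriented_partner_clip(o: Overlap, partner_seq: str, pad: int = 30) -> str:
    seq = partner_seq if o.orient == "+" else revcomp(partner_seq)
    if o.orient == "+":
        b0, b1 = o.b_start, o.b_end
    else:
        b0, b1 = o.b_len - o.b_end, o.b_len - o.b_start
    return seq[max(0, b0 - pad) : b1 + pad]


def vote_errors(
    read_id: str,
    read_seq: str,
    overlaps: list[Overlap],
    seqs: dict[str, str],
    min_support: float = 0.25,
    min_depth: int = 3,
) -> list[Edit]:
    """Proposed edits for one read from its overlapping alignments.

    An edit is proposed at a column when the read's symbol disagrees with
    a strict majority of covering partners and fewer than `min_support` of
    them agree with the read. Balanced columns (diverged copies,
    heterozygous sites) are preserved.
    """
    acc = VoteAccumulator(read_seq)
    for o in overlaps:
        if o.a_id != read_id:
            o = o.flipped()
        acc.add_aligned(_oriented_partner_clip(o, seqs[o.b_id]),
                        o.a_start, o.a_end)
    if acc.kept == 0:
        return []
    votes = acc.votes
    coverage = votes.sum(axis=1)
    tcodes = acc.tcodes
    T = acc.T
    best = np.argmax(votes, axis=1)
    best_w = votes[np.arange(T), best]
    own_w = votes[np.arange(T), tcodes]
    edits: list[Edit] = []
    eligible = (
        (coverage >= min_depth)
        & (best != tcodes)
        & (best_w * 2 > coverage)                 # strict majority disagrees
        & (own_w < np.ceil(min_support * coverage))  # little support for the read
    )
    bases = "ACGT-"
    for t in np.flatnonzero(eligible):
        edits.append(Edit(read_id, int(t), read_seq[t], bases[best[t]]))
    # insertion edits: a majority of partners carry a base the read lacks
    for (tpos, slot, base), cnt in acc.insertion_counts().items():
        if slot != 0:
            continue  # single-base resolution is enough for error adjustment
        cov = coverage[tpos]
        if cov >= min_depth and cnt * 2 > cov:
            edits.append(Edit(read_id, int(tpos), "-", "ACGT"[base]))
    edits.sort(key=lambda e: (e.pos, e.src, e.dst))
    return edits


def apply_edits(seq: str, edits: list[Edit], lo: int = 0, hi: int | None = None) -> str:
    """Edited copy of seq[lo:hi] (edits outside the window ignored)."""
    hi = len(seq) if hi is None else hi
    sub = list(seq[lo:hi])
    for e in sorted(edits, key=lambda e: -e.pos):
        p = e.pos - lo
        if not 0 <= p < len(sub) + (1 if e.src == "-" else 0):
            continue
        if e.src == "-":                     # insert before p
            sub.insert(p, e.dst)
        elif e.dst == "-":                   # delete
            if p < len(sub):
                del sub[p]
        else:                                # substitute
            if p < len(sub):
                sub[p] = e.dst
    return "".join(sub)


def recompute_error_rates(
    store: OverlapStore,
    seqs: dict[str, str],
    edits_by_read: dict[str, list[Edit]],
) -> OverlapStore:
    """Replace each overlap's error rate with the post-edit alignment error.

    Both reads' proposed edits are applied to temporary copies of the
    overlapping substrings; intervals are unchanged.
    """
    seen: dict[tuple, float] = {}
    new_records: list[Overlap] = []
    for o in store.records:
        key = o.key() + (min(o.a_start, o.b_start),)
        if key in seen:
            new_records.append(replace(o, error=seen[key]))
            continue
        ea = edits_by_read.get(o.a_id, [])
        eb = edits_by_read.get(o.b_id, [])
        if not ea and not eb:
            seen[key] = o.error
            new_records.append(o)
            continue
        sub_a = apply_edits(seqs[o.a_id], ea, o.a_start, o.a_end)
        sub_b_f = apply_edits(seqs[o.b_id], eb, o.b_start, o.b_end)
        sub_b = sub_b_f if o.orient == "+" else revcomp(sub_b_f)
        res = edlib.align(sub_a, sub_b, mode="NW", task="distance")
        align_len = max(len(sub_a), len(sub_b))
        err = res["editDistance"] / max(align_len, 1)
        seen[key] = err
        new_records.append(replace(o, error=err))
    return build_store_from_overlaps(new_records, duplicate=False)


def adjust_store(
    reads: list[tuple[str, str]],
    store: OverlapStore,
    cfg: PipelineConfig,
) -> tuple[OverlapStore, dict[str, list[Edit]]]:
    """Both passes: vote edits per read, then recompute all error rates."""
    seqs = dict(reads)
    edits_by_read: dict[str, list[Edit]] = {}
    for rid, seq in reads:
        ovs = store.get(rid)
        if not ovs:
            continue
        ed = vote_errors(rid, seq, ovs, seqs,
                         cfg.adjust_min_support, cfg.adjust_min_depth)
        if ed:
            edits_by_read[rid] = ed
    n_edits = sum(len(v) for v in edits_by_read.values())
    log.info("error adjustment: %d proposed edits on %d reads",
             n_edits, len(edits_by_read))
    return recompute_error_rates(store, seqs, edits_by_read), edits_by_read


def write_edits(path, edits_by_read: dict[str, list[Edit]]) -> None:
    with open(path, "w") as fh:
        for rid in sorted(edits_by_read):
            for e in edits_by_read[rid]:
                fh.write(f"{e.read_id}\t{e.pos}\t{e.src}\t{e.dst}\n")
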