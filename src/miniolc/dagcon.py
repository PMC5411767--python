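"""Alignment-DAG consensus shared by read correction and contig consensus.

Evidence sequences are aligned to a template with a banded edit-distance
aligner (edlib). Each alignment contributes weighted edges to a DAG whose
nodes are (template position, symbol): a match/mismatch votes for a base
at that column, a deletion votes for a gap, and inserted bases vote for
insertion slots between columns. The consensus is the highest-weight path:
per column the best-supported symbol, with insertions accepted when a
majority of covering sequences contain them.

For correction, columns where every parallel edge has weight below
`min_weight` (default 4) split the output into separate pieces; pieces
shorter than `min_piece` are dropped. For contig consensus the template
itself guarantees a continuous path (min_weight=1, ties broken toward the
template base).
"""

from __future__ import annotations

import re

import edlib
import numpy as np

from .hashing import decode, encode

_GAP = 4
_MAX_INS = 8  # insertion slots tracked between adjacent columns


_OP_LUT = np.zeros(256, dtype=np.int8)
for _o, _c in zip(b"=XID M", (0, 1, 2, 3, 0, 0)):
    _OP_LUT[_o] = _c
_NUM_RE = re.compile(r"\d+")
_OPS_RE = re.compile(r"[=XIDM]")


def _parse_cigar(cigar: str) -> tuple[np.ndarray, np.ndarray]:
    lens = np.array(_NUM_RE.findall(cigar), dtype=np.int64)
    ops = _OP_LUT[np.frombuffer("".join(_OPS_RE.findall(cigar)).encode(), dtype=np.uint8)]
    return ops, lens


def align_to_template(template: str, seq: str, start_hint: int | None = None,
                      end_hint: int | None = None, margin: int = 200):
    """Locate and align `seq` within a template window.

    Returns (t_start, (ops, lens), identity) — the CIGAR pre-parsed into
    op-code and run-length arrays — or None when edlib finds no alignment.
    edlib CIGARs are SAM-style with `seq` as the query: 'I' consumes the
    query, 'D' the template.
    """
    lo = 0 if start_hint is None else max(0, start_hint - margin)
    hi = len(template) if end_hint is None else min(len(template), end_hint + margin)
    window = template[lo:hi]
    if not window or not seq:
        return None
    res = edlib.align(seq, window, mode="HW", task="path")
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    t0, t1 = res["locations"][0]
    ops, lens = _parse_cigar(res["cigar"])
    identity = 1.0 - res["editDistance"] / max(int(lens.sum()), 1)
    return lo + t0, (ops, lens), identity


class VoteAccumulator:
    """Column votes of evidence alignments against a template.

    votes[t] holds weights for (A, C, G, T, gap) at template column t;
    insertion votes are keyed (t, slot, base) for query bases absent from
    the template, slot being the index within the insertion run.
    """

    def __init__(self, template: str):
        self.T = len(template)
        self.template = template
        self.tcodes = encode(template)
        self.votes = np.zeros((self.T, 5), dtype=np.int32)
        self._ins_keys: list[np.ndarray] = []
        self.kept = 0

    def add(self, seq: str, t_start: int, parsed, weight: int = 1) -> None:
        ops, lens = parsed
        n = int(lens.sum())
        op_arr = np.repeat(ops, lens)
        # edlib CIGAR is SAM-style with the evidence as query:
        # '=' 'X' consume both; 'I' consumes the query; 'D' the template.
        q_adv = (op_arr == 0) | (op_arr == 1) | (op_arr == 2)
        t_adv = (op_arr == 0) | (op_arr == 1) | (op_arr == 3)
        q_idx = np.cumsum(q_adv) - q_adv
        t_idx = t_start + np.cumsum(t_adv) - t_adv
        qcodes = encode(seq)
        votes = self.votes
        mm = (op_arr == 0) | (op_arr == 1)
        if mm.any():
            np.add.at(votes, (t_idx[mm], qcodes[q_idx[mm]]), weight)
        dl = op_arr == 3  # template base skipped by query -> gap vote
        if dl.any():
            np.add.at(votes, (t_idx[dl], np.full(int(dl.sum()), _GAP)), weight)
        ins = op_arr == 2  # query base absent from template -> insertion slot
        if ins.any():
            idx = np.arange(n)
            run_start = np.where(ins & ~np.roll(ins, 1), idx, -1)
            run_start[0] = idx[0] if ins[0] else -1
            run_start = np.maximum.accumulate(run_start)
            kth = (idx - run_start)[ins]
            keep = kth < _MAX_INS
            tpos = np.minimum(t_idx[ins][keep], self.T - 1)
            key = (tpos.astype(np.int64) * _MAX_INS + kth[keep]) * 4 + qcodes[q_idx[ins][keep]]
            self._ins_keys.append(np.repeat(key, weight))

    def add_aligned(self, seq: str, s_hint=None, e_hint=None,
                    min_identity: float = 0.0, margin: int = 200) -> bool:
        loc = align_to_template(self.template, seq, s_hint, e_hint, margin)
        if loc is None:
            return False
        t0, parsed, ident = loc
        if ident < min_identity:
            return False
        self.add(seq, t0, parsed)
        self.kept += 1
        return True

    def insertion_counts(self) -> dict[tuple[int, int, int], int]:
        """{(template_pos, slot, base): weight} for all insertion votes."""
        if not self._ins_keys:
            return {}
        allk = np.concatenate(self._ins_keys)
        uk, uc = np.unique(allk, return_counts=True)
        out = {}
        for key, cnt in zip(uk, uc):
            base = int(key % 4)
            slot = int((key // 4) % _MAX_INS)
            tpos = int(key // (4 * _MAX_INS))
            out[(tpos, slot, base)] = int(cnt)
        return out


def consensus_pieces(
    template: str,
    evidence: list[tuple[str, int | None, int | None]],
    min_weight: int = 4,
    min_piece: int = 500,
    min_identity: float = 0.0,
    include_template: bool = True,
    template_weight: int = 1,
    margin: int = 200,
    trim_template_only_ends: bool = False,
) -> list[tuple[str, int, int]]:
    """Consensus of evidence aligned to a template.

    `evidence` holds (sequence, approx_template_start, approx_template_end)
    with None hints meaning "search the whole template". Returns
    [(sequence, template_start, template_end)] pieces, ordered along the
    template. Evidence that fails to align, or aligns below
    `min_identity`, is excluded.
    """
    acc = VoteAccumulator(template)
    if include_template:
        acc.add(template, 0, _parse_cigar(f"{len(template)}="), weight=template_weight)
    for seq, s_hint, e_hint in evidence:
        acc.add_aligned(seq, s_hint, e_hint, min_identity, margin)

    T = acc.T
    votes = acc.votes
    coverage = votes.sum(axis=1)
    tie = votes.astype(np.float64)
    tie[np.arange(T), acc.tcodes] += 0.25  # break exact ties toward the template
    best = np.argmax(tie, axis=1)
    best_w = votes[np.arange(T), best]
    split = best_w < min_weight
    if trim_template_only_ends:
        # terminal template overhang no evidence reaches (e.g. trailing
        # read noise at a contig end) is unpolishable: drop it
        supported = np.flatnonzero(coverage > template_weight)
        if len(supported):
            split[: supported[0]] = True
            split[supported[-1] + 1 :] = True
        else:
            split[:] = True

    # accepted insertions: majority of covering sequences, and min_weight
    accepted_ins: dict[int, list[tuple[int, int]]] = {}
    for (tpos, slot, base), cnt in acc.insertion_counts().items():
        need = max(min_weight, coverage[tpos] // 2 + 1)
        if cnt >= need:
            accepted_ins.setdefault(tpos, []).append((slot, base))

    pieces: list[tuple[str, int, int]] = []
    out: list[int] = []
    piece_start = 0

    def flush(end_t: int) -> None:
        nonlocal out, piece_start
        if out and len(out) >= 1:
            seq = decode(np.array(out, dtype=np.uint8))
            if len(seq) >= min_piece:
                pieces.append((seq, piece_start, end_t))
        out = []

    in_piece = False
    for t in range(T):
        if split[t]:
            if in_piece:
                flush(t)
                in_piece = False
            continue
        if not in_piece:
            piece_start = t
            in_piece = True
        for _slot, base in sorted(accepted_ins.get(t, [])):
            out.append(base)
        if best[t] != _GAP:
            out.append(int(best[t]))
    if in_piece:
        flush(T)
    return pieces


def consensus_sequence(template: str, evidence, min_identity: float = 0.7,
                       margin: int = 500, rounds: int = 2) -> str:
    """Single-path consensus (contig polishing): no splitting, template
    carries the path through uncovered columns.

    Runs `rounds` passes: indel placement in pairwise alignments wobbles
    against a noisy template, splitting votes across adjacent columns; a
    second pass against the round-one consensus aligns consistently and
    recovers those columns.
    """
    current = template
    for _ in range(max(rounds, 1)):
        pieces = consensus_pieces(
            current, evidence, min_weight=1, min_piece=1,
            min_identity=min_identity, include_template=True, margin=margin,
            trim_template_only_ends=True,
        )
        new = "".join(p[0] for p in pieces)
        if not new or new == current:
            break
        current = new
    return current
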