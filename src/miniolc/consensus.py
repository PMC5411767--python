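"""Contig consensus: template splicing plus DAG consensus.

A template is spliced from the layout reads at their approximate offsets
(accurate within reads — they are error-corrected — but with possible
indel error at read junctions), then every layout read is realigned to
its template region and merged into the shared alignment-DAG; the
highest-weight path repairs the junctions.
"""

from __future__ import annotations

import logging

from .assemble import Contig
from .dagcon import consensus_sequence
from .hashing import revcomp

log = logging.getLogger("miniolc.consensus")


def oriented(seq: str, orient: str) -> str:
    return seq if orient == "+" else revcomp(seq)


def build_template(contig: Contig, seqs: dict[str, str]) -> tuple[str, dict[str, int]]:
    """Template sequence + per-read anchor offsets.

    Walks the backbone layout left to right; each read contributes its
    non-redundant extension beyond the current template end.
    """
    backbone = [lr for lr in contig.layout if not lr.contained]
    if not backbone:
        backbone = contig.layout
    backbone = sorted(backbone, key=lambda lr: (lr.begin, lr.rid))
    template_parts: list[str] = []
    anchors: dict[str, int] = {}
    cur_end = 0
    for lr in backbone:
        s = oriented(seqs[lr.rid], lr.orient)
        anchors[lr.rid] = lr.begin
        if not template_parts:
            template_parts.append(s)
            cur_end = lr.begin + len(s)
            continue
        if lr.end <= cur_end:
            continue  # no new sequence
        within = cur_end - lr.begin
        if within < 0:
            # layout gap (should not happen on a connected backbone): pad
            # is not possible without sequence; just concatenate
            within = 0
        template_parts.append(s[within:])
        cur_end = lr.begin + len(s)
    return "".join(template_parts), anchors


def contig_consensus(
    contig: Contig,
    seqs: dict[str, str],
    min_identity: float = 0.7,
    margin: int = 500,
) -> str:
    """Consensus sequence for one contig.

    All layout reads (backbone and contained) are aligned to their
    approximate template region and merged into the DAG; reads failing to
    align at `min_identity` are excluded.
    """
    if len(contig.layout) == 1:
        lr = contig.layout[0]
        return oriented(seqs[lr.rid], lr.orient)
    template, _anchors = build_template(contig, seqs)
    evidence = []
    for lr in sorted(contig.layout, key=lambda lr: (lr.begin, lr.rid)):
        evidence.append((oriented(seqs[lr.rid], lr.orient), lr.begin, lr.end))
    cons = consensus_sequence(template, evidence, min_identity=min_identity,
                              margin=margin)
    return cons if cons else template


def coverage_track(contig: Contig) -> list[tuple[int, int]]:
    """Per-base read depth along the contig layout, run-length encoded as
    (start_position, depth) breakpoints (wiggle-style)."""
    events: dict[int, int] = {}
    for lr in contig.layout:
        events[lr.begin] = events.get(lr.begin, 0) + 1
        events[lr.end] = events.get(lr.end, 0) - 1
    depth = 0
    track = []
    for pos in sorted(events):
        depth += events[pos]
        track.append((pos, depth))
    return track


def write_coverage(path, contigs: list[Contig]) -> None:
    with open(path, "w") as fh:
        for c in contigs:
            for pos, depth in coverage_track(c):
                fh.write(f"{c.name}\t{pos}\t{depth}\n")


def consensus_all(contigs: list[Contig], seqs: dict[str, str]) -> None:
    """Fill every contig's `consensus` attribute in place."""
    for c in contigs:
        c.consensus = contig_consensus(c, seqs)
        log.debug("%s consensus %d bp from %d reads",
                  c.name, len(c.consensus), len(c.layout))
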