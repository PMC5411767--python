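"""Hierarchical read correction.

Overlap evidence is filtered twice before consensus: a *global* filter
where each read donates evidence to at most C partners (its top-C overlaps
by length x identity, C being the expected read depth) — clustering
repetitive reads with partners likely from the same repeat copy — and a
*local* filter where each target read accepts at most 2C donated overlaps,
best by the same score. Corrected lengths are estimated from evidence
coverage, the longest reads up to a target output coverage are corrected,
and each is rebuilt by DAG consensus over its aligned evidence; columns
with insufficient evidence (weight < 4) split the read.

Evidence is scored with gapped-alignment-confirmed error rates: at a few
percent copy divergence the sketch-estimated error is too noisy to keep a
repeat read's evidence on its own copy, and mixed evidence would erase
the copy-specific variants the global filter exists to protect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from . import dagcon
from .config import PipelineConfig
from .hashing import revcomp
from .overlap import Overlap
from .sketch import TfIdfParams, count_kmers
from .store import OverlapStore, build_store_from_overlaps

log = logging.getLogger("miniolc.correct")


def overlap_score(o: Overlap) -> float:
    """overlap_length * identity."""
    return o.length * (1.0 - o.error)


def _score_key(o: Overlap) -> tuple:
    # descending score, then longer overlap, then lower partner id
    return (-overlap_score(o), -o.length, o.b_id)


def _error_score_key(o: Overlap) -> tuple:
    # lowest error first, then longer overlap, then lower partner id
    return (o.error, -o.length, o.b_id)


def score_key_for(mode: str):
    """Donation ranking: 'length_identity' is the classic score; 'error'
    ranks by alignment error first, which at short read lengths separates
    repeat copies far better (the length term otherwise swamps a
    few-percent identity gap)."""
    if mode == "error":
        return _error_score_key
    return _score_key


@dataclass
class CorrectionPlan:
    C: int
    donations: dict[str, list[Overlap]] = field(default_factory=dict)   # donor -> overlaps (a=donor)
    accepted: dict[str, list[Overlap]] = field(default_factory=dict)    # target -> overlaps (a=target)
    estimated_lengths: dict[str, int] = field(default_factory=dict)
    uncorrectable: set[str] = field(default_factory=set)


def global_filter(store: OverlapStore, C: int,
                  score: str = "length_identity") -> dict[str, list[Overlap]]:
    """Each read keeps its top-C overlaps as the partners it will help correct."""
    if C < 1:
        raise ValueError("C must be >= 1")
    key = score_key_for(score)
    donations: dict[str, list[Overlap]] = {}
    for rid in store.read_ids:
        ovs = sorted(store.get(rid), key=key)
        donations[rid] = ovs[:C]
    return donations


def local_filter(donations: dict[str, list[Overlap]], C: int,
                 score: str = "length_identity") -> dict[str, list[Overlap]]:
    """Each target accepts at most 2C donated overlaps, best by score.

    Donated overlap (a=donor, b=target) becomes an evidence record seen
    from the target (a=target, b=donor).
    """
    key = score_key_for(score)
    received: dict[str, list[Overlap]] = {}
    for donor, ovs in donations.items():
        for o in ovs:
            received.setdefault(o.b_id, []).append(o.flipped())
    accepted = {}
    for target, ovs in received.items():
        ovs.sort(key=key)
        accepted[target] = ovs[: 2 * C]
    return accepted


def estimate_corrected_lengths(
    accepted: dict[str, list[Overlap]],
    read_lengths: dict[str, int],
    min_depth: int = 2,
) -> dict[str, int]:
    """Expected corrected length: bases covered by >= min_depth evidence."""
    out = {}
    for rid, ln in read_lengths.items():
        ovs = accepted.get(rid, [])
        if not ovs:
            out[rid] = 0
            continue
        events: list[tuple[int, int]] = []
        for o in ovs:
            events.append((o.a_start, 1))
            events.append((o.a_end, -1))
        events.sort()
        depth = 0
        covered = 0
        prev = 0
        for pos, d in events:
            if depth >= min_depth:
                covered += pos - prev
            prev = pos
            depth += d
        out[rid] = covered
    return out


def select_longest(
    estimates: dict[str, int], target_coverage: float, genome_size: int
) -> list[str]:
    """Greedy selection of reads by descending estimated corrected length
    until the cumulative bases reach target_coverage x genome_size."""
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    target = target_coverage * genome_size
    chosen = []
    total = 0
    for rid, ln in sorted(estimates.items(), key=lambda kv: (-kv[1], kv[0])):
        if ln <= 0:
            break
        chosen.append(rid)
        total += ln
        if total >= target:
            break
    return chosen


def build_plan(store: OverlapStore, read_lengths: dict[str, int], C: int,
               min_depth: int = 2,
               score: str = "error") -> CorrectionPlan:
    donations = global_filter(store, C, score)
    accepted = local_filter(donations, C, score)
    estimates = estimate_corrected_lengths(accepted, read_lengths, min_depth)
    plan = CorrectionPlan(C=C, donations=donations, accepted=accepted,
                          estimated_lengths=estimates)
    plan.uncorrectable = {r for r in read_lengths if not accepted.get(r)}
    return plan


def dag_correct(
    read_seq: str,
    evidence: list[tuple[Overlap, str]],
    min_weight: int = 4,
    min_piece: int = 500,
) -> list[tuple[str, int, int]]:
    """Correct one read from its accepted evidence.

    `evidence` pairs each accepted overlap (a = the read under correction)
    with the partner's full sequence; partners on the opposite strand are
    reverse-complemented, and each is clipped to its overlapping
    subsequence (the aligner must place the whole evidence string, so
    sequence beyond the shared region would only inject noise). Returns
    corrected pieces as (sequence, start_on_read, end_on_read).
    """
    ev = []
    for o, partner_seq in evidence:
        seq = partner_seq if o.orient == "+" else revcomp(partner_seq)
        if o.orient == "+":
            b0, b1 = o.b_start, o.b_end
        else:
            b0, b1 = o.b_len - o.b_end, o.b_len - o.b_start
        pad = 50  # sketch-estimated extents are ~min-mer-resolution accurate
        ev.append((seq[max(0, b0 - pad) : b1 + pad], o.a_start, o.a_end))
    return dagcon.consensus_pieces(
        read_seq, ev, min_weight=min_weight, min_piece=min_piece,
        include_template=True, template_weight=1,
    )


def piece_name(rid: str, i: int, start: int) -> str:
    return f"{rid}_p{i}_{start}"


def correct_reads(
    reads: list[tuple[str, str]],
    cfg: PipelineConfig,
    overlaps: list[Overlap] | None = None,
) -> tuple[list[tuple[str, str]], CorrectionPlan]:
    """One full correction round: overlap, filter, select, DAG-correct.

    Returns (corrected reads, plan). Corrected reads are named
    '<origId>_p<i>_<startOffset>' so provenance survives splitting.
    """
    from .overlap import overlap_read_set  # deferred: cycle with this module's users

    seqs = dict(reads)
    read_lengths = {r: len(s) for r, s in reads}
    total_bases = sum(read_lengths.values())
    C = cfg.cor_coverage or max(1, round(total_bases / cfg.genome_size))

    if overlaps is None:
        spectrum = count_kmers(reads, cfg.k, cfg.spectrum_cutoff)
        params = TfIdfParams(a=cfg.idf_a, idf_max=cfg.idf_max, tf_cap=cfg.tf_cap,
                             cutoff_interpretation=cfg.cutoff_interpretation)
        overlaps = overlap_read_set(
            reads, spectrum, params, s=cfg.sketch_size, k=cfg.k, seed=cfg.seed,
            bottom_size=cfg.bottom_size, min_slot_matches=cfg.min_slot_matches,
            min_overlap=cfg.min_overlap, confirm=True, weighting=cfg.weighting,
            max_kmer_count=cfg.max_kmer_count,
        )
    store = build_store_from_overlaps(overlaps, known_reads=set(read_lengths))
    plan = build_plan(store, read_lengths, C, cfg.cor_min_depth, cfg.cor_score)
    selected = select_longest(plan.estimated_lengths, cfg.cor_out_coverage,
                              cfg.genome_size)
    log.info("correction: C=%d, %d/%d reads selected", C, len(selected), len(reads))

    corrected: list[tuple[str, str]] = []
    for rid in sorted(selected):
        evidence = [(o, seqs[o.b_id]) for o in plan.accepted.get(rid, [])]
        if not evidence:
            continue
        pieces = dag_correct(seqs[rid], evidence,
                             min_weight=cfg.cor_min_weight,
                             min_piece=cfg.cor_min_piece)
        for i, (seq, start, _end) in enumerate(pieces):
            corrected.append((piece_name(rid, i, start), seq))
    return corrected, plan


def iterate_correction(
    reads: list[tuple[str, str]], cfg: PipelineConfig, rounds: int = 1
) -> list[tuple[str, str]]:
    """Chained correction rounds; round n+1 corrects round n's output."""
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    current = reads
    for r in range(rounds):
        if not current:
            return []
        current, _plan = correct_reads(current, cfg)
        log.info("correction round %d: %d reads out", r + 1, len(current))
    return current
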