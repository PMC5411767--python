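"""Synthetic genomes and noisy long reads with known truth.

Generates the study conditions every downstream stage is tested against:
random genomes carrying multi-copy repeats with controlled pairwise
divergence, and reads with log-normally distributed lengths and uniform
substitution/insertion/deletion errors. Every read carries an exact truth
record (source interval, strand) so correction, trimming and assembly can
be scored against ground truth.

Coordinates are 0-based, half-open, forward-strand throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hashing import decode, encode, revcomp

_BASES = "ACGT"


@dataclass
class RepeatSpec:
    copy_count: int
    unit_length: int
    pairwise_divergence: float  # expected per-base difference between any two copies
    placements: list[int]       # start coordinate of each copy

    def __post_init__(self) -> None:
        if not 0.0 <= self.pairwise_divergence <= 0.5:
            raise ValueError("divergence must be in [0, 0.5]")
        if len(self.placements) != self.copy_count:
            raise ValueError("need one placement per copy")


@dataclass
class GenomeSpec:
    length: int
    repeats: list[RepeatSpec] = field(default_factory=list)
    circular: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        intervals = sorted(
            (p, p + r.unit_length) for r in self.repeats for p in r.placements
        )
        for (s0, e0), (s1, e1) in zip(intervals, intervals[1:]):
            if s1 < e0:
                raise ValueError(f"overlapping repeat placements: {(s0, e0)} vs {(s1, e1)}")
        for r in self.repeats:
            if r.unit_length >= self.length:
                raise ValueError("repeat unit longer than genome")
            for p in r.placements:
                if p < 0 or p + r.unit_length > self.length:
                    raise ValueError("repeat placement outside genome")


@dataclass
class GenomeTruth:
    sequence: str
    repeat_intervals: list[tuple[int, int]]            # (start, end) per copy, all repeats
    copy_mutations: list[list[tuple[int, str]]]        # per copy: (offset in unit, new base)
    circular: bool = False


@dataclass
class ReadSimSpec:
    coverage: float = 30.0
    length_mu: float = 8.0       # log-normal location of read length (ln bp)
    length_sigma: float = 0.4
    length_min: int = 1000
    length_max: int = 6000
    error_rate: float = 0.10
    # substitution : insertion : deletion proportions (must sum to 1); the
    # even default is a deliberate neutral choice, not an instrument model.
    error_mix: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_rate <= 0.5:
            raise ValueError("error_rate must be in [0, 0.5]")
        if abs(sum(self.error_mix) - 1.0) > 1e-9:
            raise ValueError("error_mix must sum to 1")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")


@dataclass
class TruthRead:
    read_id: str
    start: int      # source interval on the genome forward strand
    end: int
    strand: str     # '+' or '-'


def simulate_genome(spec: GenomeSpec) -> GenomeTruth:
    """Random uniform-ACGT genome with diverged repeat copies planted.

    Each repeat family gets one random unit consensus; every copy receives
    independent substitutions at rate divergence/2 so that the *pairwise*
    expected divergence between two copies is ~the requested value
    (substitutions only, so "3% divergence" is unambiguous).
    """
    rng = np.random.default_rng(spec.seed)
    codes = rng.integers(0, 4, size=spec.length, dtype=np.uint8)
    repeat_intervals: list[tuple[int, int]] = []
    copy_mutations: list[list[tuple[int, str]]] = []
    for rep in spec.repeats:
        unit = rng.integers(0, 4, size=rep.unit_length, dtype=np.uint8)
        # per-copy substitution rate r gives pairwise divergence 2r(1 - r/...);
        # for small r pairwise ~ 2r, so use r = d/2.
        per_copy = rep.pairwise_divergence / 2.0
        for p in rep.placements:
            copy = unit.copy()
            muts: list[tuple[int, str]] = []
            if per_copy > 0:
                hit = np.flatnonzero(rng.random(rep.unit_length) < per_copy)
                for pos in hit:
                    new = (copy[pos] + rng.integers(1, 4)) % 4
                    copy[pos] = new
                    muts.append((int(pos), _BASES[new]))
            codes[p : p + rep.unit_length] = copy
            repeat_intervals.append((p, p + rep.unit_length))
            copy_mutations.append(muts)
    return GenomeTruth(
        sequence=decode(codes),
        repeat_intervals=repeat_intervals,
        copy_mutations=copy_mutations,
        circular=spec.circular,
    )


def _apply_errors(codes: np.ndarray, spec: ReadSimSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.error_rate == 0:
        return codes
    ps, pi, _ = spec.error_mix
    out = []
    u = rng.random(len(codes))
    kind = rng.random(len(codes))
    for i, c in enumerate(codes):
        if u[i] >= spec.error_rate:
            out.append(c)
            continue
        if kind[i] < ps:  # substitution
            out.append((c + rng.integers(1, 4)) % 4)
        elif kind[i] < ps + pi:  # insertion before the base
            out.append(rng.integers(0, 4))
            out.append(c)
        # else deletion: emit nothing
    return np.array(out, dtype=np.uint8)


def simulate_reads(
    genome: str, spec: ReadSimSpec, id_prefix: str = "read",
    circular: bool = False,
) -> tuple[list[tuple[str, str]], list[TruthRead]]:
    """Sample noisy reads to the requested coverage.

    Returns (reads, truth) where reads are (id, sequence) pairs and truth
    records each read's exact source interval and strand (for circular
    genomes, intervals wrapping the origin have end > genome length,
    interpreted modulo the length). Deterministic for a fixed spec.
    """
    if not genome:
        raise ValueError("genome is empty")
    glen = len(genome)
    if circular:
        # virtual concatenation: reads may wrap the origin
        g = encode(genome + genome[: min(spec.length_max, glen)])
    else:
        g = encode(genome)
    if spec.length_min > glen:
        raise ValueError("minimum read length exceeds genome length")
    rng = np.random.default_rng(spec.seed)
    target = spec.coverage * glen
    total = 0
    reads: list[tuple[str, str]] = []
    truth: list[TruthRead] = []
    i = 0
    while total < target:
        ln = int(round(rng.lognormal(spec.length_mu, spec.length_sigma)))
        ln = int(np.clip(ln, spec.length_min, min(spec.length_max, glen)))
        start = int(rng.integers(0, glen if circular else glen - ln + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        src = g[start : start + ln]
        if strand == "-":
            src = encode(revcomp(decode(src)))
        seq_codes = _apply_errors(src, spec, rng)
        if len(seq_codes) == 0:
            continue
        rid = f"{id_prefix}{i:05d}"
        reads.append((rid, decode(seq_codes)))
        truth.append(TruthRead(rid, start, start + ln, strand))
        total += ln
        i += 1
    return reads, truth


def exclude_spanning_reads(
    reads: list[tuple[str, str]],
    truth: list[TruthRead],
    interval: tuple[int, int],
) -> tuple[list[tuple[str, str]], list[TruthRead]]:
    """Drop every read whose source interval fully contains `interval`."""
    s, e = interval
    keep_r, keep_t = [], []
    for (rid, seq), t in zip(reads, truth):
        if t.start <= s and t.end >= e:
            continue
        keep_r.append((rid, seq))
        keep_t.append(t)
    return keep_r, keep_t


# ---------------------------------------------------------------- file output

def write_fasta(path, records) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def write_fastq(path, records) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_truth(path, truth: list[TruthRead]) -> None:
    with open(path, "w") as fh:
        for t in truth:
            fh.write(f"{t.read_id}\t{t.start}\t{t.end}\t{t.strand}\n")


def read_truth(path) -> list[TruthRead]:
    out = []
    with open(path) as fh:
        for line in fh:
            rid, s, e, strand = line.rstrip("\n").split("\t")
            out.append(TruthRead(rid, int(s), int(e), strand))
    return out


# ------------------------------------------------------- truth-based scoring

def true_overlap_pairs(truth: list[TruthRead], min_overlap: int) -> set[tuple[str, str]]:
    """All unordered read-id pairs whose source intervals overlap >= min_overlap."""
    pairs: set[tuple[str, str]] = set()
    order = sorted(truth, key=lambda t: t.start)
    for i, a in enumerate(order):
        for b in order[i + 1 :]:
            if b.start >= a.end - min_overlap + 1:
                break
            if min(a.end, b.end) - max(a.start, b.start) >= min_overlap:
                pairs.add(tuple(sorted((a.read_id, b.read_id))))
    return pairs


def derived_truth_interval(
    rid: str, length: int | None, truth_by_id: dict[str, TruthRead]
) -> tuple[int, int] | None:
    """Genome interval of a (possibly corrected/split) read.

    Correction pieces are named '<orig>_p<i>_<startOffset>'; the offset is
    in read coordinates, so it maps forward on '+' reads and backward on
    '-' reads. `length` is the piece's current length (None = to read end).
    """
    t = truth_by_id.get(base_read_id(rid))
    if t is None:
        return None
    off = 0
    parts = rid.split("_")
    if len(parts) >= 3 and parts[-2].startswith("p"):
        off = int(parts[-1])
    plen = length if length is not None else (t.end - t.start - off)
    if t.strand == "+":
        s = t.start + off
        return s, min(t.end, s + plen)
    e = t.end - off
    return max(t.start, e - plen), e


def layout_is_collinear(
    layout: list[tuple[str, int] | tuple[str, int, int]],
    truth_by_id: dict[str, TruthRead],
    max_gap: int = 2000,
) -> bool:
    """True if consecutive layout reads come from overlapping (or nearly
    adjacent) genome loci in a monotone order — i.e., no misjoin.

    `layout` is [(read_id, contig_offset)] or [(read_id, offset, length)]
    sorted by offset; corrected-read ids map back to their raw read.
    """
    src = []
    for entry in sorted(layout, key=lambda x: x[1]):
        rid, _off = entry[0], entry[1]
        length = entry[2] if len(entry) > 2 else None
        iv = derived_truth_interval(rid, length, truth_by_id)
        if iv is None:
            return False
        src.append(iv)
    if len(src) <= 1:
        return True
    slack = 500  # placement noise tolerance
    ascending = src[-1][0] >= src[0][0]
    for (s0, e0), (s1, e1) in zip(src, src[1:]):
        if min(e0, e1) - max(s0, s1) < -max_gap:
            return False  # consecutive reads from disjoint loci
        if ascending and s1 < s0 - slack:
            return False
        if not ascending and e1 > e0 + slack:
            return False
    return True


def base_read_id(rid: str) -> str:
    """Strip correction-piece suffixes: 'read00001_p0_1200' -> 'read00001'."""
    return rid.split("_", 1)[0]


def repeat_resolved(
    layouts: list[list[tuple[str, int]]],
    truth: list[TruthRead],
    repeat_intervals: list[tuple[int, int]],
    flank: int = 1000,
) -> bool:
    """Truth check for repeat separation.

    Every repeat copy must sit inside some contig whose reads walk
    collinearly from its left flank, across the copy, into its right flank
    — and no contig anywhere may contain a misjoin.
    """
    truth_by_id = {t.read_id: t for t in truth}
    for layout in layouts:
        if not layout_is_collinear(layout, truth_by_id):
            return False
    for (rs, re_) in repeat_intervals:
        ok = False
        for layout in layouts:
            ivals = []
            for entry in sorted(layout, key=lambda x: x[1]):
                rid, length = entry[0], (entry[2] if len(entry) > 2 else None)
                iv = derived_truth_interval(rid, length, truth_by_id)
                if iv is not None:
                    ivals.append(iv)
            if not ivals:
                continue
            # contiguous truth chain covering [rs - flank, re_ + flank]?
            lo, hi = rs - flank, re_ + flank
            cov = [iv for iv in ivals if iv[1] > lo and iv[0] < hi]
            if not cov:
                continue
            cov.sort()
            reach = cov[0][1]
            start = cov[0][0]
            for s, e in cov[1:]:
                if s > reach:
                    break
                reach = max(reach, e)
            if start <= lo and reach >= hi:
                ok = True
                break
        if not ok:
            return False
    return True
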