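"""k-mer counting, tf-idf weighting, and MinHash sketch construction.

Two sketch kinds feed the two-stage overlapper:

* a fixed-size *weighted* MinHash sketch (one min-mer per hash slot, where
  a k-mer with integer weight w receives w hash draws per slot) used as a
  cheap first-stage candidate filter; and
* a *bottom sketch* (the smallest `size` hash values under one hash
  function, with read positions) from which overlap extent and error rate
  are estimated in the second stage.

Weights follow w_q = tf_q * idf_q, with idf_q = T(log(f_max/f_q - a))
linearly rescaled onto [1, idf_max] and rounded; k-mers outside the
recorded abundant set take idf_max. Counting is strand-canonical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import hashing
from .hashing import encode, kmer_hashes


@dataclass
class TfIdfParams:
    a: float = 0.9
    idf_max: int = 3
    tf_cap: int = 4
    cutoff_interpretation: str = "count"  # T upper endpoint: "count" | "fraction"

    def __post_init__(self) -> None:
        if not 0.0 <= self.a <= 1.0:
            raise ValueError("a must be in [0, 1]")
        if self.idf_max < 1:
            raise ValueError("idf_max must be >= 1")

    @property
    def w_max(self) -> int:
        return self.idf_max * self.tf_cap


@dataclass
class KmerSpectrum:
    """Global k-mer frequency summary.

    Only the most abundant `filter_cutoff` fraction of distinct k-mers is
    recorded (hash -> count); everything else is implicitly at f_min.
    """

    k: int
    recorded_hashes: np.ndarray      # sorted uint64
    recorded_counts: np.ndarray      # aligned with recorded_hashes
    f_max: int
    f_min: int
    filter_cutoff: float
    cutoff_count: int                # smallest recorded count (T endpoint, "count" mode)
    total_kmers: int

    MAGIC = b"MOLCSPEC"

    def save(self, path) -> None:
        """Persist as a small binary file: magic, header, hash/count pairs."""
        import struct

        with open(path, "wb") as fh:
            fh.write(self.MAGIC)
            fh.write(struct.pack("<iqqqdq", self.k, self.f_max, self.f_min,
                                 self.cutoff_count, self.filter_cutoff,
                                 self.total_kmers))
            fh.write(struct.pack("<q", len(self.recorded_hashes)))
            fh.write(self.recorded_hashes.astype("<u8").tobytes())
            fh.write(self.recorded_counts.astype("<i8").tobytes())

    @classmethod
    def load(cls, path) -> "KmerSpectrum":
        import struct

        with open(path, "rb") as fh:
            if fh.read(8) != cls.MAGIC:
                raise ValueError("not a k-mer spectrum file")
            k, f_max, f_min, cutoff_count, filter_cutoff, total = \
                struct.unpack("<iqqqdq", fh.read(44))
            (n,) = struct.unpack("<q", fh.read(8))
            hashes = np.frombuffer(fh.read(8 * n), dtype="<u8").copy()
            counts = np.frombuffer(fh.read(8 * n), dtype="<i8").copy()
        return cls(k=k, recorded_hashes=hashes, recorded_counts=counts,
                   f_max=f_max, f_min=f_min, filter_cutoff=filter_cutoff,
                   cutoff_count=cutoff_count, total_kmers=total)

    def lookup(self, hashes: np.ndarray) -> np.ndarray:
        """Counts for base hashes; unrecorded k-mers get 0 (= 'not recorded')."""
        idx = np.searchsorted(self.recorded_hashes, hashes)
        idx = np.clip(idx, 0, max(len(self.recorded_hashes) - 1, 0))
        out = np.zeros(len(hashes), dtype=np.int64)
        if len(self.recorded_hashes):
            hit = self.recorded_hashes[idx] == hashes
            out[hit] = self.recorded_counts[idx[hit]]
        return out


def count_kmers(reads, k: int, filter_cutoff: float = 5e-6) -> KmerSpectrum:
    """Strand-canonical k-mer spectrum over a read set.

    `reads` is an iterable of (id, sequence) pairs. Counts below the cutoff
    rank are dropped and represented implicitly as f_min.
    """
    chunks = []
    for _rid, seq in reads:
        if len(seq) >= k:
            chunks.append(kmer_hashes(encode(seq), k))
    if not chunks:
        raise ValueError(f"no read is at least k={k} long")
    allh = np.concatenate(chunks)
    uniq, counts = np.unique(allh, return_counts=True)
    f_max = int(counts.max())
    f_min = int(counts.min())
    n_keep = max(1, int(math.ceil(filter_cutoff * len(uniq))))
    n_keep = min(n_keep, len(uniq))
    # keep the n_keep most abundant; ties at the boundary broken by hash order
    order = np.lexsort((uniq, -counts))
    keep = np.sort(order[:n_keep])
    rh, rc = uniq[keep], counts[keep]
    srt = np.argsort(rh)
    return KmerSpectrum(
        k=k,
        recorded_hashes=rh[srt],
        recorded_counts=rc[srt].astype(np.int64),
        f_max=f_max,
        f_min=f_min,
        filter_cutoff=filter_cutoff,
        cutoff_count=int(rc.min()),
        total_kmers=int(len(allh)),
    )


def _idf_raw(f: float, f_max: int, a: float) -> float:
    return math.log(max(f_max / f - a, 1e-12))


def _idf_endpoints(spectrum: KmerSpectrum, params: TfIdfParams) -> tuple[float, float]:
    lo = _idf_raw(spectrum.f_max, spectrum.f_max, params.a)  # most popular k-mer
    if params.cutoff_interpretation == "fraction":
        f_cut = max(spectrum.filter_cutoff * spectrum.total_kmers, 1.0)
    else:
        f_cut = float(spectrum.cutoff_count)
    hi = _idf_raw(f_cut, spectrum.f_max, params.a)
    if hi <= lo:
        hi = lo + 1.0
    return lo, hi


def idf(f_q: int, spectrum: KmerSpectrum, params: TfIdfParams) -> int:
    """Integer idf weight in [1, idf_max] for a recorded frequency f_q.

    f_q = 0 means "not in the recorded set" and maps to idf_max.
    """
    if f_q > spectrum.f_max:
        raise ValueError("frequency exceeds f_max")
    if f_q <= 0:
        return params.idf_max
    lo, hi = _idf_endpoints(spectrum, params)
    v = _idf_raw(float(f_q), spectrum.f_max, params.a)
    scaled = 1.0 + (params.idf_max - 1.0) * (v - lo) / (hi - lo)
    scaled = min(max(scaled, 1.0), float(params.idf_max))
    return int(math.floor(scaled + 0.5))  # round half up


def idf_array(f_q: np.ndarray, spectrum: KmerSpectrum, params: TfIdfParams) -> np.ndarray:
    lo, hi = _idf_endpoints(spectrum, params)
    f = f_q.astype(np.float64)
    with np.errstate(divide="ignore"):
        v = np.log(np.maximum(spectrum.f_max / np.maximum(f, 1e-300) - params.a, 1e-12))
    scaled = 1.0 + (params.idf_max - 1.0) * (v - lo) / (hi - lo)
    scaled = np.clip(scaled, 1.0, float(params.idf_max))
    out = np.floor(scaled + 0.5).astype(np.int64)
    out[f_q <= 0] = params.idf_max
    return out


def tf_idf(tf_q: int, f_q: int, spectrum: KmerSpectrum, params: TfIdfParams) -> int:
    """w_q = tf_q * idf_q, capped at w_max."""
    w = min(tf_q, params.tf_cap) * idf(f_q, spectrum, params)
    return min(w, params.w_max)


@dataclass
class Sketch:
    read_id: str
    s: int
    k: int
    seed: int
    entries: np.ndarray = field(repr=False)  # s base hashes of chosen min-mers


def read_weights(
    hashes: np.ndarray,
    spectrum: KmerSpectrum | None,
    params: TfIdfParams,
    weighting: str = "tfidf",
    max_kmer_count: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Distinct k-mer hashes of a read and their integer weights.

    weighting "tfidf": w = min(tf, cap) * idf, capped at w_max.
    weighting "none": every k-mer weight 1 (plain MinHash).
    weighting "threshold": all-or-nothing filter — k-mers with recorded
    global count > max_kmer_count are dropped entirely; the rest weight 1.
    """
    uniq, tf = np.unique(hashes, return_counts=True)
    if weighting == "none" or spectrum is None:
        return uniq, np.ones(len(uniq), dtype=np.uint8)
    f = spectrum.lookup(uniq)
    if weighting == "threshold":
        keep = f <= max_kmer_count
        return uniq[keep], np.ones(int(keep.sum()), dtype=np.uint8)
    w = np.minimum(tf, params.tf_cap) * idf_array(f, spectrum, params)
    w = np.minimum(w, params.w_max)
    return uniq, w.astype(np.uint8)


def build_sketch(
    read_id: str,
    seq: str,
    s: int,
    spectrum: KmerSpectrum | None,
    params: TfIdfParams,
    seed: int = 0,
    k: int | None = None,
    weighting: str = "tfidf",
    max_kmer_count: int = 0,
) -> Sketch:
    """Weighted MinHash sketch of a read (canonical k-mers).

    Slot i stores the *base hash* of the k-mer minimizing, over that
    k-mer's w_q per-slot draws, a deterministic mix of (base hash, slot
    salt, draw index) — so identical k-mers match across reads whatever
    their weights.
    """
    if s < 1:
        raise ValueError("sketch size must be >= 1")
    kk = k if k is not None else (spectrum.k if spectrum is not None else 16)
    if len(seq) < kk:
        raise ValueError("read shorter than k")
    hashes = kmer_hashes(encode(seq), kk)
    uniq, w = read_weights(hashes, spectrum, params, weighting, max_kmer_count)
    if len(uniq) == 0:
        entries = np.zeros(s, dtype=np.uint64)
    else:
        entries = hashing.weighted_minhash_kernel(uniq, w, hashing.slot_salts(s, seed))
    return Sketch(read_id=read_id, s=s, k=kk, seed=seed, entries=entries)


def sketch_similarity(a: Sketch, b: Sketch) -> float:
    """Fraction of matching slots; unbiased estimate of the weighted Jaccard."""
    if (a.s, a.k, a.seed) != (b.s, b.k, b.seed):
        raise ValueError("sketches built with different parameters")
    return float(np.mean(a.entries == b.entries))


def weighted_jaccard(wa: dict[int, int], wb: dict[int, int]) -> float:
    """Exact generalized Jaccard of two integer-weighted k-mer sets."""
    keys = set(wa) | set(wb)
    num = sum(min(wa.get(q, 0), wb.get(q, 0)) for q in keys)
    den = sum(max(wa.get(q, 0), wb.get(q, 0)) for q in keys)
    return num / den if den else 0.0


@dataclass
class BottomSketch:
    read_id: str
    k: int
    length: int                      # read length
    values: np.ndarray = field(repr=False)     # sorted distinct hash values
    positions: np.ndarray = field(repr=False)  # first position of each value in the read


def build_bottom_sketch(read_id: str, seq: str, k: int, size: int = 1500) -> BottomSketch:
    """Bottom sketch: the `size` smallest distinct canonical k-mer hashes,
    each with its first position in the read."""
    if len(seq) < k:
        raise ValueError("read shorter than k")
    hashes = kmer_hashes(encode(seq), k)
    # first occurrence position per distinct hash
    uniq, first = np.unique(hashes, return_index=True)
    if len(uniq) > size:
        uniq, first = uniq[:size], first[:size]  # uniq already ascending
    return BottomSketch(read_id=read_id, k=k, length=len(seq),
                        values=uniq, positions=first.astype(np.int64))


def bottom_jaccard(a: BottomSketch, b: BottomSketch) -> tuple[float, np.ndarray]:
    """Jaccard estimate from the merged bottom sketch.

    Returns (j, shared_values): j is |shared among the s smallest of the
    union| / s with s = min(|a|, |b|, configured size), the Mash estimator.
    """
    s = min(len(a.values), len(b.values))
    if s == 0:
        return 0.0, np.empty(0, dtype=np.uint64)
    union = np.union1d(a.values, b.values)[:s]
    shared = np.intersect1d(a.values, b.values, assume_unique=True)
    shared_in_union = shared[np.isin(shared, union, assume_unique=False)]
    return len(shared_in_union) / s, shared_in_union
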