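"""k-mer spectrum, tf-idf weighting, weighted MinHash and bottom sketches."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from miniolc import sketch
from miniolc.hashing import encode, kmer_hashes, revcomp
from miniolc.sketch import TfIdfParams


class TestCountKmers:
    def test_hand_countable(self):
        sp = sketch.count_kmers([("r", "AAAA")], 2, filter_cutoff=1.0)
        # "AA" occurs 3 times (canonical AA = min(AA, TT))
        assert sp.f_max == 3
        assert len(sp.recorded_hashes) == 1

    def test_reverse_complement_gives_identical_spectrum(self, small_reads):
        reads, _ = small_reads
        seq = reads[0][1]
        sp1 = sketch.count_kmers([("a", seq)], 16, 1.0)
        sp2 = sketch.count_kmers([("a", revcomp(seq))], 16, 1.0)
        assert np.array_equal(sp1.recorded_hashes, sp2.recorded_hashes)
        assert np.array_equal(sp1.recorded_counts, sp2.recorded_counts)

    def test_recorded_set_is_top_cutoff_of_exhaustive_count(self, small_reads):
        reads, _ = small_reads
        reads = reads[:100]
        cutoff = 0.01
        sp = sketch.count_kmers(reads, 16, cutoff)
        # exhaustive oracle
        from collections import Counter
        counts = Counter()
        for _, seq in reads:
            for h in kmer_hashes(encode(seq), 16):
                counts[int(h)] += 1
        n_keep = max(1, math.ceil(cutoff * len(counts)))
        top = sorted(counts.values(), reverse=True)[:n_keep]
        assert sorted(sp.recorded_counts.tolist(), reverse=True) == top

    def test_k_longer_than_reads_raises(self):
        with pytest.raises(ValueError):
            sketch.count_kmers([("r", "ACGT")], 16)


class TestIdf:
    def test_most_frequent_kmer_gets_minimum_weight(self, spectrum, tfidf_params):
        assert sketch.idf(spectrum.f_max, spectrum, tfidf_params) == 1

    def test_unrecorded_kmer_gets_idf_max(self, spectrum, tfidf_params):
        assert sketch.idf(0, spectrum, tfidf_params) == tfidf_params.idf_max == 3

    def test_matches_scalar_formula_oracle(self, tfidf_params):
        sp = sketch.KmerSpectrum(
            k=16, recorded_hashes=np.array([1, 2, 3], dtype=np.uint64),
            recorded_counts=np.array([10_000, 500, 40]), f_max=10_000, f_min=1,
            filter_cutoff=5e-6, cutoff_count=40, total_kmers=1_000_000)
        a, idf_max = tfidf_params.a, tfidf_params.idf_max
        lo = math.log(1 - a)
        hi = math.log(10_000 / 40 - a)
        for f in (10_000, 5000, 500, 100, 40):
            v = math.log(10_000 / f - a)
            expect = 1 + (idf_max - 1) * (v - lo) / (hi - lo)
            expect = int(math.floor(min(max(expect, 1), idf_max) + 0.5))
            assert sketch.idf(f, sp, tfidf_params) == expect

    def test_monotone_nonincreasing_in_frequency(self, spectrum, tfidf_params):
        freqs = np.arange(1, spectrum.f_max + 1)
        weights = [sketch.idf(int(f), spectrum, tfidf_params) for f in freqs]
        assert all(w0 >= w1 for w0, w1 in zip(weights, weights[1:]))

    def test_frequency_above_fmax_rejected(self, spectrum, tfidf_params):
        with pytest.raises(ValueError):
            sketch.idf(spectrum.f_max + 1, spectrum, tfidf_params)


class TestTfIdf:
    def test_products_and_cap(self, spectrum, tfidf_params):
        # tf * idf, verified against a brute-force table over a toy read
        assert sketch.tf_idf(1, 0, spectrum, tfidf_params) == 3  # 1 * idf_max
        assert sketch.tf_idf(3, 0, spectrum, tfidf_params) == 9
        assert sketch.tf_idf(100, 0, spectrum, tfidf_params) == tfidf_params.w_max

    def test_read_weights_equal_bruteforce_table(self, spectrum, tfidf_params):
        seq = "ACGTACGTTTGACGTACGGGACGTACGTTTGA" * 4
        hashes = kmer_hashes(encode(seq), 16)
        uniq, w = sketch.read_weights(hashes, spectrum, tfidf_params)
        from collections import Counter
        tf = Counter(map(int, hashes))
        for h, weight in zip(uniq, w):
            f = int(spectrum.lookup(np.array([h], dtype=np.uint64))[0])
            expect = min(min(tf[int(h)], tfidf_params.tf_cap)
                         * sketch.idf(f, spectrum, tfidf_params),
                         tfidf_params.w_max)
            assert weight == expect


class TestWeightedSketch:
    def test_unit_weights_reduce_to_plain_minhash(self, spectrum, tfidf_params):
        seq = "ACGT" * 200
        s1 = sketch.build_sketch("a", seq, 64, spectrum, tfidf_params,
                                 seed=3, weighting="none")
        # oracle: plain MinHash = argmin over single draw per slot
        from miniolc import hashing
        hashes = np.unique(kmer_hashes(encode(seq), 16))
        salts = hashing.slot_salts(64, 3)
        for i, salt in enumerate(salts):
            draws = hashing.splitmix64(hashes ^ salt, np.uint64(0))
            # kernel mixes h ^ salt with draw index 0
            vals = [int(hashing._mix(np.uint64(int(h) ^ int(salt)))) for h in hashes]
            assert s1.entries[i] == hashes[int(np.argmin(vals))]

    def test_identical_reads_identical_sketches(self, small_reads, spectrum,
                                                tfidf_params):
        seq = small_reads[0][0][1]
        s1 = sketch.build_sketch("a", seq, 128, spectrum, tfidf_params, seed=1)
        s2 = sketch.build_sketch("b", seq, 128, spectrum, tfidf_params, seed=1)
        assert np.array_equal(s1.entries, s2.entries)
        assert sketch.sketch_similarity(s1, s2) == 1.0

    def test_mixed_parameters_rejected(self, spectrum, tfidf_params):
        seq = "ACGT" * 100
        s1 = sketch.build_sketch("a", seq, 64, spectrum, tfidf_params, seed=1)
        s2 = sketch.build_sketch("b", seq, 64, spectrum, tfidf_params, seed=2)
        with pytest.raises(ValueError):
            sketch.sketch_similarity(s1, s2)

    def test_similarity_estimates_weighted_jaccard(self, spectrum, tfidf_params):
        """Mean slot-match fraction over 50 seeds approximates the exact
        generalized Jaccard of the two weighted k-mer sets within 3 s.e."""
        rng = np.random.default_rng(42)
        bases = "ACGT"
        seq_a = "".join(rng.choice(list(bases), 600))
        seq_b = seq_a[:350] + "".join(rng.choice(list(bases), 250))
        wa = dict(zip(*[arr.tolist() for arr in sketch.read_weights(
            kmer_hashes(encode(seq_a), 16), spectrum, tfidf_params)]))
        wb = dict(zip(*[arr.tolist() for arr in sketch.read_weights(
            kmer_hashes(encode(seq_b), 16), spectrum, tfidf_params)]))
        exact = sketch.weighted_jaccard(wa, wb)
        s = 256
        n_seeds = 50
        sims = []
        for seed in range(n_seeds):
            sa = sketch.build_sketch("a", seq_a, s, spectrum, tfidf_params, seed=seed)
            sb = sketch.build_sketch("b", seq_b, s, spectrum, tfidf_params, seed=seed)
            sims.append(sketch.sketch_similarity(sa, sb))
        se = math.sqrt(exact * (1 - exact) / (n_seeds * s))
        assert abs(np.mean(sims) - exact) <= 3 * se


class TestBottomSketch:
    def test_small_read_keeps_all_kmers(self):
        seq = "ACGTACGTACGTACGTACGTGTCA"
        bs = sketch.build_bottom_sketch("r", seq, 16, size=1500)
        n_distinct = len(np.unique(kmer_hashes(encode(seq), 16)))
        assert len(bs.values) == n_distinct

    def test_substring_sketch_subset_of_full(self, small_reads):
        seq = small_reads[0][0][1]
        full = sketch.build_bottom_sketch("r", seq, 16, size=400)
        sub = sketch.build_bottom_sketch("s", seq[300:1200], 16, size=400)
        # every sub min-mer present in the read is obtainable from the full
        # read's k-mer set (bottom property: subset after re-ranking)
        full_all = set(np.unique(kmer_hashes(encode(seq), 16)).tolist())
        assert set(sub.values.tolist()) <= full_all

    def test_values_strictly_increasing(self, small_reads):
        seq = small_reads[0][0][1]
        bs = sketch.build_bottom_sketch("r", seq, 16, size=500)
        assert np.all(np.diff(bs.values.astype(np.float64)) > 0)

    def test_merged_jaccard_matches_exact_set_jaccard(self, small_genome):
        # high sketch size relative to k-mer count -> near-exact estimate
        a = small_genome.sequence[0:3000]
        b = small_genome.sequence[1500:4500]
        ba = sketch.build_bottom_sketch("a", a, 16, size=1500)
        bb = sketch.build_bottom_sketch("b", b, 16, size=1500)
        j, _ = sketch.bottom_jaccard(ba, bb)
        sa = set(np.unique(kmer_hashes(encode(a), 16)).tolist())
        sb = set(np.unique(kmer_hashes(encode(b), 16)).tolist())
        exact = len(sa & sb) / len(sa | sb)
        assert abs(j - exact) < 0.05


class TestRepeatFlattening:
    def test_tfidf_flattens_sketched_kmer_distribution(self):
        """On a genome with a heavily repeated unit, tf-idf sketching
        samples k-mers more uniformly (lower Gini) than unweighted."""
        from miniolc import simdata
        rng = np.random.default_rng(3)
        unit = "".join(rng.choice(list("ACGT"), 300))
        g = simdata.simulate_genome(simdata.GenomeSpec(length=12_000, seed=4))
        genome = g.sequence[:3000] + unit * 20 + g.sequence[3000:6000]
        spec = simdata.ReadSimSpec(coverage=8, error_rate=0.02, seed=5,
                                   length_min=800, length_max=2500, length_mu=7.2)
        reads, _ = simdata.simulate_reads(genome, spec)
        sp = sketch.count_kmers(reads, 16, 0.05)
        params = TfIdfParams()

        def gini(counts):
            x = np.sort(np.asarray(counts, dtype=float))
            n = len(x)
            return (2 * np.sum((np.arange(1, n + 1)) * x) / (n * x.sum())
                    - (n + 1) / n)

        from collections import Counter
        freq_w, freq_u = Counter(), Counter()
        for rid, seq in reads[:60]:
            sw = sketch.build_sketch(rid, seq, 96, sp, params, seed=1)
            su = sketch.build_sketch(rid, seq, 96, sp, params, seed=1,
                                     weighting="none")
            freq_w.update(map(int, sw.entries))
            freq_u.update(map(int, su.entries))
        assert gini(list(freq_w.values())) < gini(list(freq_u.values()))


@settings(max_examples=25, deadline=None)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_sketch_determinism_across_calls(seed):
    """Same read, same seed: identical sketch entries (pure function)."""
    seq = "ACGTTGCACGTACGGATCGATCGTACGTAGCATCGA" * 8
    params = TfIdfParams()
    s1 = sketch.build_sketch("r", seq, 32, None, params, seed=seed)
    s2 = sketch.build_sketch("r", seq, 32, None, params, seed=seed)
    assert np.array_equal(s1.entries, s2.entries)


def test_spectrum_binary_round_trip(tmp_path, spectrum):
    path = tmp_path / "spectrum.bin"
    spectrum.save(path)
    back = sketch.KmerSpectrum.load(path)
    assert back.k == spectrum.k
    assert back.f_max == spectrum.f_max
    assert back.cutoff_count == spectrum.cutoff_count
    assert np.array_equal(back.recorded_hashes, spectrum.recorded_hashes)
    assert np.array_equal(back.recorded_counts, spectrum.recorded_counts)
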