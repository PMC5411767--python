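"""Correction filters, corrected-length estimation, DAG correction."""

import numpy as np
import pytest

from miniolc import correct, simdata
from miniolc.config import PipelineConfig
from miniolc.overlap import Overlap
from miniolc.store import build_store_from_overlaps

from conftest import noisy_copy


def mk_ovl(a, b, length, error, a_start=0):
    return Overlap(a_id=a, b_id=b, a_len=3000, b_len=3000,
                   a_start=a_start, a_end=a_start + length,
                   b_start=0, b_end=length, orient="+",
                   error=error, kind="dovetail", evidence="sketch",
                   align_len=length)


class TestGlobalFilter:
    def test_few_overlaps_all_kept(self):
        ovs = [mk_ovl("r1", f"p{i}", 1000, 0.05) for i in range(3)]
        store = build_store_from_overlaps(ovs)
        don = correct.global_filter(store, C=5)
        assert len(don["r1"]) == 3

    def test_top_c_by_length_times_identity(self):
        # scores: 4000*0.98=3920, 3000*0.99=2970, 5000*0.90=4500
        ovs = [mk_ovl("r1", "a", 4000, 0.02), mk_ovl("r1", "b", 3000, 0.01),
               mk_ovl("r1", "c", 5000, 0.10)]
        store = build_store_from_overlaps(ovs)
        don = correct.global_filter(store, C=2)
        kept = {o.b_id for o in don["r1"]}
        assert kept == {"a", "c"}  # two highest products

    def test_repeat_reads_donate_to_same_copy(self):
        """On a two-copy 5%-diverged repeat at ~30x, donated evidence goes
        overwhelmingly to same-copy partners (lower error => higher score)."""
        rng = np.random.default_rng(21)
        g = simdata.simulate_genome(simdata.GenomeSpec(
            length=14_000, seed=22,
            repeats=[simdata.RepeatSpec(2, 6000, 0.05, [500, 7000])]))
        c1, c2 = g.sequence[500:6500], g.sequence[7000:13_000]
        reads = []
        for i in range(15):
            reads.append((f"a{i:02d}", noisy_copy(c1, 0.10, 500 + i)))
            reads.append((f"b{i:02d}", noisy_copy(c2, 0.10, 700 + i)))
        from miniolc.pipeline import compute_overlaps
        cfg = PipelineConfig(genome_size=14_000, seed=1)
        ovs = compute_overlaps(reads, cfg, confirm=True, corrected=False)
        store = build_store_from_overlaps(ovs, known_reads={r for r, _ in reads})
        don = correct.global_filter(store, C=15, score="error")
        same = cross = 0
        for donor, kept in don.items():
            for o in kept:
                if donor[0] == o.b_id[0]:
                    same += 1
                else:
                    cross += 1
        assert same / max(same + cross, 1) >= 0.9


class TestLocalFilter:
    def test_caps_at_two_c(self):
        donations = {f"d{i}": [mk_ovl(f"d{i}", "t", 1000 + i, 0.05)]
                     for i in range(10)}
        acc = correct.local_filter(donations, C=2)
        assert len(acc["t"]) == 4
        # the four longest survive
        assert {o.b_id for o in acc["t"]} == {"d6", "d7", "d8", "d9"}

    def test_under_limit_all_kept(self):
        donations = {"d": [mk_ovl("d", "t", 1000, 0.05)]}
        acc = correct.local_filter(donations, C=3)
        assert len(acc["t"]) == 1


class TestEstimateCorrectedLengths:
    def test_full_coverage_keeps_length(self):
        acc = {"r": [mk_ovl("r", f"p{i}", 3000, 0.05) for i in range(3)]}
        est = correct.estimate_corrected_lengths(acc, {"r": 3000}, min_depth=2)
        assert est["r"] == 3000

    def test_half_coverage_half_length(self):
        acc = {"r": [mk_ovl("r", f"p{i}", 1500, 0.05) for i in range(3)]}
        est = correct.estimate_corrected_lengths(acc, {"r": 3000}, min_depth=2)
        # interval-union oracle: evidence covers [0, 1500) at depth 3
        assert est["r"] == 1500

    def test_no_evidence_zero(self):
        est = correct.estimate_corrected_lengths({}, {"r": 3000})
        assert est["r"] == 0


class TestSelectLongest:
    def test_insufficient_pool_takes_all(self):
        est = {"a": 5000, "b": 4000}
        sel = correct.select_longest(est, 40, 10_000)
        assert set(sel) == {"a", "b"}

    def test_greedy_stops_at_target(self):
        est = {f"r{i:02d}": 1000 for i in range(80)}
        sel = correct.select_longest(est, 40, 1000)  # target 40 kb
        assert len(sel) == 40
        # equal lengths: lower ids first
        assert sel == sorted(est)[:40]

    def test_target_boundary_within_one_read(self):
        rng = np.random.default_rng(30)
        est = {f"r{i:03d}": int(rng.integers(2000, 9000)) for i in range(60)}
        target, gsize = 20, 10_000
        sel = correct.select_longest(est, target, gsize)
        total = sum(est[r] for r in sel)
        assert target * gsize <= total <= target * gsize + max(est.values())


class TestDagCorrect:
    def test_errorfree_identical_evidence_reproduces_template(self):
        seq = "ACGTTGCA" * 200
        ev = [(mk_ovl("t", f"e{i}", len(seq), 0.0), seq) for i in range(10)]
        for o, _ in ev:
            o.a_len = o.b_len = o.a_end = o.b_end = len(seq)
            o.a_start = o.b_start = 0
        pieces = correct.dag_correct(seq, ev, min_piece=100)
        assert len(pieces) == 1
        assert pieces[0][0] == seq

    def test_corrects_noisy_template_to_99pct(self, small_genome):
        import edlib
        src = small_genome.sequence[2000:5000]
        template = noisy_copy(src, 0.10, 40)
        ev = []
        for i in range(20):
            e_seq = noisy_copy(src, 0.10, 50 + i)
            o = mk_ovl("t", f"e{i}", min(len(template), len(e_seq)), 0.2)
            o.a_len, o.b_len = len(template), len(e_seq)
            o.a_end, o.b_end = len(template), len(e_seq)
            ev.append((o, e_seq))
        pieces = correct.dag_correct(template, ev)
        assert len(pieces) >= 1
        cons = pieces[0][0]
        d = edlib.align(cons, src, mode="NW")["editDistance"]
        assert 1 - d / max(len(cons), len(src)) >= 0.99

    def test_disjoint_evidence_splits_read(self, small_genome):
        src = small_genome.sequence[0:3000]
        template = noisy_copy(src, 0.02, 60)
        ev = []
        for i in range(6):  # left half only
            e = noisy_copy(src[:1300], 0.01, 70 + i)
            o = mk_ovl("t", f"l{i}", 1300, 0.05)
            o.a_len, o.b_len = len(template), len(e)
            o.a_start, o.a_end, o.b_start, o.b_end = 0, 1300, 0, len(e)
            ev.append((o, e))
        for i in range(6):  # right half only
            e = noisy_copy(src[1700:], 0.01, 80 + i)
            o = mk_ovl("t", f"r{i}", 1300, 0.05)
            o.a_len, o.b_len = len(template), len(e)
            o.a_start, o.a_end = 1700, 3000
            o.b_start, o.b_end = 0, len(e)
            ev.append((o, e))
        pieces = correct.dag_correct(template, ev, min_weight=4, min_piece=500)
        assert len(pieces) == 2


class TestIterateCorrection:
    def test_empty_input_empty_output(self, cfg):
        assert correct.iterate_correction([], cfg, rounds=2) == []

    def test_rounds_must_be_positive(self, cfg):
        with pytest.raises(ValueError):
            correct.iterate_correction([], cfg, rounds=0)

    def test_second_round_does_not_degrade_identity(self, small_genome):
        """Mean identity to truth after round 2 >= after round 1 on very
        noisy reads (iterative correction for high-error data)."""
        import edlib
        from miniolc.hashing import revcomp
        spec = simdata.ReadSimSpec(coverage=25, error_rate=0.15, seed=31,
                                   length_min=800, length_max=3000, length_mu=7.4)
        reads, truth = simdata.simulate_reads(small_genome.sequence[:12_000], spec)
        tb = {t.read_id: t for t in truth}
        cfg = PipelineConfig(genome_size=12_000, seed=1)

        def mean_identity(rds):
            idents = []
            for rid, seq in rds[:60]:
                t = tb[simdata.base_read_id(rid)]
                src = small_genome.sequence[t.start:t.end]
                if t.strand == "-":
                    src = revcomp(src)
                d = edlib.align(seq, src, mode="HW")["editDistance"]
                idents.append(1 - d / len(seq))
            return np.mean(idents)

        r1 = correct.iterate_correction(reads, cfg, rounds=1)
        r2 = correct.iterate_correction(reads, cfg, rounds=2)
        assert len(r1) and len(r2)
        assert mean_identity(r2) >= mean_identity(r1) - 0.002
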