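"""Best-overlap-graph assembly: error model, best edges, contigs, GFA."""

import numpy as np
import pytest

from miniolc import assemble
from miniolc.config import PipelineConfig
from miniolc.overlap import Overlap


def dovetail(a, b, a_len=3000, b_len=3000, hang=1000, error=0.005, orient="+"):
    """A 3'-of-A to 5'-of-B dovetail with the given unaligned hang."""
    length = a_len - hang
    return Overlap(a_id=a, b_id=b, a_len=a_len, b_len=b_len,
                   a_start=hang, a_end=a_len,
                   b_start=0, b_end=length, orient=orient,
                   error=error, kind="dovetail", evidence="dp",
                   align_len=length)


class TestErrorModel:
    def test_degenerate_distribution_uses_floor(self):
        m = assemble.estimate_error_model([0.002] * 20, 6.0, 0.005)
        assert m.median == pytest.approx(0.002)
        assert m.mad == 0.0
        assert m.cutoff == 0.005  # floor

    def test_stated_formula(self):
        # median 0.25%, MAD 0.15% -> cutoff 1.15%
        errs = [0.001, 0.0025, 0.004, 0.0025, 0.001, 0.004, 0.0025]
        m = assemble.estimate_error_model(errs, 6.0, 0.005)
        assert m.median == pytest.approx(0.0025)
        assert m.mad == pytest.approx(0.0015)
        assert m.cutoff == pytest.approx(0.0025 + 6 * 0.0015)

    def test_matches_order_statistics_oracle(self):
        rng = np.random.default_rng(77)
        errs = rng.gamma(2.0, 0.002, size=501).tolist()
        m = assemble.estimate_error_model(errs, 6.0, 0.0)
        # oracle: explicit order statistics (odd n -> middle element)
        s = sorted(errs)
        med = s[250]
        dev = sorted(abs(x - med) for x in errs)
        mad = dev[250]
        assert m.median == pytest.approx(med)
        assert m.mad == pytest.approx(mad)
        assert m.cutoff == pytest.approx(med + 6 * mad)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            assemble.estimate_error_model([])


class TestBestEdges:
    def test_longest_dovetail_wins(self):
        from miniolc.store import build_store_from_overlaps
        ovs = [dovetail("r", "a", hang=2000, error=0.004),   # 1 kb
               dovetail("r", "b", hang=1000, error=0.004),   # 2 kb
               dovetail("r", "c", hang=500, error=0.004)]    # 2.5 kb
        store = build_store_from_overlaps(ovs)
        bes = assemble.pick_best_edges(store, cutoff=0.01)
        assert bes.three["r"].b_id == "c"

    def test_above_cutoff_excluded(self):
        from miniolc.store import build_store_from_overlaps
        ovs = [dovetail("r", "a", hang=500, error=0.05),
               dovetail("r", "b", hang=1000, error=0.004)]
        store = build_store_from_overlaps(ovs)
        bes = assemble.pick_best_edges(store, cutoff=0.01)
        assert bes.three["r"].b_id == "b"

    def test_containment_only_read_has_no_best_edges(self):
        from miniolc.store import build_store_from_overlaps
        o = Overlap("r", "big", 1000, 3000, 0, 1000, 500, 1500, "+",
                    0.004, "containment", "dp", 1000)
        store = build_store_from_overlaps([o])
        contained = assemble.find_contained(store)
        assert contained == {"r"}
        bes = assemble.pick_best_edges(store, 0.01, contained)
        assert bes.five["r"] is None and bes.three["r"] is None

    def test_best_edges_match_bruteforce_scan(self, small_genome):
        from miniolc.pipeline import compute_overlaps
        from miniolc.store import build_store_from_overlaps
        from conftest import noisy_copy
        rng = np.random.default_rng(88)
        reads = []
        for i in range(40):
            ln = int(rng.integers(1500, 3500))
            start = int(rng.integers(0, 20_000 - ln))
            reads.append((f"r{i:03d}",
                          noisy_copy(small_genome.sequence[start:start + ln],
                                     0.01, 800 + i)))
        cfg = PipelineConfig(genome_size=20_000, seed=1)
        ovs = compute_overlaps(reads, cfg, confirm=True, corrected=True)
        store = build_store_from_overlaps(ovs, known_reads={r for r, _ in reads})
        bes = assemble.pick_best_edges(store, cutoff=0.02)
        for rid in store.read_ids:
            for end in ("5", "3"):
                # brute force: longest qualifying dovetail touching the end
                cands = [o for o in store.get(rid)
                         if o.kind == "dovetail" and o.error <= 0.02
                         and assemble._touches(o, end)]
                got = bes.edge(rid, end)
                if not cands:
                    assert got is None
                else:
                    best = max(cands, key=lambda o: (o.length, -o.error))
                    assert got is not None and got.length == best.length


class TestBuildContigs:
    def _chain_store(self, n=6):
        """n reads in a clean mutual-best chain."""
        from miniolc.store import build_store_from_overlaps
        ovs = [dovetail(f"r{i}", f"r{i+1}") for i in range(n - 1)]
        return build_store_from_overlaps(ovs), {f"r{i}": 3000 for i in range(n)}

    def test_single_chain_one_contig(self):
        store, lengths = self._chain_store()
        bes = assemble.pick_best_edges(store, 0.01)
        contigs = assemble.build_contigs(bes, lengths)
        assert len(contigs) == 1
        c = contigs[0]
        assert len(c.layout) == 6
        # offsets step by the hang
        begins = [lr.begin for lr in sorted(c.layout, key=lambda l: l.begin)]
        assert begins == [i * 1000 for i in range(6)]
        assert c.length == 3000 + 5 * 1000

    def test_disconnected_components_two_contigs(self):
        from miniolc.store import build_store_from_overlaps
        ovs = [dovetail("a0", "a1"), dovetail("b0", "b1")]
        store = build_store_from_overlaps(ovs)
        bes = assemble.pick_best_edges(store, 0.01)
        contigs = assemble.build_contigs(
            bes, {r: 3000 for r in ("a0", "a1", "b0", "b1")})
        assert len(contigs) == 2

    def test_flipped_orientation_chain(self):
        from miniolc.store import build_store_from_overlaps
        # r0 3' overlaps r1 3' (r1 reversed in contig frame)
        o = Overlap("r0", "r1", 3000, 3000, 1000, 3000, 1000, 3000, "-",
                    0.004, "dovetail", "dp", 2000)
        store = build_store_from_overlaps([o])
        bes = assemble.pick_best_edges(store, 0.01)
        contigs = assemble.build_contigs(bes, {"r0": 3000, "r1": 3000})
        assert len(contigs) == 1
        orients = {lr.rid: lr.orient for lr in contigs[0].layout}
        assert orients["r0"] != orients["r1"]


class TestErrorProfile:
    def test_windows_tile_and_empty_windows_inherit(self):
        from miniolc.store import build_store_from_overlaps
        ovs = [dovetail(f"r{i}", f"r{i+1}", error=0.004) for i in range(3)]
        store = build_store_from_overlaps(ovs)
        bes = assemble.pick_best_edges(store, 0.01)
        contig = assemble.build_contigs(bes, {f"r{i}": 3000 for i in range(4)})[0]
        prof = assemble.compute_error_profile(contig, store, window=1000)
        assert len(prof.medians) == -(-contig.length // 1000)
        assert np.all(prof.medians >= 0)
        assert prof.medians[0] == pytest.approx(0.004)


class TestGfa:
    def test_single_contig_header_and_s_line(self):
        c = assemble.Contig("ctg0001", [assemble.LayoutRead("r", "+", 0, 100)],
                            100, consensus="A" * 100)
        doc = assemble.emit_gfa([c], [])
        lines = doc.strip().split("\n")
        assert lines[0] == "H\tVN:Z:1.0"
        assert lines[1].startswith("S\tctg0001\t")
        assert "LN:i:100" in lines[1]

    def test_circular_contig_self_link(self):
        c = assemble.Contig("ctg0001", [assemble.LayoutRead("r", "+", 0, 100)],
                            100, circular=True, consensus="A" * 100)
        links = assemble.contig_end_links([c], __import__(
            "miniolc.store", fromlist=["build_store_from_overlaps"]
        ).build_store_from_overlaps([]), 0.01)
        doc = assemble.emit_gfa([c], links)
        assert any(line.startswith("L\tctg0001\t+\tctg0001\t+")
                   for line in doc.split("\n"))

    def test_gfa_parses_and_round_trips(self):
        contigs = [
            assemble.Contig("u1", [assemble.LayoutRead("a", "+", 0, 100)], 100,
                            consensus="ACGT" * 25),
            assemble.Contig("rep", [assemble.LayoutRead("b", "+", 0, 100)], 100,
                            cls="repeat", consensus="TTGA" * 25),
            assemble.Contig("u2", [assemble.LayoutRead("c", "+", 0, 100)], 100,
                            consensus="GACT" * 25),
        ]
        links = [("u1", "+", "rep", "+", 50), ("rep", "+", "u2", "+", 60)]
        doc = assemble.emit_gfa(contigs, links)
        # minimal GFA 1.0 grammar check + structure round-trip
        segs, parsed_links = {}, []
        for line in doc.strip().split("\n"):
            f = line.split("\t")
            if f[0] == "H":
                assert f[1] == "VN:Z:1.0"
            elif f[0] == "S":
                assert len(f) >= 3 and set(f[2]) <= set("ACGTN*")
                segs[f[1]] = f[2]
            elif f[0] == "L":
                assert f[2] in "+-" and f[4] in "+-"
                assert f[5].endswith("M")
                parsed_links.append((f[1], f[2], f[3], f[4], int(f[5][:-1])))
            else:
                pytest.fail(f"unexpected GFA record {f[0]}")
        assert set(segs) == {"u1", "rep", "u2"}
        assert set(parsed_links) == set(links)
        # the repeat segment connects both unique contigs
        assert {l[0] for l in parsed_links} | {l[2] for l in parsed_links} == \
            {"u1", "rep", "u2"}


class TestCircular:
    def test_circular_genome_one_contig_with_self_link(self):
        """Error-free reads of a circular genome give one contig whose
        terminal overlap is recorded as a self edge in the graph."""
        from miniolc import simdata
        from miniolc.config import PipelineConfig
        from miniolc.pipeline import stage_assemble
        from miniolc.hashing import revcomp

        g = simdata.simulate_genome(simdata.GenomeSpec(length=12_000, seed=95,
                                                       circular=True))
        spec = simdata.ReadSimSpec(coverage=12, error_rate=0.0, seed=96,
                                   length_min=1500, length_max=3000,
                                   length_mu=7.6)
        reads, truth = simdata.simulate_reads(g.sequence, spec, circular=True)
        cfg = PipelineConfig(genome_size=12_000, seed=1)
        out = stage_assemble(reads, cfg)
        main = [c for c in out.contigs if c.cls == "contig"]
        assert len(main) == 1
        assert main[0].circular
        assert any(a == b for a, _, b, _, _ in out.links)
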