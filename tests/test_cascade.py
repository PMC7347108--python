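"""Cascade engine: fusion, lifetimes, breakage, ligation, TST, kataegis,
second wave, mis-segregation, full lineages."""

import json
import math

import numpy as np
import pytest

from bridgecascade import (
    CascadeConfig,
    CellGenome,
    GenomicInterval,
    apply_kataegis,
    break_bridge,
    diploid_cell,
    divide_with_missegregation,
    generate_tst_chain,
    ligate_fragments,
    make_fusion,
    make_rng,
    mitotic_second_wave,
    run_cascade,
    sample_bridge_lifetime,
    truth_cn_profile,
)
from bridgecascade.cascade import CascadeError, RETAINED, SISTER, TYPE1, TYPE2
from bridgecascade.genome import reference_derivative
from bridgecascade.stats import wilson_ci


class TestFusion:
    def test_sister_fusion_is_mirror_dicentric(self, genome, config, rng):
        fus = make_fusion(genome, config, rng, kind="sister")
        der = fus.dicentrics[0].derivative
        assert der.centromere_count(genome) == 2
        s1, s2 = der.segments
        assert s1.interval == s2.interval and {s1.orientation, s2.orientation} == {"+", "-"}
        assert der.left_telomere and der.right_telomere

    def test_chromosome_type_gives_dicentric_pair(self, genome, config, rng):
        fus = make_fusion(genome, config, rng, kind="chromosome_type")
        assert len(fus.dicentrics) == 2 and fus.antiparallel
        for dic in fus.dicentrics:
            chroms = {s.interval.chrom for s in dic.derivative.segments}
            assert len(chroms) == 2
            assert dic.derivative.centromere_count(genome) == 2

    def test_fusion_type_probabilities_respected(self, genome, rng):
        cfg = CascadeConfig(p_fusion_type=(1.0, 0.0, 0.0))
        kinds = {make_fusion(genome, cfg, rng).kind for _ in range(1000)}
        assert kinds == {SISTER}


class TestBridgeLifetime:
    def test_empirical_median_matches_configured(self, config):
        rng = make_rng(2)
        cfg = config.with_(cell_cycle_h=1e9)
        draws = [sample_bridge_lifetime(cfg, rng)[0] for _ in range(10_000)]
        assert abs(np.median(draws) - 10.0) < 0.5

    def test_zero_horizon_always_censored(self, config):
        rng = make_rng(3)
        cfg = config.with_(cell_cycle_h=1e-9)
        assert all(sample_bridge_lifetime(cfg, rng)[1] for _ in range(100))

    def test_censoring_fraction_closed_form(self, config):
        # P(survive 24 h | median 10 h) = 2^(-2.4) ~ 0.19
        rng = make_rng(4)
        frac = np.mean([sample_bridge_lifetime(config, rng)[1] for _ in range(20_000)])
        assert abs(frac - 2 ** (-2.4)) < 0.01
        assert abs(config.p_break_before_mitosis - (1 - 2 ** (-2.4))) < 1e-12


class TestBreakBridge:
    def test_simple_sister_reciprocal_terminal(self, genome, config):
        rng = make_rng(10)
        cfg = config.with_(p_fragmentation=0.0, p_tst=0.0)
        fus = make_fusion(genome, cfg, rng, kind="sister")
        out = break_bridge(genome, fus, cfg, rng)
        assert out.mode == "simple"
        (truth,) = out.truth_events
        assert truth.kinds == [TYPE1]
        iv = truth.intervals[0]
        pa = truth_cn_profile(out.daughter_a, 100_000, genome)
        pb = truth_cn_profile(out.daughter_b, 100_000, genome)
        cn_a, cn_b = pa.cn(iv.chrom, iv.haplotype), pb.cn(iv.chrom, iv.haplotype)
        b0, b1 = iv.start // 100_000 + 1, iv.end // 100_000 - 1
        assert np.all(cn_a[b0:b1] == 2.0) and np.all(cn_b[b0:b1] == 0.0)

    def test_chromosome_type_internal_exchange(self, genome, config):
        cfg = config.with_(p_fragmentation=0.0, p_tst=0.0)
        found = False
        for seed in range(40):
            rng = make_rng(seed, 8)
            fus = make_fusion(genome, cfg, rng, kind="chromosome_type")
            out = break_bridge(genome, fus, cfg, rng)
            (truth,) = out.truth_events
            if truth.kinds == [TYPE2]:
                found = True
                iv = truth.intervals[0]
                gain = out.daughter_a if truth.gaining_daughter == "a" else out.daughter_b
                loss = out.daughter_b if truth.gaining_daughter == "a" else out.daughter_a
                pg = truth_cn_profile(gain, 100_000, genome)
                pl = truth_cn_profile(loss, 100_000, genome)
                b0, b1 = iv.start // 100_000 + 1, iv.end // 100_000 - 1
                assert np.all(pg.cn(iv.chrom, iv.haplotype)[b0:b1] == 2.0)
                assert np.all(pl.cn(iv.chrom, iv.haplotype)[b0:b1] == 0.0)
                # flanks unchanged at one copy
                assert pg.cn(iv.chrom, iv.haplotype)[b0 - 2] == 1.0
                break
        assert found

    def test_exchange_respects_min_break_offset(self, genome, config):
        rng = make_rng(6)
        for _ in range(50):
            fus = make_fusion(genome, config, rng)
            out = break_bridge(genome, fus, config, rng)
            exchanged = sum(iv.length for t in out.truth_events for iv in t.intervals)
            assert exchanged >= config.min_break_offset

    def test_fragmentation_conserves_cn_when_nothing_lost(self, genome):
        cfg = CascadeConfig(retention_floor=0.73, replicated_fraction=0.27)
        for seed in range(15):
            rng = make_rng(seed, 55)
            fus = make_fusion(genome, cfg, rng)
            out = break_bridge(genome, fus, cfg, rng)
            pa = truth_cn_profile(out.daughter_a, 100_000, genome)
            pb = truth_cn_profile(out.daughter_b, 100_000, genome)
            for key in pa.cov:
                total = (pa.cov[key] + pb.cov[key]) / pa.bin_widths(key[0])
                assert np.allclose(total, 2.0), (seed, key)

    def test_non_dicentric_input_rejected(self, genome, config, rng):
        fus = make_fusion(genome, config, rng, kind="sister")
        fus.dicentrics[0].derivative = reference_derivative(genome, "chrA", "A")
        with pytest.raises(CascadeError):
            break_bridge(genome, fus, config, rng)


class TestLigation:
    def _frags(self, genome, n):
        from bridgecascade import Segment

        return [
            Segment(GenomicInterval("chrB", i * 1_000_000, (i + 1) * 1_000_000, "A"))
            for i in range(n)
        ]

    def test_single_fragment_single_junction(self, genome, rng):
        stub, _ = reference_derivative(genome, "chrA", "A").split_at(30_000_000)
        der, jx = ligate_fragments(genome, stub, self._frags(genome, 1), rng)
        assert len(jx) == 1
        assert der.length == stub.length + 1_000_000

    def test_n_fragments_n_junctions(self, genome, rng):
        stub, _ = reference_derivative(genome, "chrA", "A").split_at(30_000_000)
        for n in (2, 5, 8):
            der, jx = ligate_fragments(genome, stub, self._frags(genome, n), rng)
            assert len(jx) == n

    def test_order_orientation_uniform(self, genome):
        # 3 fragments -> 3! x 2^3 = 48 equally likely outcomes
        rng = make_rng(8)
        stub, _ = reference_derivative(genome, "chrA", "A").split_at(30_000_000)
        frags = self._frags(genome, 3)
        counts = {}
        n_draws = 10_000
        for _ in range(n_draws):
            der, _ = ligate_fragments(genome, stub, frags, rng)
            key = tuple(
                (s.interval.start, s.orientation) for s in der.segments[1:]
            )
            counts[key] = counts.get(key, 0) + 1
        assert len(counts) == 48
        expected = n_draws / 48
        sd = math.sqrt(n_draws * (1 / 48) * (47 / 48))
        assert all(abs(c - expected) < 3 * sd for c in counts.values())


class TestTST:
    def test_insertion_length_median(self, small_genome, config):
        rng = make_rng(31)
        regions = [GenomicInterval("c1", 4_500_000, 7_500_000, "A")]
        lengths = []
        while len(lengths) < 2000:
            ts = generate_tst_chain(small_genome, regions, config, rng)
            lengths += ts.insertion_lengths()
        med = np.median(lengths[:2000])
        assert 160 <= med <= 210

    def test_hotspot_span_within_window(self, small_genome, config):
        rng = make_rng(32)
        regions = [GenomicInterval("c1", 4_500_000, 7_500_000, "A")]
        for _ in range(20):
            ts = generate_tst_chain(small_genome, regions, config, rng)
            for h in ts.hotspots:
                assert max(h.breakpoints) - min(h.breakpoints) <= config.tst_hotspot_window
                assert h.end - h.start <= config.tst_hotspot_window

    def test_thirteen_junction_chain_with_mixed_homology_producible(self, small_genome, config):
        rng = make_rng(33)
        regions = [GenomicInterval("c1", 4_500_000, 7_500_000, "A")]
        seen_13 = False
        kinds = set()
        for _ in range(200):
            ts = generate_tst_chain(small_genome, regions, config, rng)
            for chain, homs in zip(ts.chains, ts.inner_homologies):
                kinds |= {h.kind for h in homs}
                if len(homs) >= 13:
                    seen_13 = True
        assert seen_13
        assert kinds == {"blunt", "microhomology", "untemplated_insert"}


class TestKataegis:
    def test_strand_and_context_forced(self, genome, config):
        rng = make_rng(41)
        region = GenomicInterval("chrA", 25_000_000, 27_000_000, "A")
        muts = apply_kataegis(genome, region, "+", config, rng)
        assert len(muts) >= config.kataegis_min_mutations
        assert {m.strand for m in muts} == {"+"}
        for m in muts:
            assert genome.sequence(m.chrom, m.pos - 1, m.pos + 1) == "TC"
            assert m.ref == "C" and m.alt in "TG"

    def test_mean_imd_below_1kb(self, genome, config):
        rng = make_rng(42)
        region = GenomicInterval("chrA", 25_000_000, 29_000_000, "A")
        ok = 0
        for _ in range(500):
            muts = apply_kataegis(genome, region, "+", config, rng)
            pos = sorted(m.pos for m in muts)
            ok += np.mean(np.diff(pos)) <= 1000
        assert ok / 500 >= 0.99


class TestSecondWave:
    def _stub_cell(self, genome, config, seed):
        rng = make_rng(seed, 91)
        fus = make_fusion(genome, config, rng, kind="sister")
        out = break_bridge(genome, fus, config, rng)
        return out.daughter_b, rng

    def test_zero_mean_is_noop(self, genome, config):
        cell, rng = self._stub_cell(genome, config.with_(second_wave_breaks_mean=0.0), 1)
        before = [list(d.segments) for d in cell.derivatives]
        sw = mitotic_second_wave(genome, cell, config.with_(second_wave_breaks_mean=0.0), rng)
        assert not sw.applied
        assert [list(d.segments) for d in cell.derivatives] == before

    def test_no_stub_is_logged_noop(self, genome, config, rng):
        cell = diploid_cell(genome)
        sw = mitotic_second_wave(genome, cell, config, rng)
        assert not sw.applied and sw.n_breaks == 0

    def test_breaks_confined_to_stub_region(self, genome, config):
        cell, rng = self._stub_cell(genome, config, 2)
        idx = cell.stub_index
        der = cell.derivatives[idx]
        region_ivs = None
        sw = mitotic_second_wave(genome, cell, config, rng)
        if sw.applied:
            allowed = {
                (iv.chrom, iv.haplotype): (iv.start, iv.end) for iv in sw.region
            }
            span = config.stub_region_bp
            for f in sw.fragments:
                iv = f.segment.interval
                lo, hi = min(a for a, b in allowed.values()), max(b for a, b in allowed.values())
                assert iv.end - iv.start <= span


class TestDivision:
    def test_control_cells_never_micronucleate(self, genome, config):
        rng = make_rng(51)
        for _ in range(2000):
            cell = diploid_cell(genome)
            _, _, div = divide_with_missegregation(genome, cell, config, rng)
            assert not div.micronucleated

    def test_broken_bridge_rate_within_wilson_ci(self, genome, config):
        rng = make_rng(52)
        n, hits = 3000, 0
        for _ in range(n):
            cell = diploid_cell(genome)
            cell.bridge_history = True
            cell.bridge_broken_interphase = True
            _, _, div = divide_with_missegregation(genome, cell, config, rng)
            hits += div.micronucleated
        lo, hi = wilson_ci(hits, n)
        assert lo <= 0.52 <= hi

    def test_certain_micronucleation(self, genome):
        cfg = CascadeConfig(p_micronucleus_broken=1.0)
        rng = make_rng(53)
        for _ in range(50):
            cell = diploid_cell(genome)
            cell.bridge_history = True
            cell.bridge_broken_interphase = True
            da, db, div = divide_with_missegregation(genome, cell, cfg, rng)
            assert div.micronucleated
            assert da.micronucleated() or db.micronucleated()


class TestRunCascade:
    def test_seed_determinism_byte_identical_log(self, genome, config):
        def log_bytes(seed):
            lin = run_cascade(genome, config, 2, seed)
            return json.dumps(
                [(e.event_id, e.generation, e.cell_id, e.etype, e.payload)
                 for e in lin.events],
                sort_keys=True,
            ).encode()

        assert log_bytes(77) == log_bytes(77)
        assert log_bytes(77) != log_bytes(78)

    def test_pure_simple_mode_emits_single_reciprocal_exchange(self, genome):
        cfg = CascadeConfig(p_fragmentation=0.0, p_tst=0.0, second_wave_breaks_mean=0.0)
        for seed in range(10):
            lin = run_cascade(genome, cfg, 1, seed)
            breakage = [e for e in lin.events if e.etype == "bridge_breakage"]
            assert len(breakage) == 1
            assert breakage[0].payload["n_fragments"] == 0
            # no ligation junctions: only the fusion junction itself
            for cell in lin.cells_at(1):
                assert len(lin.junctions_by_cell[cell.cell_id]) <= 1

    def test_every_junction_traceable_to_logged_event(self, genome, config):
        lin = run_cascade(genome, config, 2, seed=5)
        breakage_events = [e for e in lin.events
                           if e.etype in ("bridge_breakage", "second_wave",
                                          "mn_chromothripsis", "mn_interphase_chromothripsis",
                                          "fusion")]
        assert breakage_events
        for cell in lin.cells_at(2):
            n_j = len(lin.junctions_by_cell[cell.cell_id])
            if n_j > 1:
                assert any(e.etype != "fusion" for e in breakage_events)


class TestParameterRecovery:
    def test_rates_recovered_from_2000_lineages(self, genome, config):
        rng = make_rng(61)
        n = 2000
        tst_pos = 0
        lengths = []
        mn = 0
        for i in range(n):
            fus = make_fusion(genome, config, rng)
            out = break_bridge(genome, fus, config, rng)
            if out.tst is not None:
                tst_pos += 1
                lengths += out.tst.insertion_lengths()
            cell = out.daughter_a
            _, _, div = divide_with_missegregation(genome, cell, config, rng)
            mn += div.micronucleated
        lo, hi = wilson_ci(tst_pos, n)
        assert lo <= config.p_tst <= hi
        lo, hi = wilson_ci(mn, n)
        assert lo <= config.p_micronucleus_broken <= hi
        med = float(np.median(lengths))
        # bootstrap-free check: median of the log-normal is the configured 183 bp
        assert 160 <= med <= 210
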