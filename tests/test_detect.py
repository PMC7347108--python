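"""Signature detectors: segmentation, reciprocity, islands, hotspots,
TST parsing, homology, kataegis, chromothripsis, sloping transitions."""

import numpy as np
import pytest

from bridgecascade import (
    CascadeConfig,
    CoverageModel,
    GenomicInterval,
    ObservedProfile,
    break_bridge,
    call_chromothripsis,
    classify_daughter_pair,
    classify_junction_homology,
    cluster_hotspots,
    detect_kataegis,
    detect_local_fragmentation,
    detect_sloping_transition,
    diploid_cell,
    generate_tst_chain,
    make_fusion,
    make_rng,
    parse_tst_chains,
    segment_cn,
    segments_from_truth,
    truth_cn_profile,
)
from bridgecascade.cascade import Mutation, mitotic_second_wave
from bridgecascade.detect import _segment_array, impute_dropout
from bridgecascade.junctions import (
    BLUNT,
    MICROHOMOLOGY,
    UNTEMPLATED,
    Breakend,
    Junction,
)


def _obs(genome, bin_size, arrays):
    counts = {k: np.asarray(v, dtype=float) for k, v in arrays.items()}
    return ObservedProfile(genome, bin_size, counts, 1.0)


def _lsq_changepoint_oracle(y):
    """Exhaustive least-squares single changepoint (O(n) via cumsums)."""
    n = len(y)
    cs = np.concatenate([[0.0], np.cumsum(y)])
    css = np.concatenate([[0.0], np.cumsum(y * y)])
    best, best_k = np.inf, None
    for k in range(1, n):
        sl, sr = cs[k], cs[-1] - cs[k]
        sse = (css[k] - sl * sl / k) + (css[-1] - css[k] - sr * sr / (n - k))
        if sse < best:
            best, best_k = sse, k
    return best_k


class TestSegmentation:
    def test_constant_profile_single_segment(self, genome):
        obs = _obs(genome, 250_000, {("chrA", "A"): np.ones(160)})
        segs = segment_cn(obs)
        assert len(segs) == 1 and segs[0].cn == 1

    def test_noiseless_step_exact_breakpoint(self, genome):
        y = np.r_[np.ones(60), 2 * np.ones(100)]
        obs = _obs(genome, 250_000, {("chrA", "A"): y})
        segs = sorted(segment_cn(obs), key=lambda s: s.start)
        assert [(s.start, s.end, s.cn) for s in segs] == [
            (0, 15_000_000, 1), (15_000_000, 40_000_000, 2)
        ]

    def test_all_zero_single_cn0_segment(self, genome):
        obs = _obs(genome, 250_000, {("chrC", "B"): np.zeros(80)})
        segs = segment_cn(obs)
        assert len(segs) == 1 and segs[0].cn == 0

    def test_noisy_step_matches_lsq_oracle_within_one_bin(self):
        rng = make_rng(71)
        hits = 0
        for _ in range(100):
            n = 300
            k_true = int(rng.integers(40, 260))
            y = np.r_[np.zeros(k_true), np.ones(n - k_true)]
            y = y + rng.normal(0, 0.3, n)
            cuts = _segment_array(y, 5.0, 3)
            boundaries = sorted({a for a, b in cuts} - {0})
            oracle = _lsq_changepoint_oracle(y)
            hits += any(abs(b - oracle) <= 1 for b in boundaries)
        assert hits == 100

    def test_dropout_imputation_only_touches_short_zero_runs(self):
        y = np.array([1.0, 0.0, 1.2, 0.0, 0.0, 0.0, 0.9, 1.1, 0.0, 0.0, 1.0])
        out = impute_dropout(y)
        assert out[1] == pytest.approx(1.1)  # isolated zero imputed
        assert np.all(out[3:6] == 0.0)  # 3-bin zero run untouched
        assert np.all(out[8:10] == pytest.approx(1.05))  # 2-bin run imputed


class TestReciprocity:
    def _pipeline(self, genome, cfg, seed, kind=None):
        rng = make_rng(seed, 13)
        fus = make_fusion(genome, cfg, rng, kind=kind)
        out = break_bridge(genome, fus, cfg, rng)
        pa = truth_cn_profile(out.daughter_a, 250_000, genome)
        pb = truth_cn_profile(out.daughter_b, 250_000, genome)
        return out, segments_from_truth(pa), segments_from_truth(pb)

    def test_terminal_exchange_called_type1(self, genome):
        cfg = CascadeConfig(p_fragmentation=0.0, p_tst=0.0)
        out, sa, sb = self._pipeline(genome, cfg, 1, kind="sister")
        events = classify_daughter_pair(sa, sb, genome)
        assert len(events) == 1 and events[0].kind == "Type1_terminal"

    def test_internal_exchange_called_type2_not_duplication(self, genome):
        cfg = CascadeConfig(p_fragmentation=0.0, p_tst=0.0)
        for seed in range(40):
            out, sa, sb = self._pipeline(genome, cfg, seed, kind="chromosome_type")
            if out.truth_events[0].kinds == ["Type2_internal"]:
                events = classify_daughter_pair(sa, sb, genome)
                assert len(events) == 1
                # with both daughters available the internal gain is reported
                # as an exchange, never as a duplication in one cell
                assert events[0].kind == "Type2_internal"
                assert events[0].gaining_daughter == out.truth_events[0].gaining_daughter
                return
        pytest.fail("no internal-exchange case drawn")

    def test_identical_profiles_no_events(self, genome):
        cell = diploid_cell(genome)
        segs = segments_from_truth(truth_cn_profile(cell, 250_000, genome))
        assert classify_daughter_pair(segs, segs, genome) == []

    def test_closure_noiseless_truth_recovers_logged_events_exactly(self, genome):
        cfg = CascadeConfig(p_fragmentation=0.0, p_tst=0.0)
        for seed in range(15):
            out, sa, sb = self._pipeline(genome, cfg, seed)
            events = classify_daughter_pair(sa, sb, genome)
            truth = [
                (iv.chrom, iv.haplotype, iv.start, iv.end, k, t.gaining_daughter)
                for t in out.truth_events
                for iv, k in zip(t.intervals, t.kinds)
                if iv.length >= 2_500_000
            ]
            got = [
                (e.chrom, e.haplotype, e.start, e.end, e.kind, e.gaining_daughter)
                for e in events
            ]
            # interval-exact up to bin quantization of the 250 kb grid
            assert len(got) == len(truth)
            for (c1, h1, s1, e1, k1, g1), (c2, h2, s2, e2, k2, g2) in zip(
                sorted(got), sorted(truth)
            ):
                assert (c1, h1, k1, g1) == (c2, h2, k2, g2)
                assert abs(s1 - s2) <= 250_000 and abs(e1 - e2) <= 250_000


class TestFragmentIslands:
    def test_no_loss_region_no_islands(self, genome):
        obs = _obs(genome, 25_000, {("chrA", "A"): np.ones(1600)})
        segs = segment_cn(obs)
        assert detect_local_fragmentation(segs, 25_000, observed=obs) == []

    def test_noiseless_islands_match_truth_overlap_oracle(self, genome):
        bs = 25_000
        y = np.ones(1600)
        y[560:960] = 0.0  # 10 Mb loss
        islands_true = [(600, 602), (700, 706), (800, 816)]  # 50, 150, 400 kb
        for a, b in islands_true:
            y[a:b] = 1.0
        obs = _obs(genome, bs, {("chrA", "A"): y})
        segs = segment_cn(obs)
        found = detect_local_fragmentation(segs, bs, observed=obs)
        # every >= 100 kb truth island is recovered with matching extent
        for a, b in islands_true:
            if (b - a) * bs >= 100_000:
                match = [
                    i for i in found
                    if abs(i.start - a * bs) <= bs and abs(i.end - b * bs) <= bs
                ]
                assert len(match) == 1
        # no hallucinated islands outside truth
        for i in found:
            assert any(
                i.start < b * bs and i.end > a * bs for a, b in islands_true
            )


class TestHotspots:
    def test_single_breakpoint(self):
        (h,) = cluster_hotspots([("chrA", 5)])
        assert h.span == 0 and h.count == 1

    def test_linkage_partition(self):
        hs = cluster_hotspots(
            [("chrA", 0), ("chrA", 1000), ("chrA", 2000),
             ("chrA", 1_000_000), ("chrA", 1_003_000)]
        )
        assert sorted(h.count for h in hs) == [2, 3]

    def test_random_set_matches_gap_scan_oracle(self, rng):
        pos = sorted(int(x) for x in rng.integers(0, 5_000_000, size=100))
        window = 10_000
        hs = cluster_hotspots([("c", p) for p in pos], window)
        # oracle: sort then split at gaps > window
        oracle, cur = [], [pos[0]]
        for p in pos[1:]:
            if p - cur[-1] <= window:
                cur.append(p)
            else:
                oracle.append(tuple(cur))
                cur = [p]
        oracle.append(tuple(cur))
        assert [h.members for h in hs] == oracle

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            cluster_hotspots([])


class TestTSTParsing:
    def test_empty_junctions_negative(self, small_genome):
        call = parse_tst_chains([], small_genome)
        assert not call.positive and call.chains == []

    def test_simple_deletion_junction_not_tst(self, small_genome):
        j = Junction(Breakend("c1", 1_000_000, "+", "A"),
                     Breakend("c1", 2_000_000, "-", "A"))
        call = parse_tst_chains([j], small_genome)
        assert not call.positive

    def test_planted_chains_recovered(self, small_genome):
        cfg = CascadeConfig()
        rng = make_rng(21)
        regions = [GenomicInterval("c1", 4_500_000, 7_500_000, "A")]
        ts = generate_tst_chain(small_genome, regions, cfg, rng)
        jx = [
            Junction(Breakend("c1", 4_600_000, "+", "A"),
                     Breakend("c1", 7_000_000, "-", "A"),
                     chain, inner_homology=hom, untemplated_seqs=unt)
            for chain, hom, unt in zip(ts.chains, ts.inner_homologies, ts.untemplated_seqs)
        ]
        call = parse_tst_chains(jx, small_genome)
        assert call.positive
        assert len(call.chains) == len(jx)
        for parsed, truth in zip(call.chains, jx):
            assert len(parsed.insertions) == len(truth.insertions)
            for got, want in zip(parsed.insertions, truth.insertions):
                # boundaries ambiguous up to accidental flank homology
                assert got.source.chrom == want.source.chrom
                assert got.strand == want.strand
                assert abs(got.source.start - want.source.start) <= 4
                assert abs(got.source.end - want.source.end) <= 4
        # hotspot count equals clustering of the planted sources
        truth_sources = [
            (i.source.chrom, p)
            for j in jx for i in j.insertions
            for p in (i.source.start, i.source.end)
        ]
        assert len(call.hotspots) == len(cluster_hotspots(truth_sources, 10_000))

    def test_insertion_length_median_reported(self, small_genome):
        cfg = CascadeConfig()
        rng = make_rng(22)
        regions = [GenomicInterval("c1", 4_500_000, 7_500_000, "A")]
        ts = generate_tst_chain(small_genome, regions, cfg, rng)
        jx = [Junction(Breakend("c1", 4_600_000, "+", "A"),
                       Breakend("c1", 7_000_000, "-", "A"),
                       ts.chains[0], inner_homology=ts.inner_homologies[0],
                       untemplated_seqs=ts.untemplated_seqs[0])]
        call = parse_tst_chains(jx, small_genome)
        assert call.insertion_length_median == pytest.approx(
            np.median([i.length for i in ts.chains[0]]), abs=5
        )


class TestJunctionHomology:
    def _brute_force_overlap(self, genome, j, flank=50):
        b1, b2 = j.bnd1, j.bnd2
        if b1.orient == "+":
            t = genome.sequence(b1.chrom, b1.pos - flank, b1.pos)
        else:
            t = genome.sequence(b1.chrom, b1.pos, b1.pos + flank, "-")
        if b2.orient == "-":
            u = genome.sequence(b2.chrom, b2.pos - flank, b2.pos)
        else:
            u = genome.sequence(b2.chrom, b2.pos, b2.pos + flank, "-")
        h = 0
        for k in range(1, flank + 1):
            if t[-k:] == u[-k:]:
                h = k
        return h

    def test_random_junction_is_blunt(self, small_genome):
        j = Junction(Breakend("c1", 500_000, "+", "A"), Breakend("c2", 800_000, "-", "A"))
        h = classify_junction_homology(j, small_genome)
        oracle = self._brute_force_overlap(small_genome, j)
        assert oracle <= 1 and h.kind == BLUNT

    def test_planted_microhomology_length(self, small_genome):
        # choose bnd2 whose upstream context repeats bnd1's 5-base tail
        tail = small_genome.sequence("c1", 499_995, 500_000)
        window = small_genome.sequence("c2", 0, 200_000)
        q = window.find(tail, 1000)
        assert q != -1
        j = Junction(Breakend("c1", 500_000, "+", "A"),
                     Breakend("c2", q + 5, "-", "A"))
        h = classify_junction_homology(j, small_genome)
        oracle = self._brute_force_overlap(small_genome, j)
        assert oracle >= 5
        assert h.kind == MICROHOMOLOGY and h.length == oracle

    def test_untemplated_insert_classified_by_length(self, small_genome):
        j = Junction(Breakend("c1", 500_000, "+", "A"),
                     Breakend("c2", 800_000, "-", "A"))
        h = classify_junction_homology(j, small_genome, insertion_seq="TTAGGCA")
        assert h.kind == UNTEMPLATED and h.length == 7


class TestKataegisDetection:
    def _muts(self, genome, positions, strand="+"):
        out = []
        for p in positions:
            out.append(Mutation("chrA", p, "C", "T", strand, "A"))
        return out

    def _tpc_positions(self, genome, start, n, gap):
        # walk TpC sites with approximately the requested spacing
        seq = genome.sequence("chrA", start, start + 400_000)
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        sites = np.flatnonzero((arr[:-1] == ord("T")) & (arr[1:] == ord("C"))) + 1
        picked, cur = [], 0
        for _ in range(n):
            picked.append(start + int(sites[cur]))
            nxt = np.searchsorted(sites, sites[cur] + gap)
            cur = min(int(nxt), len(sites) - 1)
        return picked

    def test_five_mutations_below_threshold(self, genome):
        pos = self._tpc_positions(genome, 1_000_000, 5, 200)
        assert detect_kataegis(self._muts(genome, pos), genome) == []

    def test_planted_cluster_called_once(self, genome):
        pos = self._tpc_positions(genome, 2_000_000, 8, 200)
        calls = detect_kataegis(self._muts(genome, pos), genome)
        assert len(calls) == 1
        assert calls[0].n_mutations == 8 and calls[0].tpc_fraction == 1.0

    def test_uniform_background_false_positive_rate(self, genome):
        rng = make_rng(73)
        fp = 0
        for _ in range(100):
            pos = sorted(int(x) for x in rng.integers(0, 40_000_000, size=10_000))
            muts = self._muts(genome, pos)
            fp += bool(detect_kataegis(muts, genome))
        assert fp < 1 + 0.01 * 100 * 2  # < ~1% with margin for the binomial draw

    def test_simulated_cluster_detected(self, genome, config):
        from bridgecascade import apply_kataegis

        rng = make_rng(74)
        region = GenomicInterval("chrA", 30_000_000, 32_000_000, "A")
        muts = apply_kataegis(genome, region, "-", config, rng)
        calls = detect_kataegis(muts, genome)
        assert len(calls) == 1 and calls[0].tpc_fraction >= 0.5


class TestChromothripsis:
    def test_intact_chromosome_negative(self, genome):
        cell = diploid_cell(genome)
        segs = segments_from_truth(truth_cn_profile(cell, 250_000, genome))
        rep = call_chromothripsis(segs, [], genome)
        assert not rep.positive

    def test_simple_breakage_negative(self, genome):
        cfg = CascadeConfig(p_fragmentation=0.0, p_tst=0.0)
        rng = make_rng(75)
        fus = make_fusion(genome, cfg, rng, kind="sister")
        out = break_bridge(genome, fus, cfg, rng)
        segs = segments_from_truth(truth_cn_profile(out.daughter_a, 250_000, genome))
        rep = call_chromothripsis(segs, out.junctions, genome)
        assert not rep.positive

    def test_second_wave_fires_caller_in_most_cells(self, genome, config):
        rng = make_rng(76)
        positive = 0
        n = 100
        for i in range(n):
            fus = make_fusion(genome, config, rng)
            out = break_bridge(genome, fus, config, rng)
            cell = out.daughter_b if out.daughter_b.stub_index is not None else out.daughter_a
            jx = list(out.junctions)
            sw = mitotic_second_wave(genome, cell, config, rng)
            jx += sw.junctions
            segs = segments_from_truth(truth_cn_profile(cell, 100_000, genome))
            rep = call_chromothripsis(segs, jx, genome)
            positive += rep.positive
        assert positive / n >= 0.70


class TestSlopingTransition:
    def test_clean_step(self):
        y = np.r_[np.ones(120), np.zeros(120)]
        assert detect_sloping_transition(y).kind == "step"

    def test_clean_ramp_bounds_within_two_bins(self):
        y = np.r_[np.ones(80), np.linspace(1, 0, 200), np.zeros(80)]
        fit = detect_sloping_transition(y, bin_size=25_000)
        assert fit.kind == "slope"
        i, j = fit.ramp_bounds
        assert abs(i - 80) <= 2 and abs(j - 280) <= 2

    def test_narrow_ramp_not_called_slope(self):
        # ramp under the 2 Mb width floor collapses to step
        y = np.r_[np.ones(200), np.linspace(1, 0, 20), np.zeros(200)]
        fit = detect_sloping_transition(y, bin_size=25_000)
        assert fit.kind in ("step",)

    def test_window_too_small_raises(self):
        with pytest.raises(ValueError):
            detect_sloping_transition(np.ones(20))
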