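"""Stochastic engine for the chromosome-bridge mutational cascade.

The cascade is: end-to-end fusion of chromatids -> a dicentric chromosome
bridge between the daughter nuclei -> mechanical breakage (simple break or
local fragmentation with fragment loss/retention/circularization) -> repair
by end-joining and, in a subset of events, tandem-short-template (TST)
insertion chains with kataegis -> a second wave of breakage on the
under-replicated bridge stub at the next mitosis -> frequent mis-segregation
of the bridge chromosome into micronuclei -> further breakage-fusion-bridge
iterations in later generations.

All randomness flows through one counter-based generator (Philox) seeded per
lineage, so the event log is a deterministic function of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .config import CascadeConfig
from .genome import (
    BRIDGE,
    HAPLOTYPES,
    MICRONUCLEUS,
    PRIMARY,
    CellGenome,
    DerivativeChromosome,
    GenomeDeclaration,
    GenomeError,
    GenomicInterval,
    Segment,
    diploid_cell,
    recompute_caps,
    reference_derivative,
)
from .junctions import (
    BLUNT,
    MICROHOMOLOGY,
    UNTEMPLATED,
    Breakend,
    Homology,
    Junction,
    TemplatedInsertion,
    segment_left_breakend,
    segment_right_breakend,
)

SISTER, NONSISTER, CHROMOSOME_TYPE = "sister", "nonsister", "chromosome_type"
RETAINED, LOST, CIRCULARIZED = "retained", "lost", "circularized"
TYPE1, TYPE2 = "Type1_terminal", "Type2_internal"


class CascadeError(RuntimeError):
    pass


def make_rng(seed: int, *stream: int) -> np.random.Generator:
    """Philox generator for a (seed, stream...) pair; fully reproducible."""
    return np.random.Generator(np.random.Philox(key=np.uint64(abs(hash((int(seed),) + tuple(int(s) for s in stream))) % (2**63))))


@dataclass(frozen=True)
class Mutation:
    """A single clustered point substitution (kataegis member)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    strand: str
    haplotype: str


# ---------------------------------------------------------------------------
# fusion
# ---------------------------------------------------------------------------

@dataclass
class Dicentric:
    """A two-centromere derivative plus the path position of its fusion point."""

    derivative: DerivativeChromosome
    fusion_path_pos: int

    def break_interval(self, genome: GenomeDeclaration) -> tuple[int, int]:
        """Path interval strictly between the two centromeres."""
        spans = self.derivative.centromere_spans(genome)
        if len(spans) < 2:
            raise CascadeError("break_bridge requires a dicentric (2 centromeres)")
        return spans[0][1], spans[-1][0]


@dataclass
class FusionEvent:
    kind: str
    chroms: tuple[str, ...]
    haplotype: str
    dicentrics: list[Dicentric]
    junctions: list[Junction]
    antiparallel: bool = False


def make_fusion(
    genome: GenomeDeclaration,
    config: CascadeConfig,
    rng: np.random.Generator,
    kind: str | None = None,
) -> FusionEvent:
    """Create a dicentric chromatid pair by end-to-end fusion.

    ``sister``: the two sister chromatids of one homolog fuse at their q
    termini, giving a single mirror-symmetric dicentric.  ``nonsister``: one
    chromatid of each homolog fuses.  ``chromosome_type``: two different
    chromosomes fuse before replication, so replication yields a *pair* of
    identical dicentrics whose kinetochores can attach in antiparallel
    orientation.
    """
    if kind is None:
        kind = [SISTER, NONSISTER, CHROMOSOME_TYPE][
            rng.choice(3, p=np.asarray(config.p_fusion_type, dtype=float))
        ]
    c1 = config.fusion_chrom
    hap = config.fusion_haplotype
    L1 = genome.length(c1)

    if kind == SISTER:
        der = DerivativeChromosome(
            [
                Segment(GenomicInterval(c1, 0, L1, hap), "+"),
                Segment(GenomicInterval(c1, 0, L1, hap), "-"),
            ]
        )
        der = recompute_caps(genome, der)
        jx = Junction(Breakend(c1, L1, "+", hap), Breakend(c1, L1, "+", hap))
        return FusionEvent(kind, (c1,), hap, [Dicentric(der, L1)], [jx])

    if kind == NONSISTER:
        other = HAPLOTYPES[1] if hap == HAPLOTYPES[0] else HAPLOTYPES[0]
        der = DerivativeChromosome(
            [
                Segment(GenomicInterval(c1, 0, L1, hap), "+"),
                Segment(GenomicInterval(c1, 0, L1, other), "-"),
            ]
        )
        der = recompute_caps(genome, der)
        jx = Junction(Breakend(c1, L1, "+", hap), Breakend(c1, L1, "+", other))
        return FusionEvent(kind, (c1,), hap, [Dicentric(der, L1)], [jx])

    if kind == CHROMOSOME_TYPE:
        others = [n for n in genome.names() if n != c1]
        if not others:
            raise CascadeError("chromosome_type fusion needs >= 2 chromosomes")
        c2 = others[int(rng.integers(len(others)))]
        L2 = genome.length(c2)
        segs = [
            Segment(GenomicInterval(c1, 0, L1, hap), "+"),
            Segment(GenomicInterval(c2, 0, L2, hap), "-"),
        ]
        d1 = recompute_caps(genome, DerivativeChromosome(list(segs)))
        d2 = recompute_caps(genome, DerivativeChromosome(list(segs)))
        jx = Junction(Breakend(c1, L1, "+", hap), Breakend(c2, L2, "+", hap))
        return FusionEvent(
            kind, (c1, c2), hap, [Dicentric(d1, L1), Dicentric(d2, L1)], [jx, jx],
            antiparallel=True,
        )

    raise CascadeError(f"unknown fusion kind {kind!r}")


# ---------------------------------------------------------------------------
# bridge lifetime
# ---------------------------------------------------------------------------

def sample_bridge_lifetime(
    config: CascadeConfig, rng: np.random.Generator
) -> tuple[float, bool]:
    """Exponential waiting time to breakage, right-censored at the next mitosis.

    Returns ``(hours, censored)``; censored bridges persist unbroken into
    mitosis.  The exponential scale is set so the median equals the
    configured half-life.
    """
    t = rng.exponential(config.bridge_lifetime_median_h / math.log(2.0))
    horizon = config.cell_cycle_h
    if t >= horizon:
        return horizon, True
    return t, False


# ---------------------------------------------------------------------------
# fragment ligation
# ---------------------------------------------------------------------------

def ligate_fragments(
    genome: GenomeDeclaration,
    stub: DerivativeChromosome,
    fragments: Sequence[Segment],
    rng: np.random.Generator,
    attach_side: str = "right",
) -> tuple[DerivativeChromosome, list[Junction]]:
    """End-join fragments in random order and orientation onto a broken stub.

    Produces exactly ``len(fragments)`` junctions (the stub join plus the
    joins between consecutive fragments).  ``attach_side`` names the stub's
    broken end.
    """
    if not fragments:
        return stub, []
    order = rng.permutation(len(fragments))
    flips = rng.integers(0, 2, size=len(fragments))
    placed: list[Segment] = []
    for i, fl in zip(order, flips):
        seg = fragments[int(i)]
        if fl:
            seg = Segment(seg.interval, "-" if seg.orientation == "+" else "+")
        placed.append(seg)

    junctions: list[Junction] = []
    if attach_side == "right":
        chain = list(stub.segments) + placed
        for a, b in zip([stub.segments[-1]] + placed[:-1], placed):
            junctions.append(Junction(segment_right_breakend(a), segment_left_breakend(b)))
        der = DerivativeChromosome(chain, stub.left_telomere, False, stub.centromere_inactivated)
    elif attach_side == "left":
        chain = placed + list(stub.segments)
        for a, b in zip(placed, placed[1:] + [stub.segments[0]]):
            junctions.append(Junction(segment_right_breakend(a), segment_left_breakend(b)))
        der = DerivativeChromosome(chain, False, stub.right_telomere, stub.centromere_inactivated)
    else:
        raise CascadeError("attach_side must be 'left' or 'right'")
    return recompute_caps(genome, der), junctions


# ---------------------------------------------------------------------------
# TST chains
# ---------------------------------------------------------------------------

@dataclass
class Hotspot:
    chrom: str
    start: int
    end: int
    breakpoints: list[int]
    haplotype: str = "A"


@dataclass
class TSTChainSet:
    """Truth record of generated TST chains and their source hotspots."""

    hotspots: list[Hotspot]
    chains: list[tuple[TemplatedInsertion, ...]]
    inner_homologies: list[tuple[Homology, ...]]
    untemplated_seqs: list[tuple[str, ...]]

    def insertion_lengths(self) -> list[int]:
        return [ins.length for ch in self.chains for ins in ch]


def _draw_homology(config: CascadeConfig, rng: np.random.Generator, allow_mh: bool) -> str:
    w = np.asarray(config.tst_homology_mix, dtype=float)
    if not allow_mh:
        w = w[[0, 2]]
        return [BLUNT, UNTEMPLATED][int(rng.choice(2, p=w / w.sum()))]
    return [BLUNT, MICROHOMOLOGY, UNTEMPLATED][int(rng.choice(3, p=w / w.sum()))]


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[int(i)] for i in rng.integers(0, 4, size=n))


def generate_tst_chain(
    genome: GenomeDeclaration,
    break_regions: Sequence[GenomicInterval],
    config: CascadeConfig,
    rng: np.random.Generator,
) -> TSTChainSet:
    """Draw TST insertion chains sourced from clustered breakpoint hotspots.

    Hotspots are <= 10 kb windows, mostly inside the fragmented bridge
    region, occasionally on an intact chromosome elsewhere.  Each hotspot
    carries ~Poisson(10) breakpoints; each chain is a tandem array of short
    insertions (log-normal length, median 183 bp) whose sources are the
    hotspot breakpoints.  Junction flanks between chain members follow the
    configured blunt : microhomology : untemplated mix; microhomology joins
    are realized in sequence by choosing the next source so its upstream
    flank matches the previous insertion's tail.
    """
    if not break_regions:
        raise CascadeError("TST generation needs at least one break region")
    n_chains = 1 + int(rng.poisson(0.5))
    chain_lengths = [
        config.tst_chain_length_min + int(rng.poisson(config.tst_chain_length_extra_mean))
        for _ in range(n_chains)
    ]
    lo_h, hi_h = config.tst_hotspots_range
    # hotspots are heavily reused by the chains (a handful of hotspots feed
    # many tandem insertions), so cap their number below the insertion count
    hi_h = max(lo_h, min(hi_h, int(0.6 * sum(chain_lengths))))
    n_hot = int(rng.integers(lo_h, hi_h + 1))
    hotspots: list[Hotspot] = []
    for _ in range(n_hot):
        for _try in range(50):
            if rng.random() < config.tst_hotspot_elsewhere_p:
                chrom = genome.names()[int(rng.integers(len(genome.names())))]
                hap = HAPLOTYPES[int(rng.integers(2))]
                lo, hi = 0, genome.length(chrom)
            else:
                reg = break_regions[int(rng.integers(len(break_regions)))]
                chrom, lo, hi, hap = reg.chrom, reg.start, reg.end, reg.haplotype
            w = int(rng.uniform(1_000, config.tst_hotspot_window))
            if hi - lo <= w + 2_100:
                continue
            ws = int(rng.uniform(lo, hi - w - 2_100))
            m = max(2, int(rng.poisson(config.tst_breakpoints_per_hotspot)))
            bps = sorted(int(p) for p in rng.uniform(ws, ws + w, size=m))
            hotspots.append(Hotspot(chrom, ws, ws + w, bps, hap))
            break
        else:
            raise CascadeError("could not place TST hotspot within the genome")

    chains, homs, unts = [], [], []
    for k in chain_lengths:
        ins: list[TemplatedInsertion] = []
        inner: list[Homology] = []
        untempl: list[str] = []

        def draw_insertion(start: int | None = None, hs: Hotspot | None = None,
                           strand: str | None = None) -> TemplatedInsertion:
            if hs is None:
                hs = hotspots[int(rng.integers(len(hotspots)))]
            if start is None:
                start = hs.breakpoints[int(rng.integers(len(hs.breakpoints)))]
            if strand is None:
                strand = "+" if rng.random() < 0.7 else "-"
            length = int(
                np.clip(
                    rng.lognormal(math.log(config.tst_insertion_median_bp), config.tst_insertion_sigma),
                    20,
                    2_000,
                )
            )
            end = min(start + length, genome.length(hs.chrom))
            if end - start < 20:
                start = max(0, end - 20)
            return TemplatedInsertion(GenomicInterval(hs.chrom, start, end, hs.haplotype), strand)

        for i in range(k):
            kind = _draw_homology(config, rng, allow_mh=(i > 0))
            if kind == BLUNT:
                inner.append(Homology(BLUNT))
                untempl.append("")
                ins.append(draw_insertion())
            elif kind == UNTEMPLATED:
                n = int(rng.integers(2, 21))
                inner.append(Homology(UNTEMPLATED, n))
                untempl.append(_random_bases(rng, n))
                ins.append(draw_insertion())
            else:  # microhomology: align next source's upstream flank to prev tail
                h = min(2 + int(rng.geometric(0.5)) - 1, 8)
                prev = ins[-1]
                tail = prev.sequence(genome)[-h:]
                hs = hotspots[int(rng.integers(len(hotspots)))]
                wseq = genome.sequence(hs.chrom, hs.start, hs.end)
                cand = []
                q = wseq.find(tail)
                while q != -1:
                    cand.append(hs.start + q + h)
                    q = wseq.find(tail, q + 1)
                while not cand and h > 2:
                    h -= 1
                    tail = prev.sequence(genome)[-h:]
                    q = wseq.find(tail)
                    while q != -1:
                        cand.append(hs.start + q + h)
                        q = wseq.find(tail, q + 1)
                if not cand:
                    inner.append(Homology(BLUNT))
                    untempl.append("")
                    ins.append(draw_insertion())
                else:
                    inner.append(Homology(MICROHOMOLOGY, h))
                    untempl.append("")
                    ins.append(draw_insertion(start=int(cand[int(rng.integers(len(cand)))]), hs=hs, strand="+"))
        # terminal join class (chain -> resuming breakend)
        kind = _draw_homology(config, rng, allow_mh=False)
        if kind == UNTEMPLATED:
            n = int(rng.integers(2, 21))
            inner.append(Homology(UNTEMPLATED, n))
            untempl.append(_random_bases(rng, n))
        else:
            inner.append(Homology(BLUNT))
            untempl.append("")
        chains.append(tuple(ins))
        homs.append(tuple(inner))
        unts.append(tuple(untempl))
    return TSTChainSet(hotspots, chains, homs, unts)


# ---------------------------------------------------------------------------
# kataegis
# ---------------------------------------------------------------------------

def apply_kataegis(
    genome: GenomeDeclaration,
    region: GenomicInterval,
    strand: str,
    config: CascadeConfig,
    rng: np.random.Generator,
) -> list[Mutation]:
    """Plant an APOBEC-style hypermutation cluster in one region.

    All substitutions are C->T or C->G at TpC context on a single strand;
    successive positions are TpC sites of the lazy reference chosen so the
    inter-mutation distance follows an exponential law with small mean.
    """
    n = config.kataegis_min_mutations + int(rng.poisson(config.kataegis_extra_mutations_mean))
    span = min(region.length, max(200_000, int(40 * n * config.kataegis_imd_mean_bp)))
    start = region.start if region.length <= span else int(
        rng.uniform(region.start, region.end - span)
    )
    seq = genome.sequence(region.chrom, start, start + span)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    if strand == "+":
        sites = np.flatnonzero((arr[:-1] == ord("T")) & (arr[1:] == ord("C"))) + 1
    else:
        sites = np.flatnonzero((arr[:-1] == ord("G")) & (arr[1:] == ord("A")))
    if len(sites) < n:
        raise CascadeError("region too short for a kataegis cluster")
    first = int(rng.integers(0, max(1, len(sites) - n * 4)))
    muts: list[Mutation] = []
    i = first
    for _ in range(n):
        pos = start + int(sites[i])
        ref = "C" if strand == "+" else "G"
        to = "T" if rng.random() < 0.5 else "G"
        alt = to if strand == "+" else {"T": "A", "G": "C"}[to]
        muts.append(Mutation(region.chrom, pos, ref, alt, strand, region.haplotype))
        gap = rng.exponential(config.kataegis_imd_mean_bp)
        j = int(np.searchsorted(sites, sites[i] + max(1, gap)))
        if j >= len(sites):
            j = i + 1
            if j >= len(sites):
                break
        i = j
    return muts


# ---------------------------------------------------------------------------
# bridge breakage
# ---------------------------------------------------------------------------

@dataclass
class FragmentFate:
    segment: Segment
    fate: str
    daughter: str | None = None  # "a"/"b" for retained fragments


@dataclass
class ReciprocalTruth:
    """Logged truth of one reciprocal exchange between the daughters.

    ``kinds`` parallels ``intervals``: an exchanged genome interval reaching
    a chromosome terminus is terminal (Type 1); an interior interval is
    internal (Type 2).  A chromosome-type exchange that straddles the fusion
    junction is genomically terminal on each partner chromosome.
    """

    intervals: list[GenomicInterval]
    kinds: list[str]
    gaining_daughter: str


def _label_exchange(genome: GenomeDeclaration, ivs: list[GenomicInterval]) -> list[str]:
    return [
        TYPE1 if (iv.start == 0 or iv.end >= genome.length(iv.chrom)) else TYPE2
        for iv in ivs
    ]


@dataclass
class BreakOutcome:
    mode: str  # "simple" | "local_fragmentation"
    break_path_positions: list[int]
    fragments: list[FragmentFate]
    junctions: list[Junction]
    daughter_a: CellGenome
    daughter_b: CellGenome
    truth_events: list[ReciprocalTruth]
    tst: TSTChainSet | None = None
    kataegis: list[Mutation] = field(default_factory=list)
    circles: list[Segment] = field(default_factory=list)
    junctions_a: list[Junction] = field(default_factory=list)
    junctions_b: list[Junction] = field(default_factory=list)


def _sample_break_pos(
    lo: int, hi: int, rng: np.random.Generator,
    excl_center: int | None = None, excl_radius: int = 0, max_tries: int = 10_000,
) -> int:
    for _ in range(max_tries):
        x = int(rng.uniform(lo + 1, hi - 1))
        if excl_center is None or abs(x - excl_center) >= excl_radius:
            return x
    raise CascadeError("could not sample a break position satisfying the offset")


def _path_to_genome(der: DerivativeChromosome, lo: int, hi: int) -> list[GenomicInterval]:
    """Genome intervals covered by a path window (merging nothing)."""
    return [s.interval for s in der.subpath(lo, hi)]


def _fragment_zone(
    dic: Dicentric, x: int, genome: GenomeDeclaration,
    config: CascadeConfig, rng: np.random.Generator,
) -> tuple[int, int, list[int]]:
    """Zone [zlo, zhi) of local fragmentation, extending from the break away
    from the fusion point, plus the drawn fragment lengths."""
    lo, hi = dic.break_interval(genome)
    n = 1 + int(rng.poisson(config.fragment_count_extra_mean))
    llo, lhi = config.fragment_length_range
    lengths = [int(np.exp(rng.uniform(math.log(llo), math.log(lhi)))) for _ in range(n)]
    span = sum(lengths)
    if x >= dic.fusion_path_pos:
        zlo, zhi = x, min(x + span, hi)
    else:
        zlo, zhi = max(x - span, lo), x
    # truncate drawn lengths to the clipped zone
    avail = zhi - zlo
    kept: list[int] = []
    for L in lengths:
        if avail <= 0:
            break
        kept.append(min(L, avail))
        avail -= kept[-1]
    return zlo, zhi, kept


def break_bridge(
    genome: GenomeDeclaration,
    fusion: FusionEvent,
    config: CascadeConfig,
    rng: np.random.Generator,
    generation: int = 1,
    parent_id: str = "cell0",
    broken_interphase: bool = True,
) -> BreakOutcome:
    """Break a dicentric bridge and assemble the two daughter cell genomes.

    Chromatid-type dicentrics (sister / non-sister fusions) yield reciprocal
    *terminal* gain and loss between the daughters; an antiparallel
    chromosome-type dicentric pair yields reciprocal *internal* gain and
    loss.  In fragmentation mode a zone distal to the break is shattered into
    fragments that are independently retained (end-joined onto a daughter's
    stub), lost, or circularized; retained fragments of the loss daughter
    appear as islands inside its region of complete haplotype loss.  With
    probability ``p_tst`` the repair additionally writes a TST insertion
    chain (and, half the time, a kataegis cluster).
    """
    for dic in fusion.dicentrics:
        if dic.derivative.centromere_count(genome) != 2:
            raise CascadeError("break_bridge requires dicentric input")

    mode = "local_fragmentation" if rng.random() < config.p_fragmentation else "simple"
    want_tst = rng.random() < config.p_tst
    if want_tst and mode == "simple":
        mode = "local_fragmentation"  # TST repair requires fragmented break ends

    pieces_a: list[tuple[DerivativeChromosome, str | None]] = []  # (derivative, broken side)
    pieces_b: list[tuple[DerivativeChromosome, str | None]] = []
    fragments: list[Segment] = []
    truth_events: list[ReciprocalTruth] = []
    break_positions: list[int] = []
    zone_regions: list[GenomicInterval] = []

    if fusion.kind in (SISTER, NONSISTER):
        dic = fusion.dicentrics[0]
        lo, hi = dic.break_interval(genome)
        x = _sample_break_pos(lo, hi, rng, dic.fusion_path_pos, config.min_break_offset)
        break_positions.append(x)
        F = dic.fusion_path_pos
        if mode == "simple":
            left, right = dic.derivative.split_at(x)
            if x >= F:
                gain, loss, gain_side, loss_side = left, right, "right", "left"
            else:
                gain, loss, gain_side, loss_side = right, left, "left", "right"
            pieces_a.append((gain, gain_side))
            pieces_b.append((loss, loss_side))
        else:
            zlo, zhi, lengths = _fragment_zone(dic, x, genome, config, rng)
            if x >= F:
                gain = dic.derivative.split_at(x)[0]
                loss = dic.derivative.split_at(zhi)[1] if zhi < dic.derivative.length else None
                gain_side, loss_side = "right", "left"
                frag_lo, frag_hi = zlo, zhi
            else:
                gain = dic.derivative.split_at(x)[1]
                loss = dic.derivative.split_at(zlo)[0] if zlo > 0 else None
                gain_side, loss_side = "left", "right"
                frag_lo, frag_hi = zlo, zhi
            pieces_a.append((gain, gain_side))
            if loss is not None:
                pieces_b.append((loss, loss_side))
            off = frag_lo
            for L in lengths:
                for seg in dic.derivative.subpath(off, off + L):
                    fragments.append(seg)
                off += L
            zone_regions = _path_to_genome(dic.derivative, frag_lo, frag_hi)
        # reciprocal truth: the doubly-covered copy in the gain daughter is the
        # genome image of the path interval between the break and the fusion
        lo_p, hi_p = (F, x) if x >= F else (x, F)
        ivs = _path_to_genome(dic.derivative, lo_p, hi_p)
        truth_events.append(ReciprocalTruth(ivs, _label_exchange(genome, ivs), "a"))
    else:  # chromosome_type, antiparallel dicentric pair
        d1, d2 = fusion.dicentrics
        lo, hi = d1.break_interval(genome)
        x1 = _sample_break_pos(lo, hi, rng)
        x2 = _sample_break_pos(lo, hi, rng, x1, config.min_break_offset)
        break_positions += [x1, x2]
        l1, r1 = d1.derivative.split_at(x1)
        l2, r2 = d2.derivative.split_at(x2)
        # daughter a: C1-centromere piece of D1 + C2-centromere piece of D2
        pieces_a.append((l1, "right"))
        pieces_a.append((r2, "left"))
        pieces_b.append((r1, "left"))
        pieces_b.append((l2, "right"))
        a, b = sorted((x1, x2))
        gainer = "a" if x1 > x2 else "b"
        ivs = _path_to_genome(d1.derivative, a, b)
        truth_events.append(ReciprocalTruth(ivs, _label_exchange(genome, ivs), gainer))
        if mode == "local_fragmentation":
            # shatter a zone distal to the D1 break, carved from the piece of
            # the daughter that does NOT gain the internal segment
            dic = d1
            zlo, zhi, lengths = _fragment_zone(
                Dicentric(d1.derivative, x2), x1, genome, config, rng
            )
            # the carved window sits outside the exchanged region
            target_list = pieces_b if gainer == "a" else pieces_a
            # find which piece covers the zone: r1 covers [x1:], l1 covers [:x1]
            if zlo >= x1:
                carved = d1.derivative.split_at(zhi)[1] if zhi < d1.derivative.length else None
                repl = (carved, "left")
                victim = r1
            else:
                carved = d1.derivative.split_at(zlo)[0] if zlo > 0 else None
                repl = (carved, "right")
                victim = l1
            for i, (p, s) in enumerate(list(target_list)):
                if p is victim:
                    if carved is None:
                        target_list.pop(i)
                    else:
                        target_list[i] = repl
                    break
            else:
                # victim belongs to the other daughter; carve there instead
                other = pieces_a if target_list is pieces_b else pieces_b
                for i, (p, s) in enumerate(list(other)):
                    if p is victim:
                        if carved is None:
                            other.pop(i)
                        else:
                            other[i] = repl
                        break
            off = zlo
            for L in lengths:
                for seg in d1.derivative.subpath(off, off + L):
                    fragments.append(seg)
                off += L
            zone_regions = _path_to_genome(d1.derivative, zlo, zhi)

    # --- fragment fates -----------------------------------------------------
    fates: list[FragmentFate] = []
    circles: list[Segment] = []
    p_keep = config.p_fragment_retained
    for seg in fragments:
        u = rng.random()
        if u < p_keep:
            fates.append(FragmentFate(seg, RETAINED, "a" if rng.random() < 0.5 else "b"))
        elif rng.random() < config.p_circularize_fragment:
            fates.append(FragmentFate(seg, CIRCULARIZED))
            circles.append(seg)
        else:
            fates.append(FragmentFate(seg, LOST))
    if want_tst and fragments and not any(f.fate == RETAINED for f in fates):
        fates[0] = FragmentFate(fates[0].segment, RETAINED, "a" if rng.random() < 0.5 else "b")

    # --- ligation ------------------------------------------------------------
    def build(pieces: list[tuple[DerivativeChromosome, str | None]], keep: list[Segment]):
        out: list[DerivativeChromosome] = []
        jlist: list[Junction] = []
        stub_i = None
        remaining = list(keep)
        for i, (p, side) in enumerate(pieces):
            if p is None:
                continue
            if side is not None and remaining and stub_i is None:
                der, jxs = ligate_fragments(genome, p, remaining, rng, attach_side=side)
                jlist.extend(jxs)
                out.append(der)
                stub_i = len(out) - 1
                remaining = []
            else:
                out.append(recompute_caps(genome, p))
                if side is not None and stub_i is None:
                    stub_i = len(out) - 1
        return out, stub_i, jlist

    keep_a = [f.segment for f in fates if f.fate == RETAINED and f.daughter == "a"]
    keep_b = [f.segment for f in fates if f.fate == RETAINED and f.daughter == "b"]
    ders_a, stub_a, junctions_a = build(pieces_a, keep_a)
    ders_b, stub_b, junctions_b = build(pieces_b, keep_b)
    junctions = junctions_a + junctions_b

    # --- TST + kataegis -------------------------------------------------------
    tst: TSTChainSet | None = None
    kmuts: list[Mutation] = []
    if want_tst and zone_regions:
        big = [r for r in zone_regions if r.length >= 60_000] or list(zone_regions)
        tst = generate_tst_chain(genome, big, config, rng)
        # decorate ligation junctions with the chains (one junction per chain)
        lig = [(junctions_a, i) for i in range(len(junctions_a))] + [
            (junctions_b, i) for i in range(len(junctions_b))
        ]
        for chain, hom, unt in zip(tst.chains, tst.inner_homologies, tst.untemplated_seqs):
            if not lig:
                break
            lst, i = lig.pop(int(rng.integers(len(lig))))
            j = lst[i]
            lst[i] = Junction(j.bnd1, j.bnd2, chain, j.homology, hom, unt)
        junctions = junctions_a + junctions_b
        if rng.random() < config.p_kataegis:
            reg = max(big, key=lambda r: r.length)
            if reg.length >= 50_000:
                kmuts = apply_kataegis(genome, reg, "+" if rng.random() < 0.5 else "-", config, rng)

    # --- daughter cells -------------------------------------------------------
    consumed = set()
    free_a: list[DerivativeChromosome] = []
    free_b: list[DerivativeChromosome] = []
    if fusion.kind == SISTER:
        consumed = {(fusion.chroms[0], fusion.haplotype)}
    elif fusion.kind == NONSISTER:
        other = HAPLOTYPES[1] if fusion.haplotype == HAPLOTYPES[0] else HAPLOTYPES[0]
        consumed = {(fusion.chroms[0], fusion.haplotype), (fusion.chroms[0], other)}
        # each daughter receives the free sister chromatid of the haplotype
        # whose centromere its dicentric piece lacks
        gain_has_hap1_cen = break_positions[0] >= fusion.dicentrics[0].fusion_path_pos
        if gain_has_hap1_cen:
            free_a.append(reference_derivative(genome, fusion.chroms[0], other))
            free_b.append(reference_derivative(genome, fusion.chroms[0], fusion.haplotype))
        else:
            free_a.append(reference_derivative(genome, fusion.chroms[0], fusion.haplotype))
            free_b.append(reference_derivative(genome, fusion.chroms[0], other))
    else:
        consumed = {(c, fusion.haplotype) for c in fusion.chroms}

    def make_cell(ders, free, cid):
        full = [
            reference_derivative(genome, chrom, hap)
            for chrom in genome.names()
            for hap in HAPLOTYPES
            if (chrom, hap) not in consumed
        ]
        cell = CellGenome(
            full + free + list(ders),
            generation=generation,
            cell_id=cid,
            parent_id=parent_id,
            bridge_history=True,
            bridge_broken_interphase=broken_interphase,
        )
        return cell

    cell_a = make_cell(ders_a, free_a, f"{parent_id}.a")
    cell_b = make_cell(ders_b, free_b, f"{parent_id}.b")
    base_a = len(cell_a.derivatives) - len(ders_a)
    base_b = len(cell_b.derivatives) - len(ders_b)
    cell_a.stub_index = None if stub_a is None else base_a + stub_a
    cell_b.stub_index = None if stub_b is None else base_b + stub_b
    cell_a.mutations.extend(kmuts)

    return BreakOutcome(
        mode, break_positions, fates, junctions, cell_a, cell_b,
        truth_events, tst, kmuts, circles, junctions_a, junctions_b,
    )


# ---------------------------------------------------------------------------
# mitotic second wave
# ---------------------------------------------------------------------------

@dataclass
class SecondWaveOutcome:
    applied: bool
    n_breaks: int
    junctions: list[Junction]
    fragments: list[FragmentFate]
    region: list[GenomicInterval]


def mitotic_second_wave(
    genome: GenomeDeclaration,
    cell: CellGenome,
    config: CascadeConfig,
    rng: np.random.Generator,
    derivative_index: int | None = None,
) -> SecondWaveOutcome:
    """Shatter the under-replicated terminal window of a broken-bridge stub.

    At mitotic entry the stub undergoes a burst of aberrant replication;
    modeled as ~Poisson(second_wave_breaks_mean) additional breakpoints
    confined to the ``stub_region_bp`` window behind the original break, with
    the resulting fragments re-ligated in random order/orientation or lost.
    A cell without a stub is a logged no-op.
    """
    idx = derivative_index if derivative_index is not None else getattr(cell, "stub_index", None)
    if idx is None or idx >= len(cell.derivatives):
        uncapped = cell.uncapped()
        idx = uncapped[0] if uncapped else None
    if idx is None:
        return SecondWaveOutcome(False, 0, [], [], [])
    der = cell.derivatives[idx]
    n = int(rng.poisson(config.second_wave_breaks_mean))
    if n == 0 or der.length < 200_000:
        return SecondWaveOutcome(False, 0, [], [], [])
    # window behind the uncapped end
    side = "left" if not der.left_telomere else "right"
    span = min(config.stub_region_bp, der.length - 100_000)
    if side == "right":
        wlo, whi = der.length - span, der.length
        stub = der.split_at(wlo)[0]
    else:
        wlo, whi = 0, span
        stub = der.split_at(whi)[1]
    cuts = sorted(int(c) for c in rng.uniform(wlo + 1, whi - 1, size=n))
    cuts = sorted(set(cuts))
    bounds = [wlo] + cuts + [whi]
    frags: list[Segment] = []
    fates: list[FragmentFate] = []
    for a, b in zip(bounds, bounds[1:]):
        if b <= a:
            continue
        for seg in der.subpath(a, b):
            if rng.random() < config.p_fragment_retained:
                frags.append(seg)
                fates.append(FragmentFate(seg, RETAINED, "self"))
            else:
                fates.append(FragmentFate(seg, LOST))
    attach = "right" if side == "right" else "left"
    newder, jxs = ligate_fragments(genome, stub, frags, rng, attach_side=attach)
    cell.derivatives[idx] = newder
    return SecondWaveOutcome(True, len(cuts), jxs, fates, _path_to_genome(der, wlo, whi))


# ---------------------------------------------------------------------------
# division with mis-segregation
# ---------------------------------------------------------------------------

@dataclass
class DivisionOutcome:
    micronucleated: bool
    mn_daughter: str | None
    mn_contains_bridge_chrom: bool | None
    mn_has_centromere: bool | None


def divide_with_missegregation(
    genome: GenomeDeclaration,
    cell: CellGenome,
    config: CascadeConfig,
    rng: np.random.Generator,
) -> tuple[CellGenome, CellGenome, DivisionOutcome]:
    """Divide a cell; bridge-descendant chromosomes frequently mis-segregate.

    Cells with no bridge history never micronucleate.  For bridge-descendant
    cells one daughter receives a micronucleus with probability 0.52 (broken
    bridge) or 0.65 (bridge unbroken in the previous interphase); the
    micronucleus contains the bridge chromosome with probability 0.80 and a
    centromere with probability 0.62 (otherwise only an acentric distal
    piece mis-segregates).  Micronuclear centromeres are flagged inactivated.
    """
    def child(tag: str) -> CellGenome:
        return CellGenome(
            [DerivativeChromosome(list(d.segments), d.left_telomere, d.right_telomere,
                                  d.centromere_inactivated) for d in cell.derivatives],
            list(cell.compartments),
            generation=cell.generation + 1,
            cell_id=f"{cell.cell_id}.{tag}",
            parent_id=cell.cell_id,
            mutations=list(cell.mutations),
            bridge_history=cell.bridge_history,
            bridge_broken_interphase=cell.bridge_broken_interphase,
        )

    da, db = child("a"), child("b")
    for c in (da, db):
        c.stub_index = getattr(cell, "stub_index", None)
    if not cell.bridge_history:
        return da, db, DivisionOutcome(False, None, None, None)

    p_mn = (
        config.p_micronucleus_broken
        if cell.bridge_broken_interphase in (True, None)
        else config.p_micronucleus_unbroken
    )
    if rng.random() >= p_mn:
        return da, db, DivisionOutcome(False, None, None, None)

    target = da if rng.random() < 0.5 else db
    use_bridge = rng.random() < config.p_mn_contains_bridge_chrom
    stub = getattr(cell, "stub_index", None)
    if use_bridge and stub is not None and stub < len(target.derivatives):
        idx = stub
    else:
        cands = [
            i for i, d in enumerate(target.derivatives)
            if any(s.interval.chrom == config.fusion_chrom for s in d.segments)
        ] or list(range(len(target.derivatives)))
        idx = cands[int(rng.integers(len(cands)))]
    der = target.derivatives[idx]
    with_cen = rng.random() < config.p_mn_centromere
    if with_cen or der.centromere_count(genome) == 0:
        if rng.random() < config.p_mn_centromere_inactivation:
            target.derivatives[idx] = DerivativeChromosome(
                list(der.segments), der.left_telomere, der.right_telomere, True
            )
        target.compartments[idx] = MICRONUCLEUS
        has_cen = der.centromere_count(genome) > 0
    else:
        # only an acentric distal piece mis-segregates
        spans = der.centromere_spans(genome)
        if spans and spans[-1][1] < der.length - 100_000:
            cut = int(rng.uniform(spans[-1][1] + 1, der.length - 1))
            keep, mn = der.split_at(cut)
            target.derivatives[idx] = keep
            target.add(mn, MICRONUCLEUS)
        else:
            target.compartments[idx] = MICRONUCLEUS
        has_cen = False
    return da, db, DivisionOutcome(True, "a" if target is da else "b",
                                   idx == stub, has_cen)


# ---------------------------------------------------------------------------
# lineage
# ---------------------------------------------------------------------------

@dataclass
class EventRecord:
    event_id: int
    generation: int
    cell_id: str
    etype: str
    payload: dict


@dataclass
class Lineage:
    """Division tree of cell genomes plus the typed event log."""

    genome: GenomeDeclaration
    config: CascadeConfig
    seed: int
    nodes: dict[str, CellGenome] = field(default_factory=dict)
    children: dict[str, list[str]] = field(default_factory=dict)
    events: list[EventRecord] = field(default_factory=list)
    junctions_by_cell: dict[str, list[Junction]] = field(default_factory=dict)

    def log(self, generation: int, cell_id: str, etype: str, **payload) -> int:
        eid = len(self.events)
        self.events.append(EventRecord(eid, generation, cell_id, etype, payload))
        return eid

    def add_cell(self, cell: CellGenome, junctions: Sequence[Junction] = ()) -> None:
        self.nodes[cell.cell_id] = cell
        self.children.setdefault(cell.cell_id, [])
        if cell.parent_id is not None:
            self.children.setdefault(cell.parent_id, []).append(cell.cell_id)
        parent_j = self.junctions_by_cell.get(cell.parent_id, []) if cell.parent_id else []
        self.junctions_by_cell[cell.cell_id] = list(parent_j) + list(junctions)

    def cells_at(self, generation: int) -> list[CellGenome]:
        return [c for c in self.nodes.values() if c.generation == generation]

    @property
    def root(self) -> CellGenome:
        return next(c for c in self.nodes.values() if c.parent_id is None)


def run_cascade(
    genome: GenomeDeclaration,
    config: CascadeConfig,
    n_generations: int,
    seed: int,
) -> Lineage:
    """Run the full cascade for one lineage over ``n_generations`` divisions.

    Generation 1: fusion, bridge lifetime, breakage with TST/kataegis.
    Generation 2: mitotic second wave on bridge stubs, then division with
    mis-segregation into micronuclei.  Generations >= 3: micronuclear
    chromothripsis (rare in interphase, frequent after mitosis), continued
    BFB on uncapped ends, and stabilization by translocation with an
    acrocentric-partner bias.
    """
    if n_generations < 1:
        raise CascadeError("n_generations must be >= 1")
    config.validate()
    rng = make_rng(seed)
    lin = Lineage(genome, config, seed)
    founder = diploid_cell(genome)
    lin.add_cell(founder)

    fusion = make_fusion(genome, config, rng)
    lin.log(0, founder.cell_id, "fusion", kind=fusion.kind, chroms=list(fusion.chroms),
            haplotype=fusion.haplotype)
    hours, censored = sample_bridge_lifetime(config, rng)
    lin.log(0, founder.cell_id, "bridge_lifetime", hours=round(hours, 4), censored=censored)

    out = break_bridge(genome, fusion, config, rng, generation=1,
                       parent_id=founder.cell_id, broken_interphase=not censored)
    lin.log(1, founder.cell_id, "bridge_breakage", mode=out.mode,
            positions=out.break_path_positions,
            n_fragments=len(out.fragments),
            n_retained=sum(1 for f in out.fragments if f.fate == RETAINED),
            tst=out.tst is not None, n_kataegis=len(out.kataegis))
    if out.tst is not None:
        lin.log(1, out.daughter_a.cell_id, "tst_chain",
                n_chains=len(out.tst.chains), n_hotspots=len(out.tst.hotspots),
                insertion_lengths=out.tst.insertion_lengths())
    lin.add_cell(out.daughter_a, [fusion.junctions[0]] + out.junctions_a)
    lin.add_cell(out.daughter_b, out.junctions_b)

    current = [out.daughter_a, out.daughter_b]
    for gen in range(2, n_generations + 1):
        nxt: list[CellGenome] = []
        for cell in current:
            new_j: list[Junction] = []
            # micronuclear chromothripsis before mitosis (rare)
            if cell.micronucleated() and rng.random() < config.p_interphase_chromothripsis_mn:
                mn_idx = cell.compartments.index(MICRONUCLEUS)
                sw = mitotic_second_wave(genome, cell, config, rng, derivative_index=mn_idx)
                new_j += sw.junctions
                lin.log(cell.generation, cell.cell_id, "mn_interphase_chromothripsis",
                        n_breaks=sw.n_breaks)
            # second wave on bridge stubs at mitotic entry
            if cell.bridge_history and rng.random() < config.p_mitotic_second_wave:
                sw = mitotic_second_wave(genome, cell, config, rng)
                if sw.applied:
                    new_j += sw.junctions
                    lin.log(cell.generation, cell.cell_id, "second_wave",
                            n_breaks=sw.n_breaks, n_junctions=len(sw.junctions))
            # post-mitotic chromothripsis of micronuclear chromosomes
            if cell.micronucleated() and rng.random() < config.p_mn_chromothripsis_after_mitosis:
                mn_idx = cell.compartments.index(MICRONUCLEUS)
                sw = mitotic_second_wave(genome, cell, config, rng, derivative_index=mn_idx)
                if sw.applied:
                    new_j += sw.junctions
                    lin.log(cell.generation, cell.cell_id, "mn_chromothripsis",
                            n_breaks=sw.n_breaks)
            da, db, div = divide_with_missegregation(genome, cell, config, rng)
            lin.log(da.generation, cell.cell_id, "division",
                    micronucleated=div.micronucleated, mn_daughter=div.mn_daughter,
                    mn_contains_bridge_chrom=div.mn_contains_bridge_chrom,
                    mn_has_centromere=div.mn_has_centromere)
            # continued BFB / stabilization on uncapped ends in later generations
            for d in (da, db):
                if gen >= 3:
                    _bfb_step(genome, d, config, rng, lin)
                lin.add_cell(d, new_j)
                nxt.append(d)
        current = nxt
    return lin


def _bfb_step(genome, cell: CellGenome, config: CascadeConfig,
              rng: np.random.Generator, lin: Lineage) -> None:
    for idx in cell.uncapped():
        der = cell.derivatives[idx]
        u = rng.random()
        if u < config.p_stabilize:
            # cap by translocation, acrocentric partner preferred
            acro = genome.acrocentric_names()
            if acro and rng.random() < config.p_acrocentric_partner:
                partner = acro[int(rng.integers(len(acro)))]
            else:
                partner = genome.names()[int(rng.integers(len(genome.names())))]
            plen = genome.length(partner)
            _, ce = genome.centromere(partner)
            arm_lo = max(ce + 1, plen // 3)  # acentric distal arm
            iv = GenomicInterval(partner, arm_lo, plen, HAPLOTYPES[int(rng.integers(2))])
            side = "left" if not der.left_telomere else "right"
            if side == "right":
                # forward arm ends at the partner's natural q terminus
                newder = DerivativeChromosome(list(der.segments) + [Segment(iv, "+")],
                                              der.left_telomere, False, der.centromere_inactivated)
            else:
                # reversed arm puts the natural terminus at the path's left end
                newder = DerivativeChromosome([Segment(iv, "-")] + list(der.segments),
                                              False, der.right_telomere, der.centromere_inactivated)
            cell.derivatives[idx] = recompute_caps(genome, newder)
            lin.log(cell.generation, cell.cell_id, "stabilizing_translocation",
                    partner=partner, acrocentric=genome.is_acrocentric(partner))
        elif u < config.p_stabilize + config.p_bfb_continue:
            lo, hi = config.bfb_terminal_delta_range
            delta = int(np.exp(rng.uniform(math.log(lo), math.log(hi))))
            delta = min(delta, der.length - 200_000)
            if delta <= 0:
                continue
            loss = rng.random() < (1.0 - config.replicated_fraction)
            side = "left" if not der.left_telomere else "right"
            if loss:
                if side == "right":
                    cell.derivatives[idx] = der.split_at(der.length - delta)[0]
                else:
                    cell.derivatives[idx] = der.split_at(delta)[1]
                lin.log(cell.generation, cell.cell_id, "bfb_terminal_loss", bp=delta)
            else:
                # fold-back duplication of the terminal piece
                if side == "right":
                    tail = der.subpath(der.length - delta, der.length)
                    dup = [Segment(s.interval, "-" if s.orientation == "+" else "+")
                           for s in reversed(tail)]
                    cell.derivatives[idx] = DerivativeChromosome(
                        list(der.segments) + dup, der.left_telomere, False,
                        der.centromere_inactivated)
                else:
                    head = der.subpath(0, delta)
                    dup = [Segment(s.interval, "-" if s.orientation == "+" else "+")
                           for s in reversed(head)]
                    cell.derivatives[idx] = DerivativeChromosome(
                        dup + list(der.segments), False, der.right_telomere,
                        der.centromere_inactivated)
                lin.log(cell.generation, cell.cell_id, "bfb_foldback_gain", bp=delta)
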