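"""Rearrangement junctions: breakends, templated-insertion chains, homology.

A :class:`Junction` joins two breakends, optionally through an ordered chain
of short templated insertions (the tandem short template, TST, signature)
and/or a run of untemplated bases.  Junction records are the unit consumed
by every signature detector and by the BEDPE/VCF exporters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genome import GenomeError, GenomicInterval

BLUNT = "blunt"
MICROHOMOLOGY = "microhomology"
UNTEMPLATED = "untemplated_insert"


@dataclass(frozen=True)
class Breakend:
    """One side of a junction.

    ``orient`` "+" means the retained sequence lies in reference coordinates
    to the *left* of ``pos`` (i.e. the retained piece is ``[..., pos)``);
    "-" means it lies to the right (``[pos, ...)``).  Positions are 0-based;
    VCF export converts to 1-based on write.
    """

    chrom: str
    pos: int
    orient: str
    haplotype: str = "A"

    def __post_init__(self) -> None:
        if self.orient not in ("+", "-"):
            raise GenomeError("breakend orient must be '+' or '-'")
        if self.pos < 0:
            raise GenomeError("breakend position must be >= 0")

    def key(self) -> tuple:
        return (self.chrom, self.pos, self.orient, self.haplotype)


@dataclass(frozen=True)
class TemplatedInsertion:
    """One templated segment inside a junction's insertion chain."""

    source: GenomicInterval
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise GenomeError("insertion strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.source.length

    def sequence(self, genome) -> str:
        return genome.sequence(self.source.chrom, self.source.start, self.source.end, self.strand)


@dataclass(frozen=True)
class Homology:
    """Junction flank classification.

    blunt: exact flank overlap of <= 1 bp; microhomology: overlap >= 2 bp;
    untemplated_insert: 2-20 bp of inserted sequence of ambiguous origin.
    """

    kind: str
    length: int = 0
    insert_seq: str = ""

    def __post_init__(self) -> None:
        if self.kind not in (BLUNT, MICROHOMOLOGY, UNTEMPLATED):
            raise GenomeError(f"unknown homology kind {self.kind!r}")
        if self.kind == MICROHOMOLOGY and self.length < 2:
            raise GenomeError("microhomology requires length >= 2")
        if self.kind == UNTEMPLATED and not (2 <= self.length <= 20):
            raise GenomeError("untemplated insert length must be in [2, 20]")


@dataclass(frozen=True)
class Junction:
    """A pair of breakends plus an ordered templated-insertion chain.

    ``inner_homology`` classifies the joins *between* consecutive chain
    members (length = len(insertions) + 1 when insertions are present,
    spanning bnd1->ins1, ins1->ins2, ..., insN->bnd2); ``homology`` is the
    overall class of the junction for simple (chain-free) junctions.
    """

    bnd1: Breakend
    bnd2: Breakend
    insertions: tuple[TemplatedInsertion, ...] = ()
    homology: Homology = field(default_factory=lambda: Homology(BLUNT))
    inner_homology: tuple[Homology, ...] = ()
    untemplated_seqs: tuple[str, ...] = ()

    def canonical(self) -> tuple:
        a, b = self.bnd1.key(), self.bnd2.key()
        return (a, b) if a <= b else (b, a)

    @property
    def interchromosomal(self) -> bool:
        return self.bnd1.chrom != self.bnd2.chrom

    def orientation_class(self) -> str:
        """One of '+-', '++', '--', '-+' in canonical breakend order."""
        a, b = sorted([self.bnd1, self.bnd2], key=lambda x: x.key())
        return a.orient + b.orient

    def insertion_sequence(self, genome) -> str:
        """The full inserted sequence between the two breakends."""
        parts: list[str] = []
        seqs = list(self.untemplated_seqs)
        for i, ins in enumerate(self.insertions):
            if i < len(seqs) and seqs[i]:
                parts.append(seqs[i])
            parts.append(ins.sequence(genome))
        if len(seqs) > len(self.insertions) and seqs[len(self.insertions)]:
            parts.append(seqs[len(self.insertions)])
        return "".join(parts)

    def breakpoint_coords(self) -> list[tuple[str, int]]:
        return [(self.bnd1.chrom, self.bnd1.pos), (self.bnd2.chrom, self.bnd2.pos)]


def segment_right_breakend(seg) -> Breakend:
    c, p, o = seg.path_right_breakend()
    return Breakend(c, p, o, seg.interval.haplotype)


def segment_left_breakend(seg) -> Breakend:
    c, p, o = seg.path_left_breakend()
    return Breakend(c, p, o, seg.interval.haplotype)


def derivative_junctions(der) -> list[Junction]:
    """Enumerate one junction per internal adjacency of a derivative path."""
    return [
        Junction(segment_right_breakend(a), segment_left_breakend(b))
        for a, b in zip(der.segments, der.segments[1:])
    ]


def assemble_derivative(genome, segments, junctions) -> "DerivativeChromosome":
    """Build a derivative from ordered segments and their adjacency junctions.

    Each internal adjacency must be covered by exactly one junction (matched
    on the unordered breakend pair); junctions without a matching adjacency,
    or adjacencies without a junction, raise.  Telomere caps are recomputed
    from whether the path ends are natural chromosome termini.
    """
    from .genome import DerivativeChromosome, recompute_caps

    segments = list(segments)
    if not segments:
        raise GenomeError("need at least one segment")
    der = DerivativeChromosome(segments)
    expected = [j.canonical() for j in derivative_junctions(der)]
    provided = [j.canonical() for j in junctions]
    missing = [e for e in expected if e not in provided]
    if missing:
        raise GenomeError(f"adjacency without junction: {missing[0]}")
    leftover = list(provided)
    for e in expected:
        leftover.remove(e)
    if leftover:
        raise GenomeError(f"junction without adjacency: {leftover[0]}")
    return recompute_caps(genome, der)
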