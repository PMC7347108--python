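"""Haplotype-resolved genome model.

This module provides the substrate for the bridge-cascade simulator: a
declared karyotype (chromosome lengths, centromere intervals, acrocentric
flags), derivative chromosomes built from oriented reference segments, exact
truth copy-number profiles, and a lazily evaluated, seeded reference
sequence.  No whole-genome FASTA is ever materialized; any window of sequence
is a pure function of ``(genome_seed, chrom, position)``, which is all the
templated-insertion machinery needs.

Coordinates are 0-based, half-open everywhere.  Haplotypes are labelled
``"A"`` and ``"B"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

HAPLOTYPES = ("A", "B")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


class GenomeError(ValueError):
    """Raised for inconsistent genome declarations or out-of-range intervals."""


# ---------------------------------------------------------------------------
# declaration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChromosomeDecl:
    """One declared chromosome: name, length, centromere span, acrocentric flag."""

    name: str
    length: int
    centromere: tuple[int, int]
    acrocentric: bool = False

    def __post_init__(self) -> None:
        cs, ce = self.centromere
        if not (0 <= cs < ce <= self.length):
            raise GenomeError(
                f"centromere {self.centromere} outside chromosome "
                f"{self.name} of length {self.length}"
            )
        if self.acrocentric and cs > 0.2 * self.length:
            raise GenomeError(
                f"acrocentric chromosome {self.name} must have its centromere "
                f"near the p terminus (got start {cs})"
            )


class GenomeDeclaration:
    """A small karyotype plus the seed for the lazy reference sequence.

    The default desk-scale genome has three chromosomes: a 40 Mb metacentric
    chromosome standing in for the bridge-prone chromosome 4, a 30 Mb
    metacentric partner, and a 20 Mb acrocentric chromosome (acrocentrics
    are the preferred translocation partners of broken ends).
    """

    def __init__(self, chromosomes: Iterable[ChromosomeDecl], seed: int = 0):
        self.chromosomes: dict[str, ChromosomeDecl] = {}
        for c in chromosomes:
            if c.name in self.chromosomes:
                raise GenomeError(f"duplicate chromosome {c.name}")
            self.chromosomes[c.name] = c
        if not self.chromosomes:
            raise GenomeError("empty genome declaration")
        self.seed = int(seed)

    # -- declaration queries ------------------------------------------------

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chromosomes

    def names(self) -> list[str]:
        return list(self.chromosomes)

    def length(self, chrom: str) -> int:
        return self._decl(chrom).length

    def centromere(self, chrom: str) -> tuple[int, int]:
        return self._decl(chrom).centromere

    def is_acrocentric(self, chrom: str) -> bool:
        return self._decl(chrom).acrocentric

    def acrocentric_names(self) -> list[str]:
        return [n for n, c in self.chromosomes.items() if c.acrocentric]

    def _decl(self, chrom: str) -> ChromosomeDecl:
        try:
            return self.chromosomes[chrom]
        except KeyError:
            raise GenomeError(f"unknown chromosome {chrom!r}") from None

    def total_length(self) -> int:
        return sum(c.length for c in self.chromosomes.values())

    # -- lazy sequence ------------------------------------------------------

    def _chrom_key(self, chrom: str) -> np.uint64:
        self._decl(chrom)
        h = np.uint64(self.seed & 0xFFFFFFFFFFFFFFFF)
        for ch in chrom:
            h = _splitmix64(h ^ np.uint64(ord(ch)))
        return h

    def base_codes(self, chrom: str, start: int, end: int) -> np.ndarray:
        """2-bit base codes (0..3 = ACGT) for ``chrom[start:end)``, forward strand."""
        decl = self._decl(chrom)
        if not (0 <= start <= end <= decl.length):
            raise GenomeError(
                f"interval [{start},{end}) outside {chrom} (length {decl.length})"
            )
        pos = np.arange(start, end, dtype=np.uint64)
        z = _splitmix64(pos + self._chrom_key(chrom))
        return (z & np.uint64(3)).astype(np.uint8)

    def sequence(self, chrom: str, start: int, end: int, orientation: str = "+") -> str:
        """Deterministic reference sequence for a window.

        ``orientation="-"`` returns the reverse complement of the forward
        window.  Identical calls always return identical strings, and any
        window of >= 20 bp is unique genome-wide with overwhelming
        probability (bases are i.i.d. uniform under a counter-based hash).
        """
        codes = self.base_codes(chrom, start, end)
        if orientation == "-":
            codes = (3 - codes)[::-1]
        elif orientation != "+":
            raise GenomeError(f"orientation must be '+' or '-', got {orientation!r}")
        return _BASES[codes].tobytes().decode("ascii")

    # -- k-mer search -------------------------------------------------------

    def find_kmers(
        self,
        kmers: Iterable[str],
        chroms: Sequence[str] | None = None,
        regions: Sequence[tuple[str, int, int]] | None = None,
        k: int = 20,
    ) -> dict[str, list[tuple[str, int, str]]]:
        """Locate exact occurrences of ``k``-mers in the lazy genome.

        Returns ``{kmer: [(chrom, pos, strand), ...]}`` where ``pos`` is the
        forward-strand start of the match.  Both strands are searched.  A
        k <= 32 fits in one uint64 (2 bits/base) so hashing is collision-free.
        ``regions`` restricts the scan (forward-strand windows); otherwise the
        chromosomes in ``chroms`` (default: all) are scanned in chunks.
        """
        if k > 32:
            raise GenomeError("k must be <= 32")
        queries = [q.upper() for q in kmers]
        if any(len(q) != k for q in queries):
            raise GenomeError(f"all query k-mers must have length {k}")
        enc: dict[int, list[tuple[str, str]]] = {}
        for q in queries:
            enc.setdefault(_encode_kmer(q), []).append((q, "+"))
            enc.setdefault(_encode_kmer(revcomp(q)), []).append((q, "-"))
        if not enc:
            return {}
        keys = np.array(sorted(enc), dtype=np.uint64)
        hits: dict[str, list[tuple[str, int, str]]] = {q: [] for q in queries}

        if regions is None:
            names = list(chroms) if chroms is not None else self.names()
            regions = [(n, 0, self.length(n)) for n in names]
        chunk = 2_000_000
        for chrom, rs, re_ in regions:
            rs, re_ = max(0, rs), min(self.length(chrom), re_)
            s = rs
            while s < re_:
                e = min(s + chunk, re_)
                if e - s < k:
                    break
                codes = self.base_codes(chrom, s, e).astype(np.uint64)
                h = _rolling_encode(codes, k)
                idx = np.searchsorted(keys, h)
                idx[idx == len(keys)] = 0
                match = keys[idx] == h
                for off in np.flatnonzero(match):
                    for q, strand in enc[int(h[off])]:
                        hits[q].append((chrom, s + int(off), strand))
                s = e - (k - 1)
        return hits

    # -- FASTA export -------------------------------------------------------

    def export_fasta(self, path, windows: Sequence[tuple[str, int, int]]) -> None:
        """Write the requested windows as standard FASTA (60-column wrap)."""
        with open(path, "w") as fh:
            for chrom, start, end in windows:
                seq = self.sequence(chrom, start, end)
                fh.write(f">{chrom}:{start}-{end}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")


def default_genome(seed: int = 0) -> GenomeDeclaration:
    """The desk-scale three-chromosome genome used throughout."""
    return GenomeDeclaration(
        [
            ChromosomeDecl("chrA", 40_000_000, (18_000_000, 22_000_000)),
            ChromosomeDecl("chrB", 30_000_000, (13_000_000, 16_000_000)),
            ChromosomeDecl("chrC", 20_000_000, (500_000, 1_500_000), acrocentric=True),
        ],
        seed=seed,
    )


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq.upper()))


def _splitmix64(x: np.ndarray | np.uint64) -> np.ndarray | np.uint64:
    # SplitMix64 finalizer; uint64 wrap-around arithmetic is intentional.
    with np.errstate(over="ignore"):
        z = np.uint64(x) + np.uint64(0x9E3779B97F4A7C15)
        z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
        z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
        return z ^ (z >> np.uint64(31))


def _encode_kmer(kmer: str) -> int:
    code = 0
    for b in kmer:
        code = (code << 2) | "ACGT".index(b)
    return code


def _rolling_encode(codes: np.ndarray, k: int) -> np.ndarray:
    """Exact 2-bit polynomial encoding of every k-window of a code array."""
    n = len(codes) - k + 1
    out = np.zeros(n, dtype=np.uint64)
    for i in range(k):
        out |= codes[i : i + n] << np.uint64(2 * (k - 1 - i))
    return out


# ---------------------------------------------------------------------------
# intervals, segments, derivatives
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval on one haplotype of one chromosome."""

    chrom: str
    start: int
    end: int
    haplotype: str = "A"

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise GenomeError(f"bad interval [{self.start},{self.end})")
        if self.haplotype not in HAPLOTYPES:
            raise GenomeError(f"haplotype must be one of {HAPLOTYPES}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap(self, start: int, end: int) -> int:
        return max(0, min(self.end, end) - max(self.start, start))


@dataclass(frozen=True)
class Segment:
    """An oriented copy of a reference interval inside a derivative chromosome."""

    interval: GenomicInterval
    orientation: str = "+"  # "+" forward, "-" reverse

    def __post_init__(self) -> None:
        if self.orientation not in ("+", "-"):
            raise GenomeError(f"orientation must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.interval.length

    # Breakends at the two path ends of the segment.  Convention: a breakend
    # with orient "+" retains reference sequence to its left ([..., pos)),
    # orient "-" retains sequence to its right ([pos, ...)).
    def path_left_breakend(self) -> tuple[str, int, str]:
        iv = self.interval
        return (iv.chrom, iv.start, "-") if self.orientation == "+" else (iv.chrom, iv.end, "+")

    def path_right_breakend(self) -> tuple[str, int, str]:
        iv = self.interval
        return (iv.chrom, iv.end, "+") if self.orientation == "+" else (iv.chrom, iv.start, "-")

    def split(self, offset: int) -> tuple["Segment", "Segment"]:
        """Split at a path offset (0 < offset < length) into (left, right)."""
        iv = self.interval
        if not 0 < offset < self.length:
            raise GenomeError(f"split offset {offset} outside segment of length {self.length}")
        if self.orientation == "+":
            a = GenomicInterval(iv.chrom, iv.start, iv.start + offset, iv.haplotype)
            b = GenomicInterval(iv.chrom, iv.start + offset, iv.end, iv.haplotype)
        else:
            a = GenomicInterval(iv.chrom, iv.end - offset, iv.end, iv.haplotype)
            b = GenomicInterval(iv.chrom, iv.start, iv.end - offset, iv.haplotype)
        return Segment(a, self.orientation), Segment(b, self.orientation)


@dataclass
class DerivativeChromosome:
    """An ordered path of oriented segments; the unit mutated by the cascade.

    ``left_telomere``/``right_telomere`` mark whether each path end is a
    natural (capped) chromosome terminus.  A derivative is *stable* when it
    has exactly one active centromere and both ends capped.
    """

    segments: list[Segment]
    left_telomere: bool = False
    right_telomere: bool = False
    centromere_inactivated: bool = False

    def __post_init__(self) -> None:
        if not self.segments:
            raise GenomeError("derivative must contain at least one segment")

    @property
    def length(self) -> int:
        return sum(s.length for s in self.segments)

    def haplotypes(self) -> set[str]:
        return {s.interval.haplotype for s in self.segments}

    def centromere_spans(self, genome: GenomeDeclaration) -> list[tuple[int, int]]:
        """Path spans covered by declared centromere intervals (may be partial)."""
        spans: list[tuple[int, int]] = []
        off = 0
        for seg in self.segments:
            iv = seg.interval
            cs, ce = genome.centromere(iv.chrom)
            ov = iv.overlap(cs, ce)
            if ov > 0:
                lo = max(iv.start, cs)
                hi = min(iv.end, ce)
                if seg.orientation == "+":
                    spans.append((off + lo - iv.start, off + hi - iv.start))
                else:
                    spans.append((off + iv.end - hi, off + iv.end - lo))
            off += seg.length
        return sorted(spans)

    def centromere_count(self, genome: GenomeDeclaration, min_fraction: float = 0.5) -> int:
        """Number of centromeres substantially present (>= min_fraction of span)."""
        n = 0
        for seg in self.segments:
            iv = seg.interval
            cs, ce = genome.centromere(iv.chrom)
            if iv.overlap(cs, ce) >= min_fraction * (ce - cs):
                n += 1
        return n

    def is_stable(self, genome: GenomeDeclaration) -> bool:
        return (
            self.left_telomere
            and self.right_telomere
            and self.centromere_count(genome) == 1
            and not self.centromere_inactivated
        )

    def split_at(self, path_pos: int) -> tuple["DerivativeChromosome", "DerivativeChromosome"]:
        """Cut the path at ``path_pos``; both products lose the cut-side cap."""
        if not 0 < path_pos < self.length:
            raise GenomeError(f"cut position {path_pos} outside derivative of length {self.length}")
        left: list[Segment] = []
        right: list[Segment] = []
        off = 0
        for seg in self.segments:
            if off + seg.length <= path_pos:
                left.append(seg)
            elif off >= path_pos:
                right.append(seg)
            else:
                a, b = seg.split(path_pos - off)
                left.append(a)
                right.append(b)
            off += seg.length
        return (
            DerivativeChromosome(left, self.left_telomere, False, self.centromere_inactivated),
            DerivativeChromosome(right, False, self.right_telomere, self.centromere_inactivated),
        )

    def subpath(self, start: int, end: int) -> list[Segment]:
        """Segments covering path interval [start, end)."""
        if not 0 <= start < end <= self.length:
            raise GenomeError(f"subpath [{start},{end}) outside derivative")
        out: list[Segment] = []
        off = 0
        for seg in self.segments:
            lo = max(start, off)
            hi = min(end, off + seg.length)
            if lo < hi:
                piece = seg
                if hi < off + seg.length:
                    piece = piece.split(hi - off)[0]
                if lo > off:
                    piece = piece.split(lo - off)[1]
                out.append(piece)
            off += seg.length
        return out

    def adjacencies(self) -> list[tuple[tuple[str, int, str], tuple[str, int, str]]]:
        """Ordered breakend pairs at each internal join of the path."""
        out = []
        for a, b in zip(self.segments, self.segments[1:]):
            out.append((a.path_right_breakend(), b.path_left_breakend()))
        return out


def reference_derivative(genome: GenomeDeclaration, chrom: str, haplotype: str) -> DerivativeChromosome:
    """A full-length, telomere-capped copy of one reference chromosome."""
    seg = Segment(GenomicInterval(chrom, 0, genome.length(chrom), haplotype))
    return DerivativeChromosome([seg], left_telomere=True, right_telomere=True)


def recompute_caps(genome: GenomeDeclaration, der: DerivativeChromosome) -> DerivativeChromosome:
    """Set telomere flags from whether the path ends are natural termini."""
    first, last = der.segments[0], der.segments[-1]
    c1, p1, o1 = first.path_left_breakend()
    left = (o1 == "-" and p1 == 0) or (o1 == "+" and p1 == genome.length(c1))
    c2, p2, o2 = last.path_right_breakend()
    right = (o2 == "+" and p2 == genome.length(c2)) or (o2 == "-" and p2 == 0)
    return replace(der, left_telomere=left, right_telomere=right)


# ---------------------------------------------------------------------------
# cells
# ---------------------------------------------------------------------------

PRIMARY, BRIDGE, MICRONUCLEUS = "primary", "bridge", "micronucleus"


@dataclass
class CellGenome:
    """All derivative chromosomes of one cell plus compartment labels.

    ``compartments`` is parallel to ``derivatives``; at most one derivative
    may sit in the ``bridge`` compartment.  The per-cell mutation list holds
    clustered point mutations (kataegis) acquired along the lineage.
    """

    derivatives: list[DerivativeChromosome]
    compartments: list[str] = field(default_factory=list)
    generation: int = 0
    cell_id: str = "cell0"
    parent_id: str | None = None
    event_ids: list[int] = field(default_factory=list)
    mutations: list = field(default_factory=list)
    bridge_history: bool = False
    bridge_broken_interphase: bool | None = None

    def __post_init__(self) -> None:
        if not self.compartments:
            self.compartments = [PRIMARY] * len(self.derivatives)
        if len(self.compartments) != len(self.derivatives):
            raise GenomeError("compartments must parallel derivatives")
        if self.compartments.count(BRIDGE) > 1:
            raise GenomeError("at most one bridge compartment per cell")
        if self.generation < 0:
            raise GenomeError("generation must be >= 0")

    def add(self, der: DerivativeChromosome, compartment: str = PRIMARY) -> None:
        if compartment == BRIDGE and BRIDGE in self.compartments:
            raise GenomeError("at most one bridge compartment per cell")
        self.derivatives.append(der)
        self.compartments.append(compartment)

    def micronucleated(self) -> bool:
        return MICRONUCLEUS in self.compartments

    def uncapped(self) -> list[int]:
        """Indices of derivatives with at least one uncapped end."""
        return [
            i
            for i, d in enumerate(self.derivatives)
            if not (d.left_telomere and d.right_telomere)
        ]


def diploid_cell(genome: GenomeDeclaration, cell_id: str = "cell0") -> CellGenome:
    """An intact G1 diploid cell: one capped copy of each chromosome per haplotype."""
    ders = [
        reference_derivative(genome, chrom, hap)
        for chrom in genome.names()
        for hap in HAPLOTYPES
    ]
    return CellGenome(ders, cell_id=cell_id)


# ---------------------------------------------------------------------------
# truth copy number
# ---------------------------------------------------------------------------

class CNProfile:
    """Binned haplotype-resolved copy number.

    Stores covered bases per bin, so the copy number of a bin is the exact
    mean coverage over its width: integer wherever segment boundaries align
    with bin boundaries, fractional only in boundary bins.  Base conservation
    (sum of CN x bin width == total segment length per haplotype) is exact.
    """

    def __init__(self, genome: GenomeDeclaration, bin_size: int):
        if bin_size <= 0:
            raise GenomeError("bin_size must be positive")
        self.genome = genome
        self.bin_size = int(bin_size)
        self.cov: dict[tuple[str, str], np.ndarray] = {
            (chrom, hap): np.zeros(self.n_bins(chrom), dtype=float)
            for chrom in genome.names()
            for hap in HAPLOTYPES
        }

    def n_bins(self, chrom: str) -> int:
        return -(-self.genome.length(chrom) // self.bin_size)

    def bin_starts(self, chrom: str) -> np.ndarray:
        return np.arange(self.n_bins(chrom), dtype=np.int64) * self.bin_size

    def bin_widths(self, chrom: str) -> np.ndarray:
        starts = self.bin_starts(chrom)
        ends = np.minimum(starts + self.bin_size, self.genome.length(chrom))
        return (ends - starts).astype(float)

    def add_segment(self, seg: Segment, copies: int = 1) -> None:
        iv = seg.interval
        if iv.chrom not in self.genome:
            raise GenomeError(f"unknown chromosome {iv.chrom!r}")
        if iv.end > self.genome.length(iv.chrom):
            raise GenomeError(f"segment {iv} beyond declared chromosome length")
        bs = self.bin_size
        b0, b1 = iv.start // bs, (iv.end - 1) // bs
        idx = np.arange(b0, b1 + 1)
        lo = np.maximum(idx * bs, iv.start)
        hi = np.minimum((idx + 1) * bs, iv.end)
        self.cov[(iv.chrom, iv.haplotype)][idx] += copies * (hi - lo)

    def cn(self, chrom: str, hap: str) -> np.ndarray:
        return self.cov[(chrom, hap)] / self.bin_widths(chrom)

    def integer_cn(self, chrom: str, hap: str) -> np.ndarray:
        return np.rint(self.cn(chrom, hap)).astype(int)

    def total_bases(self, hap: str) -> float:
        return float(sum(v.sum() for (c, h), v in self.cov.items() if h == hap))

    def copy(self) -> "CNProfile":
        out = CNProfile(self.genome, self.bin_size)
        for k, v in self.cov.items():
            out.cov[k] = v.copy()
        return out

    def __add__(self, other: "CNProfile") -> "CNProfile":
        if other.bin_size != self.bin_size or other.genome is not self.genome:
            raise GenomeError("profiles must share genome and bin size")
        out = self.copy()
        for k in out.cov:
            out.cov[k] += other.cov[k]
        return out


def truth_cn_profile(
    cell: CellGenome,
    bin_size: int,
    genome: GenomeDeclaration,
    compartments: Iterable[str] | None = None,
) -> CNProfile:
    """Exact per-bin, per-haplotype copy number over all of a cell's derivatives.

    ``compartments`` restricts which compartments contribute (default: all —
    micronuclear DNA is still part of the cell).
    """
    wanted = set(compartments) if compartments is not None else None
    prof = CNProfile(genome, bin_size)
    for der, comp in zip(cell.derivatives, cell.compartments):
        if wanted is not None and comp not in wanted:
            continue
        for seg in der.segments:
            prof.add_segment(seg)
    return prof


def lazy_sequence(
    genome: GenomeDeclaration, chrom: str, start: int, end: int, orientation: str = "+"
) -> str:
    """Module-level alias for :meth:`GenomeDeclaration.sequence`."""
    return genome.sequence(chrom, start, end, orientation)
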