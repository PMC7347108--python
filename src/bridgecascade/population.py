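"""Clonal expansion after a bridge event and subclonal decomposition.

Models the long-term population experiments: a founder cell (typically a
bridge-breakage daughter) expands by binary division with continued BFB on
uncapped ends, stabilizing translocations, and micronucleation; a viability
rule removes cells with dicentric derivatives or fully lost chromosome arms;
the population is down-sampled to a cap each generation (neutral drift).
Downstream utilities deduplicate subclonal CN profiles and classify
breakpoint sharing across subclones (ancestral / subset / private).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cascade import Lineage, _bfb_step, divide_with_missegregation, make_rng
from .config import CascadeConfig
from .detect import CNSegment, segment_cn
from .genome import CellGenome, CNProfile, GenomeDeclaration, HAPLOTYPES, truth_cn_profile

ANCESTRAL, SUBSET, PRIVATE = "ancestral_shared", "subset_shared", "private"


@dataclass
class Population:
    genome: GenomeDeclaration
    config: CascadeConfig
    founder_id: str
    cells: list[CellGenome]
    n_generations: int
    lineage_log: Lineage | None = None


def _viable(genome: GenomeDeclaration, cell: CellGenome) -> bool:
    # dicentric derivatives break again at the next division; zero copies of
    # a whole chromosome arm are lethal by default
    arm_cov: dict[tuple[str, str, str], int] = {}
    for chrom in genome.names():
        cs, ce = genome.centromere(chrom)
        for hap in HAPLOTYPES:
            arm_cov[(chrom, hap, "p")] = 0
            arm_cov[(chrom, hap, "q")] = 0
    for der in cell.derivatives:
        if der.centromere_count(genome) >= 2:
            return False
        for seg in der.segments:
            iv = seg.interval
            cs, ce = genome.centromere(iv.chrom)
            if iv.overlap(0, cs) > 0.25 * max(cs, 1):
                arm_cov[(iv.chrom, iv.haplotype, "p")] += 1
            if iv.overlap(ce, genome.length(iv.chrom)) > 0.25 * (genome.length(iv.chrom) - ce):
                arm_cov[(iv.chrom, iv.haplotype, "q")] += 1
    for chrom in genome.names():
        for arm in ("p", "q"):
            if arm_cov[(chrom, "A", arm)] + arm_cov[(chrom, "B", arm)] == 0:
                return False
    return True


def expand_clone(
    genome: GenomeDeclaration,
    founder: CellGenome,
    n_generations: int,
    config: CascadeConfig,
    seed: int,
    cap: int = 1_000,
) -> Population:
    """Expand a founder by binary division under the per-division cascade rules."""
    if cap < 100:
        raise ValueError("population cap must be >= 100")
    rng = make_rng(seed, 101)
    lin = Lineage(genome, config, seed)
    lin.add_cell(founder)
    current = [founder]
    for gen in range(n_generations):
        nxt: list[CellGenome] = []
        for cell in current:
            if cell.uncapped():
                _bfb_step(genome, cell, config, rng, lin)
            da, db, _ = divide_with_missegregation(genome, cell, config, rng)
            for d in (da, db):
                if _viable(genome, d):
                    nxt.append(d)
        if not nxt:
            break
        if len(nxt) > cap:
            idx = rng.permutation(len(nxt))[:cap]
            nxt = [nxt[int(i)] for i in sorted(idx)]
        current = nxt
    return Population(genome, config, founder.cell_id, current, n_generations, lin)


# ---------------------------------------------------------------------------
# subclone profiles
# ---------------------------------------------------------------------------

@dataclass
class SubcloneProfile:
    profile_key: tuple
    n_cells: int
    cn: dict[tuple[str, str], np.ndarray]
    cell_ids: list[str] = field(default_factory=list)


def subclone_profiles(
    cells: list[CellGenome] | None,
    genome: GenomeDeclaration,
    bin_size: int = 25_000,
    matrix: np.ndarray | None = None,
    columns: list[tuple[str, str, int]] | None = None,
    norm_constant: float | None = None,
) -> list[SubcloneProfile]:
    """Deduplicate per-haplotype integer CN profiles, ordered by abundance.

    From cells, truth profiles are used directly; from an observed cell x bin
    matrix, each row is segmented first and deduplicated at the integer-call
    level.
    """
    profiles: dict[tuple, SubcloneProfile] = {}

    def push(cn: dict[tuple[str, str], np.ndarray], cid: str) -> None:
        key = tuple((c, h, tuple(int(v) for v in a)) for (c, h), a in sorted(cn.items()))
        if key not in profiles:
            profiles[key] = SubcloneProfile(key, 0, cn)
        profiles[key].n_cells += 1
        profiles[key].cell_ids.append(cid)

    if matrix is not None:
        if columns is None or norm_constant is None:
            raise ValueError("matrix input requires columns and norm_constant")
        from .sequencing import ObservedProfile

        keys = sorted({(c, h) for c, h, _ in columns})
        for r in range(matrix.shape[0]):
            counts = {}
            for (c, h) in keys:
                idx = [i for i, (cc, hh, _) in enumerate(columns) if (cc, hh) == (c, h)]
                counts[(c, h)] = matrix[r, idx].astype(float)
            obs = ObservedProfile(genome, bin_size, counts, norm_constant)
            segs = segment_cn(obs)
            cn = {}
            for (c, h) in keys:
                arr = np.zeros(len(counts[(c, h)]), dtype=int)
                for s in segs:
                    if (s.chrom, s.haplotype) == (c, h):
                        arr[s.start // bin_size : -(-s.end // bin_size)] = s.cn
                cn[(c, h)] = arr
            push(cn, f"row{r}")
    else:
        for cell in cells:
            prof = truth_cn_profile(cell, bin_size, genome)
            cn = {k: np.rint(prof.cn(*k)).astype(int) for k in prof.cov}
            push(cn, cell.cell_id)
    return sorted(profiles.values(), key=lambda p: -p.n_cells)


# ---------------------------------------------------------------------------
# breakpoint sharing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BreakpointSharing:
    chrom: str
    haplotype: str
    pos: int
    n_subclones: int
    n_total: int
    label: str


def classify_breakpoint_sharing(
    profiles: list[SubcloneProfile],
    genome: GenomeDeclaration,
    bin_size: int,
    tol_bins: int = 1,
) -> list[BreakpointSharing]:
    """Label each CN transition as ancestral / subset-shared / private.

    Transitions are matched across subclones within ``tol_bins`` bins.
    Requires >= 2 subclones.
    """
    if len(profiles) < 2:
        raise ValueError("breakpoint sharing needs >= 2 subclone profiles")
    per_sub: list[set[tuple[str, str, int]]] = []
    for p in profiles:
        bps: set[tuple[str, str, int]] = set()
        for (chrom, hap), arr in p.cn.items():
            d = np.flatnonzero(np.diff(arr))
            for b in d:
                bps.add((chrom, hap, int(b) + 1))
        per_sub.append(bps)
    all_bps = sorted(set().union(*per_sub))
    out: list[BreakpointSharing] = []
    used: set[tuple[str, str, int]] = set()
    for chrom, hap, b in all_bps:
        if (chrom, hap, b) in used:
            continue
        group = [
            (c, h, x)
            for (c, h, x) in all_bps
            if c == chrom and h == hap and abs(x - b) <= tol_bins
        ]
        used.update(group)
        n = sum(1 for s in per_sub if any(g in s for g in group))
        label = ANCESTRAL if n == len(profiles) else (PRIVATE if n == 1 else SUBSET)
        out.append(
            BreakpointSharing(chrom, hap, b * bin_size, n, len(profiles), label)
        )
    return out
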