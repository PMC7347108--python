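"""Emulation of binned sequencing readouts from truth copy number.

Three observables are produced, mirroring the experimental designs the
detectors consume: single-cell whole-genome coverage at ~25x (Look-Seq
style: ~90% of bins of each homolog covered by at least one read, strong
amplification dispersion), bulk sequencing of a cell population (cell-
averaged copy number plus Gaussian noise; subclonal mixtures produce
non-integer plateaus and sloping transitions), and single-cell copy-number
matrices (one noisy row per sampled cell).

Read-level simulation is intentionally replaced by bin-count emulation: all
downstream detectors operate on binned haplotype-resolved coverage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .genome import CNProfile, GenomeDeclaration, HAPLOTYPES


@dataclass(frozen=True)
class CoverageModel:
    """Per-bin single-cell coverage model.

    ``depth``: haploid-genome-wide mean depth (x).  ``read_length``: used only
    to convert depth to expected reads per copy per bin.  ``dropout``:
    probability that whole-genome amplification misses a bin entirely,
    calibrated so ~90% of bins of a CN=1 homolog carry >= 1 read at default
    depth.  ``amp_sigma``: log-normal sigma of the per-bin amplification
    factor.  ``allelic_sigma``: extra per-haplotype overdispersion.
    """

    depth: float = 25.0
    read_length: int = 150
    dropout: float = 0.10
    amp_sigma: float = 0.45
    allelic_sigma: float = 0.0
    bulk_sigma: float = 0.05

    def reads_per_copy(self, bin_size: int) -> float:
        # depth counts both haplotypes: depth/2 per copy
        return self.depth / 2.0 * bin_size / self.read_length


@dataclass
class ObservedProfile:
    """Noisy per-bin, per-haplotype counts (or real values for bulk)."""

    genome: GenomeDeclaration
    bin_size: int
    counts: dict[tuple[str, str], np.ndarray]
    norm_constant: float  # expected counts per copy per bin

    def normalized(self, chrom: str, hap: str) -> np.ndarray:
        return self.counts[(chrom, hap)] / self.norm_constant

    def keys(self):
        return self.counts.keys()


def emulate_cell_coverage(
    truth: CNProfile,
    model: CoverageModel,
    rng: np.random.Generator,
) -> ObservedProfile:
    """One single cell's binned coverage given its truth copy number.

    Per bin: with probability ``dropout`` the bin is zeroed regardless of CN;
    otherwise counts ~ Poisson(CN * reads_per_copy * A) with A log-normal
    (amplification).  CN-0 bins emit exactly zero (no mapping noise).
    """
    mu = model.reads_per_copy(truth.bin_size)
    counts: dict[tuple[str, str], np.ndarray] = {}
    for (chrom, hap), cov in truth.cov.items():
        cn = cov / truth.bin_widths(chrom)
        amp = rng.lognormal(-0.5 * model.amp_sigma**2, model.amp_sigma, size=cn.shape)
        if model.allelic_sigma > 0:
            amp = amp * rng.lognormal(
                -0.5 * model.allelic_sigma**2, model.allelic_sigma, size=cn.shape
            )
        lam = cn * mu * amp
        c = rng.poisson(lam).astype(float)
        keep = rng.random(cn.shape) >= model.dropout
        counts[(chrom, hap)] = c * keep
    return ObservedProfile(truth.genome, truth.bin_size, counts, mu)


def emulate_bulk(
    truths: Sequence[CNProfile],
    model: CoverageModel,
    rng: np.random.Generator | None = None,
    weights: Sequence[float] | None = None,
) -> ObservedProfile:
    """Bulk sequencing of a population: cell-weighted mean CN plus noise.

    Subclonal mixtures produce non-integer plateaus; staggered terminal
    losses produce gradual sloping transitions.
    """
    if not truths:
        raise ValueError("need at least one cell")
    g, bs = truths[0].genome, truths[0].bin_size
    w = np.ones(len(truths)) if weights is None else np.asarray(weights, dtype=float)
    w = w / w.sum()
    counts: dict[tuple[str, str], np.ndarray] = {}
    for key in truths[0].cov:
        chrom, hap = key
        widths = truths[0].bin_widths(chrom)
        mean = sum(wi * t.cov[key] / widths for wi, t in zip(w, truths))
        if rng is not None and model.bulk_sigma > 0:
            mean = mean + rng.normal(0.0, model.bulk_sigma, size=mean.shape)
        counts[key] = np.asarray(mean, dtype=float)
    return ObservedProfile(g, bs, counts, 1.0)


def emulate_cn_matrix(
    truths: Sequence[CNProfile],
    n_cells: int,
    model: CoverageModel,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[int], list[tuple[str, str, int]]]:
    """Cell x bin matrix of noisy counts for a sample of the population.

    Samples ``n_cells`` cells without replacement.  Returns (matrix,
    sampled indices, column index of (chrom, haplotype, bin)).
    """
    if n_cells > len(truths):
        raise ValueError(f"n_cells={n_cells} exceeds population size {len(truths)}")
    order = rng.permutation(len(truths))[:n_cells]
    columns: list[tuple[str, str, int]] = []
    first = truths[0]
    for (chrom, hap) in first.cov:
        for b in range(first.n_bins(chrom)):
            columns.append((chrom, hap, b))
    rows = []
    for i in order:
        obs = emulate_cell_coverage(truths[int(i)], model, rng)
        rows.append(np.concatenate([obs.counts[(c, h)] for (c, h) in first.cov]))
    return np.vstack(rows), [int(i) for i in order], columns
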