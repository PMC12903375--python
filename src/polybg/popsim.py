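"""Population simulation: genotypes, polygenic scores, and variance scaling.

Genotypes are diploid allele counts drawn independently per locus as
Binomial(2, p) (Hardy-Weinberg, no linkage), so the additive PGS is a sum of
independent scaled binomials and its variance grows linearly with the number
of contributing genes.  With pairwise epistatic terms present, the number of
interacting pairs grows quadratically in the gene count and the PGS variance
grows super-linearly.  :func:`variance_scaling_experiment` measures both
regimes across a gene-count grid with replicates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .architecture import (
    Architecture,
    NormalEffects,
    UniformFrequencies,
    add_epistatic_terms,
    child_seed,
    sample_architecture,
)

__all__ = [
    "GenotypeMatrix",
    "PGSVector",
    "VarianceScalingResult",
    "simulate_genotypes",
    "compute_pgs",
    "variance_scaling_experiment",
    "pgs_density",
]

_MODES = ("additive", "epistatic")
# epistatic score accumulation is chunked over terms to bound peak memory
_EPI_CHUNK = 2048


@dataclass(frozen=True)
class GenotypeMatrix:
    """Individuals x loci table of diploid allele counts in {0, 1, 2}."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2:
            raise ValueError("counts must be 2-D (individuals x loci)")
        if c.size and (c.min() < 0 or c.max() > 2):
            raise ValueError("genotype counts must lie in {0, 1, 2}")
        object.__setattr__(self, "counts", c)

    @property
    def n_individuals(self) -> int:
        return self.counts.shape[0]

    @property
    def n_loci(self) -> int:
        return self.counts.shape[1]

    def allele_frequencies(self) -> np.ndarray:
        """Observed effect-allele frequencies, one per locus."""
        return self.counts.mean(axis=0) / 2.0


@dataclass(frozen=True)
class PGSVector:
    """Polygenic scores for one simulated population."""

    scores: np.ndarray
    mode: str

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}, got {self.mode!r}")
        s = np.asarray(self.scores, dtype=float)
        if not np.all(np.isfinite(s)):
            raise ValueError("scores must be finite")
        object.__setattr__(self, "scores", s)

    def __len__(self) -> int:
        return self.scores.size

    def sample_variance(self) -> float:
        """Unbiased (n-1 denominator) sample variance of the scores."""
        return float(np.var(self.scores, ddof=1))


def simulate_genotypes(
    arch: Architecture, n_individuals: int, seed: int = 0
) -> GenotypeMatrix:
    """Draw a population of independent Hardy-Weinberg genotypes.

    Entry (i, j) ~ Binomial(2, p_j), independent across individuals and loci.
    Deterministic under a fixed seed.
    """
    if n_individuals < 1:
        raise ValueError(f"n_individuals must be >= 1, got {n_individuals}")
    rng = np.random.default_rng(seed)
    counts = rng.binomial(2, arch.frequencies, size=(n_individuals, arch.n_genes))
    return GenotypeMatrix(counts=counts.astype(np.int8))


def compute_pgs(
    genotypes: GenotypeMatrix, arch: Architecture, mode: str = "additive"
) -> PGSVector:
    """Compute polygenic scores for every individual.

    additive:   score_i = sum_j w_j g_ij
    epistatic:  additive + sum over terms (a, b, u) of u * g_ia * g_ib

    Epistatic mode on an architecture without interaction terms reduces
    exactly to the additive score.
    """
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {_MODES}, got {mode!r}")
    if genotypes.n_loci != arch.n_genes:
        raise ValueError(
            f"genotype matrix has {genotypes.n_loci} loci but architecture "
            f"has {arch.n_genes}"
        )
    counts = genotypes.counts
    scores = counts.astype(float) @ arch.effects
    if mode == "epistatic":
        a_idx, b_idx, weights = arch.interaction_arrays()
        for start in range(0, weights.size, _EPI_CHUNK):
            sl = slice(start, start + _EPI_CHUNK)
            prod = (counts[:, a_idx[sl]] * counts[:, b_idx[sl]]).astype(float)
            scores += prod @ weights[sl]
    return PGSVector(scores=scores, mode=mode)


@dataclass(frozen=True)
class VarianceScalingResult:
    """Replicate PGS variances across a gene-count grid for one scoring mode.

    ``variances[i, r]`` is the sample variance of the PGS in replicate ``r``
    of the ``gene_counts[i]``-gene condition.
    """

    mode: str
    gene_counts: tuple[int, ...]
    variances: np.ndarray  # shape (len(gene_counts), n_replicates)

    def __post_init__(self) -> None:
        v = np.asarray(self.variances, dtype=float)
        if v.shape[0] != len(self.gene_counts):
            raise ValueError("variances row count must match gene_counts")
        if v.shape[1] < 2:
            raise ValueError("need >= 2 replicates (SEM undefined otherwise)")
        object.__setattr__(self, "variances", v)

    @property
    def n_replicates(self) -> int:
        return self.variances.shape[1]

    @property
    def mean_variance(self) -> np.ndarray:
        return self.variances.mean(axis=1)

    @property
    def sem(self) -> np.ndarray:
        """Standard error of the mean across replicates (ddof=1)."""
        return self.variances.std(axis=1, ddof=1) / math.sqrt(self.n_replicates)

    def to_frame(self) -> pd.DataFrame:
        """Long table: one row per (gene_count, replicate)."""
        rows = [
            (self.mode, g, r, self.variances[i, r])
            for i, g in enumerate(self.gene_counts)
            for r in range(self.n_replicates)
        ]
        return pd.DataFrame(rows, columns=["mode", "gene_count", "replicate", "variance"])

    def aggregate_frame(self) -> pd.DataFrame:
        """Summary table: mean variance and SEM per gene count."""
        return pd.DataFrame(
            {
                "mode": self.mode,
                "gene_count": list(self.gene_counts),
                "mean_variance": self.mean_variance,
                "sem": self.sem,
            }
        )

    def linear_fit(self) -> tuple[float, float, float]:
        """(slope, intercept, R^2) of mean variance regressed on gene count."""
        x = np.asarray(self.gene_counts, dtype=float)
        y = self.mean_variance
        res = stats.linregress(x, y)
        return float(res.slope), float(res.intercept), float(res.rvalue**2)


def variance_scaling_experiment(
    gene_counts: Sequence[int],
    n_individuals: int = 10_000,
    n_replicates: int = 10,
    freq_dist: UniformFrequencies | None = None,
    effect_dist: NormalEffects | None = None,
    interaction_density: float = 0.05,
    interaction_dist: NormalEffects | None = None,
    modes: Sequence[str] = _MODES,
    root_seed: int = 0,
    resample_architectures: bool = True,
) -> dict[str, VarianceScalingResult]:
    """Measure PGS variance across gene counts, modes, and replicates.

    For each (gene_count, replicate) a fresh architecture is sampled (or, with
    ``resample_architectures=False``, one architecture per gene count is
    reused across replicates), genotypes are simulated, and the sample
    variance of the PGS recorded.  The additive and epistatic modes share the
    architecture's loci and genotype matrix within a replicate — the
    epistatic condition adds interaction terms on top of the same additive
    basis — so their comparison is paired.

    Seeds: replicate slot k = i * n_replicates + r (gene-count index i)
    consumes child seeds (root_seed + 3k, +3k+1, +3k+2) for architecture,
    epistasis, and genotypes respectively.
    """
    gene_counts = tuple(int(g) for g in gene_counts)
    if any(g < 1 for g in gene_counts):
        raise ValueError("gene_counts must be positive")
    if list(gene_counts) != sorted(set(gene_counts)):
        raise ValueError("gene_counts must be strictly increasing")
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2 (SEM undefined otherwise)")
    modes = tuple(modes)
    for m in modes:
        if m not in _MODES:
            raise ValueError(f"unknown mode {m!r}")

    variances = {m: np.zeros((len(gene_counts), n_replicates)) for m in modes}
    for i, g in enumerate(gene_counts):
        for r in range(n_replicates):
            k = i * n_replicates + r
            base = 3 * k
            arch_slot = base if resample_architectures else 3 * i * n_replicates
            arch = sample_architecture(
                g, freq_dist, effect_dist, seed=child_seed(root_seed, arch_slot)
            )
            genotypes = simulate_genotypes(
                arch, n_individuals, seed=child_seed(root_seed, base + 2)
            )
            for m in modes:
                if m == "epistatic":
                    arch_m = add_epistatic_terms(
                        arch,
                        interaction_density,
                        interaction_dist,
                        seed=child_seed(root_seed, base + 1),
                    )
                else:
                    arch_m = arch
                pgs = compute_pgs(genotypes, arch_m, mode=m)
                variances[m][i, r] = pgs.sample_variance()
    return {
        m: VarianceScalingResult(mode=m, gene_counts=gene_counts, variances=variances[m])
        for m in modes
    }


def pgs_density(
    scores: PGSVector | np.ndarray, grid: Sequence[float] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian kernel density estimate of a PGS distribution.

    Bandwidth follows Silverman's rule.  If no grid is given, a 512-point
    grid spanning the data plus/minus four bandwidths is used, over which the
    trapezoid integral of the density is 1 to within ~1%.

    Raises ``ValueError`` for degenerate (constant or near-constant) scores.
    """
    values = scores.scores if isinstance(scores, PGSVector) else np.asarray(scores, float)
    if values.size < 2 or np.unique(values).size < 2:
        raise ValueError("density estimation needs >= 2 distinct scores")
    kde = stats.gaussian_kde(values, bw_method="silverman")
    bandwidth = float(kde.factor) * float(values.std(ddof=1))
    if grid is None:
        grid = np.linspace(
            values.min() - 4.0 * bandwidth, values.max() + 4.0 * bandwidth, 512
        )
    else:
        grid = np.asarray(grid, dtype=float)
        if grid.ndim != 1 or grid.size < 2 or not np.all(np.diff(grid) > 0):
            raise ValueError("grid must be 1-D and strictly increasing")
    return grid, kde(grid)
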