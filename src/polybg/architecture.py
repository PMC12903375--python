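"""Genetic architectures: loci, effect sizes, and optional pairwise epistasis.

An :class:`Architecture` is the genetic basis of a simulated complex trait:
a set of unlinked diallelic loci, each with a population allele frequency
``p`` and a per-allele effect ``w`` on the log-odds scale, plus an optional
set of pairwise interaction (epistatic) terms.  Loci are assumed to be in
Hardy-Weinberg equilibrium and mutually independent (no linkage
disequilibrium), so the additive polygenic score is a sum of independent
scaled Binomial(2, p) random variables and its variance has the closed form

    Var(PGS) = sum_i  w_i^2 * 2 p_i (1 - p_i)

which this module exposes both analytically and via exhaustive enumeration
for small architectures (the enumeration serves as an independent oracle in
tests).
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "LocusSpec",
    "EpistaticTerm",
    "Architecture",
    "UniformFrequencies",
    "NormalEffects",
    "sample_architecture",
    "add_epistatic_terms",
    "analytic_additive_variance",
    "exhaustive_pgs_moments",
    "expected_variance_per_locus",
    "child_seed",
]

_SEED_MOD = 2_147_483_647


def child_seed(root_seed: int, offset: int) -> int:
    """Deterministic child seed for a sub-draw: (root + offset) mod 2^31-1.

    Sub-draws of a larger experiment consume consecutive offsets in a
    documented order, so replicates are independent yet fully reproducible
    from a single root seed.
    """
    return (int(root_seed) + int(offset)) % _SEED_MOD


@dataclass(frozen=True)
class LocusSpec:
    """A single diallelic locus.

    Parameters
    ----------
    allele_frequency:
        Population frequency of the effect allele, strictly inside (0, 1).
    effect_size:
        Additive effect per allele copy, in log-odds units.
    """

    allele_frequency: float
    effect_size: float

    def __post_init__(self) -> None:
        p = self.allele_frequency
        if not (0.0 < p < 1.0):
            raise ValueError(f"allele_frequency must be in (0, 1), got {p!r}")
        if not math.isfinite(self.effect_size):
            raise ValueError(f"effect_size must be finite, got {self.effect_size!r}")


@dataclass(frozen=True)
class EpistaticTerm:
    """Pairwise interaction between two loci.

    The term contributes ``interaction_weight * g_a * g_b`` log-odds units to
    an individual's liability, where ``g_a`` and ``g_b`` are the diploid
    allele counts at the two loci.
    """

    locus_index_a: int
    locus_index_b: int
    interaction_weight: float

    def __post_init__(self) -> None:
        if self.locus_index_a >= self.locus_index_b:
            raise ValueError(
                "epistatic term requires locus_index_a < locus_index_b, got "
                f"({self.locus_index_a}, {self.locus_index_b})"
            )
        if self.locus_index_a < 0:
            raise ValueError("locus indices must be non-negative")
        if not math.isfinite(self.interaction_weight):
            raise ValueError("interaction_weight must be finite")


@dataclass(frozen=True)
class Architecture:
    """An ordered set of loci plus (possibly empty) pairwise epistatic terms."""

    loci: tuple[LocusSpec, ...]
    epistatic_terms: tuple[EpistaticTerm, ...] = field(default=())

    def __post_init__(self) -> None:
        object.__setattr__(self, "loci", tuple(self.loci))
        object.__setattr__(self, "epistatic_terms", tuple(self.epistatic_terms))
        if len(self.loci) < 1:
            raise ValueError("an Architecture needs at least one locus")
        n = len(self.loci)
        seen: set[tuple[int, int]] = set()
        for term in self.epistatic_terms:
            pair = (term.locus_index_a, term.locus_index_b)
            if term.locus_index_b >= n:
                raise ValueError(f"epistatic term {pair} out of range for {n} loci")
            if pair in seen:
                raise ValueError(f"duplicate epistatic pair {pair}")
            seen.add(pair)

    @property
    def n_genes(self) -> int:
        return len(self.loci)

    @property
    def frequencies(self) -> np.ndarray:
        """Allele frequencies as a float array of length ``n_genes``."""
        return np.array([l.allele_frequency for l in self.loci], dtype=float)

    @property
    def effects(self) -> np.ndarray:
        """Per-allele effect sizes as a float array of length ``n_genes``."""
        return np.array([l.effect_size for l in self.loci], dtype=float)

    def interaction_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Epistatic terms as parallel index/index/weight arrays."""
        if not self.epistatic_terms:
            empty_i = np.empty(0, dtype=np.intp)
            return empty_i, empty_i.copy(), np.empty(0, dtype=float)
        a = np.array([t.locus_index_a for t in self.epistatic_terms], dtype=np.intp)
        b = np.array([t.locus_index_b for t in self.epistatic_terms], dtype=np.intp)
        w = np.array([t.interaction_weight for t in self.epistatic_terms], dtype=float)
        return a, b, w

    # -- plain-JSON serialization ------------------------------------------
    def to_json(self) -> str:
        doc = {
            "loci": [[l.allele_frequency, l.effect_size] for l in self.loci],
            "epistatic_terms": [
                [t.locus_index_a, t.locus_index_b, t.interaction_weight]
                for t in self.epistatic_terms
            ],
        }
        return json.dumps(doc)

    @classmethod
    def from_json(cls, text: str) -> "Architecture":
        doc = json.loads(text)
        loci = tuple(LocusSpec(p, w) for p, w in doc["loci"])
        terms = tuple(EpistaticTerm(a, b, u) for a, b, u in doc.get("epistatic_terms", []))
        return cls(loci=loci, epistatic_terms=terms)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "Architecture":
        return cls.from_json(Path(path).read_text())


@dataclass(frozen=True)
class UniformFrequencies:
    """Uniform(low, high) allele-frequency distribution, bounded inside (0, 1).

    The default range [0.05, 0.5] is a minor-allele-frequency-like band that
    keeps every sampled locus polymorphic enough to contribute variance.
    ``low == high`` gives a degenerate (point-mass) distribution, useful for
    fixed-frequency tests.
    """

    low: float = 0.05
    high: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.low <= self.high < 1.0):
            raise ValueError(
                f"require 0 < low <= high < 1, got ({self.low}, {self.high})"
            )

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.low == self.high:
            return np.full(size, self.low)
        return rng.uniform(self.low, self.high, size=size)

    @property
    def mean(self) -> float:
        return 0.5 * (self.low + self.high)

    @property
    def sd(self) -> float:
        return (self.high - self.low) / math.sqrt(12.0)

    @property
    def mean_heterozygosity_variance(self) -> float:
        """E[2 p (1 - p)], the expected per-unit-weight genotype variance."""
        second = (self.low**2 + self.low * self.high + self.high**2) / 3.0
        return 2.0 * (self.mean - second)


@dataclass(frozen=True)
class NormalEffects:
    """Normal(mean, sd) effect-size distribution in log-odds units.

    The default is mean zero: risk and protective alleles are equally likely,
    so growing the number of contributing genes grows the liability variance
    while leaving the population mean unchanged.  ``sd == 0`` gives a point
    mass at ``mean``.
    """

    mean: float = 0.0
    sd: float = 0.1

    def __post_init__(self) -> None:
        if self.sd < 0 or not math.isfinite(self.sd) or not math.isfinite(self.mean):
            raise ValueError(f"invalid Normal parameters ({self.mean}, {self.sd})")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.sd == 0.0:
            return np.full(size, self.mean)
        return rng.normal(self.mean, self.sd, size=size)

    @property
    def second_moment(self) -> float:
        """E[w^2] = mean^2 + sd^2."""
        return self.mean**2 + self.sd**2


def expected_variance_per_locus(
    freq_dist: UniformFrequencies, effect_dist: NormalEffects
) -> float:
    """E[w^2] * E[2 p (1-p)]: expected additive variance contributed per locus.

    With loci drawn i.i.d., the expected additive PGS variance of a G-locus
    architecture is G times this constant — the slope of the linear
    variance-vs-gene-count relationship.
    """
    return effect_dist.second_moment * freq_dist.mean_heterozygosity_variance


def sample_architecture(
    n_genes: int,
    freq_dist: UniformFrequencies | None = None,
    effect_dist: NormalEffects | None = None,
    seed: int = 0,
) -> Architecture:
    """Draw an additive architecture of ``n_genes`` i.i.d. loci.

    Every locus's allele frequency and effect size is drawn from the same
    underlying distributions, so architectures with different gene counts are
    matched in their per-locus statistics and differ only in size.

    Identical (parameters, seed) pairs yield identical architectures.
    """
    if n_genes < 1:
        raise ValueError(f"n_genes must be >= 1, got {n_genes}")
    freq_dist = freq_dist or UniformFrequencies()
    effect_dist = effect_dist or NormalEffects()
    rng = np.random.default_rng(seed)
    freqs = freq_dist.sample(rng, n_genes)
    effects = effect_dist.sample(rng, n_genes)
    loci = tuple(LocusSpec(float(p), float(w)) for p, w in zip(freqs, effects))
    return Architecture(loci=loci)


def add_epistatic_terms(
    arch: Architecture,
    interaction_density: float,
    interaction_dist: NormalEffects | None = None,
    seed: int = 0,
) -> Architecture:
    """Return a copy of ``arch`` with random pairwise interaction terms.

    Each of the C(G, 2) unordered locus pairs is included independently with
    probability ``interaction_density``; included pairs get weights drawn
    from ``interaction_dist`` (default: the same Normal family as the main
    effects).  Because the number of candidate pairs grows quadratically in
    the gene count, any fixed positive density produces super-linear growth
    of liability variance with gene count.  The input is not modified.
    """
    if not (0.0 <= interaction_density <= 1.0):
        raise ValueError(
            f"interaction_density must be in [0, 1], got {interaction_density}"
        )
    interaction_dist = interaction_dist or NormalEffects()
    rng = np.random.default_rng(seed)
    n = arch.n_genes
    pairs = list(itertools.combinations(range(n), 2))
    if interaction_density == 0.0 or not pairs:
        return Architecture(loci=arch.loci, epistatic_terms=())
    if interaction_density == 1.0:
        keep = np.ones(len(pairs), dtype=bool)
    else:
        keep = rng.random(len(pairs)) < interaction_density
    chosen = [pairs[i] for i in np.flatnonzero(keep)]
    weights = interaction_dist.sample(rng, len(chosen))
    terms = tuple(
        EpistaticTerm(a, b, float(u)) for (a, b), u in zip(chosen, weights)
    )
    return Architecture(loci=arch.loci, epistatic_terms=terms)


def analytic_additive_variance(arch: Architecture) -> float:
    """Exact additive-PGS variance: sum_i w_i^2 * 2 p_i (1 - p_i).

    Assumes independent Hardy-Weinberg diploid genotypes at every locus.
    Epistatic terms, if present, are ignored (this is the additive component).
    """
    p = arch.frequencies
    w = arch.effects
    return float(np.sum(w**2 * 2.0 * p * (1.0 - p)))


def exhaustive_pgs_moments(
    arch: Architecture, mode: str = "additive"
) -> tuple[float, float]:
    """(mean, variance) of the PGS by enumerating all 3^G genotype vectors.

    Each genotype vector's probability is the product of its per-locus
    Hardy-Weinberg probabilities Binomial(2, p).  Exact up to floating point;
    only feasible for small architectures (G <= 12 enforced).
    """
    if mode not in ("additive", "epistatic"):
        raise ValueError(f"unknown mode {mode!r}")
    G = arch.n_genes
    if G > 12:
        raise ValueError(f"exhaustive enumeration limited to 12 loci, got {G}")
    p = arch.frequencies
    w = arch.effects
    a_idx, b_idx, u = arch.interaction_arrays()
    # per-locus genotype pmf: rows = locus, cols = count 0/1/2
    pmf = np.stack([stats.binom.pmf(k, 2, p) for k in (0, 1, 2)], axis=1)
    mean = 0.0
    second = 0.0
    for counts in itertools.product((0, 1, 2), repeat=G):
        g = np.asarray(counts, dtype=float)
        prob = float(np.prod(pmf[np.arange(G), counts]))
        score = float(g @ w)
        if mode == "epistatic" and u.size:
            score += float(np.sum(u * g[a_idx] * g[b_idx]))
        mean += prob * score
        second += prob * score * score
    return mean, second - mean * mean
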