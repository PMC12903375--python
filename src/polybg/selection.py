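"""Selection on disease liability: fitness, selection coefficients, evolution.

Fitness maps disease probability to reproductive success,

    fitness(pgs) = 1 - s * P(disease | beta0 + pgs + environment_offset)

with selection strength ``s`` in (0, 1] (fitness is bounded between 0, unable
to reproduce, and 1, maximal reproduction).  Because the logistic maps a
fixed log-odds variant effect to very different probability changes across
backgrounds, the selection coefficient of a variant is not one number but a
distribution over polygenic backgrounds: near-zero in low-liability
individuals (effectively neutral) and large at the high-risk tail.

Generational dynamics use an individual-based Wright-Fisher model with
fitness-proportional parent sampling and Mendelian transmission.  The
environment enters only as a per-phase additive offset on liability;
:func:`environment_shift_scenario` runs the baseline / shifted / relaxed
three-phase experiment in which a transient environmental stressor leaves
the population with permanently lower genetic liability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .architecture import Architecture, child_seed
from .liability import LiabilityModel, prevalence_at
from .popsim import GenotypeMatrix, PGSVector, compute_pgs

__all__ = [
    "FitnessModel",
    "SelectionCoefficientDistribution",
    "ScenarioTrajectory",
    "ExtinctionError",
    "fitness_of",
    "selection_coefficient_distribution",
    "evolve_generation",
    "environment_shift_scenario",
]

_PHASES = ("baseline", "shifted", "relaxed")
_QUANTILES = (0.025, 0.25, 0.5, 0.75, 0.975)


class ExtinctionError(RuntimeError):
    """Raised when every individual has zero fitness (no possible parents)."""


@dataclass(frozen=True)
class FitnessModel:
    """Soft-selection fitness model.

    selection_strength:
        Fitness cost ``s`` of disease, in (0, 1]; an individual's expected
        fitness is 1 - s * P(disease).
    environment_offset:
        Environmental modifier of liability, in log-odds units, added to
        every individual's liability before the disease-probability map.
    """

    selection_strength: float
    environment_offset: float = 0.0

    def __post_init__(self) -> None:
        s = self.selection_strength
        if not (0.0 < s <= 1.0):
            raise ValueError(f"selection_strength must be in (0, 1], got {s!r}")
        if not math.isfinite(self.environment_offset):
            raise ValueError("environment_offset must be finite")


def fitness_of(
    model: FitnessModel,
    liability_model: LiabilityModel,
    pgs: float | np.ndarray,
) -> float | np.ndarray:
    """Expected fitness 1 - s * P(disease | beta0 + pgs + offset).

    Lies in [1 - s, 1] and decreases monotonically in ``pgs``.
    """
    p_disease = prevalence_at(
        liability_model, np.asarray(pgs, dtype=float) + model.environment_offset
    )
    out = 1.0 - model.selection_strength * np.asarray(p_disease)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class SelectionCoefficientDistribution:
    """Per-background selection coefficients of a variant, with summaries.

    The coefficient at background ``b`` is the relative fitness reduction of
    a carrier versus a matched non-carrier:

        s(b) = [fitness(b) - fitness(b + delta)] / fitness(b)

    so coefficients lie in [0, 1] for deleterious deltas.
    """

    background_pgs_values: np.ndarray
    coefficients: np.ndarray
    variant_delta: float

    def __post_init__(self) -> None:
        b = np.asarray(self.background_pgs_values, dtype=float)
        c = np.asarray(self.coefficients, dtype=float)
        if b.shape != c.shape:
            raise ValueError("backgrounds and coefficients must align")
        object.__setattr__(self, "background_pgs_values", b)
        object.__setattr__(self, "coefficients", c)

    @property
    def summary(self) -> dict[str, float]:
        c = self.coefficients
        out = {"mean": float(c.mean()), "sd": float(c.std(ddof=1)) if c.size > 1 else 0.0}
        for q in _QUANTILES:
            out[f"q{q:g}"] = float(np.quantile(c, q))
        return out


def selection_coefficient_distribution(
    backgrounds: PGSVector | np.ndarray | Sequence[float],
    liability_model: LiabilityModel,
    fitness_model: FitnessModel,
    variant_delta: float,
) -> SelectionCoefficientDistribution:
    """Selection coefficient of a ``variant_delta`` variant per background.

    Raises ``ZeroDivisionError`` if any background has zero fitness (possible
    only at s = 1 with disease probability saturating at 1).
    """
    b = (
        backgrounds.scores
        if isinstance(backgrounds, PGSVector)
        else np.asarray(backgrounds, dtype=float)
    )
    if b.size == 0:
        raise ValueError("background PGS sample must be non-empty")
    if not math.isfinite(variant_delta):
        raise ValueError("variant_delta must be finite")
    f_without = np.asarray(fitness_of(fitness_model, liability_model, b))
    f_with = np.asarray(fitness_of(fitness_model, liability_model, b + variant_delta))
    if np.any(f_without == 0.0):
        raise ZeroDivisionError(
            "zero-fitness background encountered (s = 1 with certain disease); "
            "selection coefficient undefined there"
        )
    coefficients = (f_without - f_with) / f_without
    return SelectionCoefficientDistribution(
        background_pgs_values=b,
        coefficients=coefficients,
        variant_delta=float(variant_delta),
    )


def _realized_fitness(
    genotypes: GenotypeMatrix,
    arch: Architecture,
    liability_model: LiabilityModel,
    fitness_model: FitnessModel,
    rng: np.random.Generator,
    selection_mode: str,
) -> np.ndarray:
    pgs = compute_pgs(
        genotypes, arch, mode="epistatic" if arch.epistatic_terms else "additive"
    )
    p_disease = np.asarray(
        prevalence_at(liability_model, pgs.scores + fitness_model.environment_offset)
    )
    if selection_mode == "soft":
        # expected fitness; lower-variance than realizing disease events
        return 1.0 - fitness_model.selection_strength * p_disease
    if selection_mode == "hard":
        diseased = rng.random(p_disease.size) < p_disease
        return 1.0 - fitness_model.selection_strength * diseased.astype(float)
    raise ValueError(f"selection_mode must be 'soft' or 'hard', got {selection_mode!r}")


def evolve_generation(
    genotypes: GenotypeMatrix,
    arch: Architecture,
    liability_model: LiabilityModel,
    fitness_model: FitnessModel,
    seed: int = 0,
    selection_mode: str = "soft",
) -> GenotypeMatrix:
    """One Wright-Fisher generation under fitness-proportional mating.

    Population size is constant.  Each offspring draws two parents with
    probability proportional to fitness, then inherits, at every locus
    independently, one allele from each parent (an allele is transmitted
    from a parent with count g with probability g/2).  Deterministic under a
    fixed seed.
    """
    n = genotypes.n_individuals
    if n < 2:
        raise ValueError("population size must be >= 2")
    rng = np.random.default_rng(seed)
    fitness = _realized_fitness(
        genotypes, arch, liability_model, fitness_model, rng, selection_mode
    )
    total = fitness.sum()
    if total <= 0.0:
        raise ExtinctionError("all individuals have zero fitness")
    parents = rng.choice(n, size=(n, 2), p=fitness / total)
    half_m = genotypes.counts[parents[:, 0]].astype(np.float64) / 2.0
    half_f = genotypes.counts[parents[:, 1]].astype(np.float64) / 2.0
    child = rng.binomial(1, half_m) + rng.binomial(1, half_f)
    return GenotypeMatrix(counts=child.astype(np.int8))


@dataclass(frozen=True)
class ScenarioTrajectory:
    """Per-generation population summaries across environment phases."""

    generation: np.ndarray
    phase: tuple[str, ...]
    mean_liability: np.ndarray
    prevalence: np.ndarray
    allele_frequencies: np.ndarray  # generations x loci
    phase_boundaries: tuple[int, int, int]  # first generation of each phase

    def to_frame(self) -> pd.DataFrame:
        """Long table: generation, phase, summaries, one column per locus."""
        frame = pd.DataFrame(
            {
                "generation": self.generation,
                "phase": list(self.phase),
                "mean_liability": self.mean_liability,
                "prevalence": self.prevalence,
            }
        )
        freq = pd.DataFrame(
            self.allele_frequencies,
            columns=[f"freq_locus_{j}" for j in range(self.allele_frequencies.shape[1])],
        )
        return pd.concat([frame, freq], axis=1)

    def phase_end_index(self, phase: str) -> int:
        """Index of the last generation recorded in the given phase."""
        if phase not in _PHASES:
            raise ValueError(f"unknown phase {phase!r}")
        idx = [i for i, ph in enumerate(self.phase) if ph == phase]
        if not idx:
            raise ValueError(f"phase {phase!r} has no recorded generations")
        return idx[-1]

    def phase_summary(self) -> dict[str, dict[str, float]]:
        """End-of-phase mean liability and prevalence, per phase."""
        out = {}
        for ph in _PHASES:
            i = self.phase_end_index(ph)
            out[ph] = {
                "end_generation": int(self.generation[i]),
                "end_mean_liability": float(self.mean_liability[i]),
                "end_prevalence": float(self.prevalence[i]),
            }
        return out


def environment_shift_scenario(
    arch: Architecture,
    n_individuals: int,
    liability_model: LiabilityModel,
    fitness_model: FitnessModel,
    generations_per_phase: tuple[int, int, int] = (10, 50, 10),
    shift_offset: float = 2.0,
    seed: int = 0,
    selection_mode: str = "soft",
) -> ScenarioTrajectory:
    """Three-phase environment-shift experiment.

    Phase 1 (baseline) and phase 3 (relaxed) use environment offset 0; phase
    2 (shifted) adds ``shift_offset`` log-odds units to every individual's
    liability, increasing disease probability and hence the strength of
    selection against high-PGS individuals.  Per generation the trajectory
    records the mean genetic liability (mean PGS), the disease prevalence
    under that phase's environment, and the per-locus allele frequencies.
    Generation 0 is the founding population before any selection.

    Seeds: generation t consumes child seed root + 1 + t (offset 0 founds the
    population).
    """
    if len(generations_per_phase) != 3 or any(g < 1 for g in generations_per_phase):
        raise ValueError("generations_per_phase must be three positive integers")
    if shift_offset < 0:
        raise ValueError("shift_offset must be >= 0")
    if fitness_model.environment_offset != 0.0:
        raise ValueError(
            "scenario controls the environment offset per phase; pass a "
            "fitness model with environment_offset = 0"
        )
    offsets = (0.0, float(shift_offset), 0.0)
    genotypes = _found_population(arch, n_individuals, seed)

    generation, phases, mean_liab, prev, freqs = [], [], [], [], []

    def record(g: GenotypeMatrix, gen: int, phase_idx: int) -> None:
        pgs = compute_pgs(
            g, arch, mode="epistatic" if arch.epistatic_terms else "additive"
        )
        p = np.asarray(prevalence_at(liability_model, pgs.scores + offsets[phase_idx]))
        generation.append(gen)
        phases.append(_PHASES[phase_idx])
        mean_liab.append(float(pgs.scores.mean()))
        prev.append(float(p.mean()))
        freqs.append(g.allele_frequencies())

    boundaries = [0]
    record(genotypes, 0, 0)
    gen = 0
    for phase_idx, n_gen in enumerate(generations_per_phase):
        if phase_idx > 0:
            boundaries.append(gen + 1)
        phase_fitness = FitnessModel(
            selection_strength=fitness_model.selection_strength,
            environment_offset=offsets[phase_idx],
        )
        for _ in range(n_gen):
            gen += 1
            genotypes = evolve_generation(
                genotypes,
                arch,
                liability_model,
                phase_fitness,
                seed=child_seed(seed, 1 + gen),
                selection_mode=selection_mode,
            )
            record(genotypes, gen, phase_idx)

    return ScenarioTrajectory(
        generation=np.asarray(generation),
        phase=tuple(phases),
        mean_liability=np.asarray(mean_liab),
        prevalence=np.asarray(prev),
        allele_frequencies=np.vstack(freqs),
        phase_boundaries=tuple(boundaries),
    )


def _found_population(arch: Architecture, n_individuals: int, seed: int) -> GenotypeMatrix:
    from .popsim import simulate_genotypes

    return simulate_genotypes(arch, n_individuals, seed=child_seed(seed, 0))
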