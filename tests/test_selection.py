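"""Fitness, selection-coefficient distributions, and generational dynamics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

from polybg import (
    Architecture,
    FitnessModel,
    GenotypeMatrix,
    LocusSpec,
    environment_shift_scenario,
    evolve_generation,
    fitness_of,
    model_from_background_rate,
    sample_architecture,
    selection_coefficient_distribution,
    simulate_genotypes,
)
from polybg.liability import LiabilityModel


class TestFitness:
    def test_no_disease_means_no_cost(self, rare_disease_model):
        fm = FitnessModel(selection_strength=0.9)
        assert fitness_of(fm, rare_disease_model, -700.0) == pytest.approx(1.0)

    def test_logistic_midpoint_half_cost(self):
        # liability 0 -> P(disease) = 1/2 -> fitness = 1 - s/2
        model = model_from_background_rate(0.5)
        fm = FitnessModel(selection_strength=0.5)
        assert fitness_of(fm, model, 0.0) == pytest.approx(0.75)

    def test_environment_offset_shifts_liability(self):
        model = model_from_background_rate(0.5)
        shifted = FitnessModel(selection_strength=0.5, environment_offset=2.0)
        flat = FitnessModel(selection_strength=0.5)
        assert fitness_of(shifted, model, -2.0) == pytest.approx(
            fitness_of(flat, model, 0.0)
        )

    @given(
        st.floats(min_value=1e-6, max_value=1.0),
        st.floats(min_value=-100, max_value=100),
        st.floats(min_value=0.001, max_value=0.999),
    )
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_fitness_bounded_and_decreasing(self, s, pgs, rate):
        model = model_from_background_rate(rate)
        fm = FitnessModel(selection_strength=s)
        f = fitness_of(fm, model, pgs)
        assert 1 - s <= f <= 1
        assert fitness_of(fm, model, pgs + 1.0) <= f

    @pytest.mark.parametrize("s", [0.0, -0.5, 1.5])
    def test_selection_strength_domain(self, s):
        with pytest.raises(ValueError, match="selection_strength"):
            FitnessModel(selection_strength=s)


class TestSelectionCoefficients:
    def test_null_variant_is_exactly_neutral(self, rare_disease_model):
        fm = FitnessModel(selection_strength=0.5)
        dist = selection_coefficient_distribution(
            np.linspace(-3, 3, 50), rare_disease_model, fm, 0.0
        )
        assert np.all(dist.coefficients == 0.0)

    def test_coefficients_increase_with_background_risk(self, rare_disease_model):
        # denser scan over the region where all liabilities stay <= 0
        fm = FitnessModel(selection_strength=0.5)
        beta0 = rare_disease_model.baseline_log_odds
        backgrounds = np.linspace(-6.0, -beta0 - 1.0, 500)
        dist = selection_coefficient_distribution(
            backgrounds, rare_disease_model, fm, 1.0
        )
        assert np.all(np.diff(dist.coefficients) > 0)
        assert np.all((dist.coefficients >= 0) & (dist.coefficients <= 1))

    def test_rare_disease_variants_effectively_neutral(self):
        # beta0 = -15: even a unit-effect variant has coefficient < 1e-4 s
        model = LiabilityModel(background_rate=float(expit(-15.0)))
        s = 0.5
        fm = FitnessModel(selection_strength=s)
        backgrounds = np.linspace(-4, 4, 200)
        dist = selection_coefficient_distribution(backgrounds, model, fm, 1.0)
        assert np.all(dist.coefficients < 1e-4 * s)
        # analytic rare-disease bound: coef <= s * P(b + delta) <= s e^{beta0+b+1}
        bound = s * np.exp(model.baseline_log_odds + backgrounds + 1.0)
        assert np.all(dist.coefficients <= bound)

    def test_summary_consistent_with_samples(self, rare_disease_model):
        fm = FitnessModel(selection_strength=0.8)
        dist = selection_coefficient_distribution(
            np.linspace(-2, 4, 101), rare_disease_model, fm, 1.5
        )
        s = dist.summary
        assert s["mean"] == pytest.approx(dist.coefficients.mean())
        assert s["q0.5"] == pytest.approx(np.median(dist.coefficients))

    def test_empty_background_sample_rejected(self, rare_disease_model):
        fm = FitnessModel(selection_strength=0.5)
        with pytest.raises(ValueError, match="non-empty"):
            selection_coefficient_distribution([], rare_disease_model, fm, 1.0)


class TestEvolveGeneration:
    def test_deterministic_under_fixed_seed(self, rare_disease_model):
        arch = sample_architecture(10, seed=1)
        g = simulate_genotypes(arch, 100, seed=2)
        fm = FitnessModel(selection_strength=0.5)
        a = evolve_generation(g, arch, rare_disease_model, fm, seed=3)
        b = evolve_generation(g, arch, rare_disease_model, fm, seed=3)
        assert np.array_equal(a.counts, b.counts)

    def test_population_size_constant(self, rare_disease_model):
        arch = sample_architecture(5, seed=1)
        g = simulate_genotypes(arch, 77, seed=2)
        fm = FitnessModel(selection_strength=0.5)
        out = evolve_generation(g, arch, rare_disease_model, fm, seed=0)
        assert out.n_individuals == 77 and out.n_loci == 5

    def test_fixed_locus_is_absorbing(self, rare_disease_model):
        arch = Architecture((LocusSpec(0.5, 0.2), LocusSpec(0.5, -0.1)))
        counts = np.column_stack(
            [np.full(60, 2), np.random.default_rng(0).binomial(2, 0.5, 60)]
        )
        g = GenotypeMatrix(counts)
        fm = FitnessModel(selection_strength=0.5)
        for seed in range(5):
            out = evolve_generation(g, arch, rare_disease_model, fm, seed=seed)
            assert np.all(out.counts[:, 0] == 2)

    def test_near_neutral_selection_preserves_frequencies(self, rare_disease_model):
        # with s -> 0 the expected frequency change is zero (pure drift)
        arch = Architecture((LocusSpec(0.5, 1.0),))
        fm = FitnessModel(selection_strength=1e-9)
        n, n_rep = 200, 40
        deltas = []
        for rep in range(n_rep):
            g = simulate_genotypes(arch, n, seed=100 + rep)
            out = evolve_generation(g, arch, rare_disease_model, fm, seed=500 + rep)
            deltas.append(
                out.allele_frequencies()[0] - g.allele_frequencies()[0]
            )
        # drift sd of p-hat per generation ~ sqrt(p q / 2n)
        se = math.sqrt(0.25 / (2 * n)) / math.sqrt(n_rep)
        assert abs(np.mean(deltas)) < 4 * se

    def test_strong_selection_matches_deterministic_recursion(self):
        # single-locus oracle: iterate the exact expected-frequency recursion
        # p' = sum_g HW_g(p) w_g (g/2) / sum_g HW_g(p) w_g under soft selection
        w_effect, s, rate, p0 = 2.0, 0.8, 0.3, 0.5
        model = model_from_background_rate(rate)
        beta0 = model.baseline_log_odds
        fm = FitnessModel(selection_strength=s)
        arch = Architecture((LocusSpec(p0, w_effect),))

        def recursion_step(p):
            hw = np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
            fit = 1 - s * expit(beta0 + w_effect * np.arange(3))
            weighted = hw * fit
            return float(weighted @ (np.arange(3) / 2) / weighted.sum())

        n_gen, n, n_rep = 8, 400, 20
        p_det = p0
        for _ in range(n_gen):
            p_det = recursion_step(p_det)

        finals = []
        for rep in range(n_rep):
            g = simulate_genotypes(arch, n, seed=1000 + rep)
            for t in range(n_gen):
                g = evolve_generation(g, arch, model, fm, seed=2000 + 31 * rep + t)
            finals.append(g.allele_frequencies()[0])
        mean_final = np.mean(finals)
        assert mean_final < p0  # risk allele is purged
        assert abs(mean_final - p_det) < 0.045  # ~4x the drift SE of the mean

    def test_tiny_population_rejected(self, rare_disease_model):
        arch = Architecture((LocusSpec(0.5, 0.1),))
        g = GenotypeMatrix(np.array([[1]]))
        fm = FitnessModel(selection_strength=0.5)
        with pytest.raises(ValueError, match="population size"):
            evolve_generation(g, arch, rare_disease_model, fm)


class TestEnvironmentShiftScenario:
    def test_trajectory_structure(self, rare_disease_model):
        arch = sample_architecture(10, seed=4)
        fm = FitnessModel(selection_strength=0.5)
        traj = environment_shift_scenario(
            arch, 300, rare_disease_model, fm, (2, 3, 2), 2.0, seed=5
        )
        assert len(traj.generation) == 1 + 2 + 3 + 2
        phases = list(traj.phase)
        assert phases == sorted(phases, key=("baseline", "shifted", "relaxed").index)
        assert traj.phase_boundaries == (0, 3, 6)
        assert np.all((traj.allele_frequencies >= 0) & (traj.allele_frequencies <= 1))
        assert np.all((traj.prevalence > 0) & (traj.prevalence < 1))
        frame = traj.to_frame()
        assert {"generation", "phase", "mean_liability", "prevalence"} <= set(frame.columns)
        assert sum(c.startswith("freq_locus_") for c in frame.columns) == 10

    def test_null_scenario_only_drifts(self, rare_disease_model):
        arch = sample_architecture(20, seed=6)
        fm = FitnessModel(selection_strength=1e-9)
        traj = environment_shift_scenario(
            arch, 2000, rare_disease_model, fm, (2, 4, 2), 0.0, seed=7
        )
        drift_sd = math.sqrt(8 * 20 * 0.004 / 2000)  # ~ sqrt(T Var(pgs) / n)
        assert abs(traj.mean_liability[-1] - traj.mean_liability[0]) < 5 * drift_sd

    def test_shift_raises_prevalence_at_matched_generations(self, rare_disease_model):
        arch = sample_architecture(30, seed=8)
        fm = FitnessModel(selection_strength=0.5)
        traj = environment_shift_scenario(
            arch, 500, rare_disease_model, fm, (5, 5, 5), 2.0, seed=9
        )
        phase1 = traj.prevalence[np.array(traj.phase) == "baseline"][1:]  # gens 1-5
        phase2 = traj.prevalence[np.array(traj.phase) == "shifted"]
        assert np.all(phase2 > phase1)

    def test_stronger_shift_gives_stronger_response(self, rare_disease_model):
        finals = {}
        fm = FitnessModel(selection_strength=0.5)
        for shift in (0.5, 3.0):
            ends = []
            for rep in range(3):
                arch = sample_architecture(100, seed=300 + rep)
                traj = environment_shift_scenario(
                    arch, 2000, rare_disease_model, fm, (5, 30, 5), shift,
                    seed=400 + rep,
                )
                # response = final mean liability relative to the founding mean
                ends.append(traj.mean_liability[-1] - traj.mean_liability[0])
            finals[shift] = np.mean(ends)
        assert finals[3.0] < finals[0.5]

    def test_scenario_rejects_preset_environment_offset(self, rare_disease_model):
        arch = sample_architecture(5, seed=1)
        fm = FitnessModel(selection_strength=0.5, environment_offset=1.0)
        with pytest.raises(ValueError, match="environment_offset"):
            environment_shift_scenario(arch, 100, rare_disease_model, fm)
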