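"""Calibration machinery: quadratic loss, binary decode/encode, GA mechanics,
elite selection and parameter histograms.

GA runs here use a one-compartment grid so each objective evaluation is a
well-mixed solve — the GA's control flow (selection, crossover, elitism,
epidemic restarts, determinism) does not depend on the grid size.
"""

import numpy as np
import pytest

from dorsalgrad import (
    GAConfig,
    GAIndividual,
    GradientProfile,
    ModelParameters,
    ParameterBound,
    SolverConfig,
    SpatialGrid,
    decode,
    default_bounds,
    elite_selection,
    encode,
    evolve,
    loss,
    parameter_histograms,
)
from dorsalgrad.model import PARAMETER_NAMES


@pytest.fixture(scope="module")
def tiny_setup():
    """One-compartment target profile + small GA configuration."""
    grid = SpatialGrid(1)
    solver = SolverConfig(method="pseudo", steady_tol=1e-7)
    from dorsalgrad import integrate_to_steady_state

    result = integrate_to_steady_state(ModelParameters(), grid, solver)
    profile = GradientProfile(grid.positions, result.state.totals().nDl_total)
    return grid, solver, profile


class TestLoss:
    def test_identical_profiles_have_zero_loss(self):
        x = np.linspace(0, 1, 30)
        profile = GradientProfile(x, np.exp(-x))
        assert loss(profile, profile) == 0.0

    def test_constant_offset_sums_squared_differences(self):
        x = np.array([0.1, 0.5, 0.9])
        exp = GradientProfile(x, np.array([1.0, 0.5, 0.2]))
        model = GradientProfile(x, exp.values + 0.1)
        assert loss(model, exp) == pytest.approx(0.03)

    def test_model_interpolated_onto_data_positions(self):
        model = GradientProfile(np.linspace(0, 1, 101), np.linspace(1, 0, 101))
        exp = GradientProfile(np.array([0.25, 0.75]), np.array([0.75, 0.25]))
        assert loss(model, exp) == pytest.approx(0.0, abs=1e-12)

    def test_empty_experimental_profile_rejected(self):
        model = GradientProfile(np.linspace(0, 1, 5), np.ones(5))
        with pytest.raises(ValueError):
            loss(model, GradientProfile(np.array([]), np.array([])))


class TestDecode:
    def test_all_zero_genome_hits_lower_bounds(self):
        config = GAConfig()
        params = decode(np.zeros(config.genome_length, dtype=np.uint8), config)
        for name in PARAMETER_NAMES:
            assert getattr(params, name) == pytest.approx(config.bounds[name].lo)

    def test_all_one_genome_hits_upper_bounds(self):
        config = GAConfig()
        genome = np.ones(config.genome_length, dtype=np.uint8)
        params = decode(genome, config)
        for name in PARAMETER_NAMES:
            assert getattr(params, name) == pytest.approx(
                config.bounds[name].hi, rel=1e-12
            )

    def test_linear_slice_maps_affinely(self):
        bounds = {n: ParameterBound(0.0, 255.0) for n in PARAMETER_NAMES}
        bounds["toll_sigma"] = ParameterBound(0.05, 0.5)
        config = GAConfig(bits_per_parameter=8, bounds=bounds)
        genome = np.zeros(config.genome_length, dtype=np.uint8)
        genome[0] = 1  # MSB of the first parameter: integer 128
        params = decode(genome, config)
        assert getattr(params, PARAMETER_NAMES[0]) == pytest.approx(255 * 128 / 255)

    def test_encode_decode_round_trip(self):
        config = GAConfig()
        truth = ModelParameters()
        recovered = decode(encode(truth, config), config)
        for name in PARAMETER_NAMES:
            assert getattr(recovered, name) == pytest.approx(
                getattr(truth, name), rel=1e-3
            )

    def test_wrong_genome_length_rejected(self):
        with pytest.raises(ValueError):
            decode(np.zeros(7, dtype=np.uint8), GAConfig())

    def test_log_bound_requires_positive_lo(self):
        with pytest.raises(ValueError):
            ParameterBound(0.0, 1.0, log=True)


class TestEvolve:
    def test_same_seed_gives_identical_history(self, tiny_setup):
        grid, solver, profile = tiny_setup
        ga = GAConfig(population_size=8, generations=4, seed=11)
        _, _, hist1 = evolve(profile, ga, grid, solver)
        _, _, hist2 = evolve(profile, ga, grid, solver)
        assert hist1["best_cost"] == hist2["best_cost"]
        assert hist1["mean_cost"] == hist2["mean_cost"]

    def test_best_cost_never_increases(self, tiny_setup):
        grid, solver, profile = tiny_setup
        ga = GAConfig(population_size=10, generations=8, seed=3)
        _, _, history = evolve(profile, ga, grid, solver)
        best = history["best_cost"]
        assert all(a >= b for a, b in zip(best, best[1:]))

    def test_failed_simulations_receive_penalty_not_crash(self, tiny_setup):
        grid, solver, profile = tiny_setup
        # absurd bounds make most candidates non-convergent within t_max
        bounds = default_bounds()
        ga = GAConfig(population_size=4, generations=2, seed=1, bounds=bounds,
                      penalty_cost=1e6)
        tight = SolverConfig(method="pseudo", t_max=100.0, check_interval=1.0,
                             steady_tol=1e-12)
        best, pop, _ = evolve(profile, ga, grid, tight)
        assert all(ind.cost is not None for ind in pop)

    def test_epidemic_restart_fires_on_stagnation(self, tiny_setup):
        grid, solver, profile = tiny_setup
        ga = GAConfig(
            population_size=6, generations=10, seed=5,
            epidemic_stagnation=2, epidemic_survivors=2,
            crossover_rate=0.0, mutation_rate=0.0,  # force stagnation
        )
        _, _, history = evolve(profile, ga, grid, solver)
        assert len(history["epidemics"]) >= 1


class TestEliteSelection:
    def _population(self, costs):
        genome = np.zeros(4, dtype=np.uint8)
        return [GAIndividual(genome, ModelParameters(), c) for c in costs]

    def test_threshold_below_best_returns_empty(self):
        assert elite_selection(self._population([0.1, 0.2]), 0.05) == []

    def test_infinite_threshold_returns_sorted_population(self):
        elite = elite_selection(self._population([0.3, 0.1, 0.2]), np.inf)
        assert [e.cost for e in elite] == [0.1, 0.2, 0.3]

    def test_published_threshold_filters_and_sorts(self):
        elite = elite_selection(self._population([0.01, 0.07, 0.05]), 0.069)
        assert [e.cost for e in elite] == [0.01, 0.05]

    def test_unevaluated_individual_rejected(self):
        pop = self._population([0.1])
        pop[0].cost = None
        with pytest.raises(ValueError):
            elite_selection(pop, 1.0)


class TestParameterHistograms:
    def test_clone_elite_has_zero_spread(self):
        genome = np.zeros(4, dtype=np.uint8)
        elite = [GAIndividual(genome, ModelParameters(), 0.01) for _ in range(5)]
        hists = parameter_histograms(elite)
        for name in PARAMETER_NAMES:
            assert hists[name]["iqr"] == 0.0
            assert hists[name]["narrow"]

    def test_single_individual_degenerate_histogram(self):
        elite = [GAIndividual(np.zeros(4, dtype=np.uint8), ModelParameters(), 0.0)]
        hists = parameter_histograms(elite, n_bins=5)
        assert hists["k1"]["counts"].sum() == 1

    def test_spread_flags_follow_dispersion(self):
        rng = np.random.default_rng(2)
        elite = []
        for _ in range(40):
            params = ModelParameters(
                toll_sigma=float(rng.uniform(0.15, 0.20)),  # tight
                k7=float(10 ** rng.uniform(-2, 1)),          # 3 decades wide
            )
            elite.append(GAIndividual(np.zeros(4, dtype=np.uint8), params, 0.01))
        hists = parameter_histograms(elite)
        assert hists["toll_sigma"]["narrow"]
        assert not hists["k7"]["narrow"]

    def test_empty_elite_rejected(self):
        with pytest.raises(ValueError):
            parameter_histograms([])
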