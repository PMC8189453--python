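"""Scenario application, nuclear-route decomposition, genotype comparisons,
gradient metrics and perturbation sweeps."""

import numpy as np
import pytest

from dorsalgrad import (
    GradientProfile,
    MutantScenario,
    PRESET_SCENARIOS,
    SolverConfig,
    apply_scenario,
    cactus_total_fraction,
    decompose_nuclear,
    gradient_metrics,
    parameter_sweep,
    species_percent_change,
    steady_state_profile,
)


class TestApplyScenario:
    def test_dl6_preset_changes_only_total_dorsal(self, wt_params):
        mutant = apply_scenario(wt_params, PRESET_SCENARIOS["dl6_heterozygote"])
        assert mutant.Dl_tot == 0.4605
        for name in ("k1", "k5", "toll_amp"):
            assert getattr(mutant, name) == getattr(wt_params, name)
        assert wt_params.Dl_tot == 0.525  # base untouched

    def test_empty_scenario_is_identity(self, wt_params):
        same = apply_scenario(wt_params, MutantScenario("none"))
        assert same.as_dict() == wt_params.as_dict()

    def test_multipliers_scale_the_base_values(self, wt_params):
        scen = MutantScenario("pll_partial", multipliers={"k9": 0.5, "k10": 0.5})
        mutant = apply_scenario(wt_params, scen)
        assert mutant.k9 == pytest.approx(0.0018)
        assert mutant.k10 == pytest.approx(213.5)

    def test_unknown_parameter_rejected(self):
        with pytest.raises(KeyError):
            MutantScenario("bad", overrides={"k99": 1.0})

    def test_parameter_in_both_maps_rejected(self):
        with pytest.raises(ValueError):
            MutantScenario("bad", overrides={"k1": 1.0}, multipliers={"k1": 2.0})


class TestDecomposeNuclear:
    def test_routes_sum_to_total(self, wt_steady):
        nDl0, nDlstar, total = decompose_nuclear(wt_steady.state)
        assert np.allclose(total, nDl0 + nDlstar)

    def test_direct_flow_is_uniform_along_axis(self, wt_steady):
        nDl0, _, _ = decompose_nuclear(wt_steady.state)
        assert np.ptp(nDl0) / nDl0.max() < 0.05

    def test_direct_flow_dominates_dorsally(self, wt_steady):
        nDl0, nDlstar, _ = decompose_nuclear(wt_steady.state)
        assert nDlstar[-1] < 0.1 * nDl0[-1]

    def test_toll_route_dominates_ventrally(self, wt_steady):
        nDl0, nDlstar, _ = decompose_nuclear(wt_steady.state)
        assert nDlstar[0] > nDl0[0]


class TestGenotypeComparisons:
    def test_wild_type_against_itself_is_100_percent(self, wt_steady):
        assert cactus_total_fraction(wt_steady.state, wt_steady.state) == 100.0

    def test_identical_states_have_zero_percent_change(self, wt_steady):
        for region in ("ventral", "dorsal", "mean"):
            change = species_percent_change(
                wt_steady.state, wt_steady.state, "DlC", region
            )
            assert change == 0.0

    def test_cactus_mutant_dual_effect(self, wt_steady, mutant_steady):
        wt_nDl = wt_steady.state.totals().nDl_total
        mut_nDl = mutant_steady["cactA2_cact011"].state.totals().nDl_total
        assert mut_nDl[0] < wt_nDl[0]    # less nuclear Dl ventrally
        assert mut_nDl[-1] > wt_nDl[-1]  # more nuclear Dl dorsally

    def test_crossover_sits_where_routes_balance(self, wt_steady, mutant_steady):
        mut = mutant_steady["cactA2_cact011"].state
        wt_nDl = wt_steady.state.totals().nDl_total
        mut_nDl = mut.totals().nDl_total
        sign_change = np.nonzero(np.diff(np.sign(mut_nDl - wt_nDl)))[0]
        assert sign_change.size >= 1
        cross = sign_change[0]
        balance = np.nonzero(np.diff(np.sign(mut.nDlstar - mut.nDl0)))[0]
        assert balance.size >= 1
        assert abs(int(cross) - int(balance[0])) <= 2  # within two compartments

    def test_dl6_signature_peak_down_dorsal_barely_changed(
        self, wt_steady, mutant_steady
    ):
        # reduced Dl dose hits the ventral peak hard but only mildly lowers
        # the dorsal basal level (direct-flow nuclear Dl tracks free Dl)
        wt_nDl = wt_steady.state.totals().nDl_total
        mut_nDl = mutant_steady["dl6_heterozygote"].state.totals().nDl_total
        peak_drop = (wt_nDl[0] - mut_nDl[0]) / wt_nDl[0]
        dorsal_drop = abs(mut_nDl[-1] - wt_nDl[-1]) / wt_nDl[-1]
        assert mut_nDl[0] < wt_nDl[0]
        assert dorsal_drop < 0.10
        assert dorsal_drop < peak_drop

    def test_region_argument_validated(self, wt_steady):
        with pytest.raises(ValueError, match="region"):
            species_percent_change(wt_steady.state, wt_steady.state, "DlC", "apical")

    def test_zero_wild_type_value_rejected(self, wt_steady, mutant_steady):
        zeroed = wt_steady.state.copy()
        zeroed.array[:] = 0.0
        with pytest.raises(ZeroDivisionError):
            cactus_total_fraction(mutant_steady["dl6_heterozygote"].state, zeroed)


class TestGradientMetrics:
    def test_flat_profile_has_no_amplitude_or_slope(self):
        profile = GradientProfile(np.linspace(0, 1, 10), np.full(10, 0.4))
        metrics = gradient_metrics(profile)
        assert metrics.peak == metrics.basal == 0.4
        assert metrics.amplitude == 0.0
        assert metrics.max_slope < 1e-12

    def test_gaussian_profile_slope_peaks_at_one_sd(self):
        x = np.linspace(0, 1, 200)
        profile = GradientProfile(x, np.exp(-(x**2) / (2 * 0.2**2)))
        metrics = gradient_metrics(profile)
        # analytic max |d/dx| = exp(-1/2)/0.2 at x = 0.2
        assert metrics.max_slope == pytest.approx(np.exp(-0.5) / 0.2, rel=1e-3)
        assert x[np.argmax(np.abs(metrics.slope_profile))] == pytest.approx(
            0.2, abs=0.01
        )

    def test_slope_ordering_across_genotypes(self, wt_steady, mutant_steady, grid50):
        def max_slope(result):
            return gradient_metrics(
                steady_state_profile(result.state, grid50)
            ).max_slope

        slopes = {
            "wt": max_slope(wt_steady),
            "dl6": max_slope(mutant_steady["dl6_heterozygote"]),
            "cact": max_slope(mutant_steady["cactA2_cact011"]),
            "double": max_slope(mutant_steady["dl6_cactA2"]),
        }
        assert slopes["wt"] == max(slopes.values())
        assert slopes["double"] == min(slopes.values())
        assert slopes["wt"] > slopes["dl6"] > slopes["double"]
        assert slopes["cact"] > slopes["double"]

    def test_too_few_positions_rejected(self):
        with pytest.raises(ValueError):
            gradient_metrics(GradientProfile([0.0, 1.0], [1.0, 0.0]))


class TestParameterSweep:
    def test_dorsal_dose_sweep_is_monotone_in_ventral_peak(
        self, wt_params, grid50, fast_solver
    ):
        results = parameter_sweep(
            wt_params, "Dl_tot", [0.8, 0.6, 0.4, 0.2], grid50, fast_solver
        )
        peaks = [r.state.totals().nDl_total[0] for r in results]
        assert all(a > b for a, b in zip(peaks, peaks[1:]))

    def test_zero_toll_sweep_leaves_only_direct_flow(
        self, wt_params, grid50, fast_solver
    ):
        (result,) = parameter_sweep(
            wt_params, "toll_amp", [0.0], grid50, fast_solver
        )
        nDl = result.state.totals().nDl_total
        assert np.ptp(nDl) / nDl.max() < 1e-6
        assert np.all(result.state.nDlstar < 1e-8)

    def test_blocked_cactus_degradation_flattens_gradient(
        self, wt_params, grid50, fast_solver, wt_steady
    ):
        (result,) = parameter_sweep(
            wt_params, ("k9", "k10"), [0.0], grid50, fast_solver
        )
        nDl = result.state.totals().nDl_total
        assert np.ptp(nDl) / nDl.max() < 1e-6
        wt_dorsal = wt_steady.state.totals().nDl_total[-1]
        assert nDl[0] == pytest.approx(wt_dorsal, rel=0.1)
        # signalling complexes pile up ventrally when not consumed
        assert result.state.DlCT[0] > wt_steady.state.DlCT[0]

    def test_negative_factor_rejected(self, wt_params, grid50, fast_solver):
        with pytest.raises(ValueError):
            parameter_sweep(wt_params, "k9", [-0.5], grid50, fast_solver)
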