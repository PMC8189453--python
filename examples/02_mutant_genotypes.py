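"""Mutant genotypes: the dual role of Cactus on Dorsal nuclear transport.

Runs the three quantified allelic combinations against wild type and prints
the total-Cactus fraction, the gradient summary metrics, and the hallmark of
the Cactus dual role: hypomorphic cact lowers nuclear Dl ventrally (fewer
Toll-responsive Dl-Cact complexes) while raising it dorsally (less
cytoplasmic retention of free Dl).
"""

from dorsalgrad import (
    ModelParameters,
    PRESET_SCENARIOS,
    SpatialGrid,
    cactus_total_fraction,
    gradient_metrics,
    run_scenario,
    steady_state_profile,
)

params = ModelParameters()
grid = SpatialGrid(50)
wt = run_scenario(params, PRESET_SCENARIOS["wild_type"], grid)
wt_nDl = wt.state.totals().nDl_total

print(f"{'genotype':>18} {'[C]tot %':>9} {'peak':>7} {'basal':>7} {'max |slope|':>12}")
for name in ("wild_type", "dl6_heterozygote", "cactA2_cact011", "dl6_cactA2"):
    result = run_scenario(params, PRESET_SCENARIOS[name], grid)
    metrics = gradient_metrics(steady_state_profile(result.state, grid))
    ctot = cactus_total_fraction(result.state, wt.state)
    print(f"{name:>18} {ctot:9.2f} {metrics.peak:7.3f} {metrics.basal:7.3f} "
          f"{metrics.max_slope:12.3f}")
    if name == "cactA2_cact011":
        nDl = result.state.totals().nDl_total
        print(f"{'':>18}  dual effect: ventral {nDl[0]:.3f} < WT "
              f"{wt_nDl[0]:.3f}; dorsal {nDl[-1]:.3f} > WT {wt_nDl[-1]:.3f}")

print(
    "\nWild type has the steepest gradient; the dl6/cactA2 double mutant the"
    "\nshallowest — the slope difference degrades the precision of target-"
    "\ngene expression borders."
)
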