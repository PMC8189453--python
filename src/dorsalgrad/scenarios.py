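"""Mutant genotypes, perturbation sweeps and genotype comparisons.

Genotypes are encoded as :class:`MutantScenario` objects — named sets of
parameter overrides (absolute values) and multipliers (scale factors) applied
to a base parameter set.  The three quantified allelic combinations of the
study system ship as presets:

* ``dl6_heterozygote`` — reduced maternal Dorsal dose ([Dl]tot 0.4605);
* ``cactA2_cact011`` — hypomorphic Cactus (synthesis constant k1 0.1825);
* ``dl6_cactA2`` — both reduced ([Dl]tot 0.375, k1 0.500).

Only [Dl]tot and/or k1 change between genotypes; total Cactus is an emergent
output of the steady state, not an input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .model import PARAMETER_NAMES, ModelParameters, SpatialGrid, SpeciesState
from .profiles import GradientMetrics, GradientProfile, gradient_metrics
from .solver import SolverConfig, SteadyStateResult, integrate_to_steady_state

__all__ = [
    "MutantScenario",
    "PRESET_SCENARIOS",
    "apply_scenario",
    "run_scenario",
    "steady_state_profile",
    "decompose_nuclear",
    "cactus_total_fraction",
    "species_percent_change",
    "gradient_metrics",
    "GradientMetrics",
    "parameter_sweep",
]


@dataclass
class MutantScenario:
    """A named genotype or perturbation as parameter overrides/multipliers."""

    name: str
    overrides: Mapping[str, float] = field(default_factory=dict)
    multipliers: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key in list(self.overrides) + list(self.multipliers):
            if key not in PARAMETER_NAMES:
                raise KeyError(f"unknown model parameter {key!r} in scenario "
                               f"{self.name!r}")
        both = set(self.overrides) & set(self.multipliers)
        if both:
            raise ValueError(
                f"parameters {sorted(both)} appear in both overrides and "
                f"multipliers of scenario {self.name!r}"
            )


#: Quantified genotypes, parameterized per the mutant-parameter table.
PRESET_SCENARIOS: dict[str, MutantScenario] = {
    "wild_type": MutantScenario("wild_type"),
    "dl6_heterozygote": MutantScenario("dl6_heterozygote",
                                       overrides={"Dl_tot": 0.4605}),
    "cactA2_cact011": MutantScenario("cactA2_cact011", overrides={"k1": 0.1825}),
    "dl6_cactA2": MutantScenario("dl6_cactA2",
                                 overrides={"Dl_tot": 0.375, "k1": 0.500}),
    # partial loss of the Toll-transducing kinase (pelle): Cactus
    # phosphorylation/degradation constants k9, k10 scaled together
    "pll_partial": MutantScenario("pll_partial",
                                  multipliers={"k9": 0.5, "k10": 0.5}),
    "toll_null": MutantScenario("toll_null", overrides={"toll_amp": 0.0}),
}


def apply_scenario(
    base: ModelParameters, scenario: MutantScenario
) -> ModelParameters:
    """Return a copy of `base` with overrides, then multipliers, applied."""
    changes = dict(scenario.overrides)
    for key, factor in scenario.multipliers.items():
        changes[key] = getattr(base, key) * factor
    return base.replace(**changes)


def run_scenario(
    base: ModelParameters,
    scenario: MutantScenario,
    grid: SpatialGrid | None = None,
    config: SolverConfig | None = None,
) -> SteadyStateResult:
    """Steady state of a scenario applied to a base parameter set."""
    grid = grid or SpatialGrid()
    return integrate_to_steady_state(apply_scenario(base, scenario), grid, config)


def steady_state_profile(state: SpeciesState, grid: SpatialGrid) -> GradientProfile:
    """Total-nDl gradient profile of a steady state on its grid."""
    totals = state.totals()
    return GradientProfile(grid.positions, totals.nDl_total)


def decompose_nuclear(
    state: SpeciesState,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split nuclear Dl into its two entry routes.

    Returns (nDl0, nDlstar, total) profiles: direct-flow nuclear Dl,
    Toll-induced nuclear Dl, and their sum — the observable gradient.
    """
    nDl0 = state.nDl0.copy()
    nDlstar = state.nDlstar.copy()
    return nDl0, nDlstar, nDl0 + nDlstar


def cactus_total_fraction(
    mutant_state: SpeciesState, wt_state: SpeciesState
) -> float:
    """Mutant total Cactus as a percentage of wild type.

    Total Cactus sums every Cactus-containing species (Cf, Cub, DlC, DlCT)
    over all compartments; this is the "[C]tot" column reported for each
    genotype.
    """
    wt_total = float(np.sum(wt_state.totals().C_total))
    if wt_total == 0:
        raise ZeroDivisionError("wild-type total Cactus is zero")
    return 100.0 * float(np.sum(mutant_state.totals().C_total)) / wt_total


_REGIONS = ("ventral", "dorsal", "mean")


def species_percent_change(
    mutant_state: SpeciesState,
    wt_state: SpeciesState,
    species: str,
    region: str = "mean",
) -> float:
    """Signed percent change of one species in a region, mutant vs wild type.

    region: "ventral" (ventral-most compartment), "dorsal" (dorsal-most) or
    "mean" (unweighted spatial mean).
    """
    if region not in _REGIONS:
        raise ValueError(f"region must be one of {_REGIONS}, got {region!r}")
    if mutant_state.n_compartments != wt_state.n_compartments:
        raise ValueError("states must share the grid")

    def select(state: SpeciesState) -> float:
        vec = state[species]
        if region == "ventral":
            return float(vec[0])
        if region == "dorsal":
            return float(vec[-1])
        return float(vec.mean())

    wt_val = select(wt_state)
    if wt_val == 0:
        raise ZeroDivisionError(
            f"wild-type {species} ({region}) is zero; percent change undefined"
        )
    return 100.0 * (select(mutant_state) - wt_val) / wt_val


def parameter_sweep(
    base: ModelParameters,
    target: str | Sequence[str],
    factors: Sequence[float],
    grid: SpatialGrid | None = None,
    config: SolverConfig | None = None,
) -> list[SteadyStateResult]:
    """Steady states with one or more parameters scaled by each factor.

    `target` may be a single parameter name or several names scaled
    together (e.g. ``("k9", "k10")`` for the pelle-pathway sweep).  Factor
    order is preserved in the output; zero factors are allowed.
    """
    grid = grid or SpatialGrid()
    names = [target] if isinstance(target, str) else list(target)
    for name in names:
        if name not in PARAMETER_NAMES:
            raise KeyError(f"unknown model parameter {name!r}")
    results = []
    for factor in factors:
        if factor < 0:
            raise ValueError(f"sweep factors must be >= 0, got {factor}")
        params = base.replace(**{n: getattr(base, n) * factor for n in names})
        try:
            results.append(integrate_to_steady_state(params, grid, config))
        except Exception as exc:
            raise RuntimeError(
                f"sweep failed at factor {factor} for {names}: {exc}"
            ) from exc
    return results
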