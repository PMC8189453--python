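"""Genetic-Algorithm calibration of the 18 model parameters.

The objective is the quadratic loss between the simulated steady-state total
nuclear-Dl profile and an experimental (or synthetic) gradient, with the
model profile linearly interpolated onto the data positions.  The GA uses a
binary codification of the parameters, k-tournament selection, uniform
bit-wise crossover, bit-flip mutation, elitism, and an optional epidemic
restart that re-randomizes all but the best individuals after a stagnation
period — a standard guard against premature convergence to local minima.

Parameters are decoded from fixed-width bit slices either linearly or in log
space; kinetic constants and diffusivities default to log-scale bounds
spanning four decades centred on the wild-type calibrated values, while the
three concentration/profile parameters use linear bounds on their physical
ranges.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .model import PARAMETER_NAMES, ModelParameters, SpatialGrid
from .profiles import GradientProfile
from .solver import SolverConfig, integrate_to_steady_state

__all__ = [
    "ParameterBound",
    "GAConfig",
    "GAIndividual",
    "default_bounds",
    "loss",
    "decode",
    "encode",
    "evolve",
    "elite_selection",
    "parameter_histograms",
    "read_profile_table",
    "write_profile_table",
    "write_elite_table",
]


@dataclass(frozen=True)
class ParameterBound:
    """Search range for one parameter; log=True decodes in log space."""

    lo: float
    hi: float
    log: bool = False

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"bound lo ({self.lo}) must be < hi ({self.hi})")
        if self.log and self.lo <= 0:
            raise ValueError("log-scale bounds must be strictly positive")


def default_bounds(
    reference: ModelParameters | None = None, decades: float = 2.0
) -> dict[str, ParameterBound]:
    """Default search bounds: ±`decades` log-decades around the reference for
    kinetic constants and diffusivities; fixed linear ranges for [Dl]tot
    (0–1), Toll peak (0–20) and Toll width (0.05–0.5)."""
    reference = reference or ModelParameters()
    bounds: dict[str, ParameterBound] = {}
    for name in PARAMETER_NAMES:
        if name == "Dl_tot":
            bounds[name] = ParameterBound(0.0, 1.0)
        elif name == "toll_amp":
            bounds[name] = ParameterBound(0.0, 20.0)
        elif name == "toll_sigma":
            bounds[name] = ParameterBound(0.05, 0.5)
        else:
            v = getattr(reference, name)
            bounds[name] = ParameterBound(v * 10**-decades, v * 10**decades, log=True)
    return bounds


@dataclass
class GAConfig:
    """Genetic-Algorithm hyper-parameters (all tunable, none hard-coded)."""

    population_size: int = 100
    generations: int = 200
    bits_per_parameter: int = 16
    bounds: dict[str, ParameterBound] = field(default_factory=default_bounds)
    tournament_k: int = 3
    crossover_rate: float = 0.9
    mutation_rate: float | None = None  # default: 1 / genome length
    epidemic_stagnation: int | None = 25  # None disables epidemic restarts
    epidemic_survivors: int = 5
    penalty_cost: float = 1e6
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.crossover_rate <= 1:
            raise ValueError("crossover_rate must be in [0, 1]")
        if self.mutation_rate is not None and not 0 <= self.mutation_rate <= 1:
            raise ValueError("mutation_rate must be in [0, 1]")
        if self.tournament_k < 2:
            raise ValueError("tournament_k must be >= 2")
        missing = set(PARAMETER_NAMES) - set(self.bounds)
        if missing:
            raise ValueError(f"bounds missing for parameters {sorted(missing)}")

    @property
    def genome_length(self) -> int:
        return len(PARAMETER_NAMES) * self.bits_per_parameter

    @property
    def effective_mutation_rate(self) -> float:
        if self.mutation_rate is not None:
            return self.mutation_rate
        return 1.0 / self.genome_length


@dataclass
class GAIndividual:
    """One candidate parameter set: binary genome, decoded values, loss."""

    genome: np.ndarray
    params: ModelParameters
    cost: float | None = None


def loss(model_profile: GradientProfile, exp_profile: GradientProfile) -> float:
    """Quadratic loss: Σ_j (nDl_model(x_j) − nDl_exp(x_j))².

    The model profile is interpolated linearly onto the experimental
    positions, so data may be nucleus-indexed rather than on the simulation
    grid; the result is invariant to reordering of the data (positions are
    sorted by construction of GradientProfile).
    """
    if len(exp_profile) == 0:
        raise ValueError("experimental profile is empty")
    model_at_data = model_profile.interpolate(exp_profile.positions)
    return float(np.sum((model_at_data - exp_profile.values) ** 2))


def _slice_fractions(genome: np.ndarray, config: GAConfig) -> np.ndarray:
    """Fraction in [0, 1] encoded by each parameter's bit slice (MSB first)."""
    b = config.bits_per_parameter
    bits = genome.reshape(len(PARAMETER_NAMES), b).astype(np.float64)
    weights = 2.0 ** np.arange(b - 1, -1, -1)
    return (bits @ weights) / (2.0**b - 1.0)


def decode(genome: np.ndarray, config: GAConfig) -> ModelParameters:
    """Map a binary genome to model parameters via the configured bounds.

    An all-zero slice decodes to the lower bound, an all-one slice to the
    upper bound; intermediate integers map affinely (in log space for
    log-flagged bounds).
    """
    genome = np.asarray(genome)
    if genome.size != config.genome_length:
        raise ValueError(
            f"genome length {genome.size} != expected {config.genome_length}"
        )
    fracs = _slice_fractions(genome, config)
    values = {}
    for name, frac in zip(PARAMETER_NAMES, fracs):
        bound = config.bounds[name]
        if bound.log:
            values[name] = float(
                np.exp(np.log(bound.lo) + frac * (np.log(bound.hi) - np.log(bound.lo)))
            )
        else:
            values[name] = float(bound.lo + frac * (bound.hi - bound.lo))
    return ModelParameters(**values)


def encode(params: ModelParameters, config: GAConfig) -> np.ndarray:
    """Nearest binary genome for a parameter set (inverse of decode)."""
    b = config.bits_per_parameter
    genome = np.zeros(config.genome_length, dtype=np.uint8)
    for i, name in enumerate(PARAMETER_NAMES):
        bound = config.bounds[name]
        v = getattr(params, name)
        if bound.log:
            frac = (np.log(v) - np.log(bound.lo)) / (np.log(bound.hi) - np.log(bound.lo))
        else:
            frac = (v - bound.lo) / (bound.hi - bound.lo)
        integer = int(round(np.clip(frac, 0, 1) * (2**b - 1)))
        bits = [(integer >> (b - 1 - j)) & 1 for j in range(b)]
        genome[i * b : (i + 1) * b] = bits
    return genome


def _evaluate(
    individual: GAIndividual,
    exp_profile: GradientProfile,
    grid: SpatialGrid,
    solver_config: SolverConfig,
    config: GAConfig,
    cache: dict,
) -> float:
    key = individual.genome.tobytes()
    if key in cache:
        return cache[key]
    try:
        result = integrate_to_steady_state(individual.params, grid, solver_config)
        totals = result.state.totals()
        model_profile = GradientProfile(grid.positions, totals.nDl_total)
        cost = loss(model_profile, exp_profile)
    except Exception:
        cost = config.penalty_cost
    cache[key] = cost
    return cost


def evolve(
    exp_profile: GradientProfile,
    ga_config: GAConfig,
    grid: SpatialGrid | None = None,
    solver_config: SolverConfig | None = None,
) -> tuple[GAIndividual, list[GAIndividual], dict]:
    """Run the Genetic Algorithm against a gradient profile.

    Returns ``(best, final_population, history)``; history holds the
    per-generation best and mean cost (best is non-increasing thanks to
    elitism) and the generations at which epidemic restarts fired.  The run
    is fully determined by ``ga_config.seed``.

    Individuals whose simulation fails to converge receive
    ``ga_config.penalty_cost`` instead of aborting the run.
    """
    grid = grid or SpatialGrid()
    # GA evaluations only consume the steady state, so the fast
    # pseudo-transient route is the default here.
    solver_config = solver_config or SolverConfig(method="pseudo", steady_tol=1e-7)
    rng = np.random.default_rng(ga_config.seed)
    n_pop = ga_config.population_size
    glen = ga_config.genome_length
    cache: dict[bytes, float] = {}

    def fresh(n: int) -> list[GAIndividual]:
        genomes = rng.integers(0, 2, size=(n, glen), dtype=np.uint8)
        return [GAIndividual(g, decode(g, ga_config)) for g in genomes]

    population = fresh(n_pop)
    history: dict = {"best_cost": [], "mean_cost": [], "epidemics": []}
    best: GAIndividual | None = None
    stagnant = 0

    for gen in range(ga_config.generations):
        for ind in population:
            ind.cost = _evaluate(
                ind, exp_profile, grid, solver_config, ga_config, cache
            )
        population.sort(key=lambda ind: ind.cost)
        gen_best = population[0]
        if best is None or gen_best.cost < best.cost:
            best = GAIndividual(gen_best.genome.copy(), gen_best.params, gen_best.cost)
            stagnant = 0
        else:
            stagnant += 1
        history["best_cost"].append(best.cost)
        history["mean_cost"].append(
            float(np.mean([ind.cost for ind in population]))
        )

        if gen == ga_config.generations - 1:
            break

        if (
            ga_config.epidemic_stagnation is not None
            and stagnant >= ga_config.epidemic_stagnation
        ):
            survivors = population[: ga_config.epidemic_survivors]
            population = [
                GAIndividual(s.genome.copy(), s.params, s.cost) for s in survivors
            ] + fresh(n_pop - len(survivors))
            history["epidemics"].append(gen)
            stagnant = 0
            continue

        # k-tournament selection of parents
        costs = np.array([ind.cost for ind in population])
        picks = rng.integers(0, n_pop, size=(n_pop, ga_config.tournament_k))
        winners = picks[np.arange(n_pop), np.argmin(costs[picks], axis=1)]
        parents = [population[w] for w in winners]

        children: list[GAIndividual] = [
            GAIndividual(best.genome.copy(), best.params, best.cost)  # elitism
        ]
        i = 0
        while len(children) < n_pop:
            pa = parents[i % n_pop].genome
            pb = parents[(i + 1) % n_pop].genome
            i += 2
            if rng.random() < ga_config.crossover_rate:
                mask = rng.integers(0, 2, size=glen, dtype=np.uint8)
                ca = np.where(mask, pa, pb)
                cb = np.where(mask, pb, pa)
            else:
                ca, cb = pa.copy(), pb.copy()
            for child_genome in (ca, cb):
                if len(children) >= n_pop:
                    break
                flips = rng.random(glen) < ga_config.effective_mutation_rate
                child_genome = np.where(flips, 1 - child_genome, child_genome).astype(
                    np.uint8
                )
                children.append(
                    GAIndividual(child_genome, decode(child_genome, ga_config))
                )
        population = children

    population.sort(key=lambda ind: ind.cost)
    return best, population, history


def elite_selection(
    population: Sequence[GAIndividual], threshold: float
) -> list[GAIndividual]:
    """Individuals with cost ≤ threshold, sorted ascending by cost."""
    for ind in population:
        if ind.cost is None:
            raise ValueError("all individuals must be evaluated before selection")
    return sorted(
        (ind for ind in population if ind.cost <= threshold),
        key=lambda ind: ind.cost,
    )


def parameter_histograms(
    elite: Sequence[GAIndividual],
    n_bins: int = 10,
    narrow_ratio: float = 0.5,
) -> dict[str, dict]:
    """Per-parameter histograms and spread summaries over an elite set.

    Kinetic constants and diffusivities are binned in log space (mirroring
    how their search bounds are defined); the spread summary reports the
    interquartile range, the median, and a "narrow" flag when
    IQR/median < `narrow_ratio` — the parameters the fit pins down tightly.
    """
    if len(elite) == 0:
        raise ValueError("elite set is empty")
    out: dict[str, dict] = {}
    log_params = {
        n for n in PARAMETER_NAMES if n not in ("Dl_tot", "toll_amp", "toll_sigma")
    }
    for name in PARAMETER_NAMES:
        values = np.array([getattr(ind.params, name) for ind in elite], dtype=float)
        if name in log_params and np.all(values > 0):
            counts, edges = np.histogram(np.log10(values), bins=n_bins)
            edges = 10.0**edges
        else:
            counts, edges = np.histogram(values, bins=n_bins)
        q1, median, q3 = np.percentile(values, [25, 50, 75])
        iqr = q3 - q1
        out[name] = {
            "counts": counts,
            "bin_edges": edges,
            "median": float(median),
            "iqr": float(iqr),
            "narrow": bool(median != 0 and iqr / abs(median) < narrow_ratio),
        }
    return out


# ---------------------------------------------------------------------------
# tabular I/O: experimental-data reader and GA run artifacts


def read_profile_table(path: str | Path) -> GradientProfile:
    """Read a gradient table (CSV or XLSX) with columns position, nDl_mean
    and optionally nDl_sem — the layout of the study's nuclear-quantification
    supplement."""
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path)
    df = df.sort_values("position")
    sem = df["nDl_sem"].to_numpy() if "nDl_sem" in df.columns else None
    return GradientProfile(df["position"].to_numpy(), df["nDl_mean"].to_numpy(), sem)


def write_profile_table(profile: GradientProfile, path: str | Path) -> None:
    """Write a gradient profile as CSV (position, nDl_mean, nDl_sem)."""
    data = {"position": profile.positions, "nDl_mean": profile.values}
    if profile.sem is not None:
        data["nDl_sem"] = profile.sem
    pd.DataFrame(data).to_csv(path, index=False)


def write_elite_table(elite: Sequence[GAIndividual], path: str | Path) -> None:
    """Write an elite set as CSV: one row per individual, 18 parameters + cost."""
    rows = [
        {**ind.params.as_dict(), "cost": ind.cost}
        for ind in elite
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_history(history: dict, path: str | Path) -> None:
    """Write a GA history (per-generation best/mean cost) as JSON."""
    Path(path).write_text(json.dumps(history, indent=2))
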