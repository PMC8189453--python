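"""Configuration and artifact I/O.

Parameter files are flat YAML/JSON key-value maps mirroring the dimensionless
parameter names (k1…k12, D_Dl, D_C, D_DlC, Dl_tot, toll_amp, toll_sigma) plus
structural switches (synthesis_driver, k12_destination, toll_recycling) and
grid/solver keys (n_compartments, rel_tol, abs_tol, steady_tol, t_max,
method).  Scenario files carry name/overrides/multipliers.  CSV is the
canonical exchange format for profiles and species tables; XLSX is accepted
read-only for gradient data (see calibration.read_profile_table).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import (
    PARAMETER_NAMES,
    SPECIES,
    ModelParameters,
    SpatialGrid,
    SpeciesState,
    StructuralOptions,
)
from .scenarios import MutantScenario
from .solver import SolverConfig

__all__ = [
    "load_parameters",
    "dump_parameters",
    "load_scenario",
    "load_solver_config",
    "write_species_table",
    "read_species_table",
    "config_hash",
]

_STRUCTURAL_KEYS = ("synthesis_driver", "k12_destination", "toll_recycling")
_SOLVER_KEYS = tuple(f.name for f in fields(SolverConfig))


def _read_mapping(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    data = (
        json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    )
    if not isinstance(data, dict):
        raise ValueError(f"{path} does not contain a key-value mapping")
    return data


def load_parameters(path: str | Path) -> ModelParameters:
    """Load model parameters (and structural switches) from YAML/JSON.

    Missing parameters keep their wild-type calibrated defaults; unknown keys
    other than grid/solver keys are rejected.
    """
    data = _read_mapping(path)
    values = {k: float(v) for k, v in data.items() if k in PARAMETER_NAMES}
    structural = {k: data[k] for k in _STRUCTURAL_KEYS if k in data}
    known = set(PARAMETER_NAMES) | set(_STRUCTURAL_KEYS) | set(_SOLVER_KEYS)
    known.add("n_compartments")
    unknown = set(data) - known
    if unknown:
        raise KeyError(f"unknown parameter keys {sorted(unknown)}")
    options = StructuralOptions(**structural)
    return ModelParameters(**values, options=options)


def dump_parameters(params: ModelParameters, path: str | Path) -> None:
    """Write a parameter set as flat YAML (values + structural switches)."""
    data = {k: float(v) for k, v in params.as_dict().items()}
    data["synthesis_driver"] = params.options.synthesis_driver
    data["k12_destination"] = params.options.k12_destination
    data["toll_recycling"] = params.options.toll_recycling
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def load_scenario(path: str | Path) -> MutantScenario:
    """Load a mutant scenario (name, overrides, multipliers) from YAML/JSON."""
    data = _read_mapping(path)
    return MutantScenario(
        name=data.get("name", Path(path).stem),
        overrides={k: float(v) for k, v in data.get("overrides", {}).items()},
        multipliers={k: float(v) for k, v in data.get("multipliers", {}).items()},
    )


def load_solver_config(path: str | Path) -> SolverConfig:
    """Build a SolverConfig from the solver keys of a config file."""
    data = _read_mapping(path)
    kwargs = {k: data[k] for k in _SOLVER_KEYS if k in data}
    return SolverConfig(**kwargs)


def load_grid(path: str | Path) -> SpatialGrid:
    data = _read_mapping(path)
    return SpatialGrid(int(data.get("n_compartments", 50)))


def write_species_table(
    state: SpeciesState, grid: SpatialGrid, path: str | Path
) -> None:
    """Write a steady state as CSV: position, nDl_total, then all species."""
    totals = state.totals()
    data: dict = {"position": grid.positions, "nDl_total": totals.nDl_total}
    for name in SPECIES:
        data[name] = state[name]
    pd.DataFrame(data).to_csv(path, index=False)


def read_species_table(path: str | Path) -> tuple[SpeciesState, SpatialGrid]:
    """Read a species CSV back into a state and its grid."""
    df = pd.read_csv(path)
    grid = SpatialGrid(len(df))
    arr = np.vstack([df[name].to_numpy() for name in SPECIES])
    return SpeciesState(arr), grid


def config_hash(*objects) -> str:
    """Short deterministic hash of configuration objects, for artifact
    provenance lines."""
    text = json.dumps(
        [repr(o) for o in objects], sort_keys=True, default=str
    ).encode()
    return hashlib.sha256(text).hexdigest()[:12]
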