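"""Synthetic nuclear-Dorsal gradient datasets.

Emulates the statistical structure of embryo quantifications — ~50 positions
along the ventral→dorsal half axis, a decreasing Gaussian-plus-basal mean
shape, and mean ± s.e.m. over replicate embryos — so calibration and every
analysis stage are testable without the study's measurement data.

Two generators are provided: ``generate_model_based`` simulates a steady
state from known "truth" parameters and adds measurement noise (the setting
for parameter-recovery experiments), while ``generate_phenomenological``
draws from a closed-form Gaussian-plus-basal shape (a stand-in for gradient
data when no mechanistic truth is wanted).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import ModelParameters, SpatialGrid
from .profiles import GradientProfile
from .solver import SolverConfig, integrate_to_steady_state

__all__ = [
    "SyntheticConfig",
    "generate_model_based",
    "generate_phenomenological",
    "normalize_to_control",
]


@dataclass
class SyntheticConfig:
    """Settings for synthetic gradient generation.

    noise_sd is the per-measurement (per nucleus, per embryo) additive
    Gaussian standard deviation in dimensionless nDl units; the default 0.05
    corresponds to ~5% of the ventral wild-type level, which puts the
    residual of a perfect model in the band the study's fits occupy.  A
    heteroscedastic option (sd proportional to the mean) is available but
    off by default.  ``jitter_positions`` perturbs the sampling positions to
    emulate nucleus-indexed (non-uniform) data.
    """

    n_positions: int = 50
    n_embryos: int = 10
    noise_sd: float = 0.05
    heteroscedastic: bool = False
    jitter_positions: bool = False
    seed: int = 0
    truth: ModelParameters = field(default_factory=ModelParameters)

    def __post_init__(self) -> None:
        if self.n_positions < 3:
            raise ValueError("n_positions must be >= 3")
        if self.n_embryos < 1:
            raise ValueError("n_embryos must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _positions(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    grid = SpatialGrid(config.n_positions)
    x = grid.positions
    if config.jitter_positions:
        # nucleus-indexed sampling: independent jitter within 1/4 compartment
        x = np.sort(x + rng.uniform(-0.25, 0.25, size=x.size) * grid.dx)
        x = np.clip(x, 0.0, 1.0)
    return x


def _noisy_profile(
    positions: np.ndarray,
    mean: np.ndarray,
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> GradientProfile:
    sd = config.noise_sd * (np.abs(mean) if config.heteroscedastic else 1.0)
    replicates = mean + sd * rng.standard_normal((config.n_embryos, mean.size))
    obs_mean = replicates.mean(axis=0)
    if config.n_embryos > 1:
        sem = replicates.std(axis=0, ddof=1) / np.sqrt(config.n_embryos)
    else:
        sem = np.zeros_like(obs_mean)
    return GradientProfile(positions, obs_mean, sem)


def generate_model_based(
    config: SyntheticConfig,
    grid: SpatialGrid | None = None,
    solver_config: SolverConfig | None = None,
) -> tuple[GradientProfile, dict]:
    """Simulate a steady-state nDl profile from truth parameters + noise.

    Returns the noisy mean ± s.e.m. profile and a truth record carrying the
    generating parameters and the noise-free profile.  Fully reproducible
    from ``config.seed``; with ``noise_sd = 0`` the mean equals the simulated
    profile exactly and all s.e.m. values are zero.
    """
    grid = grid or SpatialGrid(config.n_positions)
    solver_config = solver_config or SolverConfig(method="pseudo")
    rng = np.random.default_rng(config.seed)
    result = integrate_to_steady_state(config.truth, grid, solver_config)
    clean = result.state.totals().nDl_total
    positions = _positions(config, rng)
    mean = np.interp(positions, grid.positions, clean)
    if config.noise_sd == 0:
        profile = GradientProfile(
            positions, mean, np.zeros_like(mean)
        )
    else:
        profile = _noisy_profile(positions, mean, config, rng)
    truth_record = {
        "params": config.truth,
        "clean_profile": GradientProfile(positions, mean),
        "noise_sd": config.noise_sd,
        "n_embryos": config.n_embryos,
        "seed": config.seed,
    }
    return profile, truth_record


def generate_phenomenological(
    config: SyntheticConfig,
    amplitude: float = 0.9,
    basal: float = 0.1,
    width: float = 0.2,
    normalize: bool = False,
) -> GradientProfile:
    """Gaussian-plus-basal synthetic gradient (no mechanistic truth).

    mean(x) = basal + amplitude·exp(−x²/(2·width²)), plus seeded replicate
    noise; with ``normalize=True`` the profile is rescaled so the
    ventral-most mean is exactly 1.
    """
    if amplitude < 0 or basal < 0 or width <= 0:
        raise ValueError("amplitude and basal must be >= 0, width > 0")
    rng = np.random.default_rng(config.seed)
    positions = _positions(config, rng)
    mean = basal + amplitude * np.exp(-(positions**2) / (2.0 * width**2))
    if config.noise_sd == 0:
        profile = GradientProfile(positions, mean, np.zeros_like(mean))
    else:
        profile = _noisy_profile(positions, mean, config, rng)
    if normalize:
        profile = profile.normalized()
    return profile


def normalize_to_control(
    profiles: dict[str, GradientProfile], control: str
) -> dict[str, GradientProfile]:
    """Normalize a set of co-processed profiles by the control's ventral value.

    Every profile (mutant and control alike) is divided by the control's
    ventral-most mean, mirroring how mutant embryos are quantified alongside
    a co-stained control; the control's ventral value becomes exactly 1 and
    the operation is idempotent.
    """
    if control not in profiles:
        raise KeyError(f"control profile {control!r} not in the set")
    factor = profiles[control].ventral_value
    if factor == 0:
        raise ZeroDivisionError("control ventral value is zero")
    return {name: p.normalized(factor) for name, p in profiles.items()}
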