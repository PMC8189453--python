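"""Nuclear-Dorsal gradient profiles and their summary metrics.

A :class:`GradientProfile` holds nDl values (optionally with per-position
standard errors) on the ventral→dorsal half axis, the form in which both
experimental quantifications and simulated steady states are compared.
Values are conventionally normalized so the control ventral-most level is 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GradientProfile", "GradientMetrics", "gradient_metrics"]


@dataclass
class GradientProfile:
    """nDl values along the ventral→dorsal half axis.

    positions are fractions of the half axis in [0, 1], strictly increasing;
    sem, when present, gives the standard error of the mean at each position.
    """

    positions: np.ndarray
    values: np.ndarray
    sem: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.positions.ndim != 1 or self.positions.shape != self.values.shape:
            raise ValueError("positions and values must be matching 1-D arrays")
        if self.positions.size and (
            self.positions.min() < 0 or self.positions.max() > 1
        ):
            raise ValueError("positions must lie in [0, 1]")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.sem is not None:
            self.sem = np.asarray(self.sem, dtype=float)
            if self.sem.shape != self.values.shape:
                raise ValueError("sem must match values in shape")
            if np.any(self.sem < 0):
                raise ValueError("sem must be non-negative")

    def __len__(self) -> int:
        return self.positions.size

    @property
    def ventral_value(self) -> float:
        """nDl at the ventral-most measured position."""
        return float(self.values[0])

    def interpolate(self, positions: np.ndarray) -> np.ndarray:
        """Linear interpolation of the profile onto new positions."""
        return np.interp(positions, self.positions, self.values)

    def normalized(self, factor: float | None = None) -> "GradientProfile":
        """Profile divided by `factor` (default: its own ventral value)."""
        factor = self.ventral_value if factor is None else factor
        if factor == 0:
            raise ZeroDivisionError("cannot normalize by a zero ventral value")
        return GradientProfile(
            self.positions.copy(),
            self.values / factor,
            None if self.sem is None else self.sem / factor,
        )


@dataclass(frozen=True)
class GradientMetrics:
    """Peak, basal, amplitude and slope summary of one gradient profile."""

    peak: float
    basal: float
    amplitude: float
    max_slope: float
    slope_profile: np.ndarray


def gradient_metrics(profile: GradientProfile) -> GradientMetrics:
    """Summary metrics of a gradient: peak/basal levels, amplitude, slope.

    The derivative is taken by central differences (one-sided at the ends);
    ``max_slope`` is the maximum of |d nDl/dx|, the quantity that measures
    how sharply neighbouring nuclei differ and hence how precisely target
    gene-expression borders can be positioned.
    """
    if len(profile) < 3:
        raise ValueError("gradient metrics need at least 3 positions")
    deriv = np.gradient(profile.values, profile.positions)
    peak = float(profile.values[0])
    basal = float(profile.values[-1])
    return GradientMetrics(
        peak=peak,
        basal=basal,
        amplitude=peak - basal,
        max_slope=float(np.max(np.abs(deriv))),
        slope_profile=deriv,
    )
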