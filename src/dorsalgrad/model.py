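"""Core reaction-diffusion network for Dorsal/Cactus/Toll signalling.

The model describes nuclear Dorsal (Dl, an NFκB/c-Rel transcription factor)
gradient formation in the syncytial *Drosophila* blastoderm on a 1-D
compartmental domain covering the ventral→dorsal half of a transverse embryo
section (position 0 = ventral midline, 1 = dorsal midline; no-flux at both
midlines encodes embryo symmetry).

Nine species are tracked per compartment:

========  =====================================================
cDl0      free cytoplasmic Dl dimer
nDl0      nuclear Dl entered by Toll-independent direct flow
Cf        free Cactus (IκB homolog)
DlC       trimeric 2Dl–Cactus complex
T         free activated Toll receptor
DlCT      Toll-bound signalling complex (DlC recruited by T)
Cub       phosphorylated/ubiquitinated Cactus (proteasome substrate)
cDlstar   Toll-phosphorylated cytoplasmic Dl dimer
nDlstar   nuclear Dl entered via the Toll-activated route
========  =====================================================

Dl is bookkept purely as dimers; DlC and DlCT each carry exactly one Dl dimer
and one Cactus unit.  All reactions follow mass-action kinetics:

  R1   ∅ → Cf           rate k1·cDl0   (Dl-dependent Cactus synthesis)
  R2   Cf → ∅           rate k2        (Toll-independent Cactus turnover)
  R3/4 cDl0 ⇌ nDl0      k3 / k4        (direct nuclear flow)
  R5/6 cDl0 + Cf ⇌ DlC  k5 / k6
  R7/8 DlC + T ⇌ DlCT   k7 / k8
  R9   DlCT → cDlstar + Cub + T   k9   (Toll-triggered dissociation)
  R10  Cub → ∅          k10            (proteasomal Cactus degradation)
  R11  cDlstar → nDlstar  k11          (Toll-route nuclear import)
  R12  nDlstar → cDl0     k12          (nuclear export)

cDl0, Cf and DlC diffuse along the axis (Fick's law); the remaining species
do not.  Three structural choices are not pinned down by the reaction scheme
alone and are exposed as switches on :class:`StructuralOptions`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Iterator

import numpy as np

__all__ = [
    "SPECIES",
    "DIFFUSING_SPECIES",
    "ModelParameters",
    "StructuralOptions",
    "SpatialGrid",
    "SpeciesState",
    "DerivedTotals",
    "toll_init_profile",
    "reaction_rates",
    "rhs",
    "initial_state",
    "reaction_jacobian",
]

#: Species names in canonical storage order.
SPECIES = ("cDl0", "nDl0", "Cf", "DlC", "T", "DlCT", "Cub", "cDlstar", "nDlstar")

#: Species transported along the axis, mapped to their diffusivity field.
DIFFUSING_SPECIES = {"cDl0": "D_Dl", "Cf": "D_C", "DlC": "D_DlC"}

#: Species that carry one Dl dimer each (conserved total).
DL_SPECIES = ("cDl0", "nDl0", "DlC", "DlCT", "cDlstar", "nDlstar")

#: Species that carry one Cactus unit each.
CACTUS_SPECIES = ("Cf", "Cub", "DlC", "DlCT")


class InvalidParameterError(ValueError):
    """A model parameter violates its physical constraints."""


@dataclass
class StructuralOptions:
    """Switches for the three reconstruction points of the reaction scheme.

    synthesis_driver
        Which Dl pool modulates Cactus synthesis (R1): ``"cDl0"`` (free
        cytoplasmic dimer, default) or ``"cytoplasmic_total"``
        (cDl0 + cDlstar + DlC + DlCT).
    k12_destination
        Where nuclear export (R12) deposits the Dl dimer: ``"cDl0"``
        (default; the exported dimer rejoins the free cytoplasmic pool) or
        ``"cDlstar"``.
    toll_recycling
        If True (default) R9 returns the Toll receptor to the free activated
        pool, conserving Toll per compartment; if False, Toll is consumed.
    """

    synthesis_driver: str = "cDl0"
    k12_destination: str = "cDl0"
    toll_recycling: bool = True

    def __post_init__(self) -> None:
        if self.synthesis_driver not in ("cDl0", "cytoplasmic_total"):
            raise InvalidParameterError(
                f"unknown synthesis_driver {self.synthesis_driver!r}"
            )
        if self.k12_destination not in ("cDl0", "cDlstar"):
            raise InvalidParameterError(
                f"unknown k12_destination {self.k12_destination!r}"
            )


# Calibrated dimensionless wild-type parameter values.  Concentrations are in
# units of the ventral-most wild-type nuclear-Dl level, lengths in half-embryo
# lengths, times in the model's characteristic time.
_WT_DEFAULTS = {
    "k1": 0.584, "k2": 0.0610, "k3": 0.0043, "k4": 0.0022,
    "k5": 877.0, "k6": 7510.0, "k7": 0.113, "k8": 0.0023,
    "k9": 0.0036, "k10": 427.0, "k11": 1.20, "k12": 0.0022,
    "D_Dl": 91.0, "D_C": 415.0, "D_DlC": 3.39e-5,
    "Dl_tot": 0.525, "toll_amp": 8.54, "toll_sigma": 0.1995,
}

#: Canonical parameter order used by configuration files and the GA genome.
PARAMETER_NAMES = tuple(_WT_DEFAULTS)


@dataclass
class ModelParameters:
    """The 18 dimensionless model parameters (wild-type calibrated defaults).

    k1–k12 are kinetic constants per characteristic time (k5, k7
    bimolecular); D_Dl, D_C, D_DlC are diffusivities in half-embryo-length²
    per characteristic time; Dl_tot is the uniform initial cytoplasmic
    Dl-dimer concentration; toll_amp and toll_sigma set the Gaussian
    activated-Toll profile (peak value and standard deviation in half-axis
    units).
    """

    k1: float = _WT_DEFAULTS["k1"]
    k2: float = _WT_DEFAULTS["k2"]
    k3: float = _WT_DEFAULTS["k3"]
    k4: float = _WT_DEFAULTS["k4"]
    k5: float = _WT_DEFAULTS["k5"]
    k6: float = _WT_DEFAULTS["k6"]
    k7: float = _WT_DEFAULTS["k7"]
    k8: float = _WT_DEFAULTS["k8"]
    k9: float = _WT_DEFAULTS["k9"]
    k10: float = _WT_DEFAULTS["k10"]
    k11: float = _WT_DEFAULTS["k11"]
    k12: float = _WT_DEFAULTS["k12"]
    D_Dl: float = _WT_DEFAULTS["D_Dl"]
    D_C: float = _WT_DEFAULTS["D_C"]
    D_DlC: float = _WT_DEFAULTS["D_DlC"]
    Dl_tot: float = _WT_DEFAULTS["Dl_tot"]
    toll_amp: float = _WT_DEFAULTS["toll_amp"]
    toll_sigma: float = _WT_DEFAULTS["toll_sigma"]
    options: StructuralOptions = field(default_factory=StructuralOptions)

    def __post_init__(self) -> None:
        import warnings

        for f in fields(self):
            if f.name in ("options",):
                continue
            v = getattr(self, f.name)
            # toll_sigma must be strictly positive (a zero-width profile is
            # ill-defined); rates, diffusivities and concentrations may be
            # zero — perturbation sweeps use k9 = k10 = 0 and toll_amp = 0.
            if f.name == "toll_sigma":
                if v <= 0:
                    raise InvalidParameterError(f"toll_sigma must be > 0, got {v}")
            elif v < 0:
                raise InvalidParameterError(f"{f.name} must be >= 0, got {v}")
        if self.toll_sigma > 1:
            warnings.warn(
                "toll_sigma > 1 half-axis unit: the Toll profile is nearly "
                "flat over the domain", stacklevel=2,
            )

    def replace(self, **changes: float) -> "ModelParameters":
        """Return a copy with the given fields changed."""
        return replace(self, **changes)

    def as_dict(self) -> dict:
        """Parameter values in canonical order (structural options excluded)."""
        return {name: getattr(self, name) for name in PARAMETER_NAMES}


@dataclass(frozen=True)
class SpatialGrid:
    """Uniform compartmental grid on the ventral→dorsal half axis [0, 1]."""

    n_compartments: int = 50

    def __post_init__(self) -> None:
        if self.n_compartments < 1:
            raise InvalidParameterError("n_compartments must be >= 1")

    @property
    def dx(self) -> float:
        return 1.0 / self.n_compartments

    @property
    def positions(self) -> np.ndarray:
        """Compartment centers; position 0 is the ventral midline side."""
        return (np.arange(self.n_compartments) + 0.5) * self.dx


class SpeciesState:
    """Per-compartment concentrations of the nine model species.

    Backed by a (9, n) array in canonical species order; species are also
    available as attributes (``state.cDl0`` etc.).
    """

    __slots__ = ("array",)

    def __init__(self, array: np.ndarray):
        array = np.asarray(array, dtype=float)
        if array.ndim != 2 or array.shape[0] != len(SPECIES):
            raise ValueError(
                f"expected a ({len(SPECIES)}, n) array, got shape {array.shape}"
            )
        self.array = array

    @classmethod
    def zeros(cls, n_compartments: int) -> "SpeciesState":
        return cls(np.zeros((len(SPECIES), n_compartments)))

    @classmethod
    def from_vector(cls, vec: np.ndarray, n_compartments: int) -> "SpeciesState":
        return cls(np.asarray(vec, dtype=float).reshape(len(SPECIES), n_compartments))

    def to_vector(self) -> np.ndarray:
        return self.array.ravel()

    @property
    def n_compartments(self) -> int:
        return self.array.shape[1]

    def __getattr__(self, name: str) -> np.ndarray:
        try:
            return self.array[SPECIES.index(name)]
        except ValueError:
            raise AttributeError(name) from None

    def __getitem__(self, name: str) -> np.ndarray:
        return self.array[SPECIES.index(name)]

    def copy(self) -> "SpeciesState":
        return SpeciesState(self.array.copy())

    def species(self) -> Iterator[str]:
        return iter(SPECIES)

    def totals(self) -> "DerivedTotals":
        return DerivedTotals.from_state(self)


@dataclass(frozen=True)
class DerivedTotals:
    """Observable aggregates over the species state.

    nDl_total is the quantity measured in fixed embryos (immunostaining does
    not distinguish the two nuclear entry routes); C_total sums every
    Cactus-containing species; Dl_grand_total is the (conserved) domain-wide
    Dl-dimer count.
    """

    nDl_total: np.ndarray
    cDl_total: np.ndarray
    C_total: np.ndarray
    Dl_grand_total: float

    @classmethod
    def from_state(cls, state: SpeciesState) -> "DerivedTotals":
        nDl = state.nDl0 + state.nDlstar
        cDl = state.cDl0 + state.cDlstar + state.DlC + state.DlCT
        C = state.Cf + state.Cub + state.DlC + state.DlCT
        return cls(
            nDl_total=nDl,
            cDl_total=cDl,
            C_total=C,
            Dl_grand_total=float(np.sum(cDl + nDl)),
        )


def toll_init_profile(
    grid: SpatialGrid, toll_amp: float, toll_sigma: float
) -> np.ndarray:
    """Gaussian activated-Toll profile, peaked at the ventral midline.

    T_init(x) = toll_amp · exp(−x² / (2·toll_sigma²)) at compartment centers.
    The mean is pinned at x = 0 (ventral midline) and the amplitude, not the
    area, is the fitted quantity.
    """
    if toll_sigma <= 0:
        raise InvalidParameterError(f"toll_sigma must be > 0, got {toll_sigma}")
    if toll_amp < 0:
        raise InvalidParameterError(f"toll_amp must be >= 0, got {toll_amp}")
    x = grid.positions
    return toll_amp * np.exp(-(x**2) / (2.0 * toll_sigma**2))


def initial_state(params: ModelParameters, grid: SpatialGrid) -> SpeciesState:
    """Initial condition: uniform cDl0 = Dl_tot, Gaussian Toll, all else zero."""
    state = SpeciesState.zeros(grid.n_compartments)
    state.array[SPECIES.index("cDl0")] = params.Dl_tot
    state.array[SPECIES.index("T")] = toll_init_profile(
        grid, params.toll_amp, params.toll_sigma
    )
    return state


def _synthesis_driver(a: np.ndarray, params: ModelParameters) -> np.ndarray:
    """The Dl pool modulating Cactus synthesis; `a` is the (9, n) array."""
    idx = SPECIES.index
    if params.options.synthesis_driver == "cDl0":
        return a[idx("cDl0")]
    return a[idx("cDl0")] + a[idx("cDlstar")] + a[idx("DlC")] + a[idx("DlCT")]


def reaction_rates(state: SpeciesState, params: ModelParameters) -> SpeciesState:
    """Mass-action net production rate of every species, per compartment.

    Works on any number of compartments (each is well-mixed; no transport
    terms here).  Negative concentrations are rejected: mass-action rates are
    only meaningful on the non-negative orthant.
    """
    a = state.array
    if np.any(a < 0):
        raise ValueError("negative concentration passed to reaction_rates")
    return SpeciesState(_reaction_rates_array(a, params))


def _reaction_rates_array(a: np.ndarray, params: ModelParameters) -> np.ndarray:
    p = params
    idx = SPECIES.index
    cDl0, nDl0, Cf = a[idx("cDl0")], a[idx("nDl0")], a[idx("Cf")]
    DlC, T, DlCT = a[idx("DlC")], a[idx("T")], a[idx("DlCT")]
    Cub, cDlstar, nDlstar = a[idx("Cub")], a[idx("cDlstar")], a[idx("nDlstar")]

    v1 = p.k1 * _synthesis_driver(a, p)
    v2 = p.k2 * Cf
    v3 = p.k3 * cDl0
    v4 = p.k4 * nDl0
    v5 = p.k5 * cDl0 * Cf
    v6 = p.k6 * DlC
    v7 = p.k7 * DlC * T
    v8 = p.k8 * DlCT
    v9 = p.k9 * DlCT
    v10 = p.k10 * Cub
    v11 = p.k11 * cDlstar
    v12 = p.k12 * nDlstar

    out = np.zeros_like(a)
    out[idx("cDl0")] = -v3 + v4 - v5 + v6
    out[idx("nDl0")] = v3 - v4
    out[idx("Cf")] = v1 - v2 - v5 + v6
    out[idx("DlC")] = v5 - v6 - v7 + v8
    out[idx("T")] = -v7 + v8
    out[idx("DlCT")] = v7 - v8 - v9
    out[idx("Cub")] = v9 - v10
    out[idx("cDlstar")] = v9 - v11
    out[idx("nDlstar")] = v11 - v12
    if p.options.k12_destination == "cDl0":
        out[idx("cDl0")] += v12
    else:
        out[idx("cDlstar")] += v12
    if p.options.toll_recycling:
        out[idx("T")] += v9
    return out


def rhs(
    state: SpeciesState, params: ModelParameters, grid: SpatialGrid
) -> SpeciesState:
    """Full time-derivative: reactions plus Fickian diffusion.

    Only cDl0, Cf and DlC carry diffusion terms; the no-flux boundaries at
    both midlines make each diffusing species' transport conservative.
    """
    from .solver import laplacian_noflux

    if state.n_compartments != grid.n_compartments:
        raise ValueError(
            f"state has {state.n_compartments} compartments, "
            f"grid has {grid.n_compartments}"
        )
    out = _reaction_rates_array(state.array, params)
    if grid.n_compartments > 1:
        for name, d_field in DIFFUSING_SPECIES.items():
            i = SPECIES.index(name)
            out[i] += getattr(params, d_field) * laplacian_noflux(
                state.array[i], grid.dx
            )
    return SpeciesState(out)


def reaction_jacobian(a: np.ndarray, params: ModelParameters) -> np.ndarray:
    """Per-compartment 9×9 Jacobian blocks of the reaction terms.

    Returns an array of shape (n, 9, 9) with J[c, i, j] = ∂(d species_i/dt) /
    ∂ species_j in compartment c.  Used to assemble the sparse system
    Jacobian for implicit integration.
    """
    p = params
    idx = SPECIES.index
    n = a.shape[1]
    i_a, i_n0, i_c = idx("cDl0"), idx("nDl0"), idx("Cf")
    i_dc, i_t, i_dct = idx("DlC"), idx("T"), idx("DlCT")
    i_u, i_as, i_ns = idx("Cub"), idx("cDlstar"), idx("nDlstar")
    cDl0, Cf, DlC, T = a[i_a], a[i_c], a[i_dc], a[i_t]

    J = np.zeros((n, len(SPECIES), len(SPECIES)))

    # d cDl0/dt
    J[:, i_a, i_a] = -p.k3 - p.k5 * Cf
    J[:, i_a, i_n0] = p.k4
    J[:, i_a, i_c] = -p.k5 * cDl0
    J[:, i_a, i_dc] = p.k6
    # d nDl0/dt
    J[:, i_n0, i_a] = p.k3
    J[:, i_n0, i_n0] = -p.k4
    # d Cf/dt
    J[:, i_c, i_a] = p.k1 - p.k5 * Cf
    J[:, i_c, i_c] = -p.k2 - p.k5 * cDl0
    J[:, i_c, i_dc] = p.k6
    if p.options.synthesis_driver == "cytoplasmic_total":
        J[:, i_c, i_dc] += p.k1
        J[:, i_c, i_dct] = p.k1
        J[:, i_c, i_as] = p.k1
    # d DlC/dt
    J[:, i_dc, i_a] = p.k5 * Cf
    J[:, i_dc, i_c] = p.k5 * cDl0
    J[:, i_dc, i_dc] = -p.k6 - p.k7 * T
    J[:, i_dc, i_t] = -p.k7 * DlC
    J[:, i_dc, i_dct] = p.k8
    # d T/dt
    J[:, i_t, i_dc] = -p.k7 * T
    J[:, i_t, i_t] = -p.k7 * DlC
    J[:, i_t, i_dct] = p.k8 + (p.k9 if p.options.toll_recycling else 0.0)
    # d DlCT/dt
    J[:, i_dct, i_dc] = p.k7 * T
    J[:, i_dct, i_t] = p.k7 * DlC
    J[:, i_dct, i_dct] = -p.k8 - p.k9
    # d Cub/dt
    J[:, i_u, i_dct] = p.k9
    J[:, i_u, i_u] = -p.k10
    # d cDlstar/dt
    J[:, i_as, i_dct] = p.k9
    J[:, i_as, i_as] = -p.k11
    # d nDlstar/dt
    J[:, i_ns, i_as] = p.k11
    J[:, i_ns, i_ns] = -p.k12
    if p.options.k12_destination == "cDl0":
        J[:, i_a, i_ns] = p.k12
    else:
        J[:, i_as, i_ns] = p.k12
    return J
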