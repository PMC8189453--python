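"""Steady-state integration of the compartmental reaction-diffusion system.

Two routes to the steady state are provided and cross-checked against each
other (and, for a single compartment, against an algebraic root-finding
oracle):

``method="bdf"``
    scipy's variable-order implicit multistep (BDF) integrator, run in
    geometrically growing time chunks until the residual test passes.  This
    is the reference route; only the steady state is consumed downstream, so
    the particular stiff multistep formula is immaterial (and tested to be).
``method="pseudo"``
    Damped pseudo-transient continuation: implicit-Euler steps with an
    adaptively growing time step, each solved by a modified-Newton linear
    solve.  Orders of magnitude faster; used for Genetic-Algorithm
    evaluations where thousands of steady states are needed.

The steady-state criterion is residual based: the max-norm of the full
right-hand side must drop below ``steady_tol × max(1, max-norm of state)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.integrate import solve_ivp
from scipy.optimize import root
from scipy.sparse.linalg import splu

from .model import (
    DIFFUSING_SPECIES,
    SPECIES,
    ModelParameters,
    SpatialGrid,
    SpeciesState,
    _reaction_rates_array,
    initial_state,
    reaction_jacobian,
)

__all__ = [
    "SolverConfig",
    "SteadyStateResult",
    "NonConvergenceError",
    "laplacian_noflux",
    "integrate_to_steady_state",
    "single_compartment_steady_state",
]

#: Concentrations more negative than this abort the run; smaller undershoots
#: are clipped to zero (implicit solvers overshoot the orthant boundary by
#: amounts on the order of their tolerance).
_NEGATIVE_GUARD = -1e-12

#: Hard cap on pseudo-transient iterations (rejections included).
_PSEUDO_MAX_STEPS = 5000


class NonConvergenceError(RuntimeError):
    """Raised when the steady-state criterion is not met within t_max."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


@dataclass
class SolverConfig:
    """Integration and steady-state detection settings.

    steady_tol is relative to max(1, max-norm of the state); t_max must
    comfortably exceed the slowest relaxation time (the nuclear-export
    constants k4 = k12 = 0.0022 set a ~10³ characteristic-time scale).
    """

    rel_tol: float = 1e-8
    abs_tol: float = 1e-10
    steady_tol: float = 1e-9
    t_max: float = 1e6
    check_interval: float = 50.0
    method: str = "bdf"

    def __post_init__(self) -> None:
        if min(self.rel_tol, self.abs_tol, self.steady_tol) <= 0:
            raise ValueError("tolerances must be positive")
        if self.t_max <= self.check_interval:
            raise ValueError("t_max must exceed check_interval")


@dataclass
class SteadyStateResult:
    """A converged steady state plus its convergence report."""

    state: SpeciesState
    t_final: float
    residual: float
    n_rhs_evals: int
    method: str

    @property
    def converged(self) -> bool:
        return True


def laplacian_noflux(field: np.ndarray, dx: float) -> np.ndarray:
    """Second-order central Laplacian with reflective (no-flux) boundaries.

    Ghost values f[-1] = f[0] and f[n] = f[n-1] implement zero diffusive
    flux through both domain ends, so the discrete operator conserves the
    field's sum exactly.
    """
    field = np.asarray(field, dtype=float)
    if field.ndim != 1 or field.size < 2:
        raise ValueError("laplacian_noflux needs a 1-D field of length >= 2")
    out = np.empty_like(field)
    out[1:-1] = field[:-2] - 2.0 * field[1:-1] + field[2:]
    out[0] = field[1] - field[0]
    out[-1] = field[-2] - field[-1]
    return out / dx**2


def _diffusion_matrix(params: ModelParameters, grid: SpatialGrid) -> sp.csr_matrix:
    """Sparse diffusion operator on the flattened (species-major) state."""
    n = grid.n_compartments
    n_sp = len(SPECIES)
    blocks: list[sp.spmatrix] = []
    if n > 1:
        lap = sp.diags(
            [np.ones(n - 1), -2.0 * np.ones(n), np.ones(n - 1)], [-1, 0, 1],
            format="lil",
        )
        lap[0, 0] = -1.0
        lap[n - 1, n - 1] = -1.0
        lap = (lap / grid.dx**2).tocsr()
    for name in SPECIES:
        if n > 1 and name in DIFFUSING_SPECIES:
            D = getattr(params, DIFFUSING_SPECIES[name])
            blocks.append(D * lap)
        else:
            blocks.append(sp.csr_matrix((n, n)))
    return sp.block_diag(blocks, format="csr")


def _rhs_flat(
    y: np.ndarray, params: ModelParameters, grid: SpatialGrid, diff: sp.csr_matrix
) -> np.ndarray:
    a = y.reshape(len(SPECIES), grid.n_compartments)
    out = _reaction_rates_array(a, params).ravel()
    out += diff @ y
    return out


def _jac_flat(
    y: np.ndarray, params: ModelParameters, grid: SpatialGrid, diff: sp.csr_matrix
) -> sp.csr_matrix:
    """Sparse Jacobian of the flattened system (reactions + diffusion)."""
    n = grid.n_compartments
    n_sp = len(SPECIES)
    a = y.reshape(n_sp, n)
    blocks = reaction_jacobian(a, params)  # (n, 9, 9)
    # entry (i_sp*n + c, j_sp*n + c) = blocks[c, i_sp, j_sp]
    i_sp, j_sp = np.meshgrid(np.arange(n_sp), np.arange(n_sp), indexing="ij")
    comp = np.arange(n)
    rows = (i_sp.reshape(1, n_sp, n_sp) * n + comp[:, None, None]).ravel()
    cols = (j_sp.reshape(1, n_sp, n_sp) * n + comp[:, None, None]).ravel()
    J = sp.coo_matrix(
        (blocks.ravel(), (rows, cols)), shape=(n_sp * n, n_sp * n)
    ).tocsr()
    return J + diff


def _check_state(y: np.ndarray) -> np.ndarray:
    worst = y.min()
    if worst < _NEGATIVE_GUARD:
        raise NonConvergenceError(
            f"state left the non-negative orthant (min concentration {worst:.3e})"
        )
    return np.clip(y, 0.0, None)


def _residual(y: np.ndarray, f: np.ndarray) -> float:
    return float(np.max(np.abs(f)) / max(1.0, np.max(np.abs(y))))


def integrate_to_steady_state(
    params: ModelParameters,
    grid: SpatialGrid,
    config: SolverConfig | None = None,
    y0: np.ndarray | None = None,
) -> SteadyStateResult:
    """Integrate from the uniform-cDl0 initial condition to steady state.

    Parameters
    ----------
    params, grid
        Model parameters and compartmental grid.
    config
        Solver settings; ``config.method`` selects the integration route
        ("bdf" or "pseudo").
    y0
        Optional flattened initial state overriding the standard initial
        condition (used by warm-started sweeps).

    Raises
    ------
    NonConvergenceError
        If the residual criterion is not met by ``t_max``.
    """
    config = config or SolverConfig()
    if y0 is None:
        y0 = initial_state(params, grid).to_vector()
    diff = _diffusion_matrix(params, grid)
    if config.method == "pseudo":
        return _pseudo_transient(y0, params, grid, config, diff)
    if config.method != "bdf":
        raise ValueError(f"unknown solver method {config.method!r}")
    return _bdf_chunked(y0, params, grid, config, diff)


def _bdf_chunked(y0, params, grid, config, diff) -> SteadyStateResult:
    n_evals = 0
    t = 0.0
    y = np.asarray(y0, dtype=float)
    t_next = config.check_interval
    while t < config.t_max:
        t_next = min(t_next, config.t_max)
        sol = solve_ivp(
            lambda tt, yy: _rhs_flat(yy, params, grid, diff),
            (t, t_next),
            y,
            method="BDF",
            jac=lambda tt, yy: _jac_flat(yy, params, grid, diff),
            rtol=config.rel_tol,
            atol=config.abs_tol,
        )
        if not sol.success:  # pragma: no cover - scipy failure path
            raise NonConvergenceError(f"BDF integration failed: {sol.message}")
        n_evals += sol.nfev
        y = _check_state(sol.y[:, -1])
        t = t_next
        f = _rhs_flat(y, params, grid, diff)
        res = _residual(y, f)
        if res <= config.steady_tol:
            return SteadyStateResult(
                SpeciesState.from_vector(y, grid.n_compartments),
                t, res, n_evals, "bdf",
            )
        t_next = t * 4.0
    raise NonConvergenceError(
        f"no steady state by t_max={config.t_max:g} (residual {res:.3e})",
        residual=res,
    )


class _SystemPattern:
    """Precomputed sparsity pattern for (I/dt − J) on one grid.

    The matrix is assembled once per step as a single COO→CSC conversion
    from three static index blocks: dense 9×9 reaction blocks per
    compartment, tridiagonal diffusion entries for the three transported
    species, and the pseudo-time identity diagonal.
    """

    def __init__(self, params: ModelParameters, grid: SpatialGrid):
        n = grid.n_compartments
        n_sp = len(SPECIES)
        size = n_sp * n
        comp = np.arange(n)
        i_sp, j_sp = np.meshgrid(np.arange(n_sp), np.arange(n_sp), indexing="ij")
        r_rows = (i_sp.reshape(1, n_sp, n_sp) * n + comp[:, None, None]).ravel()
        r_cols = (j_sp.reshape(1, n_sp, n_sp) * n + comp[:, None, None]).ravel()

        d_rows, d_cols, d_data = [], [], []
        if n > 1:
            for name, d_field in DIFFUSING_SPECIES.items():
                D = getattr(params, d_field) / grid.dx**2
                off = SPECIES.index(name) * n
                diag = np.full(n, -2.0 * D)
                diag[0] = diag[-1] = -D
                d_rows.append(off + comp)
                d_cols.append(off + comp)
                d_data.append(diag)
                d_rows.append(off + comp[1:])
                d_cols.append(off + comp[:-1])
                d_data.append(np.full(n - 1, D))
                d_rows.append(off + comp[:-1])
                d_cols.append(off + comp[1:])
                d_data.append(np.full(n - 1, D))
        if d_rows:
            d_rows = np.concatenate(d_rows)
            d_cols = np.concatenate(d_cols)
            self.diff_data = np.concatenate(d_data)
        else:
            d_rows = np.empty(0, dtype=int)
            d_cols = np.empty(0, dtype=int)
            self.diff_data = np.empty(0)
        eye = np.arange(size)
        self.rows = np.concatenate([r_rows, d_rows, eye])
        self.cols = np.concatenate([r_cols, d_cols, eye])
        self.size = size
        self.n = n
        self.params = params

    def matrix(self, y: np.ndarray, dt: float) -> sp.csc_matrix:
        """(I/dt − J) at state y (duplicate COO entries sum on conversion)."""
        blocks = reaction_jacobian(y.reshape(len(SPECIES), self.n), self.params)
        data = np.concatenate([
            -blocks.ravel(),
            -self.diff_data,
            np.full(self.size, 1.0 / dt),
        ])
        return sp.coo_matrix(
            (data, (self.rows, self.cols)), shape=(self.size, self.size)
        ).tocsc()


def _pseudo_transient(y0, params, grid, config, diff) -> SteadyStateResult:
    """Pseudo-transient continuation with SER step control.

    Implicit-Euler steps (I/dt - J) delta = f(y), one modified-Newton solve
    each, with the time step governed by switched evolution relaxation: dt
    grows in proportion to the residual reduction (bounded growth per step),
    so the iteration turns into full Newton as the steady state is
    approached.  Steps that leave the non-negative orthant or blow up the
    residual are retried with a smaller dt.
    """
    y = np.asarray(y0, dtype=float).copy()
    n_evals = 0
    # fastest relevant rate sets the opening step
    rate0 = max(
        params.k5 * max(params.Dl_tot, 1.0), params.k6, params.k10,
        max(getattr(params, d) for d in ("D_Dl", "D_C", "D_DlC")) / grid.dx**2
        if grid.n_compartments > 1 else 0.0,
        1.0,
    )
    dt = 0.1 / rate0
    t = 0.0
    pattern = _SystemPattern(params, grid)
    f = _rhs_flat(y, params, grid, diff)
    n_evals += 1
    res = _residual(y, f)
    n_steps = 0
    while t < config.t_max and n_steps < _PSEUDO_MAX_STEPS:
        n_steps += 1
        if res <= config.steady_tol:
            return SteadyStateResult(
                SpeciesState.from_vector(y, grid.n_compartments),
                t, res, n_evals, "pseudo",
            )
        try:
            lu = splu(pattern.matrix(y, dt))
            delta = lu.solve(f)
        except RuntimeError:  # singular at huge dt: retry smaller
            dt *= 0.25
            continue
        y_new = y + delta
        if (
            not np.all(np.isfinite(y_new))
            or y_new.min() < _NEGATIVE_GUARD * max(1.0, np.abs(y_new).max())
        ):
            dt *= 0.25
            continue
        y_new = np.clip(y_new, 0.0, None)
        f_new = _rhs_flat(y_new, params, grid, diff)
        n_evals += 1
        res_new = _residual(y_new, f_new)
        if not np.isfinite(res_new) or res_new > 10.0 * res:
            dt *= 0.25
            continue
        # SER: the step grows with the achieved residual reduction
        growth = min(max(res / max(res_new, 1e-300), 1.2), 4.0)
        y, f, res = y_new, f_new, res_new
        t += dt
        dt = min(dt * growth, config.t_max)
    raise NonConvergenceError(
        f"pseudo-transient run stalled at t={t:g} after {n_steps} steps "
        f"(residual {res:.3e})",
        residual=res,
    )


def single_compartment_steady_state(
    params: ModelParameters, toll_total: float
) -> SpeciesState:
    """Algebraic steady state of the well-mixed (diffusion-free) system.

    Serves as an independent oracle for the time integrator on a
    one-compartment grid.  The system is reduced analytically before root
    finding: at steady state every balance except those of cDl0 and Cf is
    slaved —

    * nDl0 = (k3/k4)·cDl0, cDlstar = (k9/k11)·DlCT, nDlstar = (k9/k12)·DlCT;
    * adding the DlC and DlCT balances gives k5·cDl0·Cf − k6·DlC − k9·DlCT = 0,
      and the DlCT balance with Toll conservation (T + DlCT = toll_total)
      closes a quadratic in DlC;

    which leaves two equations — the Cf balance and Dl conservation — solved
    by a damped Newton root find in log(cDl0), log(Cf).
    """
    if toll_total < 0:
        raise ValueError("toll_total must be >= 0")
    p = params
    if p.options.k12_destination != "cDl0":
        raise NotImplementedError(
            "the algebraic oracle assumes nuclear export returns Dl to cDl0 "
            "(the starred-loop variant has no non-degenerate Toll branch)"
        )
    if p.Dl_tot == 0:
        state = SpeciesState.zeros(1)
        state.array[SPECIES.index("T")] = toll_total
        return state

    def branch(x: float, c: float) -> tuple[float, float]:
        """DlC and DlCT given free cDl0 = x and free Cactus = c."""
        s = p.k5 * x * c
        if toll_total == 0 or p.k7 == 0:
            return (s / p.k6 if p.k6 > 0 else 0.0), 0.0
        # k6·k7·d² + [k6(k8+k9) − s·k7 + k9·k7·toll_total]·d − s(k8+k9) = 0
        A = p.k6 * p.k7
        B = p.k6 * (p.k8 + p.k9) - s * p.k7 + p.k9 * p.k7 * toll_total
        C = -s * (p.k8 + p.k9)
        d = (-B + np.sqrt(B * B - 4 * A * C)) / (2 * A)
        dct = p.k7 * d * toll_total / (p.k8 + p.k9 + p.k7 * d)
        return d, dct

    def residuals(z: np.ndarray) -> np.ndarray:
        x, c = np.exp(z)
        d, dct = branch(x, c)
        if p.options.synthesis_driver == "cDl0":
            driver = x
        else:
            driver = x + (p.k9 / p.k11) * dct + d + dct
        f_cactus = p.k1 * driver - p.k2 * c - p.k5 * x * c + p.k6 * d
        dl_total = (
            x * (1.0 + p.k3 / p.k4)
            + d
            + dct * (1.0 + p.k9 / p.k11 + p.k9 / p.k12)
        )
        return np.array([f_cactus, dl_total - p.Dl_tot])

    x0 = 0.1 * p.Dl_tot
    c0 = max(p.k1 * x0 / p.k2, 1e-8) if p.k2 > 0 else 1.0
    sol = root(residuals, np.log([x0, c0]), method="hybr", options={"xtol": 1e-12})
    if not sol.success and np.max(np.abs(sol.fun)) > 1e-10:
        raise NonConvergenceError(
            f"single-compartment root finding failed: {sol.message}",
            residual=float(np.max(np.abs(sol.fun))),
        )
    x, c = np.exp(sol.x)
    d, dct = branch(x, c)
    state = SpeciesState.zeros(1)
    values = {
        "cDl0": x,
        "nDl0": p.k3 * x / p.k4,
        "Cf": c,
        "DlC": d,
        "T": toll_total - dct,
        "DlCT": dct,
        "Cub": p.k9 * dct / p.k10 if p.k10 > 0 else 0.0,
        "cDlstar": p.k9 * dct / p.k11,
        "nDlstar": p.k9 * dct / p.k12,
    }
    for name, v in values.items():
        state.array[SPECIES.index(name), 0] = v
    residual = float(np.max(np.abs(_reaction_rates_array(state.array, p))))
    if residual > 1e-9 * max(1.0, float(state.array.max())):
        raise NonConvergenceError(
            f"single-compartment oracle residual too large ({residual:.3e})",
            residual=residual,
        )
    return state
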