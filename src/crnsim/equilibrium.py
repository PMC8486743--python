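"""Asymptotic (equilibrium) states of mass-action networks by stiff integration.

The equilibrium of a network within a stoichiometric compatibility class is
taken as the asymptotic value of the ODE solution ``xdot = S v(x, k)``.
Integration uses a backward-differentiation (BDF) method with an analytic
Jacobian, on geometrically growing time horizons, until both the steady
residual ``||S v||_inf / max(1, ||x||_inf)`` and the relative change of the
state between successive horizons fall below tolerance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .conservation import ConservationLaw, class_distance, totals
from .crn_core import CRN

__all__ = [
    "EquilibriumResult",
    "Trajectory",
    "SolverOptions",
    "find_equilibrium",
    "trajectory",
    "steady_residual",
    "export_trajectory_csv",
    "export_equilibrium_csv",
]


@dataclass(frozen=True)
class SolverOptions:
    """Integration and convergence controls.

    rtol, atol
        Solver tolerances (atol in nM).
    residual_tol
        Steady-state residual threshold on ``||S v||_inf / max(1,||x||_inf)``.
    change_tol
        Relative state change between successive horizons below which the
        state is declared stationary.
    t_first, t_cap
        First integration horizon and hard cap (s); horizons double.
    """

    rtol: float = 1e-8
    atol: float = 1e-12
    residual_tol: float = 1e-9
    change_tol: float = 1e-8
    t_first: float = 1e5
    t_cap: float = 1e9
    method: str = "BDF"


@dataclass
class EquilibriumResult:
    """Equilibrium concentrations plus convergence diagnostics."""

    x_eq: np.ndarray
    residual: float
    t_final: float
    converged: bool
    conservation_drift: float = float("nan")
    clipped: float = 0.0
    species_ids: tuple[str, ...] = field(default_factory=tuple)

    def concentration(self, species_id: str) -> float:
        return float(self.x_eq[self.species_ids.index(species_id)])


@dataclass
class Trajectory:
    """Sampled solution: times t (s) and an n x len(t) concentration matrix."""

    t: np.ndarray
    X: np.ndarray
    species_ids: tuple[str, ...] = field(default_factory=tuple)

    def series(self, species_id: str) -> np.ndarray:
        return self.X[self.species_ids.index(species_id)]


def steady_residual(crn: CRN, x: np.ndarray) -> float:
    """Scale-normalized stationarity defect ``||S v(x,k)||_inf / max(1, ||x||_inf)``."""
    x = np.asarray(x, dtype=float)
    xdot = crn.rhs(x, clip=True)
    scale = max(1.0, float(np.max(np.abs(x), initial=0.0)))
    return float(np.max(np.abs(xdot), initial=0.0)) / scale


def _clip_negative(x: np.ndarray, n_tol: float) -> tuple[np.ndarray, float]:
    clipped = float(-x[x < 0].sum()) if np.any(x < 0) else 0.0
    if clipped > n_tol:
        warnings.warn(
            f"integrator undershoot: clipped {clipped:.3g} nM of negative "
            "concentration to zero",
            stacklevel=3,
        )
    return np.maximum(x, 0.0), clipped


def find_equilibrium(
    crn: CRN,
    x0: np.ndarray | None = None,
    options: SolverOptions | None = None,
    laws: list[ConservationLaw] | None = None,
) -> EquilibriumResult:
    """Integrate to the asymptotic stable state of the compatibility class of x0.

    Returns a result with ``converged=False`` (never a silent partial
    answer) when the stationarity criterion is not met by the horizon cap.
    When ``laws`` are supplied the drift of their conserved totals between
    x0 and the equilibrium is recorded in ``conservation_drift``.
    """
    opts = options or SolverOptions()
    x = crn.x0 if x0 is None else np.asarray(x0, dtype=float)
    if x.shape != (crn.n,):
        raise ValueError(f"x0 has shape {x.shape}, expected ({crn.n},)")
    if np.any(x < 0):
        raise ValueError("negative initial concentration")

    c0 = totals(laws, x) if laws else None

    fun = lambda t, y: crn.rhs(y, clip=True)  # noqa: E731
    jac = lambda t, y: crn.jacobian(y)  # noqa: E731

    total_clipped = 0.0
    t_now = 0.0
    horizon = opts.t_first
    converged = False
    residual = steady_residual(crn, x)
    if residual <= opts.residual_tol:
        converged = True  # already stationary (e.g. empty network)
    while not converged and t_now < opts.t_cap:
        t_next = min(horizon, opts.t_cap)
        sol = solve_ivp(
            fun,
            (t_now, t_next),
            x,
            method=opts.method,
            jac=jac,
            rtol=opts.rtol,
            atol=opts.atol,
            dense_output=False,
        )
        if not sol.success:
            raise RuntimeError(
                f"stiff integration failed at t={sol.t[-1]:.3g} s: {sol.message}"
            )
        x_new, clip_amt = _clip_negative(sol.y[:, -1], crn.n * 1e-9)
        total_clipped += clip_amt
        t_now = t_next
        horizon *= 2.0
        residual = steady_residual(crn, x_new)
        denom = np.maximum(np.abs(x_new), 1.0)
        change = float(np.max(np.abs(x_new - x) / denom, initial=0.0))
        x = x_new
        if residual <= opts.residual_tol and change <= opts.change_tol:
            converged = True

    drift = float("nan")
    if c0 is not None:
        drift = class_distance(laws, x, c0)
    return EquilibriumResult(
        x_eq=x,
        residual=residual,
        t_final=t_now,
        converged=converged,
        conservation_drift=drift,
        clipped=total_clipped,
        species_ids=tuple(crn.species_ids),
    )


def trajectory(
    crn: CRN,
    x0: np.ndarray | None = None,
    t_grid: np.ndarray | None = None,
    options: SolverOptions | None = None,
) -> Trajectory:
    """Solve the ODEs and sample the solution on ``t_grid`` (same solver
    settings as :func:`find_equilibrium`)."""
    opts = options or SolverOptions()
    x = crn.x0 if x0 is None else np.asarray(x0, dtype=float)
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size == 0:
        raise ValueError("t_grid must be a non-empty 1-D array")
    if np.any(np.diff(t_grid) < 0):
        raise ValueError("t_grid must be sorted")
    if t_grid[-1] == t_grid[0]:
        X = np.tile(x[:, None], (1, t_grid.size))
        return Trajectory(t=t_grid, X=X, species_ids=tuple(crn.species_ids))

    sol = solve_ivp(
        lambda t, y: crn.rhs(y, clip=True),
        (t_grid[0], t_grid[-1]),
        x,
        method=opts.method,
        jac=lambda t, y: crn.jacobian(y),
        rtol=opts.rtol,
        atol=opts.atol,
        t_eval=t_grid,
    )
    if not sol.success:
        raise RuntimeError(
            f"stiff integration failed at t={sol.t[-1]:.3g} s: {sol.message}"
        )
    X = np.maximum(sol.y, 0.0)
    return Trajectory(t=sol.t, X=X, species_ids=tuple(crn.species_ids))


def export_trajectory_csv(traj: Trajectory, path, species: list[str] | None = None) -> None:
    """Time column plus one concentration column per requested species."""
    import pandas as pd

    names = list(species) if species is not None else list(traj.species_ids)
    data = {"time_s": traj.t}
    for name in names:
        data[name] = traj.series(name)
    pd.DataFrame(data).to_csv(path, index=False)


def export_equilibrium_csv(result: EquilibriumResult, path) -> None:
    """Two-column report: species, equilibrium concentration (nM)."""
    import pandas as pd

    pd.DataFrame(
        {"species": list(result.species_ids), "concentration_nM": result.x_eq}
    ).to_csv(path, index=False)
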