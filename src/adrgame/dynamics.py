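"""Numerical integration of the replicator system and limit detection.

The replicator field leaves every face of the unit cube invariant, so
trajectories started inside the cube stay inside it up to floating-point
drift; integrated states are clipped to [0,1]^3 to remove that drift.
Integration stops early once the max-norm of the field falls below a
stopping tolerance, which near a hyperbolic stable corner happens in
moderate time because the approach is exponential.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .game import _check_state, field_array
from .params import ParameterSet
from .stability import CORNER_COORDS, CornerPoint, corner_points

DEFAULT_HORIZON: float = 200.0
DEFAULT_STOP_TOL: float = 1e-10
#: Max-norm distance within which a limit is attributed to a corner.
CORNER_ATTRIBUTION_TOL: float = 1e-3
#: Relative slack when comparing the final field norm against the stopping
#: tolerance: the early-stop event fires at equality, so root-finding leaves
#: the final norm at the tolerance up to solver precision.
_CONVERGENCE_SLACK: float = 1e-6


@dataclass(frozen=True)
class Trajectory:
    """Time series of mixed states with convergence metadata.

    ``converged`` means the replicator field's max-norm at the final state
    is below the stopping tolerance used for the run; ``limit`` is the
    final state when converged, else ``None``. ``final_field_norm`` stores
    that norm so limit classification needs no parameter set.
    """

    times: np.ndarray        # shape (n,), nondecreasing
    states: np.ndarray       # shape (n, 3), inside the unit cube
    converged: bool
    limit: tuple[float, float, float] | None
    final_field_norm: float
    stop_tol: float

    @property
    def final_state(self) -> tuple[float, float, float]:
        return tuple(float(v) for v in self.states[-1])


def integrate(
    state0,
    params: ParameterSet,
    horizon: float = DEFAULT_HORIZON,
    tol: float = DEFAULT_STOP_TOL,
    method: str = "adaptive",
    rtol: float = 1e-8,
    atol: float = 1e-10,
    step: float = 0.01,
    clip: bool = True,
) -> Trajectory:
    """Integrate the replicator ODEs from ``state0`` up to ``horizon``.

    Parameters
    ----------
    method
        ``"adaptive"`` uses an adaptive Runge-Kutta pair (RK45) with the
        given ``rtol``/``atol``; ``"rk4"`` uses classical fixed-step RK4
        with step size ``step`` as an independent cross-check scheme.
    tol
        Stopping tolerance on the max-norm of the field; integration ends
        early once the field is this small.
    clip
        Clip states to [0,1]^3 after integration (faces are analytically
        invariant; clipping only removes floating-point drift).
    """
    x0 = np.asarray(_check_state(state0), dtype=float)
    if horizon <= 0:
        raise ValueError("horizon must be positive")

    def rhs(t, s):
        return field_array(np.clip(s, 0.0, 1.0), params)

    if method == "adaptive":
        def small_field(t, s):
            return float(np.max(np.abs(rhs(t, s)))) - tol

        small_field.terminal = True
        small_field.direction = -1
        sol = solve_ivp(
            rhs, (0.0, float(horizon)), x0, method="RK45",
            rtol=rtol, atol=atol, events=small_field, dense_output=False,
        )
        if not sol.success:
            raise RuntimeError(f"integration failed: {sol.message}")
        times = sol.t
        states = sol.y.T
    elif method == "rk4":
        times_l = [0.0]
        states_l = [x0]
        t, s = 0.0, x0
        n_steps = int(np.ceil(horizon / step))
        for _ in range(n_steps):
            h = min(step, horizon - t)
            k1 = rhs(t, s)
            k2 = rhs(t + h / 2, s + h / 2 * k1)
            k3 = rhs(t + h / 2, s + h / 2 * k2)
            k4 = rhs(t + h, s + h * k3)
            s = np.clip(s + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4), 0.0, 1.0)
            t += h
            times_l.append(t)
            states_l.append(s)
            if np.max(np.abs(rhs(t, s))) < tol:
                break
        times = np.asarray(times_l)
        states = np.asarray(states_l)
    else:
        raise ValueError(f"unknown integration method {method!r}")

    if clip:
        states = np.clip(states, 0.0, 1.0)
    final_norm = float(np.max(np.abs(field_array(np.clip(states[-1], 0, 1), params))))
    converged = final_norm <= tol * (1 + _CONVERGENCE_SLACK)
    limit = tuple(float(v) for v in states[-1]) if converged else None
    return Trajectory(times, states, converged, limit, final_norm, tol)


def nearest_corner(point, tol: float = CORNER_ATTRIBUTION_TOL) -> CornerPoint | None:
    """The corner within max-norm ``tol`` of ``point``, if any."""
    p = np.asarray(point, dtype=float)
    for c in corner_points():
        if np.max(np.abs(p - np.asarray(c.coordinates))) < tol:
            return c
    return None


def limit_point(traj: Trajectory, tol: float = DEFAULT_STOP_TOL):
    """Final state of a trajectory with convergence and corner attribution.

    Returns ``(point, converged, corner)`` where ``corner`` is the
    labelled corner within 1e-3 (max-norm) of the final state, or ``None``.
    """
    if len(traj.times) == 0:
        raise ValueError("empty trajectory")
    point = traj.final_state
    converged = traj.final_field_norm <= tol * (1 + _CONVERGENCE_SLACK)
    return point, converged, nearest_corner(point)


def basin_map(params: ParameterSet, grid_resolution: int, **integrate_kw):
    """Integrate from a uniform interior grid and report each limit.

    Starts are the grid ``((i+0.5)/r, (j+0.5)/r, (k+0.5)/r)`` for
    ``i,j,k`` in ``range(r)``; resolution 1 gives the single start
    (0.5, 0.5, 0.5). Returns a list of ``(start, limit, corner_label)``
    with ``corner_label`` ``None`` when the limit is not near a corner.
    """
    if grid_resolution < 1:
        raise ValueError("grid_resolution must be >= 1")
    coords = (np.arange(grid_resolution) + 0.5) / grid_resolution
    results = []
    for xi in coords:
        for yi in coords:
            for zi in coords:
                traj = integrate((xi, yi, zi), params, **integrate_kw)
                point, _, corner = limit_point(traj, traj.stop_tol)
                results.append(
                    ((float(xi), float(yi), float(zi)), point,
                     corner.label if corner else None)
                )
    return results
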