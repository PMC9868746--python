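"""Corner equilibria, analytic Jacobian and stability classification.

Setting all three replicator equations to zero over pure strategies yields
eight corner equilibria E1..E8 of the unit cube. Local asymptotic
stability at a corner is decided by Lyapunov's first (indirect) method:
a corner is an evolutionarily stable state of the system when all three
eigenvalues of the Jacobian there are negative. Because every off-diagonal
Jacobian entry carries a factor x(1-x), y(1-y) or z(1-z), the Jacobian is
diagonal at every corner and the eigenvalues are its diagonal entries in
closed form.

Under the standing parameter constraints, only E1=(0,0,0) — high quality,
honest agencies, lax (cheap) supervision — E5=(1,1,0) and E8=(1,1,1) can
ever have all-negative eigenvalues; the remaining five corners each carry
an eigenvalue forced positive by the constraints.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .game import field_array, _check_state
from .params import ParameterSet, validate_parameters

#: Corner labels and coordinates, in canonical order.
CORNER_COORDS: dict[str, tuple[int, int, int]] = {
    "E1": (0, 0, 0),
    "E2": (1, 0, 0),
    "E3": (0, 1, 0),
    "E4": (0, 0, 1),
    "E5": (1, 1, 0),
    "E6": (1, 0, 1),
    "E7": (0, 1, 1),
    "E8": (1, 1, 1),
}

DEFAULT_EIG_TOL: float = 1e-9


@dataclass(frozen=True)
class CornerPoint:
    label: str
    coordinates: tuple[int, int, int]

    def __post_init__(self):
        if CORNER_COORDS.get(self.label) != tuple(self.coordinates):
            raise ValueError(
                f"{self.label!r} with coordinates {self.coordinates} is not "
                "one of the eight corner equilibria"
            )


@dataclass(frozen=True)
class CornerReport:
    """Stability diagnosis of one corner equilibrium."""

    corner: str
    point: tuple[int, int, int]
    eigenvalues: tuple[float, float, float]  # ascending
    verdict: str  # stable | unstable | marginal
    conditions: dict[str, dict] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "corner": self.corner,
            "point": list(self.point),
            "eigenvalues": list(self.eigenvalues),
            "verdict": self.verdict,
            "conditions": self.conditions,
        }


def corner_points() -> list[CornerPoint]:
    """The eight labelled corner equilibria, E1..E8."""
    return [CornerPoint(lbl, xyz) for lbl, xyz in CORNER_COORDS.items()]


def _as_corner(corner) -> CornerPoint:
    if isinstance(corner, CornerPoint):
        return corner
    if isinstance(corner, str):
        if corner not in CORNER_COORDS:
            raise ValueError(f"unknown corner label {corner!r}")
        return CornerPoint(corner, CORNER_COORDS[corner])
    coords = tuple(int(c) for c in corner)
    for lbl, xyz in CORNER_COORDS.items():
        if xyz == coords:
            return CornerPoint(lbl, xyz)
    raise ValueError(f"{corner!r} is not a corner of the unit cube")


def jacobian(state, params: ParameterSet) -> np.ndarray:
    """Analytic 3x3 Jacobian of the replicator field at a mixed state."""
    x, y, z = _check_state(state)
    p = params
    dU1 = (y * p.Ee - z * p.Pe - p.Cl - p.Ve - z * p.Se - p.Ee + p.Ch
           - y * z * p.K)
    dU2 = p.K - p.Vt - z * p.K - z * p.St - z * p.Pt + x * z * p.K
    dU3 = x * p.Pe + y * p.Pt - p.Cr + y * p.St + x * p.Se + x * y * p.Pg
    xx = x * (1 - x)
    yy = y * (1 - y)
    zz = z * (1 - z)
    return np.array([
        [(1 - 2 * x) * dU1, xx * (p.Ee - z * p.K), xx * (-p.Pe - p.Se - y * p.K)],
        [yy * z * p.K, (1 - 2 * y) * dU2, yy * (-p.K - p.St - p.Pt + x * p.K)],
        [zz * (p.Pe + p.Se + y * p.Pg), zz * (p.Pt + p.St + x * p.Pg),
         (1 - 2 * z) * dU3],
    ], dtype=float)


def corner_eigenvalues(corner, params: ParameterSet) -> np.ndarray:
    """Eigenvalues at a corner equilibrium, sorted ascending.

    The Jacobian is diagonal at every corner, so the eigenvalues are its
    diagonal entries exactly.
    """
    c = _as_corner(corner)
    J = jacobian(c.coordinates, params)
    return np.sort(np.diagonal(J))


def classify_corner(corner, params: ParameterSet, tol: float = DEFAULT_EIG_TOL) -> str:
    """Verdict at a corner: 'stable', 'unstable' or 'marginal'.

    Stable means all eigenvalues < -tol (locally asymptotically stable by
    Lyapunov's first method); unstable means some eigenvalue > +tol;
    anything with an eigenvalue within tol of zero and none positive is
    marginal (the linearisation is inconclusive there).
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    eig = corner_eigenvalues(corner, params)
    if np.all(eig < -tol):
        return "stable"
    if np.any(eig > tol):
        return "unstable"
    return "marginal"


def _table3_conditions(label: str, p: ParameterSet) -> dict[str, dict]:
    """Closed-form stability predicates for the three candidate ESS corners."""
    exprs: dict[str, float] = {}
    if label == "E1":
        exprs["K-Vt<0"] = p.K - p.Vt
    elif label == "E5":
        exprs["Vt-K<0"] = p.Vt - p.K
        exprs["Pe-Cr+Pg+Pt+Se+St<0"] = p.Pe - p.Cr + p.Pg + p.Pt + p.Se + p.St
    elif label == "E8":
        exprs["Vt-K+St+Pt<0"] = p.Vt - p.K + p.St + p.Pt
        exprs["Cr-Pe-Pg-Pt-Se-St<0"] = p.Cr - p.Pe - p.Pg - p.Pt - p.Se - p.St
    return {
        name: {"value": float(v), "holds": bool(v < 0)} for name, v in exprs.items()
    }


def stability_report(
    params: ParameterSet,
    tol: float = DEFAULT_EIG_TOL,
    mode: str = "exploratory",
) -> list[CornerReport]:
    """Eigenvalues, verdicts and candidate-ESS conditions for all 8 corners.

    In ``strict`` mode, parameter sets violating the standing constraints
    abort with a ``ValueError`` naming the first violation; in
    ``exploratory`` mode the report is produced regardless.
    """
    violations = validate_parameters(params)
    if violations and mode == "strict":
        raise ValueError(f"parameter constraint violated: {violations[0]}")
    reports = []
    for c in corner_points():
        eig = corner_eigenvalues(c, params)
        reports.append(CornerReport(
            corner=c.label,
            point=c.coordinates,
            eigenvalues=tuple(float(e) for e in eig),
            verdict=classify_corner(c, params, tol),
            conditions=_table3_conditions(c.label, params),
        ))
    return reports


def stable_corners(params: ParameterSet, tol: float = DEFAULT_EIG_TOL) -> list[str]:
    """Labels of the corners classified stable for these parameters."""
    return [r.corner for r in stability_report(params, tol) if r.verdict == "stable"]


# Closed-form eigenvalue that is forced nonnegative at each infeasible
# corner under the standing constraints (Ee>Ch>Cl, Ch>Cl+K+Ve+Pe+Se, all
# parameters >= 0):
#   E2: Cl-Ch+Ee+Ve          > 0 since Ee > Ch
#   E3: Ch-Cl-Ve             > 0 since Ch > Cl+K+Ve+Pe+Se
#   E4: Cr                   >= 0
#   E6: Cl-Ch+Ee+Pe+Se+Ve    > 0 since Ee > Ch
#   E7: Pt+St+Vt             >= 0
_INFEASIBLE = ("E2", "E3", "E4", "E6", "E7")


def feasible_ess_corners(
    n_samples: int = 10_000,
    seed: int = 20230109,
    cross_check: bool = True,
    max_draws: int = 100_000_000,
) -> set[str]:
    """Corners that can be evolutionarily stable under the standing constraints.

    Primary method is analytic: at each of E2, E3, E4, E6, E7 one
    eigenvalue is a parameter combination forced nonnegative by the
    standing constraints (see the table above), so those corners can never
    have all-negative eigenvalues. E1, E5 and E8 are feasible by explicit
    witnesses: the three printed simulation parameter sets stabilise one
    each. A seeded rejection-sampling cross-check verifies that no sampled
    valid parameter set ever classifies an excluded corner stable.
    """
    feasible = {"E1", "E5", "E8"}
    if cross_check:
        from .scenarios import printed_sets, sample_parameters

        for name, target in (("A", "E1"), ("B", "E5"), ("C", "E8")):
            if classify_corner(target, printed_sets()[name].params) != "stable":
                raise AssertionError(
                    f"witness scenario {name} fails to stabilise {target}"
                )
        for sc in sample_parameters("any", seed=seed, n=n_samples,
                                    max_draws=max_draws):
            for label in _INFEASIBLE:
                if classify_corner(label, sc.params) == "stable":
                    raise AssertionError(
                        f"sampled valid parameter set stabilises {label}: "
                        f"{sc.params.to_dict()}"
                    )
    return feasible
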