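"""Parameter sweeps and qualitative trajectory-shape characterisation.

The sweeps vary one parameter at a time around a base configuration and
record where the replicator dynamics settle. The headline sweeps examine
the bribe size K (around the scenario-A base), the regulation cost Cr and
the credibility loss Pg (around the scenario-C base).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .dynamics import Trajectory, integrate, limit_point
from .params import PARAM_KEYS, ParameterSet, validate_parameters
from .scenarios import Scenario, printed_sets

_COMPONENTS = {"x": 0, "y": 1, "z": 2}
#: Successive differences below this are treated as flat.
FLAT_TOL: float = 1e-6


@dataclass(frozen=True)
class SweepEntry:
    value: float
    params: ParameterSet
    trajectory: Trajectory
    limit: tuple[float, float, float]
    corner: str | None
    converged: bool


@dataclass(frozen=True)
class SweepResult:
    parameter: str
    base: ParameterSet
    state0: tuple[float, float, float]
    entries: tuple[SweepEntry, ...] = field(default_factory=tuple)

    @property
    def values(self) -> list[float]:
        return [e.value for e in self.entries]

    @property
    def corners(self) -> list[str | None]:
        return [e.corner for e in self.entries]


def sweep(
    base: ParameterSet,
    name: str,
    values,
    state0=(0.5, 0.5, 0.5),
    **integrate_kw,
) -> SweepResult:
    """Integrate from ``state0`` for each substituted value of one parameter.

    Substituted sets failing the standing constraints produce a warning
    (they are still run; sweeps may legitimately cross the boundary of the
    modelled region).
    """
    if name not in PARAM_KEYS:
        raise KeyError(f"unknown parameter name {name!r}")
    entries = []
    for v in values:
        p = base.replace(**{name: float(v)})
        bad = validate_parameters(p)
        if bad:
            warnings.warn(
                f"{name}={v}: constraint violations {bad}", stacklevel=2
            )
        traj = integrate(state0, p, **integrate_kw)
        point, converged, corner = limit_point(traj, traj.stop_tol)
        entries.append(SweepEntry(
            float(v), p, traj, point, corner.label if corner else None, converged,
        ))
    return SweepResult(name, base, tuple(float(s) for s in state0), tuple(entries))


def trajectory_shape(traj: Trajectory, component: str, flat_tol: float = FLAT_TOL) -> str:
    """Qualitative shape of one state component over time.

    The component series is smoothed with a centred 3-point moving average
    (so solver micro-oscillations cannot flip the label), then classified
    from the signs of its successive differences, treating differences
    below ``flat_tol`` as flat:

    * all flat -> ``"flat"``
    * single sign throughout -> ``"monotone_increasing"`` / ``"monotone_decreasing"``
    * one sign change - to + -> ``"single_trough"`` (falls, then rises)
    * one sign change + to - -> ``"single_peak"``
    * anything else -> ``"other"``
    """
    if component not in _COMPONENTS:
        raise ValueError(f"component must be one of {sorted(_COMPONENTS)}")
    series = np.asarray(traj.states)[:, _COMPONENTS[component]]
    if series.size < 3:
        raise ValueError("trajectory too short to classify (need >= 3 points)")
    smooth = series.copy()
    smooth[1:-1] = (series[:-2] + series[1:-1] + series[2:]) / 3.0
    diffs = np.diff(smooth)
    signs = np.sign(diffs) * (np.abs(diffs) > flat_tol)
    signs = signs[signs != 0]
    if signs.size == 0:
        return "flat"
    changes = np.flatnonzero(np.diff(signs) != 0)
    if changes.size == 0:
        return "monotone_increasing" if signs[0] > 0 else "monotone_decreasing"
    if changes.size == 1:
        return "single_trough" if signs[0] < 0 else "single_peak"
    return "other"


@dataclass(frozen=True)
class FigurePreset:
    """One headline run: a single scenario or a one-parameter sweep."""

    name: str
    base: ParameterSet
    param: str | None = None
    values: tuple[float, ...] | None = None

    @property
    def is_sweep(self) -> bool:
        return self.param is not None


def figure_scenarios() -> dict[str, FigurePreset]:
    """Named presets for the six headline simulations.

    fig2/fig3/fig4 are single runs of scenarios A, B, C; fig5 sweeps the
    bribe K over the scenario-A base; fig6 and fig7 sweep the regulation
    cost Cr and the credibility loss Pg over the scenario-C base.
    """
    sets = printed_sets()
    a, c = sets["A"].params, sets["C"].params
    return {
        "fig2": FigurePreset("fig2", a),
        "fig3": FigurePreset("fig3", sets["B"].params),
        "fig4": FigurePreset("fig4", c),
        "fig5": FigurePreset("fig5", a, "K", (30.0, 50.0, 100.0)),
        "fig6": FigurePreset("fig6", c, "Cr", (40.0, 120.0, 200.0)),
        "fig7": FigurePreset("fig7", c, "Pg", (20.0, 100.0, 180.0)),
    }
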