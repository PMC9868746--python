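"""Configuration loading and result serialisation.

Config files are JSON or YAML mappings whose keys are the fifteen
parameter names plus optional run settings. Outputs are a trajectory CSV
(``t,x,y,z``), a stability-report JSON (one entry per corner) and a sweep
summary JSON; all numbers are serialised with 12 significant digits so
identical runs produce byte-identical files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .params import OPTIONAL_KEYS, PARAM_KEYS, ParameterSet
from .sensitivity import SweepResult, trajectory_shape
from .stability import CornerReport

log = logging.getLogger("adrgame")

#: Run-setting keys accepted in a config file beside the parameter keys.
RUN_KEYS = ("x0", "y0", "z0", "horizon", "stop_tol", "eig_tol", "mode", "seed")

_RUN_DEFAULTS = dict(
    x0=0.5, y0=0.5, z0=0.5, horizon=200.0,
    stop_tol=1e-10, eig_tol=1e-9, mode="exploratory", seed=None,
)


class ConfigurationError(Exception):
    """A config file is malformed (unknown key, missing parameter...)."""


@dataclass(frozen=True)
class RunConfig:
    """A fully resolved run: parameters plus integration settings."""

    params: ParameterSet
    x0: float = 0.5
    y0: float = 0.5
    z0: float = 0.5
    horizon: float = 200.0
    stop_tol: float = 1e-10
    eig_tol: float = 1e-9
    mode: str = "exploratory"
    seed: int | None = None

    @property
    def state0(self) -> tuple[float, float, float]:
        return (self.x0, self.y0, self.z0)

    def to_dict(self) -> dict:
        d = self.params.to_dict()
        d.update(
            x0=self.x0, y0=self.y0, z0=self.z0, horizon=self.horizon,
            stop_tol=self.stop_tol, eig_tol=self.eig_tol, mode=self.mode,
        )
        if self.seed is not None:
            d["seed"] = self.seed
        return d


def load_config(path) -> RunConfig:
    """Load and validate a JSON/YAML run configuration.

    Unknown keys raise ``ConfigurationError`` naming the key; the twelve
    non-defaultable parameters are required; Et/Eg/Gg default to 0 (they
    cancel from the dynamics) and run settings default as logged.
    """
    path = Path(path)
    text = path.read_text()
    try:
        if path.suffix.lower() == ".json":
            raw = json.loads(text)
        else:
            raw = yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as e:
        raise ConfigurationError(f"cannot parse {path}: {e}") from e
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")

    unknown = set(raw) - set(PARAM_KEYS) - set(RUN_KEYS)
    if unknown:
        raise ConfigurationError(f"unknown config key: {sorted(unknown)[0]!r}")
    missing = set(PARAM_KEYS) - OPTIONAL_KEYS - set(raw)
    if missing:
        raise ConfigurationError(
            f"missing required parameter: {sorted(missing)[0]!r}"
        )

    pdict = {k: float(raw[k]) for k in PARAM_KEYS if k in raw}
    for k in sorted(OPTIONAL_KEYS - set(raw)):
        log.info("config %s: %s defaulted to 0", path.name, k)
        pdict[k] = 0.0
    settings = dict(_RUN_DEFAULTS)
    for k in RUN_KEYS:
        if k in raw:
            settings[k] = raw[k]
        else:
            log.debug("config %s: %s defaulted to %r", path.name, k, settings[k])
    if settings["mode"] not in ("strict", "exploratory"):
        raise ConfigurationError(
            f"mode must be 'strict' or 'exploratory', got {settings['mode']!r}"
        )
    return RunConfig(params=ParameterSet(**pdict), **settings)


def save_config(cfg: RunConfig, path) -> None:
    """Write a RunConfig so that load_config round-trips it."""
    path = Path(path)
    d = cfg.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(d, indent=1, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=True))


def _sig12(v: float) -> float:
    return float(f"{float(v):.12g}")


def write_trajectory_csv(traj, path, max_rows: int | None = None) -> None:
    """Trajectory CSV with header ``t,x,y,z``, 12 significant digits.

    ``max_rows`` thins long trajectories by uniform subsampling (the first
    and last accepted steps are always kept).
    """
    times, states = traj.times, traj.states
    if max_rows is not None and len(times) > max_rows:
        import numpy as np

        idx = np.unique(np.linspace(0, len(times) - 1, max_rows).astype(int))
        times, states = times[idx], states[idx]
    lines = ["t,x,y,z"]
    for t, (x, y, z) in zip(times, states):
        lines.append(f"{t:.12g},{x:.12g},{y:.12g},{z:.12g}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_stability_json(reports: list[CornerReport], path) -> None:
    """Stability report: one JSON entry per corner, schema version 1."""
    payload = {
        "schema": "adrgame/stability-report/v1",
        "corners": [
            {
                "corner": r.corner,
                "point": list(r.point),
                "eigenvalues": [_sig12(e) for e in r.eigenvalues],
                "verdict": r.verdict,
                "conditions": {
                    k: {"value": _sig12(v["value"]), "holds": v["holds"]}
                    for k, v in r.conditions.items()
                },
            }
            for r in reports
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def write_sweep_json(result: SweepResult, path) -> None:
    """Sweep summary: limits, corner attribution and shape labels."""
    payload = {
        "schema": "adrgame/sweep-summary/v1",
        "parameter": result.parameter,
        "state0": [_sig12(v) for v in result.state0],
        "entries": [
            {
                "value": _sig12(e.value),
                "limit": [_sig12(v) for v in e.limit],
                "corner": e.corner,
                "converged": e.converged,
                "shapes": {
                    c: trajectory_shape(e.trajectory, c) for c in ("x", "y", "z")
                },
            }
            for e in result.entries
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
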