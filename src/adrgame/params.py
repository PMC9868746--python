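"""Model parameters of the tripartite quality-regulation game.

The game involves three bounded-rational populations: manufacturers of
antigen detection reagents (ADRs), third-party inspection agencies, and
regulatory authorities. Fifteen nonnegative parameters, in abstract
monetary units, describe their incentives:

===== =====================================================================
Key   Meaning
===== =====================================================================
Ee    manufacturer sales revenue
Ch    cost of producing high-quality ADRs
Cl    cost of producing low-quality ADRs
K     bribe ("illegal incentive") paid by a manufacturer to an agency
Ve    manufacturer speculative cost (falsified production data etc.)
Pe    government fine on a low-quality manufacturer
Se    government subsidy to a high-quality manufacturer
Et    inspection-agency operating income
Vt    agency speculative cost of issuing false certificates
Pt    government fine on a bribed agency
St    government subsidy to an honest agency
Eg    social benefit accruing to the regulator from high-quality ADRs
Cr    cost of strict regulation
Gg    remediation cost when low-quality ADRs circulate
Pg    government credibility loss under lax supervision of misconduct
===== =====================================================================

Two standing inequalities restrict the economically meaningful region:
``Ee > Ch > Cl`` (selling high-quality ADRs is profitable, and quality is
costly) and ``Ch > Cl + K + Ve + Pe + Se`` (cutting quality pays even after
the bribe, the concealment cost, the expected fine and the forgone subsidy).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

#: Canonical ordering of the parameter keys, used by config files and the
#: vectorised samplers.
PARAM_KEYS: tuple[str, ...] = (
    "Ee", "Ch", "Cl", "K", "Ve", "Pe", "Se",
    "Et", "Vt", "Pt", "St",
    "Eg", "Cr", "Gg", "Pg",
)

#: Keys that may be omitted from a config file; they cancel from the
#: replicator dynamics and default to zero.
OPTIONAL_KEYS: frozenset[str] = frozenset({"Et", "Eg", "Gg"})

#: Tolerance for the strict standing inequalities.
CONSTRAINT_TOL: float = 1e-9


@dataclass(frozen=True)
class ParameterSet:
    """The fifteen game parameters (abstract monetary units, all >= 0)."""

    Ee: float
    Ch: float
    Cl: float
    K: float
    Ve: float
    Pe: float
    Se: float
    Vt: float
    Pt: float
    St: float
    Cr: float
    Pg: float
    Et: float = 0.0
    Eg: float = 0.0
    Gg: float = 0.0

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        """Build a parameter set from a mapping with keys from PARAM_KEYS.

        Unknown keys raise ``KeyError`` naming the offending key; missing
        required keys (anything outside Et/Eg/Gg) raise ``KeyError`` too.
        """
        unknown = set(d) - set(PARAM_KEYS)
        if unknown:
            raise KeyError(f"unknown parameter key: {sorted(unknown)[0]!r}")
        missing = set(PARAM_KEYS) - OPTIONAL_KEYS - set(d)
        if missing:
            raise KeyError(f"missing required parameter: {sorted(missing)[0]!r}")
        return cls(**{k: float(v) for k, v in d.items()})

    def to_dict(self) -> dict[str, float]:
        return {k: float(getattr(self, k)) for k in PARAM_KEYS}

    def replace(self, **changes: float) -> "ParameterSet":
        """Return a copy with the named parameters replaced."""
        unknown = set(changes) - set(PARAM_KEYS)
        if unknown:
            raise KeyError(f"unknown parameter key: {sorted(unknown)[0]!r}")
        return dataclasses.replace(self, **{k: float(v) for k, v in changes.items()})

    def as_array(self) -> np.ndarray:
        """The parameters in PARAM_KEYS order."""
        return np.array([getattr(self, k) for k in PARAM_KEYS], dtype=float)


def validate_parameters(params: ParameterSet, tol: float = CONSTRAINT_TOL) -> list[str]:
    """Check the standing constraints; return a list of named violations.

    The empty list means the parameter set lies strictly inside the
    economically meaningful region: ``Ee > Ch > Cl``,
    ``Ch > Cl + K + Ve + Pe + Se`` and every parameter nonnegative.
    Inequalities are strict up to ``tol``.
    """
    p = params
    violations: list[str] = []
    if not p.Ee - p.Ch > tol:
        violations.append("Ee>Ch")
    if not p.Ch - p.Cl > tol:
        violations.append("Ch>Cl")
    if not p.Ch - (p.Cl + p.K + p.Ve + p.Pe + p.Se) > tol:
        violations.append("Ch>Cl+K+Ve+Pe+Se")
    for key in PARAM_KEYS:
        if getattr(p, key) < -tol:
            violations.append(f"{key}>=0")
    return violations
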