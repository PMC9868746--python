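"""Payoffs, expected utilities and the replicator vector field.

Each population mixes over two pure strategies. The mixed state is
``(x, y, z)`` in the unit cube: ``x`` is the fraction of manufacturers
producing low-quality ADRs, ``y`` the fraction of inspection agencies
accepting bribes, ``z`` the fraction of regulators supervising strictly.

Strategy frequencies evolve by replicator dynamics: a strategy grows in
proportion to the excess of its expected payoff over its population's
average, giving

    dx/dt = x(1-x)(U11 - U12),
    dy/dt = y(1-y)(U21 - U22),
    dz/dt = z(1-z)(U31 - U32),

where U11/U12 are the manufacturer's conditional expected payoffs for the
low-/high-quality strategy against the opponents' mixtures, and likewise
U21/U22 (accept/refuse) and U31/U32 (strict/lax).

The payoff table is the single source of truth; the closed-form expected
utilities below are its exact mixture averages (a property the test suite
verifies by brute-force enumeration over the eight pure profiles).
"""

from __future__ import annotations

from enum import Enum
from typing import Iterable, NamedTuple

import numpy as np

from .params import ParameterSet


class ManufacturerStrategy(str, Enum):
    LOW_QUALITY = "low_quality"
    HIGH_QUALITY = "high_quality"


class AgencyStrategy(str, Enum):
    ACCEPT = "accept"
    REFUSE = "refuse"


class RegulatorStrategy(str, Enum):
    STRICT = "strict"
    LAX = "lax"


class PureProfile(NamedTuple):
    """One pure-strategy profile, one per cell of the payoff table."""

    manufacturer: ManufacturerStrategy
    agency: AgencyStrategy
    regulator: RegulatorStrategy

    @classmethod
    def make(cls, manufacturer, agency, regulator) -> "PureProfile":
        return cls(
            ManufacturerStrategy(manufacturer),
            AgencyStrategy(agency),
            RegulatorStrategy(regulator),
        )


class PayoffTriple(NamedTuple):
    manufacturer_payoff: float
    agency_payoff: float
    regulator_payoff: float


class ExpectedUtilities(NamedTuple):
    """Conditional and average expected payoffs at a mixed state."""

    U11: float  # manufacturer, low quality
    U12: float  # manufacturer, high quality
    U1bar: float
    U21: float  # agency, accept bribes
    U22: float  # agency, refuse bribes
    U2bar: float
    U31: float  # regulator, strict
    U32: float  # regulator, lax
    U3bar: float


class FieldVector(NamedTuple):
    """Replicator time-derivatives of (x, y, z)."""

    Fx: float
    Fy: float
    Fz: float


def all_profiles() -> list[PureProfile]:
    """The eight pure profiles in (manufacturer, agency, regulator) order."""
    return [
        PureProfile(m, a, r)
        for m in ManufacturerStrategy
        for a in AgencyStrategy
        for r in RegulatorStrategy
    ]


def _check_state(state: Iterable[float]) -> tuple[float, float, float]:
    s = np.asarray(tuple(state), dtype=float)
    if s.shape != (3,):
        raise ValueError(f"state must have three components, got shape {s.shape}")
    if not np.all(np.isfinite(s)):
        raise ValueError("state components must be finite")
    if np.any(s < 0.0) or np.any(s > 1.0):
        raise ValueError(f"state {tuple(s)} outside the unit cube")
    x, y, z = s
    return float(x), float(y), float(z)


def pure_payoffs(profile: PureProfile, params: ParameterSet) -> PayoffTriple:
    """Payoffs of the three players at a pure profile.

    The table encodes: a low-quality product reaches the market (earning
    ``Ee``) only if the agency accepts the bribe ``K``; a strict regulator
    fines misconduct (``Pe``, ``Pt``) and withholds the corresponding
    subsidy, while a lax regulator subsidises everyone and absorbs the
    remediation cost ``Gg`` plus credibility loss ``Pg`` when low-quality
    products circulate.
    """
    if not isinstance(profile, PureProfile):
        profile = PureProfile.make(*profile)
    m, a, r = profile
    p = params
    low = m is ManufacturerStrategy.LOW_QUALITY
    accept = a is AgencyStrategy.ACCEPT
    strict = r is RegulatorStrategy.STRICT

    if low:
        mfr = -p.Cl - p.Ve
        mfr += p.Ee - p.K if accept else 0.0
        mfr += -p.Pe if strict else p.Se
    else:
        mfr = p.Ee - p.Ch + p.Se
        if accept and not strict:
            mfr -= p.K  # bribe demanded even of honest producers when unsupervised

    if accept:
        agc = p.Et - p.Vt + p.K
        if strict:
            agc -= p.Pt
            if not low:
                agc -= p.K  # strict supervision blocks the bribe transfer itself
        else:
            agc += p.St
    else:
        agc = p.Et + p.St

    if strict:
        reg = -p.Cr
        reg += p.Pe if low else p.Eg - p.Se
        if accept:
            reg += p.Pt
            if low:
                reg -= p.Gg
        else:
            reg -= p.St
    else:
        reg = -p.Se - p.St
        if low:
            if accept:
                reg += -p.Gg - p.Pg
        else:
            reg += p.Eg
    return PayoffTriple(float(mfr), float(agc), float(reg))


def expected_utilities(state: Iterable[float], params: ParameterSet) -> ExpectedUtilities:
    """Closed-form conditional expected payoffs at a mixed state."""
    x, y, z = _check_state(state)
    p = params
    U11 = -z * p.Pe + y * p.Ee - y * p.K - p.Cl - p.Ve + p.Se - z * p.Se
    U12 = p.Ee - p.Ch + p.Se - y * p.K + y * z * p.K
    U21 = p.Et + p.K - p.Vt + p.St - z * p.K - z * p.St - z * p.Pt + x * z * p.K
    U22 = p.Et + p.St
    U31 = (x * p.Pe - x * y * p.Gg + y * p.Pt + p.Eg - p.Cr - p.Se - p.St
           + y * p.St - x * p.Eg + x * p.Se)
    U32 = -x * y * p.Gg - x * y * p.Pg + p.Eg - p.Se - p.St - x * p.Eg
    return ExpectedUtilities(
        U11, U12, x * U11 + (1 - x) * U12,
        U21, U22, y * U21 + (1 - y) * U22,
        U31, U32, z * U31 + (1 - z) * U32,
    )


def replicator_field(state: Iterable[float], params: ParameterSet) -> FieldVector:
    """Replicator vector field (dx/dt, dy/dt, dz/dt) at a mixed state.

    Note that Et, Eg and Gg cancel from every payoff difference, so the
    dynamics are exactly invariant to them.
    """
    x, y, z = _check_state(state)
    p = params
    dU1 = (y * p.Ee - z * p.Pe - p.Cl - p.Ve - z * p.Se - p.Ee + p.Ch
           - y * z * p.K)
    dU2 = p.K - p.Vt - z * p.K - z * p.St - z * p.Pt + x * z * p.K
    dU3 = x * p.Pe + y * p.Pt - p.Cr + y * p.St + x * p.Se + x * y * p.Pg
    return FieldVector(
        x * (1 - x) * dU1,
        y * (1 - y) * dU2,
        z * (1 - z) * dU3,
    )


def field_array(state: Iterable[float], params: ParameterSet) -> np.ndarray:
    """`replicator_field` as a length-3 ndarray (ODE right-hand side)."""
    return np.asarray(replicator_field(state, params), dtype=float)
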