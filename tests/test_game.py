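"""Payoff table, expected utilities and replicator field.

The independent oracle here is brute-force enumeration: conditional
expected utilities are recomputed by weighting the eight pure-profile
payoffs with the opponents' mixing probabilities, never through the
closed forms under test.
"""

import numpy as np
import pytest

from adrgame import (ParameterSet, all_profiles, expected_utilities,
                     pure_payoffs, replicator_field, sample_parameters)
from adrgame.game import (AgencyStrategy, ManufacturerStrategy, PureProfile,
                          RegulatorStrategy)

from conftest import interior_states


def brute_force_utilities(state, params):
    """Oracle: conditional expected payoffs by enumeration over profiles."""
    x, y, z = state
    pm = {ManufacturerStrategy.LOW_QUALITY: x, ManufacturerStrategy.HIGH_QUALITY: 1 - x}
    pa = {AgencyStrategy.ACCEPT: y, AgencyStrategy.REFUSE: 1 - y}
    pr = {RegulatorStrategy.STRICT: z, RegulatorStrategy.LAX: 1 - z}
    U = {}
    for m in ManufacturerStrategy:
        U["U1" + ("1" if m is ManufacturerStrategy.LOW_QUALITY else "2")] = sum(
            pa[a] * pr[r] * pure_payoffs(PureProfile(m, a, r), params)[0]
            for a in AgencyStrategy for r in RegulatorStrategy)
    for a in AgencyStrategy:
        U["U2" + ("1" if a is AgencyStrategy.ACCEPT else "2")] = sum(
            pm[m] * pr[r] * pure_payoffs(PureProfile(m, a, r), params)[1]
            for m in ManufacturerStrategy for r in RegulatorStrategy)
    for r in RegulatorStrategy:
        U["U3" + ("1" if r is RegulatorStrategy.STRICT else "2")] = sum(
            pm[m] * pa[a] * pure_payoffs(PureProfile(m, a, r), params)[2]
            for m in ManufacturerStrategy for a in AgencyStrategy)
    return U


@pytest.mark.parametrize("profile, idx, expected", [
    # low-quality maker bribes its way to market under strict supervision:
    # 500 - 30 - 20 - 30 - 10
    (("low_quality", "accept", "strict"), 0, 410.0),
    # honest agency under lax supervision keeps income plus subsidy: 0 + 20
    (("high_quality", "refuse", "strict"), 1, 20.0),
    # regulator with high quality, honest agency, lax supervision: Eg-Se-St
    (("high_quality", "refuse", "lax"), 2, -35.0),
])
def test_payoff_cells_scenario_a(scen_a, profile, idx, expected):
    assert pure_payoffs(PureProfile.make(*profile), scen_a)[idx] == expected


def test_agency_refusal_payoff_is_income_plus_subsidy(valid_sets):
    for p in valid_sets[:20]:
        for r in ("strict", "lax"):
            for m in ("low_quality", "high_quality"):
                got = pure_payoffs(PureProfile.make(m, "refuse", r), p)[1]
                assert got == pytest.approx(p.Et + p.St, abs=1e-12)


def test_all_zero_parameters_zero_payoffs():
    zero = ParameterSet(**{k: 0.0 for k in
                           ("Ee", "Ch", "Cl", "K", "Ve", "Pe", "Se",
                            "Vt", "Pt", "St", "Cr", "Pg")})
    for prof in all_profiles():
        assert pure_payoffs(prof, zero) == (0.0, 0.0, 0.0)


def test_invalid_profile_rejected(scen_a):
    with pytest.raises(ValueError):
        pure_payoffs(("bogus", "accept", "strict"), scen_a)


def test_closed_forms_match_enumeration_oracle(valid_sets, rng):
    """1000 random (params, state) cases: closed form vs enumeration, 1e-12."""
    states = interior_states(rng, len(valid_sets))
    for p, s in zip(valid_sets, states):
        u = expected_utilities(s, p)
        oracle = brute_force_utilities(s, p)
        for key, want in oracle.items():
            assert getattr(u, key) == pytest.approx(want, rel=1e-12, abs=1e-12)


def test_average_utilities_are_mixture_weights(scen_b, rng):
    for s in interior_states(rng, 25):
        u = expected_utilities(s, scen_b)
        x, y, z = s
        assert u.U1bar == pytest.approx(x * u.U11 + (1 - x) * u.U12, rel=1e-14)
        assert u.U2bar == pytest.approx(y * u.U21 + (1 - y) * u.U22, rel=1e-14)
        assert u.U3bar == pytest.approx(z * u.U31 + (1 - z) * u.U32, rel=1e-14)


def test_expected_utility_point_values(scen_a):
    u = expected_utilities((0.5, 0.5, 0.5), scen_a)
    assert u.U11 - u.U12 == pytest.approx(-140.0)
    u0 = expected_utilities((0.0, 0.0, 0.0), scen_a)
    assert u0.U22 == scen_a.Et + scen_a.St
    # y = z = 0: low-quality product never reaches market, no fine either
    assert u0.U11 == pytest.approx(-scen_a.Cl - scen_a.Ve + scen_a.Se)


def test_field_at_cube_centre(scen_a):
    f = replicator_field((0.5, 0.5, 0.5), scen_a)
    assert tuple(f) == pytest.approx((-35.0, -10.625, -19.375))


def test_field_vanishes_at_corners(valid_sets):
    for p in valid_sets[:10]:
        for corner in [(i, j, k) for i in (0, 1) for j in (0, 1) for k in (0, 1)]:
            assert replicator_field(corner, p) == (0.0, 0.0, 0.0)


def test_field_vanishes_on_own_boundary_faces(scen_c, rng):
    for s in interior_states(rng, 10):
        for axis in range(3):
            for val in (0.0, 1.0):
                st = s.copy()
                st[axis] = val
                assert replicator_field(st, scen_c)[axis] == 0.0


def test_field_invariant_to_cancelling_parameters(valid_sets, rng):
    """Et, Eg, Gg cancel from every payoff difference exactly."""
    states = interior_states(rng, 50)
    for p, s in zip(valid_sets[:50], states):
        base = replicator_field(s, p)
        shifted = p.replace(Et=p.Et + 137.5, Eg=p.Eg + 11.0, Gg=p.Gg + 499.0)
        assert replicator_field(s, shifted) == base


def test_zero_parameters_zero_field_everywhere(rng):
    zero = ParameterSet(**{k: 0.0 for k in
                           ("Ee", "Ch", "Cl", "K", "Ve", "Pe", "Se",
                            "Vt", "Pt", "St", "Cr", "Pg")})
    for s in interior_states(rng, 20):
        assert replicator_field(s, zero) == (0.0, 0.0, 0.0)


@pytest.mark.parametrize("state", [(-0.1, 0.5, 0.5), (0.5, 1.2, 0.5),
                                   (0.5, 0.5, np.nan)])
def test_states_outside_cube_rejected(scen_a, state):
    with pytest.raises(ValueError):
        expected_utilities(state, scen_a)
    with pytest.raises(ValueError):
        replicator_field(state, scen_a)
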