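"""Corner equilibria, Jacobian and eigenvalue-based classification.

Independent oracles: a central-finite-difference Jacobian of the field,
a general eigensolver applied to the corner Jacobians, and direct
evaluation of the closed-form stability predicates.
"""

import numpy as np
import pytest

from adrgame import (classify_corner, corner_eigenvalues, corner_points,
                     feasible_ess_corners, integrate, jacobian,
                     replicator_field, stability_report, stable_corners)
from adrgame.stability import CORNER_COORDS, CornerPoint

from conftest import interior_states


def fd_jacobian(state, params, h=1e-6):
    """Oracle: central finite differences of the replicator field."""
    J = np.zeros((3, 3))
    s = np.asarray(state, dtype=float)
    for j in range(3):
        up, dn = s.copy(), s.copy()
        up[j] += h
        dn[j] -= h
        J[:, j] = (np.asarray(replicator_field(up, params))
                   - np.asarray(replicator_field(dn, params))) / (2 * h)
    return J


def test_eight_labelled_corners():
    pts = corner_points()
    assert len(pts) == 8
    assert pts[0].coordinates == (0, 0, 0)
    assert pts[0].label == "E1"
    assert all(c in (0, 1) for p in pts for c in p.coordinates)
    assert [p.label for p in pts] == [f"E{i}" for i in range(1, 9)]


def test_corner_label_coordinate_pairing_enforced():
    with pytest.raises(ValueError):
        CornerPoint("E1", (1, 0, 0))


def test_corner_jacobians_are_diagonal(valid_sets):
    for p in valid_sets[:25]:
        for label, xyz in CORNER_COORDS.items():
            J = jacobian(xyz, p)
            off = J - np.diag(np.diagonal(J))
            assert np.all(off == 0.0)


def test_jacobian_matches_finite_differences(valid_sets, rng):
    """200 random interior cases vs the central-difference oracle, 1e-5."""
    states = interior_states(rng, 200)
    for p, s in zip(valid_sets[:200], states):
        J = jacobian(s, p)
        Jfd = fd_jacobian(s, p)
        np.testing.assert_allclose(J, Jfd, rtol=1e-5, atol=1e-3)


def test_corner_jacobian_diagonal_scenario_a(scen_a):
    J = jacobian((0, 0, 0), scen_a)
    # diagonal entries are Ch-Cl-Ee-Ve, K-Vt, -Cr in (x, y, z) order
    assert np.diagonal(J) == pytest.approx([-370.0, -10.0, -120.0])


def test_eigenvalues_from_general_solver_match_diagonal(valid_sets):
    for p in valid_sets[:25]:
        for label, xyz in CORNER_COORDS.items():
            eig = np.sort(np.real(np.linalg.eigvals(jacobian(xyz, p))))
            np.testing.assert_allclose(
                corner_eigenvalues(label, p), eig, rtol=0, atol=1e-12)


def test_printed_corner_eigenvalues(scen_b, scen_c):
    assert corner_eigenvalues("E5", scen_b) == pytest.approx([-130.0, -60.0, -25.0])
    assert corner_eigenvalues("E8", scen_c) == pytest.approx([-55.0, -10.0, -5.0])


def test_market_capture_eigenvalue_always_positive(valid_sets):
    """E2 carries eigenvalue Cl-Ch+Ee+Ve > 0 whenever Ee > Ch."""
    for p in valid_sets[:100]:
        want = p.Cl - p.Ch + p.Ee + p.Ve
        assert want > 0
        assert np.isclose(corner_eigenvalues("E2", p), want, rtol=1e-12).any()


def test_excluded_corners_never_all_negative(valid_sets):
    for p in valid_sets[:200]:
        assert np.max(corner_eigenvalues("E3", p)) > 0  # Ch-Cl-Ve > 0
        assert np.max(corner_eigenvalues("E6", p)) > 0
        if p.Cr > 0:  # E4 carries eigenvalue Cr
            assert np.isclose(corner_eigenvalues("E4", p), p.Cr,
                              rtol=1e-12).any()
        if p.Pt + p.St + p.Vt > 0:  # E7 carries eigenvalue Pt+St+Vt
            assert np.isclose(corner_eigenvalues("E7", p),
                              p.Pt + p.St + p.Vt, rtol=1e-12).any()


@pytest.mark.parametrize("corner, scen, verdict", [
    ("E1", "a", "stable"),
    ("E5", "a", "unstable"),  # Vt-K = +10 under scenario A
    ("E8", "c", "stable"),
])
def test_classification_examples(request, corner, scen, verdict):
    params = request.getfixturevalue(f"scen_{scen}")
    assert classify_corner(corner, params) == verdict


def test_marginal_verdict_on_zero_eigenvalue(scen_a):
    # Cr=0 makes the z-eigenvalue at E1 exactly zero
    p = scen_a.replace(Cr=0.0)
    assert classify_corner("E1", p) == "marginal"


def test_unique_stable_corner_per_scenario(scen_a, scen_b, scen_c):
    assert stable_corners(scen_a) == ["E1"]
    assert stable_corners(scen_b) == ["E5"]
    assert stable_corners(scen_c) == ["E8"]


def test_report_conditions_match_verdicts(valid_sets):
    """Verdicts for E1/E5/E8 agree with the closed-form predicates."""
    for p in valid_sets[:200]:
        for r in stability_report(p):
            if r.corner in ("E1", "E5", "E8"):
                all_hold = all(c["holds"] for c in r.conditions.values())
                # predicates assume the standing constraints, under which the
                # remaining eigenvalue at each candidate corner is negative
                assert (r.verdict == "stable") == all_hold, (r.corner, p.to_dict())


def test_strict_mode_aborts_on_violation(scen_a):
    bad = scen_a.replace(K=200.0)
    with pytest.raises(ValueError, match="Ch>Cl"):
        stability_report(bad, mode="strict")
    assert len(stability_report(bad, mode="exploratory")) == 8


def test_feasible_ess_corners():
    feasible = feasible_ess_corners(n_samples=1000, seed=42)
    assert feasible == {"E1", "E5", "E8"}


def test_stable_corners_attract_perturbed_starts(scen_a, scen_b, scen_c):
    """Local stability implies the dynamics return from small perturbations."""
    for params in (scen_a, scen_b, scen_c):
        (label,) = stable_corners(params)
        corner = np.asarray(CORNER_COORDS[label], dtype=float)
        start = np.clip(corner + np.where(corner == 0, 0.01, -0.01), 0, 1)
        traj = integrate(start, params)
        assert traj.converged
        assert np.max(np.abs(np.asarray(traj.final_state) - corner)) < 1e-3
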