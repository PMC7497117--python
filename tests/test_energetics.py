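"""Alchemical potentials: soft core, reaction field, Boresch restraints."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from duores.constants import F_COULOMB
from duores.energetics import (
    BoreschRestraints, ElectrostaticsParams, LambdaHamiltonian, SoftCoreParams,
    boresch_energy, boresch_forces, coulomb_rf_energy, coulomb_rf_force,
    lj_energy, lj_force, measure_boresch, read_restraints, softcore_lj,
    softcore_lj_force, wrap_angle, write_restraints,
)
from duores.errors import GeometryError

R_GRID = np.linspace(0.05, 1.5, 60)


# ---------------------------------------------------------------------------
# soft-core Lennard-Jones
# ---------------------------------------------------------------------------

def test_softcore_reduces_to_plain_lj_at_full_coupling():
    u, _ = softcore_lj(R_GRID, 0.3, 0.5, 1.0)
    assert np.allclose(u, lj_energy(R_GRID, 0.3, 0.5), atol=1e-12, rtol=1e-12)


def test_softcore_vanishes_at_zero_coupling():
    u, _ = softcore_lj(R_GRID, 0.3, 0.5, 0.0)
    assert np.all(u == 0.0)


def test_softcore_is_finite_at_contact_for_partial_coupling():
    for lam in (0.1, 0.5, 0.9):
        u, dudl = softcore_lj(0.0, 0.3, 0.5, lam)
        assert np.isfinite(u) and np.isfinite(dudl)


def test_softcore_lambda_derivative_matches_finite_differences():
    h = 1e-6
    for lam in (0.2, 0.5, 0.8):
        _, dudl = softcore_lj(R_GRID, 0.3, 0.5, lam)
        up, _ = softcore_lj(R_GRID, 0.3, 0.5, lam + h)
        um, _ = softcore_lj(R_GRID, 0.3, 0.5, lam - h)
        assert np.allclose(dudl, (up - um) / (2 * h), rtol=1e-5, atol=1e-8)


def test_softcore_radial_force_matches_finite_differences():
    h = 1e-7
    for lam in (0.3, 0.7, 1.0):
        f = softcore_lj_force(R_GRID, 0.3, 0.5, lam)
        up, _ = softcore_lj(R_GRID + h, 0.3, 0.5, lam)
        um, _ = softcore_lj(R_GRID - h, 0.3, 0.5, lam)
        assert np.allclose(f, -(up - um) / (2 * h), rtol=1e-4, atol=1e-5)


def test_softcore_rejects_lambda_outside_unit_interval():
    with pytest.raises(ValueError):
        softcore_lj(0.3, 0.3, 0.5, 1.5)
    with pytest.raises(ValueError):
        softcore_lj(0.3, 0.3, 0.5, -0.1)


def test_softcore_params_validate_shape_parameters():
    with pytest.raises(ValueError):
        SoftCoreParams(alpha=-0.1)
    with pytest.raises(ValueError):
        SoftCoreParams(p=0.0)


def test_plain_lj_force_matches_finite_differences():
    h = 1e-7
    f = lj_force(R_GRID, 0.3, 0.5)
    fd = -(lj_energy(R_GRID + h, 0.3, 0.5) - lj_energy(R_GRID - h, 0.3, 0.5)) / (2 * h)
    assert np.allclose(f, fd, rtol=1e-4, atol=1e-4)


# ---------------------------------------------------------------------------
# reaction-field electrostatics
# ---------------------------------------------------------------------------

def test_reaction_field_constant_matches_formula():
    p = ElectrostaticsParams(eps_rf=80.0, r_cut=1.2)
    assert np.isclose(p.k_rf, (80.0 - 1.0) / ((2 * 80.0 + 1.0) * 1.2 ** 3))
    assert np.isclose(p.c_rf, 1.0 / 1.2 + p.k_rf * 1.2 ** 2)


def test_reaction_field_energy_vanishes_at_cutoff():
    p = ElectrostaticsParams()
    assert abs(coulomb_rf_energy(p.r_cut, 1.0, -1.0, p)) < 1e-12
    assert coulomb_rf_energy(p.r_cut * 1.01, 1.0, -1.0, p) == 0.0


def test_reaction_field_decomposes_into_bare_coulomb_plus_polarization():
    p = ElectrostaticsParams()
    r = np.linspace(0.05, 1.2, 30)
    u = coulomb_rf_energy(r, 1.0, 1.0, p)
    bare = F_COULOMB / r
    polarization = F_COULOMB * (p.k_rf * r ** 2 - p.c_rf)
    assert np.allclose(u, bare + polarization, rtol=1e-12)


def test_reaction_field_force_matches_finite_differences():
    p = ElectrostaticsParams()
    h = 1e-7
    r = np.linspace(0.1, 1.1, 40)
    f = coulomb_rf_force(r, 0.5, -0.8, p)
    fd = -(coulomb_rf_energy(r + h, 0.5, -0.8, p)
           - coulomb_rf_energy(r - h, 0.5, -0.8, p)) / (2 * h)
    assert np.allclose(f, fd, rtol=1e-4, atol=1e-6)


# ---------------------------------------------------------------------------
# Boresch restraints
# ---------------------------------------------------------------------------

@pytest.fixture()
def pose(rng):
    coords = np.array([
        [0.0, 0.0, 0.0],    # P1
        [0.4, 0.1, 0.0],    # P2
        [0.7, 0.0, 0.3],    # P3
        [-0.3, 0.4, 0.2],   # L1
        [-0.6, 0.5, 0.0],   # L2
        [-0.8, 0.2, 0.4],   # L3
    ])
    restraints = BoreschRestraints.from_configuration(
        coords, protein_anchors=(0, 1, 2), ligand_anchors=(3, 4, 5))
    return coords, restraints


def test_boresch_energy_is_zero_at_the_reference_pose(pose):
    coords, restraints = pose
    assert boresch_energy(coords, restraints, 1.0) == pytest.approx(0.0, abs=1e-18)
    assert np.allclose(boresch_forces(coords, restraints, 1.0), 0.0, atol=1e-9)


def test_boresch_energy_scales_linearly_with_lambda(pose, rng):
    coords, restraints = pose
    x = coords + rng.normal(scale=0.03, size=coords.shape)
    full = boresch_energy(x, restraints, 1.0)
    assert full > 0.0
    assert np.isclose(boresch_energy(x, restraints, 0.4), 0.4 * full)
    assert boresch_energy(x, restraints, 0.0) == 0.0


def test_boresch_forces_match_finite_differences(pose, rng):
    coords, restraints = pose
    x = coords + rng.normal(scale=0.04, size=coords.shape)
    f = boresch_forces(x, restraints, 0.8)
    h = 1e-6
    for atom in range(6):
        for axis in range(3):
            dp = np.zeros_like(x)
            dp[atom, axis] = h
            fd = -(boresch_energy(x + dp, restraints, 0.8)
                   - boresch_energy(x - dp, restraints, 0.8)) / (2 * h)
            assert np.isclose(f[atom, axis], fd, rtol=1e-4, atol=1e-6)


def test_boresch_energy_invariant_under_rigid_motion(pose, rng):
    coords, restraints = pose
    x = coords + rng.normal(scale=0.03, size=coords.shape)
    e0 = boresch_energy(x, restraints, 1.0)
    rot = Rotation.random(random_state=3).as_matrix()
    moved = x @ rot.T + np.array([1.2, -0.7, 0.4])
    assert np.isclose(boresch_energy(moved, restraints, 1.0), e0, rtol=1e-10)


def test_measured_coordinates_match_reference_at_build_pose(pose):
    coords, restraints = pose
    x = measure_boresch(coords, restraints)
    x0 = np.array([restraints.r0, restraints.theta_a0, restraints.theta_b0,
                   restraints.phi_a0, restraints.phi_b0, restraints.phi_c0])
    assert np.allclose(x, x0, atol=1e-12)


def test_dihedral_deviation_is_wrapped_across_the_branch_cut():
    assert np.isclose(wrap_angle(np.pi + 0.1), -np.pi + 0.1)
    assert np.isclose(wrap_angle(-np.pi - 0.1), np.pi - 0.1)
    assert np.isclose(wrap_angle(0.3), 0.3)
    assert np.allclose(wrap_angle(np.array([2 * np.pi, -2 * np.pi])), 0.0,
                       atol=1e-12)


def test_boresch_rejects_degenerate_configurations(pose):
    coords, _ = pose
    collinear = coords.copy()
    collinear[:3] = [[0, 0, 0], [0.4, 0, 0], [0.8, 0, 0]]
    with pytest.raises(GeometryError):
        BoreschRestraints.from_configuration(collinear, (0, 1, 2), (3, 4, 5))
    with pytest.raises(ValueError):
        BoreschRestraints.from_configuration(coords, (0, 1, 2), (2, 4, 5))


def test_restraint_definition_round_trip(tmp_path, pose):
    _, restraints = pose
    path = tmp_path / "restraints.txt"
    write_restraints(restraints, path)
    back = read_restraints(path)
    assert back.protein_anchors == restraints.protein_anchors
    assert back.ligand_anchors == restraints.ligand_anchors
    assert np.allclose(back.force_constants, restraints.force_constants)
    assert np.isclose(back.r0, restraints.r0)
    assert np.isclose(back.phi_c0, restraints.phi_c0)


# ---------------------------------------------------------------------------
# composite lambda Hamiltonian
# ---------------------------------------------------------------------------

def test_linear_mix_derivative_is_state_difference(rng):
    u_a = lambda x: float(np.sum(x ** 2))
    u_b = lambda x: float(np.sum((x - 1.0) ** 2))
    h = LambdaHamiltonian.linear_mix(u_a, u_b, lam=0.3)
    x = rng.normal(size=4)
    assert np.isclose(h.energy(x), 0.3 * u_a(x) + 0.7 * u_b(x))
    assert np.isclose(h.du_dlambda(x), u_a(x) - u_b(x))
    h.lam = 1.0
    assert np.isclose(h.energy(x), u_a(x))
    with pytest.raises(ValueError):
        h.lam = 1.2
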