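"""Drivetrain equations of motion, forces and linearized eigenanalysis."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import flapsim as fs
from flapsim.model import (
    StateVector,
    coupled_mass_matrix,
    eom_rhs,
    muscle_force,
    nonconservative_forces,
)
from flapsim.wing import ParameterError

finite = st.floats(
    min_value=-1.0, max_value=1.0, allow_nan=False, allow_infinity=False
)


def drag_power(state, config):
    """Generalized drag power (F_NC - F) xdot + 2 sum Q_k qdot_k."""
    F_nc, Q_nc = nonconservative_forces(0.0, state, config)
    drag = F_nc - muscle_force(0.0, config.drive)
    return drag * state.xdot + 2.0 * float(Q_nc @ state.qdot)


def test_muscle_force_harmonic(default_cfg):
    drive = default_cfg.drive
    T = drive.period
    assert muscle_force(0.0, drive) == 0.0
    assert muscle_force(T / 4, drive) == pytest.approx(1.5, rel=1e-12)
    assert abs(muscle_force(T / 2, drive)) < 1e-12


def test_rigid_effective_mass_matches_arithmetic(default_cfg):
    M = coupled_mass_matrix(default_cfg.rigid())
    expected = 0.7e-3 + 2 * (50e-6 * 0.05**2 / 3) / (0.8e-3) ** 2
    assert M.shape == (1, 1)
    assert M[0, 0] == pytest.approx(expected, rel=1e-12)
    assert M[0, 0] == pytest.approx(0.1309, rel=1e-3)


def test_mass_matrix_decouples_at_large_transmission(default_cfg):
    huge = replace(default_cfg, transmission=fs.Transmission(1e6))
    M = coupled_mass_matrix(huge)
    assert M[0, 0] == pytest.approx(default_cfg.thorax.mass, rel=1e-9)
    assert abs(M[0, 1]) < 1e-9 and abs(M[1, 0]) < 1e-9
    assert M[1, 1] == 1.0


def test_coupled_mass_matrix_is_invertible(default_cfg):
    M = coupled_mass_matrix(default_cfg)
    assert np.linalg.det(M) > 0


def test_aero_force_needs_motion(default_cfg):
    state = StateVector(x=1e-3, xdot=0.0, q=np.array([1e-4]), qdot=np.array([0.0]))
    total, rigid, elastic = fs.aero_surface_force(state, default_cfg)
    assert total == 0 and rigid == 0 and elastic == 0


def test_aero_force_odd_in_velocity(default_cfg):
    state = StateVector(x=0.0, xdot=0.07, q=np.array([2e-5]), qdot=np.array([5e-3]))
    flipped = StateVector(x=0.0, xdot=-0.07, q=np.array([2e-5]), qdot=np.array([-5e-3]))
    f = fs.aero_surface_force(state, default_cfg)
    g = fs.aero_surface_force(flipped, default_cfg)
    assert np.allclose(f, [-v for v in g], rtol=1e-14)


def test_nonconservative_forces_without_fluid(default_cfg):
    dry = replace(default_cfg, aero=fs.AeroEnv(0.0, 0.0))
    state = StateVector(x=1e-3, xdot=0.1, q=np.array([1e-4]), qdot=np.array([0.5]))
    t = 0.013
    F_nc, Q_nc = nonconservative_forces(t, state, dry)
    assert F_nc == pytest.approx(muscle_force(t, dry.drive), rel=1e-14)
    assert np.all(Q_nc == 0)


def test_modal_drag_vanishes_without_stroke_velocity(default_cfg):
    """Both modal drag terms carry the rigid-body angular velocity factor."""
    state = StateVector(x=1e-3, xdot=0.0, q=np.array([1e-4]), qdot=np.array([0.9]))
    t = 0.003
    F_nc, Q_nc = nonconservative_forces(t, state, default_cfg)
    assert np.all(Q_nc == 0)
    assert F_nc == pytest.approx(muscle_force(t, default_cfg.drive), rel=1e-14)


def test_equilibrium_state_has_zero_derivative(default_cfg):
    d = eom_rhs(0.0, np.zeros(4), default_cfg)
    assert np.all(d == 0)


def test_free_rigid_oscillator_acceleration(default_cfg):
    free = replace(
        default_cfg.rigid(),
        drive=fs.Drive(0.0, 25.0),
        aero=fs.AeroEnv(0.0, 0.0),
    )
    x0 = 2e-3
    d = eom_rhs(0.0, [x0, 0.0], free)
    m_eff = free.effective_mass
    assert d[0] == 0.0
    assert d[1] == pytest.approx(-free.thorax.stiffness * x0 / m_eff, rel=1e-12)


def test_modal_restoring_force_against_2x2_inverse(default_cfg):
    """Unit modal displacement at rest: accelerations solve M a = [0, -w1^2 q]."""
    cfg = replace(default_cfg, drive=fs.Drive(0.0, 25.0), aero=fs.AeroEnv(0.0, 0.0))
    q1 = 1.0e-4
    d = eom_rhs(0.0, [0.0, 0.0, q1, 0.0], cfg)
    M = coupled_mass_matrix(cfg)
    rhs = np.array([0.0, -cfg.basis.omega[0] ** 2 * q1])
    expected = np.linalg.solve(M, rhs)
    assert d[1] == pytest.approx(expected[0], rel=1e-10)
    assert d[3] == pytest.approx(expected[1], rel=1e-10)


def test_linearized_frequencies(default_cfg):
    rws = fs.linearized_natural_frequencies(default_cfg.rigid())
    assert rws[0] == pytest.approx(23.483, abs=0.01)
    fws = fs.linearized_natural_frequencies(default_cfg)
    assert fws[0] == pytest.approx(21.91, abs=0.02)
    assert fws[0] < rws[0]


def test_linearized_frequencies_decouple_without_coupling(default_cfg):
    basis = replace(default_cfg.basis, lam=np.zeros(1))
    decoupled = replace(default_cfg, basis=basis)
    freqs = fs.linearized_natural_frequencies(decoupled)
    rws = fs.linearized_natural_frequencies(default_cfg.rigid())[0]
    assert freqs[0] == pytest.approx(rws, rel=1e-10)
    assert freqs[1] == pytest.approx(default_cfg.basis.frequencies_hz[0], rel=1e-10)


from functools import lru_cache


@lru_cache(maxsize=1)
def _cached_cfg():
    return fs.default_config()[0]


@settings(max_examples=200, deadline=None)
@given(xdot=finite, q=finite, qdot=finite)
def test_drag_power_is_dissipative(xdot, q, qdot):
    """The generalized drag never injects energy, on either half-stroke."""
    cfg = _cached_cfg()
    state = StateVector(
        x=0.0, xdot=0.2 * xdot,
        q=np.array([1e-3 * q]), qdot=np.array([0.5 * qdot]),
    )
    assert drag_power(state, cfg) <= 1e-18


def test_state_vector_round_trip(default_cfg):
    s = StateVector.from_array([1e-3, 0.1, 2e-5, 0.3], n_modes=1)
    assert np.allclose(s.to_array(), [1e-3, 0.1, 2e-5, 0.3])
    assert s.theta(default_cfg.transmission) == pytest.approx(1e-3 / 0.8e-3)
    with pytest.raises(ParameterError):
        StateVector.from_array([0.0, 0.0, 0.0], n_modes=1)


def test_parameter_validation():
    with pytest.raises(ParameterError):
        fs.ThoraxParams(mass=0.0, stiffness=2850.0)
    with pytest.raises(ParameterError):
        fs.Transmission(-0.8e-3)
    with pytest.raises(ParameterError):
        fs.AeroEnv(drag_coefficient=-1.0)
    with pytest.raises(ParameterError):
        fs.Drive(amplitude=1.5, frequency=0.0)
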