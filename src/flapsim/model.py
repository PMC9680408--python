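"""Coupled thorax--wing drivetrain: parameters, forces and equations of motion.

The thorax is a sprung mass (effective mass ``m``, stiffness ``k``) driven by
the harmonic indirect-flight-muscle force ``F(t) = F0 sin(2 pi f t)``.  Its
displacement ``x`` maps to the rigid-body wing rotation through the linear
hinge transmission ``x = Gamma theta``.  Two wings flap and deform
symmetrically, so a single set of modal coordinates ``q_k`` describes both.

Generalized coordinates are ``[x, q_1 ... q_K]``; the state vector is
``[x, xdot, q_1..q_K, qdot_1..qdot_K]``.  The coupled equations are

    (m + 2 I_O / Gamma^2) xddot + (2/Gamma) sum_k lambda_k qddot_k + k x = F_NC
    (lambda_k / Gamma) xddot + qddot_k + (omega_k^2 - xdot^2/Gamma^2) q_k = Q_NC_k

with quasi-steady blade-element drag entering the non-conservative forces.
Even powers of velocity in the printed drag law are implemented sign-correctly
as ``|v| v`` so the drag always opposes the normal velocity on both
half-strokes; this is the only reading under which the generalized drag power
is non-positive for every state (the quadratic form ``theta_dot^2 J3 +
2 theta_dot qdot J2 + 4 qdot J1 qdot`` is pointwise ``(theta_dot y + W_dot)^2
+ 3 W_dot^2 >= 0`` under the surface integral).

The ``omega_k^2 - xdot^2/Gamma^2`` spin-softening stiffness is retained
exactly as the model states it, without the conjugate convective terms in the
thorax equation; consequences for energy bookkeeping are handled in
:mod:`flapsim.energetics`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import eig

from .wing import ParameterError, WingGeometry, WingModalBasis, build_modal_basis

__all__ = [
    "ThoraxParams",
    "Transmission",
    "AeroEnv",
    "Drive",
    "SystemConfig",
    "StateVector",
    "muscle_force",
    "coupled_mass_matrix",
    "aero_surface_force",
    "nonconservative_forces",
    "eom_rhs",
    "make_rhs",
    "trajectory_accelerations",
    "linearized_natural_frequencies",
]


@dataclass(frozen=True)
class ThoraxParams:
    """Effective thorax mass (kg) and stiffness (N/m)."""

    mass: float
    stiffness: float

    def __post_init__(self):
        if not (self.mass > 0 and self.stiffness > 0):
            raise ParameterError("thorax mass and stiffness must be positive")


@dataclass(frozen=True)
class Transmission:
    """Linear wing-hinge transmission ratio Gamma (m of thorax travel per rad)."""

    ratio: float

    def __post_init__(self):
        if not self.ratio > 0:
            raise ParameterError("transmission ratio must be positive")


@dataclass(frozen=True)
class AeroEnv:
    """Drag coefficient (dimensionless) and fluid density (kg/m^3).

    ``drag_coefficient = 0`` switches the fluid off, which is useful for
    conservative-system tests.
    """

    drag_coefficient: float = 3.0
    fluid_density: float = 1.25

    def __post_init__(self):
        if self.drag_coefficient < 0 or self.fluid_density < 0:
            raise ParameterError("drag coefficient and density must be >= 0")


@dataclass(frozen=True)
class Drive:
    """Harmonic muscle drive: amplitude F0 (N) and frequency f (Hz)."""

    amplitude: float = 1.5
    frequency: float = 25.0

    def __post_init__(self):
        if self.amplitude < 0 or not self.frequency > 0:
            raise ParameterError("drive needs F0 >= 0 and f > 0")

    @property
    def period(self) -> float:
        return 1.0 / self.frequency

    @property
    def omega(self) -> float:
        return 2.0 * np.pi * self.frequency


def _hawkmoth_wing() -> WingGeometry:
    return WingGeometry(length=0.05, chord=0.018, thickness=50e-6, mass=50e-6)


@dataclass(frozen=True)
class SystemConfig:
    """Full parameter bundle for one simulation.

    ``basis.n_modes == 0`` is the rigid-wing system (RWS); any retained mode
    makes it the flexible-wing system (FWS).  Defaults are hawkmoth-like.
    """

    thorax: ThoraxParams = field(
        default_factory=lambda: ThoraxParams(mass=0.7e-3, stiffness=2850.0)
    )
    transmission: Transmission = field(default_factory=lambda: Transmission(0.8e-3))
    aero: AeroEnv = field(default_factory=AeroEnv)
    drive: Drive = field(default_factory=Drive)
    wing: WingGeometry = field(default_factory=_hawkmoth_wing)
    basis: WingModalBasis = None

    def __post_init__(self):
        if self.basis is None:
            object.__setattr__(
                self,
                "basis",
                build_modal_basis(
                    self.wing, flap_frequency_hz=self.drive.frequency
                ),
            )

    @property
    def flexible(self) -> bool:
        return self.basis.n_modes > 0

    @property
    def n_modes(self) -> int:
        return self.basis.n_modes

    @property
    def effective_mass(self) -> float:
        """Thorax-frame inertia m + 2 I_O / Gamma^2 of the two rigid wings."""
        return self.thorax.mass + 2.0 * self.wing.inertia / self.transmission.ratio**2

    def rigid(self) -> "SystemConfig":
        """The rigid-wing variant of this configuration (all modes dropped)."""
        empty = replace(
            self.basis,
            omega=self.basis.omega[:0],
            shapes=self.basis.shapes[:0],
            slopes=self.basis.slopes[:0],
            lam=self.basis.lam[:0],
            J2=self.basis.J2[:0],
            J1=self.basis.J1[:0, :0],
        )
        return replace(self, basis=empty)


@dataclass
class StateVector:
    """State ``[x, xdot, q, qdot]`` with transmission-derived quantities."""

    x: float
    xdot: float
    q: np.ndarray
    qdot: np.ndarray

    @classmethod
    def from_array(cls, arr, n_modes: int) -> "StateVector":
        arr = np.asarray(arr, dtype=float)
        if len(arr) != 2 + 2 * n_modes:
            raise ParameterError("state vector length must be 2 + 2K")
        return cls(
            x=arr[0], xdot=arr[1],
            q=arr[2:2 + n_modes].copy(), qdot=arr[2 + n_modes:].copy(),
        )

    def to_array(self) -> np.ndarray:
        return np.concatenate(([self.x, self.xdot], self.q, self.qdot))

    def theta(self, transmission: Transmission) -> float:
        return self.x / transmission.ratio

    def thetadot(self, transmission: Transmission) -> float:
        return self.xdot / transmission.ratio

    def deflection(self, basis: WingModalBasis, y) -> np.ndarray:
        """Elastic wing deflection W(y) = sum_k phi_k(y) q_k."""
        out = np.zeros_like(np.asarray(y, dtype=float))
        for k in range(basis.n_modes):
            out = out + basis.phi(y, k) * self.q[k]
        return out


# ---------------------------------------------------------------------------
# Forces
# ---------------------------------------------------------------------------

def muscle_force(t, drive: Drive):
    """Harmonic indirect-flight-muscle force F0 sin(2 pi f t)."""
    return drive.amplitude * np.sin(drive.omega * np.asarray(t, dtype=float))


def coupled_mass_matrix(config: SystemConfig) -> np.ndarray:
    """Constant (1+K)x(1+K) mass matrix of the coupled equations.

    Row 0 carries the factor-2 of two symmetric wings driving one thorax
    coordinate; rows k >= 1 are the per-wing modal equations, so the matrix
    is deliberately non-symmetric.
    """
    K = config.n_modes
    G = config.transmission.ratio
    M = np.eye(1 + K)
    M[0, 0] = config.effective_mass
    if K:
        M[0, 1:] = 2.0 * config.basis.lam / G
        M[1:, 0] = config.basis.lam / G
    if abs(np.linalg.det(M)) < 1e-300:
        raise ParameterError("coupled mass matrix is singular: nonphysical parameters")
    return M


def aero_surface_force(state: StateVector, config: SystemConfig):
    """Two-wing blade-element drag and its rigid/elastic decomposition (N).

    Per wing the rigid-rotation component is
    ``-(1/2) C_D rho |thetadot| thetadot int_S y^2 dS`` and the elastic
    component ``-C_D rho |thetadot| sum_k qdot_k int_S y phi_k dS``; totals
    are doubled for the two wings.  Accepts scalar or array-valued states.
    """
    geom, aero = config.wing, config.aero
    G = config.transmission.ratio
    thetadot = np.asarray(state.xdot, dtype=float) / G
    coeff = aero.drag_coefficient * aero.fluid_density
    y2_moment = geom.chord * geom.length**3 / 3.0   # int_S y^2 dS
    rigid = -0.5 * coeff * np.abs(thetadot) * thetadot * y2_moment
    elastic = np.zeros_like(rigid)
    if config.n_modes:
        # int_S y phi_k dS = w int y phi_k dy = w lambda_k / mu (uniform wing)
        y_phi = config.basis.lam * geom.chord / geom.mu
        qdot = np.asarray(state.qdot, dtype=float)
        elastic = -coeff * np.abs(thetadot) * np.tensordot(
            y_phi, qdot.reshape(config.n_modes, -1), axes=(0, 0)
        ).reshape(np.shape(rigid))
    total = 2.0 * (rigid + elastic)
    return total, 2.0 * rigid, 2.0 * elastic


def nonconservative_forces(t, state: StateVector, config: SystemConfig):
    """Generalized non-conservative forces (F_NC on x, Q_NC on each q_k).

    F_NC already contains both wings (the wing count cancels the 1/2 of the
    blade-element law); Q_NC is the printed two-wing generalized force paired
    with the per-wing modal equation, matching the source dynamics.
    """
    aero = config.aero
    G = config.transmission.ratio
    xd = state.xdot
    coeff = aero.drag_coefficient * aero.fluid_density
    F_nc = muscle_force(t, config.drive) - coeff * abs(xd) * xd / G**3 * config.basis.J3
    K = config.n_modes
    if K == 0:
        return F_nc, np.zeros(0)
    Q_nc = (
        -coeff * abs(xd) * xd / G**2 * config.basis.J2
        - 2.0 * coeff * abs(xd) / G * (config.basis.J1 @ state.qdot)
    )
    return F_nc, Q_nc


# ---------------------------------------------------------------------------
# Equations of motion
# ---------------------------------------------------------------------------

def make_rhs(config: SystemConfig):
    """Build a fast closure computing the state derivative.

    The constant mass matrix is inverted once.  K = 0 and K = 1 use scalar
    arithmetic (these are the production cases); general K falls back to
    vectorized numpy.
    """
    K = config.n_modes
    k_th = config.thorax.stiffness
    G = config.transmission.ratio
    coeff = config.aero.drag_coefficient * config.aero.fluid_density
    F0, om_drive = config.drive.amplitude, config.drive.omega
    J3 = config.basis.J3 if config.basis.J3 is not None else (
        config.wing.chord * config.wing.length**4 / 4.0
    )
    m_eff = config.effective_mass
    cJ3 = coeff * J3 / G**3
    from math import sin  # scalar-fast in the hot loop

    if K == 0:
        inv_m = 1.0 / m_eff

        def rhs(t, s):
            x, xd = s.tolist() if isinstance(s, np.ndarray) else s
            F_nc = F0 * sin(om_drive * t) - cJ3 * abs(xd) * xd
            return (xd, (F_nc - k_th * x) * inv_m)

        return rhs

    Mi = np.linalg.inv(coupled_mass_matrix(config))
    om2 = config.basis.omega**2
    J2 = config.basis.J2
    J1 = config.basis.J1
    cJ2 = coeff * J2 / G**2
    cJ1 = 2.0 * coeff * J1 / G
    inv_G2 = 1.0 / G**2

    if K == 1:
        a00, a01, a10, a11 = Mi[0, 0], Mi[0, 1], Mi[1, 0], Mi[1, 1]
        cJ2s, cJ1s, om2s = cJ2[0], cJ1[0, 0], om2[0]

        def rhs(t, s):
            x, xd, q, qd = s.tolist() if isinstance(s, np.ndarray) else s
            axd = abs(xd)
            F_nc = F0 * sin(om_drive * t) - cJ3 * axd * xd
            Q_nc = -cJ2s * axd * xd - cJ1s * axd * qd
            r0 = F_nc - k_th * x
            r1 = Q_nc - (om2s - xd * xd * inv_G2) * q
            return (xd, a00 * r0 + a01 * r1, qd, a10 * r0 + a11 * r1)

        return rhs

    def rhs(t, s):
        x, xd = float(s[0]), float(s[1])
        q = s[2:2 + K]
        qd = s[2 + K:]
        axd = abs(xd)
        F_nc = F0 * sin(om_drive * t) - cJ3 * axd * xd
        Q_nc = -cJ2 * axd * xd - axd * (cJ1 @ qd)
        r = np.empty(1 + K)
        r[0] = F_nc - k_th * x
        r[1:] = Q_nc - (om2 - xd * xd * inv_G2) * q
        acc = Mi @ r
        out = np.empty(2 + 2 * K)
        out[0] = xd
        out[1] = acc[0]
        out[2:2 + K] = qd
        out[2 + K:] = acc[1:]
        return out

    return rhs


def eom_rhs(t, state, config: SystemConfig):
    """State derivative of the coupled equations at one instant.

    ``state`` may be a :class:`StateVector` or a flat array
    ``[x, xdot, q, qdot]``.
    """
    if isinstance(state, StateVector):
        state = state.to_array()
    out = make_rhs(config)(t, np.asarray(state, dtype=float))
    return np.asarray(out, dtype=float)


def trajectory_accelerations(t, x, xd, q, qd, config: SystemConfig):
    """Vectorized (xddot, qddot) along a sampled trajectory.

    ``q``/``qdot`` have shape (K, n_samples).  Used by the energetics module
    when evaluating the spin-softening power channel.
    """
    K = config.n_modes
    G = config.transmission.ratio
    coeff = config.aero.drag_coefficient * config.aero.fluid_density
    Mi = np.linalg.inv(coupled_mass_matrix(config))
    F_nc = muscle_force(t, config.drive) - coeff * np.abs(xd) * xd / G**3 * config.basis.J3
    rows = [F_nc - config.thorax.stiffness * x]
    for kk in range(K):
        Q_nc = (
            -coeff * np.abs(xd) * xd / G**2 * config.basis.J2[kk]
            - 2.0 * coeff * np.abs(xd) / G * (config.basis.J1[kk] @ qd)
        )
        rows.append(Q_nc - (config.basis.omega[kk]**2 - xd**2 / G**2) * q[kk])
    acc = Mi @ np.vstack(rows)
    return acc[0], acc[1:]


def linearized_natural_frequencies(config: SystemConfig) -> np.ndarray:
    """Undamped, unforced natural frequencies (Hz, ascending).

    Drops the aerodynamic terms and the xdot^2 spin softening, leaving the
    generalized problem det(K_lin - omega^2 M) = 0 with
    K_lin = diag(k, omega_1^2, ..) and the coupled mass matrix.
    """
    M = coupled_mass_matrix(config)
    K_lin = np.diag(
        np.concatenate(([config.thorax.stiffness], config.basis.omega**2))
    )
    vals = eig(K_lin, M)[0]
    vals = np.sort(np.real(vals))
    return np.sqrt(np.clip(vals, 0.0, None)) / (2.0 * np.pi)
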