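"""Power and energy observables of the coupled wing--thorax system.

The applied (muscle) power is ``P_F = F(t) xdot`` and the per-wingbeat input
energy is the rectified integral ``E_in = int |P_F| dt`` over one steady
wingbeat.  Potential energy splits into the thorax spring ``(1/2) k x^2`` and
the wings' modal elastic energy ``2 * (1/2) sum_k omega_k^2 q_k^2`` (both
wings; mass-normalized modes make the modal stiffness ``omega_k^2``).
Kinetic energy uses the full wing quadratic form, including the centrifugal
``(xdot/Gamma)^2 sum_k q_k^2`` term, as an observable for balance tests.

Energy-ledger subtlety: the governing equations retain the spin-softening
modal stiffness ``omega_k^2 - xdot^2/Gamma^2`` without the conjugate
convective terms in the thorax equation.  The truncated dynamics are
therefore *not* conservative when undamped; the residual power is exactly

    P_soft = 4 (xdot^2/Gamma^2) sum_k q_k qdot_k
             + 2 (xdot xddot/Gamma^2) sum_k q_k^2

and the balance d(T+U)/dt = P_F + P_aero + P_soft closes to quadrature
accuracy.  :func:`energy_balance_residual` verifies this identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import (
    SystemConfig,
    muscle_force,
    trajectory_accelerations,
)
from .wing import ParameterError

__all__ = [
    "EnergyBreakdown",
    "applied_power",
    "input_energy_per_wingbeat",
    "potential_energies",
    "kinetic_energies",
    "aero_power",
    "softening_power",
    "energy_balance_residual",
    "energy_ratio",
]


@dataclass
class EnergyBreakdown:
    """Energy time series (J, W) plus per-wingbeat scalars."""

    time: np.ndarray
    applied_power_w: np.ndarray = None
    pe_thorax_j: np.ndarray = None
    pe_wing_j: np.ndarray = None
    pe_total_j: np.ndarray = None
    ke_thorax_j: np.ndarray = None
    ke_wing_j: np.ndarray = None
    e_in_j: float = np.nan
    pe_max_j: float = np.nan
    pe_min_j: float = np.nan
    pe_recovered_j: float = np.nan
    pe_thorax_frac: float = np.nan
    pe_wing_frac: float = np.nan


def applied_power(result) -> np.ndarray:
    """Instantaneous muscle power P_F(t) = F(t) xdot (W)."""
    return muscle_force(result.time, result.config.drive) * result.xdot


def input_energy_per_wingbeat(power, drive, time) -> float:
    """Rectified input energy over the last complete wingbeat (J).

    Trapezoidal integral of |P_F| over exactly one drive period, taken at
    the end of the supplied window.
    """
    power = np.asarray(power, dtype=float)
    time = np.asarray(time, dtype=float)
    T = drive.period
    if time[-1] - time[0] < T * (1 - 1e-9):
        raise ParameterError("window must span at least one full wingbeat")
    mask = time >= time[-1] - T * (1 + 1e-12)
    return float(np.trapezoid(np.abs(power[mask]), time[mask]))


def potential_energies(result, config: SystemConfig) -> EnergyBreakdown:
    """Thorax, wing and total potential energy over the window.

    The component split fractions are defined from each component's peak
    stored energy over the window (its storage), normalized by the sum of
    the two peaks; the instantaneous split is available from the series.
    """
    pe_thorax = 0.5 * config.thorax.stiffness * result.x**2
    if config.n_modes:
        pe_wing = (config.basis.omega**2) @ (result.q**2)  # 2 wings x 1/2
    else:
        pe_wing = np.zeros_like(result.x)
    pe_total = pe_thorax + pe_wing
    peak_th, peak_w = pe_thorax.max(), pe_wing.max()
    denom = peak_th + peak_w
    return EnergyBreakdown(
        time=result.time,
        pe_thorax_j=pe_thorax,
        pe_wing_j=pe_wing,
        pe_total_j=pe_total,
        pe_max_j=float(pe_total.max()),
        pe_min_j=float(pe_total.min()),
        pe_recovered_j=float(pe_total.max() - pe_total.min()),
        pe_thorax_frac=float(peak_th / denom) if denom > 0 else np.nan,
        pe_wing_frac=float(peak_w / denom) if denom > 0 else np.nan,
    )


def kinetic_energies(result, config: SystemConfig) -> EnergyBreakdown:
    """Thorax and two-wing kinetic energy (full quadratic form) over the window."""
    G = config.transmission.ratio
    ke_thorax = 0.5 * config.thorax.mass * result.xdot**2
    thetadot2 = (result.xdot / G) ** 2
    ke_wing = thetadot2 * config.wing.inertia  # 2 wings x 1/2 I_O thetadot^2
    if config.n_modes:
        ke_wing = (
            ke_wing
            + thetadot2 * np.sum(result.q**2, axis=0)
            + 2.0 * (result.xdot / G) * (config.basis.lam @ result.qdot)
            + np.sum(result.qdot**2, axis=0)
        )
    return EnergyBreakdown(
        time=result.time,
        ke_thorax_j=ke_thorax,
        ke_wing_j=ke_wing,
    )


def aero_power(result, config: SystemConfig | None = None) -> np.ndarray:
    """Generalized aerodynamic (drag) power along the trajectory (W).

    ``(F_NC - F) xdot + 2 sum_k Q_NC_k qdot_k`` with the two-wing
    bookkeeping of the equations of motion; non-positive at every state for
    the sign-corrected drag law.
    """
    config = config or result.config
    G = config.transmission.ratio
    coeff = config.aero.drag_coefficient * config.aero.fluid_density
    xd = result.xdot
    p = -coeff * np.abs(xd) * xd**2 / G**3 * config.basis.J3
    for kk in range(config.n_modes):
        Q_k = (
            -coeff * np.abs(xd) * xd / G**2 * config.basis.J2[kk]
            - 2.0 * coeff * np.abs(xd) / G * (config.basis.J1[kk] @ result.qdot)
        )
        p = p + 2.0 * Q_k * result.qdot[kk]
    return p


def softening_power(result, config: SystemConfig | None = None) -> np.ndarray:
    """Spin-softening residual power channel of the truncated dynamics (W)."""
    config = config or result.config
    if config.n_modes == 0:
        return np.zeros_like(result.time)
    G = config.transmission.ratio
    xdd, _ = trajectory_accelerations(
        result.time, result.x, result.xdot, result.q, result.qdot, config
    )
    q2 = np.sum(result.q**2, axis=0)
    qqd = np.sum(result.q * result.qdot, axis=0)
    return 4.0 * (result.xdot**2 / G**2) * qqd + 2.0 * (result.xdot * xdd / G**2) * q2


def energy_balance_residual(
    result, n_tail_wingbeats: int = 10, samples_per_wingbeat: int = 1000
) -> float:
    """Relative energy-balance closure over the steady window.

    Re-samples the dense solution at ``samples_per_wingbeat`` and compares
    the change of total mechanical energy against the integrated applied,
    aerodynamic and spin-softening powers, normalized by E_in.
    """
    from .simulate import SimResult

    config = result.config
    T = config.drive.period
    n = result.n_wingbeats
    t = (n - n_tail_wingbeats) * T + np.arange(
        n_tail_wingbeats * samples_per_wingbeat + 1
    ) * (T / samples_per_wingbeat)
    K = config.n_modes
    states = result.dense(t)
    fine = SimResult(
        time=t,
        x=states[0],
        xdot=states[1],
        q=states[2:2 + K],
        qdot=states[2 + K:],
        config=config,
        samples_per_wingbeat=samples_per_wingbeat,
    )
    pe = potential_energies(fine, config)
    ke = kinetic_energies(fine, config)
    total = pe.pe_total_j + ke.ke_thorax_j + ke.ke_wing_j
    p_sum = applied_power(fine) + aero_power(fine) + softening_power(fine)
    e_in = input_energy_per_wingbeat(applied_power(fine), config.drive, t)
    scale = e_in if e_in > 0 else max(np.max(np.abs(total)), 1e-300)
    worst = 0.0
    for b in range(n_tail_wingbeats):
        sl = slice(b * samples_per_wingbeat, (b + 1) * samples_per_wingbeat + 1)
        d_energy = total[sl][-1] - total[sl][0]
        balance = float(np.trapezoid(p_sum[sl], t[sl]))
        worst = max(worst, abs(d_energy - balance) / scale)
    return worst


def energy_ratio(e_fws: float, e_rws: float) -> float:
    """Per-wingbeat FWS/RWS input-energy ratio; < 1 favors wing flexibility."""
    if e_rws == 0:
        raise ParameterError("rigid-wing input energy is zero: ratio undefined")
    return e_fws / e_rws
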