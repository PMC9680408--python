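"""Time integration, steady-state extraction and summary metrics.

Responses are integrated from rest with an adaptive Dormand--Prince 4(5)
scheme and densely re-sampled on an exactly uniform grid of
``samples_per_wingbeat`` points per drive period.  Reported quantities are
taken from a steady-state window (the final wingbeats of the run), with a
steadiness diagnostic quantifying how settled the response is.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model import (
    StateVector,
    SystemConfig,
    aero_surface_force,
    muscle_force,
)
from .wing import ParameterError

__all__ = [
    "SimResult",
    "SummaryMetrics",
    "IntegrationError",
    "integrate",
    "steady_state_window",
    "amplitude_and_phase",
    "summarize",
]


class IntegrationError(RuntimeError):
    """The ODE solver failed or produced a non-finite state."""


def wrap_phase(phi):
    """Wrap an angle into (-pi, pi]."""
    out = (-phi + np.pi) % (2.0 * np.pi)
    return -(out - np.pi)


@dataclass
class SimResult:
    """Uniformly sampled trajectories of one run.

    ``q``/``qdot`` have shape (K, n_samples).  ``dense`` keeps the
    integrator's dense-output object so downstream consumers (energy-balance
    checks) can re-sample at higher resolution.
    """

    time: np.ndarray
    x: np.ndarray
    xdot: np.ndarray
    q: np.ndarray
    qdot: np.ndarray
    config: SystemConfig
    samples_per_wingbeat: int
    dense: object = None
    steadiness: float = np.nan

    @property
    def n_wingbeats(self) -> int:
        return int(round((len(self.time) - 1) / self.samples_per_wingbeat))

    @property
    def theta(self) -> np.ndarray:
        return self.x / self.config.transmission.ratio

    @property
    def thetadot(self) -> np.ndarray:
        return self.xdot / self.config.transmission.ratio

    @property
    def tip_deflection(self) -> np.ndarray:
        """Wingtip elastic deflection W(L, t) = sum_k phi_k(L) q_k."""
        if self.config.n_modes == 0:
            return np.zeros_like(self.time)
        return self.config.basis.tip_values() @ self.q

    @property
    def applied_force(self) -> np.ndarray:
        return muscle_force(self.time, self.config.drive)

    def aero_force(self):
        """(total, rigid, elastic) two-wing drag along the trajectory (N)."""
        state = StateVector(x=self.x, xdot=self.xdot, q=self.q, qdot=self.qdot)
        return aero_surface_force(state, self.config)

    @property
    def applied_power(self) -> np.ndarray:
        return self.applied_force * self.xdot

    def config_hash(self) -> str:
        geom = self.config.wing
        key = (
            f"{geom.mass!r}|{geom.length!r}|{geom.chord!r}|{geom.thickness!r}|"
            f"{self.config.thorax.mass!r}|{self.config.thorax.stiffness!r}|"
            f"{self.config.transmission.ratio!r}|{self.config.drive.amplitude!r}|"
            f"{self.config.drive.frequency!r}|{self.config.aero.drag_coefficient!r}|"
            f"{self.config.aero.fluid_density!r}|K={self.config.n_modes}|"
            f"om={np.array2string(self.config.basis.omega, precision=12)}"
        )
        return hashlib.sha256(key.encode()).hexdigest()[:12]

    def to_frame(self) -> pd.DataFrame:
        total, rigid, elastic = self.aero_force()
        cols = {
            "time_s": self.time,
            "x_m": self.x,
            "xdot_m_s": self.xdot,
            "theta_rad": self.theta,
        }
        for kk in range(self.config.n_modes):
            cols[f"q_{kk + 1}"] = self.q[kk]
        cols.update(
            {
                "tip_deflection_m": self.tip_deflection,
                "F_applied_N": self.applied_force,
                "F_aero_total_N": total,
                "F_aero_rigid_N": rigid,
                "F_aero_elastic_N": elastic,
                "P_F_W": self.applied_power,
            }
        )
        return pd.DataFrame(cols)


def integrate(
    config: SystemConfig,
    n_wingbeats: int = 50,
    samples_per_wingbeat: int = 100,
    rtol: float = 1e-8,
    atol: float = 1e-11,
    method: str = "RK45",
    initial_state=None,
) -> SimResult:
    """Integrate the coupled equations from rest over ``n_wingbeats`` periods.

    ``method`` is passed to :func:`scipy.integrate.solve_ivp`; the default
    Dormand--Prince RK45 suits the production parameter range, while "Radau"
    is useful for artificially stiffened wings (rigid-limit studies).
    ``initial_state`` overrides the zero initial conditions.
    """
    if n_wingbeats < 1:
        raise ParameterError("n_wingbeats must be >= 1")
    K = config.n_modes
    y0 = np.zeros(2 + 2 * K) if initial_state is None else np.asarray(
        initial_state, dtype=float
    )
    if len(y0) != 2 + 2 * K:
        raise ParameterError("initial state length must be 2 + 2K")
    from .model import make_rhs

    T = config.drive.period
    dt = T / samples_per_wingbeat
    t_end = n_wingbeats * T
    sol = solve_ivp(
        make_rhs(config),
        (0.0, t_end),
        y0,
        method=method,
        rtol=rtol,
        atol=atol,
        dense_output=True,
    )
    if not sol.success:
        raise IntegrationError(
            f"integration failed at t={sol.t[-1]:.6g}s "
            f"(f={config.drive.frequency} Hz, F0={config.drive.amplitude} N, "
            f"K={K}): {sol.message}"
        )
    time = np.arange(n_wingbeats * samples_per_wingbeat + 1) * dt
    states = sol.sol(time)
    if not np.all(np.isfinite(states)):
        bad = time[np.argmax(~np.isfinite(states).all(axis=0))]
        raise IntegrationError(f"non-finite state near t={bad:.6g}s")
    return SimResult(
        time=time,
        x=states[0],
        xdot=states[1],
        q=states[2:2 + K],
        qdot=states[2 + K:],
        config=config,
        samples_per_wingbeat=samples_per_wingbeat,
        dense=sol.sol,
    )


def steady_state_window(result: SimResult, n_tail_wingbeats: int = 10) -> SimResult:
    """Restrict to the final wingbeats and attach a steadiness diagnostic.

    The diagnostic is the relative spread of per-wingbeat thorax amplitudes
    across the window; above 1% a warning is emitted (the window is still
    returned).
    """
    if n_tail_wingbeats >= result.n_wingbeats:
        raise ParameterError("n_tail_wingbeats must be < n_wingbeats")
    spb = result.samples_per_wingbeat
    start = (result.n_wingbeats - n_tail_wingbeats) * spb
    sl = slice(start, len(result.time))
    amps = []
    for b in range(n_tail_wingbeats):
        seg = result.x[start + b * spb: start + (b + 1) * spb + 1]
        amps.append((seg.max() - seg.min()) / 2.0)
    amps = np.asarray(amps)
    scale = np.max(np.abs(amps))
    diagnostic = 0.0 if scale == 0 else (amps.max() - amps.min()) / scale
    if diagnostic > 0.01:
        warnings.warn(
            f"steady-state window not settled: per-wingbeat amplitude varies "
            f"by {diagnostic:.2%}",
            stacklevel=2,
        )
    return replace(
        result,
        time=result.time[sl],
        x=result.x[sl],
        xdot=result.xdot[sl],
        q=result.q[:, sl],
        qdot=result.qdot[:, sl],
        steadiness=diagnostic,
    )


def amplitude_and_phase(signal, reference, frequency_hz, time):
    """Amplitude of ``signal`` and its phase lag behind ``reference``.

    Amplitude is half the peak-to-peak excursion (robust to small mean
    offsets).  The lag comes from the fundamental Fourier coefficients of
    both signals at the drive frequency, evaluated over the largest integer
    number of periods in the window, and is wrapped into (-pi, pi].
    """
    signal = np.asarray(signal, dtype=float)
    reference = np.asarray(reference, dtype=float)
    time = np.asarray(time, dtype=float)
    T = 1.0 / frequency_hz
    n_periods = int(np.floor((time[-1] - time[0]) / T + 1e-9))
    if n_periods < 1:
        raise ParameterError("window must span at least one period")
    mask = time - time[0] <= n_periods * T * (1 + 1e-12)
    t, s, r = time[mask], signal[mask], reference[mask]
    carrier = np.exp(-2j * np.pi * frequency_hz * t)
    c_sig = np.trapezoid(s * carrier, t)
    c_ref = np.trapezoid(r * carrier, t)
    if np.abs(c_ref) < 1e-300 or np.max(np.abs(r)) == 0:
        raise ParameterError("zero-amplitude reference: phase undefined")
    amplitude = (signal.max() - signal.min()) / 2.0
    lag = wrap_phase(np.angle(c_ref) - np.angle(c_sig))
    return amplitude, lag


@dataclass
class SummaryMetrics:
    """Steady-state scalar summary of one run (SI units unless suffixed)."""

    thorax_amplitude_m: float
    thorax_peak_velocity_m_s: float
    tip_amplitude_m: float
    peak_aero_force_n: float
    peak_aero_rigid_n: float
    peak_aero_elastic_n: float
    mean_rect_aero_force_n: float
    peak_power_w: float
    mean_rect_power_w: float
    input_energy_per_wingbeat_j: float
    pe_max_j: float
    pe_min_j: float
    pe_thorax_frac: float
    pe_wing_frac: float
    phase_thorax_behind_force_rad: float
    phase_tip_behind_thorax_rad: float
    steadiness: float

    def to_frame(self, config_hash: str = "") -> pd.DataFrame:
        row = {k: [v] for k, v in self.__dict__.items()}
        row["config_hash"] = [config_hash]
        return pd.DataFrame(row)


def summarize(result: SimResult, n_tail_wingbeats: int = 10) -> SummaryMetrics:
    """Populate all summary metrics from the steady-state window."""
    from . import energetics

    win = steady_state_window(result, n_tail_wingbeats)
    f = win.config.drive.frequency
    total, rigid, elastic = win.aero_force()
    power = win.applied_power
    amp_x = (win.x.max() - win.x.min()) / 2.0
    try:
        _, lag_x = amplitude_and_phase(win.x, win.applied_force, f, win.time)
    except ParameterError:  # at-rest run: phase undefined
        lag_x = np.nan
    tip_amp = float(np.max(np.abs(win.tip_deflection))) if win.config.flexible else 0.0
    if tip_amp > 0:
        try:
            _, lag_tip = amplitude_and_phase(win.tip_deflection, win.x, f, win.time)
        except ParameterError:
            lag_tip = np.nan
    else:
        lag_tip = np.nan
    breakdown = energetics.potential_energies(win, win.config)
    e_in = energetics.input_energy_per_wingbeat(power, win.config.drive, win.time)
    return SummaryMetrics(
        thorax_amplitude_m=amp_x,
        thorax_peak_velocity_m_s=float(np.max(np.abs(win.xdot))),
        tip_amplitude_m=float(tip_amp),
        peak_aero_force_n=float(np.max(np.abs(total))),
        peak_aero_rigid_n=float(np.max(np.abs(rigid))),
        peak_aero_elastic_n=float(np.max(np.abs(elastic))),
        mean_rect_aero_force_n=float(np.mean(np.abs(total))),
        peak_power_w=float(np.max(np.abs(power))),
        mean_rect_power_w=float(np.mean(np.abs(power))),
        input_energy_per_wingbeat_j=e_in,
        pe_max_j=breakdown.pe_max_j,
        pe_min_j=breakdown.pe_min_j,
        pe_thorax_frac=breakdown.pe_thorax_frac,
        pe_wing_frac=breakdown.pe_wing_frac,
        phase_thorax_behind_force_rad=lag_x,
        phase_tip_behind_thorax_rad=lag_tip,
        steadiness=win.steadiness,
    )
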