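"""End-to-end experiments: rigid-vs-flexible baseline and parameter sweeps.

The baseline runs the same parameter set with the flexible wing (FWS) and a
rigid wing (RWS) and reports the comparison a drivetrain designer cares
about: amplitude, force, power and per-wingbeat energy ratios plus the phase
lags.  The sweeps vary one of force amplitude, transmission ratio, thorax
stiffness or wing mass across a flapping-frequency grid and tabulate thorax
amplitude, mean rectified drag, input energy and the FWS/RWS energy ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import energetics
from .model import Drive, SystemConfig, ThoraxParams, Transmission
from .simulate import IntegrationError, SimResult, SummaryMetrics, integrate, summarize
from .wing import ParameterError, WingGeometry, build_modal_basis, retain_modes

__all__ = ["SweepSpec", "BaselineComparison", "run_baseline", "run_sweep",
           "SWEEPABLE_PARAMETERS"]

log = logging.getLogger(__name__)

SWEEPABLE_PARAMETERS = (
    "force_amplitude",      # N
    "transmission_ratio",   # m/rad
    "thorax_stiffness",     # N/m
    "wing_mass",            # kg
)


@dataclass(frozen=True)
class SweepSpec:
    """One-parameter sweep over a flapping-frequency grid.

    ``hold_f1`` keeps the wing's first natural frequency pinned (the
    measured value) when wing mass changes; set False to hold the bending
    rigidity EI instead.
    """

    parameter: str
    values: tuple
    frequencies_hz: tuple = field(
        default_factory=lambda: tuple(np.arange(15.0, 35.0 + 0.25, 0.5))
    )
    systems: tuple = ("RWS", "FWS")
    hold_f1: bool = True

    def __post_init__(self):
        if self.parameter not in SWEEPABLE_PARAMETERS:
            raise ParameterError(
                f"unknown sweep parameter {self.parameter!r}; "
                f"one of {SWEEPABLE_PARAMETERS}"
            )
        if not len(self.values):
            raise ParameterError("sweep needs at least one parameter value")
        freqs = np.asarray(self.frequencies_hz, dtype=float)
        if np.any(freqs <= 0) or np.any(np.diff(freqs) <= 0):
            raise ParameterError("frequencies must be positive and increasing")
        bad = set(self.systems) - {"RWS", "FWS"}
        if bad:
            raise ParameterError(f"unknown system(s): {sorted(bad)}")


@dataclass
class BaselineComparison:
    """Scalar FWS-vs-RWS comparison record (NaN-safe for at-rest runs)."""

    amplitude_ratio: float
    peak_force_ratio: float
    peak_power_ratio: float
    mean_power_ratio: float
    energy_ratio: float
    phase_thorax_behind_force_rad: float
    phase_tip_behind_thorax_rad: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({k: [v] for k, v in self.__dict__.items()})


def _ratio(a: float, b: float) -> float:
    return a / b if b else (np.nan if a == 0 else np.inf)


def run_baseline(
    config: SystemConfig,
    n_wingbeats: int = 50,
    samples_per_wingbeat: int = 100,
) -> tuple[dict[str, SimResult], dict[str, SummaryMetrics], BaselineComparison]:
    """Run FWS and RWS at identical parameters and compare them."""
    results: dict[str, SimResult] = {}
    metrics: dict[str, SummaryMetrics] = {}
    for name, cfg in (("FWS", config), ("RWS", config.rigid())):
        results[name] = integrate(
            cfg, n_wingbeats=n_wingbeats, samples_per_wingbeat=samples_per_wingbeat
        )
        metrics[name] = summarize(results[name])
    fws, rws = metrics["FWS"], metrics["RWS"]
    comparison = BaselineComparison(
        amplitude_ratio=_ratio(fws.thorax_amplitude_m, rws.thorax_amplitude_m),
        peak_force_ratio=_ratio(fws.peak_aero_force_n, rws.peak_aero_force_n),
        peak_power_ratio=_ratio(fws.peak_power_w, rws.peak_power_w),
        mean_power_ratio=_ratio(fws.mean_rect_power_w, rws.mean_rect_power_w),
        energy_ratio=_ratio(
            fws.input_energy_per_wingbeat_j, rws.input_energy_per_wingbeat_j
        ),
        phase_thorax_behind_force_rad=fws.phase_thorax_behind_force_rad,
        phase_tip_behind_thorax_rad=fws.phase_tip_behind_thorax_rad,
    )
    return results, metrics, comparison


def _apply_parameter(
    config: SystemConfig, parameter: str, value: float, hold_f1: bool
) -> SystemConfig:
    if parameter == "force_amplitude":
        return replace(config, drive=Drive(value, config.drive.frequency))
    if parameter == "transmission_ratio":
        return replace(config, transmission=Transmission(value))
    if parameter == "thorax_stiffness":
        return replace(
            config, thorax=ThoraxParams(config.thorax.mass, value)
        )
    # wing mass: the modal basis must be rebuilt (lambda_k, J2_k scale with
    # sqrt(m_w)); by default the measured first frequency is held fixed.
    geom = WingGeometry(
        length=config.wing.length,
        chord=config.wing.chord,
        thickness=config.wing.thickness,
        mass=value,
    )
    if hold_f1:
        f1 = config.basis.frequencies_hz[0] if config.basis.n_modes else 60.0
        basis = build_modal_basis(geom, f1_hz=f1)
    else:
        from .wing import assemble_beam_fem, modal_integrals, solve_modes

        EI = config.basis.bending_rigidity
        M, K = assemble_beam_fem(geom, EI)
        basis = modal_integrals(solve_modes(M, K, geom, EI, n_modes=4))
    return replace(config, wing=geom, basis=basis)


def run_sweep(
    spec: SweepSpec,
    base_config: SystemConfig,
    n_wingbeats: int = 50,
    samples_per_wingbeat: int = 100,
    out_csv=None,
) -> pd.DataFrame:
    """Run every (value, frequency, system) combination and tabulate results.

    Rows already present in ``out_csv`` are skipped (resumable); failed runs
    are recorded as flagged rows and the sweep continues.  The energy ratio
    is attached wherever both systems ran at matching (value, frequency).
    """
    done = set()
    rows = []
    if out_csv is not None and Path(out_csv).exists():
        previous = pd.read_csv(out_csv, float_precision="round_trip")
        rows = previous.to_dict("records")
        done = {
            (r["value"], r["frequency_hz"], r["system"]) for r in rows
        }
        log.info("resuming sweep: %d rows already present", len(rows))
    # work from an untruncated basis so the retention rule can add modes
    # back at higher flapping frequencies
    f1 = (
        base_config.basis.frequencies_hz[0]
        if base_config.basis.n_modes
        else 60.0
    )
    base_full = replace(
        base_config, basis=build_modal_basis(base_config.wing, f1_hz=f1)
    )
    for value in spec.values:
        cfg_v = _apply_parameter(base_full, spec.parameter, value, spec.hold_f1)
        for freq in spec.frequencies_hz:
            cfg = replace(
                cfg_v,
                drive=Drive(cfg_v.drive.amplitude, freq),
                basis=retain_modes(cfg_v.basis, freq),
            )
            for system in spec.systems:
                key = (float(value), float(freq), system)
                if key in done:
                    continue
                run_cfg = cfg.rigid() if system == "RWS" else cfg
                row = {
                    "parameter": spec.parameter,
                    "value": float(value),
                    "frequency_hz": float(freq),
                    "system": system,
                    "thorax_amplitude_m": np.nan,
                    "mean_rect_aero_force_n": np.nan,
                    "e_in_j": np.nan,
                    "failed": False,
                }
                try:
                    result = integrate(
                        run_cfg,
                        n_wingbeats=n_wingbeats,
                        samples_per_wingbeat=samples_per_wingbeat,
                    )
                    m = summarize(result)
                    row.update(
                        thorax_amplitude_m=m.thorax_amplitude_m,
                        mean_rect_aero_force_n=m.mean_rect_aero_force_n,
                        e_in_j=m.input_energy_per_wingbeat_j,
                    )
                except IntegrationError as exc:
                    log.warning("sweep point %s failed: %s", key, exc)
                    row["failed"] = True
                rows.append(row)
                if out_csv is not None:
                    _write_sweep(rows, out_csv)
    table = _attach_energy_ratio(pd.DataFrame(rows))
    if out_csv is not None:
        table.to_csv(out_csv, index=False)
    return table


def _attach_energy_ratio(table: pd.DataFrame) -> pd.DataFrame:
    table = table.sort_values(["value", "frequency_hz", "system"]).reset_index(
        drop=True
    )
    ratio = np.full(len(table), np.nan)
    grouped = table.groupby(["value", "frequency_hz"])
    for _, idx in grouped.groups.items():
        sub = table.loc[idx]
        if {"RWS", "FWS"} <= set(sub["system"]):
            e_f = sub.loc[sub["system"] == "FWS", "e_in_j"].iloc[0]
            e_r = sub.loc[sub["system"] == "RWS", "e_in_j"].iloc[0]
            if e_r and np.isfinite(e_r) and np.isfinite(e_f):
                ratio[idx] = e_f / e_r
    table["energy_ratio"] = ratio
    return table


def _write_sweep(rows, out_csv) -> None:
    pd.DataFrame(rows).to_csv(out_csv, index=False)
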