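"""Plain-text (TOML) configuration files.

The schema uses the units practitioners quote for hawkmoth-scale systems
(mg, cm, µm, g, mm/rad) and converts to SI on load.  All keys are optional;
missing ones take the hawkmoth-like defaults.

    [wing]
    mass_mg = 50.0
    length_cm = 5.0
    width_cm = 1.8
    thickness_um = 50.0
    f1_hz = 60.0
    [thorax]
    mass_g = 0.7
    stiffness_n_per_m = 2850.0
    [transmission]
    mm_per_rad = 0.8
    [drive]
    amplitude_n = 1.5
    frequency_hz = 25.0
    [aero]
    cd = 3.0
    rho = 1.25
    [sim]
    n_wingbeats = 50
    samples_per_wingbeat = 100
    [model]
    flexible = true
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass
from pathlib import Path

from .model import AeroEnv, Drive, SystemConfig, ThoraxParams, Transmission
from .wing import WingGeometry, build_modal_basis

__all__ = ["SimSettings", "DEFAULTS", "load_config", "default_config", "write_default"]

DEFAULTS = {
    "wing": {"mass_mg": 50.0, "length_cm": 5.0, "width_cm": 1.8,
             "thickness_um": 50.0, "f1_hz": 60.0},
    "thorax": {"mass_g": 0.7, "stiffness_n_per_m": 2850.0},
    "transmission": {"mm_per_rad": 0.8},
    "drive": {"amplitude_n": 1.5, "frequency_hz": 25.0},
    "aero": {"cd": 3.0, "rho": 1.25},
    "sim": {"n_wingbeats": 50, "samples_per_wingbeat": 100},
    "model": {"flexible": True},
}


@dataclass(frozen=True)
class SimSettings:
    n_wingbeats: int = 50
    samples_per_wingbeat: int = 100


def _merged(user: dict) -> dict:
    out = {}
    for section, keys in DEFAULTS.items():
        got = user.get(section, {})
        unknown = set(got) - set(keys)
        if unknown:
            raise KeyError(
                f"unknown config key(s) in [{section}]: {sorted(unknown)}"
            )
        out[section] = {**keys, **got}
    unknown_sections = set(user) - set(DEFAULTS)
    if unknown_sections:
        raise KeyError(f"unknown config section(s): {sorted(unknown_sections)}")
    return out


def _build(tree: dict) -> tuple[SystemConfig, SimSettings, float]:
    w = tree["wing"]
    geometry = WingGeometry(
        length=w["length_cm"] * 1e-2,
        chord=w["width_cm"] * 1e-2,
        thickness=w["thickness_um"] * 1e-6,
        mass=w["mass_mg"] * 1e-6,
    )
    drive = Drive(
        amplitude=tree["drive"]["amplitude_n"],
        frequency=tree["drive"]["frequency_hz"],
    )
    basis = build_modal_basis(
        geometry, f1_hz=w["f1_hz"], flap_frequency_hz=drive.frequency
    )
    config = SystemConfig(
        thorax=ThoraxParams(
            mass=tree["thorax"]["mass_g"] * 1e-3,
            stiffness=tree["thorax"]["stiffness_n_per_m"],
        ),
        transmission=Transmission(tree["transmission"]["mm_per_rad"] * 1e-3),
        aero=AeroEnv(
            drag_coefficient=tree["aero"]["cd"], fluid_density=tree["aero"]["rho"]
        ),
        drive=drive,
        wing=geometry,
        basis=basis,
    )
    if not tree["model"]["flexible"]:
        config = config.rigid()
    settings = SimSettings(
        n_wingbeats=int(tree["sim"]["n_wingbeats"]),
        samples_per_wingbeat=int(tree["sim"]["samples_per_wingbeat"]),
    )
    return config, settings, w["f1_hz"]


def load_config(path) -> tuple[SystemConfig, SimSettings]:
    """Read a TOML configuration file into a system config and run settings."""
    with open(path, "rb") as fh:
        user = tomllib.load(fh)
    config, settings, _ = _build(_merged(user))
    return config, settings


def default_config() -> tuple[SystemConfig, SimSettings]:
    """The hawkmoth-like defaults without touching the filesystem."""
    config, settings, _ = _build(_merged({}))
    return config, settings


def write_default(path) -> None:
    """Write a fully commented default configuration file."""
    lines = []
    for section, keys in DEFAULTS.items():
        lines.append(f"[{section}]")
        for key, val in keys.items():
            lines.append(f"{key} = {str(val).lower() if isinstance(val, bool) else val}")
        lines.append("")
    Path(path).write_text("\n".join(lines))
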