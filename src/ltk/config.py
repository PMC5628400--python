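"""Run configuration: a single YAML file with layered defaults.

Unknown keys are rejected loudly (no silent typos) and the full
effective configuration is echoed to a provenance file in the output
directory so any run can be reproduced from its own outputs.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "validate_config", "DEFAULTS"]

DEFAULTS: dict = {
    "seed": 0,
    "outdir": "ltk_out",
    "log_level": "INFO",
    "stages": ["synth", "tunnels", "transport", "wham", "eda", "dynamics"],
    "inputs": {
        "structure": None,
        "trajectory": None,
        "parameters": None,
        "window_metadata": None,
    },
    "synth": {
        "channel_inner_radius": 3.0,
        "channel_length": 20.0,
        "n_ligands": 10,
        "n_frames": 500,
        "n_windows": 30,
        "window_spacing": 0.3,
        "spring_constant": 10.0,
        "samples_per_window": 5000,
        "pmf_form": "double_well",
    },
    "tunnel": {
        "probe_radius": 1.2,
        "spacing": 0.6,
        "padding": 4.0,
        "max_tunnels": 3,
        "cost_exponent": 2.0,
    },
    "transport": {
        "entrance_threshold": 6.0,
        "min_frames": 1,
        "density_spacing": 1.0,
        "isovalue": 0.006,
    },
    "wham": {
        "temperature": 300.0,
        "tol": 1e-6,
        "max_iter": 100000,
        "n_boot": 20,
        "bias_convention": "full",
    },
    "eda": {
        "target_residue": 1,
        "cutoff": None,
    },
    "dynamics": {
        "hbond_distance": 3.0,
        "hbond_angle": 135.0,
        "hbond_report_threshold": 0.30,
    },
}


@dataclass
class RunConfig:
    """Validated, defaults-filled pipeline configuration."""

    settings: dict = field(default_factory=lambda: copy.deepcopy(DEFAULTS))
    source: Path | None = None

    @property
    def seed(self) -> int:
        return int(self.settings["seed"])

    @property
    def outdir(self) -> Path:
        return Path(self.settings["outdir"])

    def __getitem__(self, key: str):
        return self.settings[key]

    def dump(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.settings, fh, sort_keys=True)


def _merge(defaults: dict, overrides: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, value in overrides.items():
        here = f"{path}.{key}" if path else key
        if key not in defaults:
            raise KeyError(f"unknown configuration key: {here!r}")
        if isinstance(defaults[key], dict) and defaults[key]:
            if not isinstance(value, dict):
                raise ValueError(f"configuration key {here!r} must be a mapping")
            out[key] = _merge(defaults[key], value, here)
        else:
            out[key] = value
    return out


def validate_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load and validate a YAML config, filling defaults.

    With no path, the packaged defaults (a fully synthetic demo run) are
    used.  ``overrides`` are applied on top of the file (CLI flags beat
    file values beat defaults).  Referenced input paths must exist.
    """
    settings = copy.deepcopy(DEFAULTS)
    source = None
    if path is not None:
        source = Path(path)
        with open(source) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{source}: config must be a mapping")
        settings = _merge(settings, loaded)
    if overrides:
        settings = _merge(settings, overrides)
    missing = [
        f"inputs.{k}"
        for k, v in settings["inputs"].items()
        if v is not None and not Path(v).exists()
    ]
    if missing:
        raise FileNotFoundError(f"configured inputs do not exist: {missing}")
    return RunConfig(settings=settings, source=source)
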