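"""Default relaxation parameters for the sodium environments.

The shipped values in ``data/environments.yaml`` are *calibrated
stand-ins*: spectral densities and residual quadrupole splittings chosen
so that the simulated relaxation weightings of the three sequences match
the published per-compartment weightings (see the package methods note).
They are not measured tissue parameters; override them with your own
config for sensitivity analyses.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml

from .spin32 import EnvironmentRelaxation

__all__ = ["load_environments", "default_environments", "DEFAULT_CONFIG"]

DEFAULT_CONFIG = "environments.yaml"


def _parse(doc: dict) -> dict[str, EnvironmentRelaxation]:
    envs: dict[str, EnvironmentRelaxation] = {}
    for name, p in doc["environments"].items():
        envs[name] = EnvironmentRelaxation(
            name=name,
            J0=float(p["J0"]),
            J1=float(p["J1"]),
            J2=float(p["J2"]),
            fQ=float(p.get("fQ_hz", 0.0)),
            fQ_model=p.get("fQ_model", "single-value"),
            fQ_width=float(p.get("fQ_width", 0.0)),
        )
    return envs


def load_environments(path: str | Path) -> dict[str, EnvironmentRelaxation]:
    """Read per-environment ``{J0, J1, J2, fQ_hz, fQ_model}`` from YAML."""
    with open(path) as fh:
        return _parse(yaml.safe_load(fh))


def default_environments() -> dict[str, EnvironmentRelaxation]:
    """The calibrated default environment set shipped with the package."""
    text = resources.files("na_contrast").joinpath("data", DEFAULT_CONFIG).read_text()
    return _parse(yaml.safe_load(text))
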