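"""Run configuration: calibrated parameter sets, experiment configs, and
provenance records.

A run is reproducible from its archived config and seed alone: every file
written by :func:`pfcpersist.cli` experiments embeds the config hash.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

_CAL_CACHE: dict | None = None


class ConfigError(ValueError):
    """Invalid run configuration."""


def load_calibrated(path: str | Path | None = None) -> dict:
    """Load the calibrated parameter set (packaged ``data/calibrated.yaml``).

    Returns an empty dict when no calibration file exists (uncalibrated
    defaults are then used throughout)."""
    global _CAL_CACHE
    if path is not None:
        with open(path) as fh:
            return yaml.safe_load(fh) or {}
    if _CAL_CACHE is None:
        try:
            ref = resources.files("pfcpersist").joinpath("data/calibrated.yaml")
            _CAL_CACHE = yaml.safe_load(ref.read_text()) or {}
        except (FileNotFoundError, ModuleNotFoundError):
            _CAL_CACHE = {}
    return _CAL_CACHE


_ALLOWED_EXPERIMENTS = (
    "validate", "nmda-spike", "dadp", "sweep", "trials", "spatial", "decode",
)


@dataclass
class RunConfig:
    """Declarative description of one experiment run."""

    experiment: str = "validate"
    phenotype: str = "RS"
    nmda_ratio: float = 1.2
    g_can: float | None = None
    target_dadp_mv: float | None = None
    n_trials: int = 10
    base_seed: int = 1
    dt: float = 0.025
    noise: bool = True
    morphology_seed: int = 1
    swc_path: str | None = None
    out_dir: str = "results"
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        errs = []
        if self.experiment not in _ALLOWED_EXPERIMENTS:
            errs.append(f"experiment must be one of {_ALLOWED_EXPERIMENTS}")
        if self.phenotype not in ("RS", "IB"):
            errs.append("phenotype must be RS or IB")
        if self.nmda_ratio <= 0:
            errs.append("nmda_ratio must be > 0")
        if not 0 < self.dt <= 0.1:
            errs.append("dt must be in (0, 0.1]")
        if self.n_trials < 1:
            errs.append("n_trials must be >= 1")
        if errs:
            raise ConfigError("; ".join(errs))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        kwargs = {k: v for k, v in data.items() if k in known}
        unknown = {k: v for k, v in data.items() if k not in known}
        cfg = cls(**kwargs)
        cfg.extra.update(unknown)
        return cfg

    def to_dict(self) -> dict:
        from dataclasses import asdict
        return asdict(self)

    @property
    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
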