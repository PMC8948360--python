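"""Run configuration: a validated, file-backed parameter set.

Configurations are YAML key/value files; unknown keys are rejected and every
field is validated against the preconditions of the module it feeds, with the
offending key named in the error.  ``sbr: inf`` maps to the internal
large-SBR no-background convention (1e6).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator

from .beams import make_beam_profile
from .crb import NO_BACKGROUND_SBR
from .exceptions import ConfigError
from .photons import Scenario
from .sequences import minflux_sequence, rastmin_sequence

__all__ = ["RunConfig", "load_config"]


class RunConfig(BaseModel):
    """Validated parameters for one run.

    Defaults follow the reference configuration: MINFLUX pattern of size
    L = 100 nm, N = 500 detected photons, SBR = 4, one-photon excitation at
    647 nm through an NA 1.4 objective, 41 x 41 precision-map grid.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    method: Literal["minflux", "rastmin"] = "minflux"
    L: float = Field(default=100.0, gt=0, description="pattern size, nm")
    m: int = Field(default=4, ge=2, description="rastmin grid side")
    wavelength: float = Field(default=647.0, gt=0, description="nm")
    numerical_aperture: float = Field(default=1.4, gt=0, le=1.7)
    order: float = Field(default=1.0, ge=1.0, description="excitation order c")
    N: int = Field(default=500, ge=1, description="photon budget")
    sbr: float | str = Field(default=4.0, description="signal-to-background ratio or 'inf'")
    map_grid: int = Field(default=41, ge=3, description="precision-map side g")
    seed: int = Field(default=0, ge=0)
    output_dir: str = "runs"

    @field_validator("sbr")
    @classmethod
    def _check_sbr(cls, v):
        if isinstance(v, str):
            if v.lower() in {"inf", "infinity"}:
                return "inf"
            raise ValueError(f"sbr must be a positive number or 'inf', got {v!r}")
        if not (v > 0) or not np.isfinite(v):
            raise ValueError(f"sbr must be > 0 and finite (or 'inf'), got {v}")
        return float(v)

    @property
    def sbr_value(self) -> float:
        """Numeric SBR; 'inf' maps to the large-SBR no-background convention."""
        return NO_BACKGROUND_SBR if self.sbr == "inf" else float(self.sbr)

    def sequence(self):
        if self.method == "minflux":
            return minflux_sequence(self.L)
        return rastmin_sequence(self.L, self.m)

    def beam(self):
        return make_beam_profile(self.wavelength, self.numerical_aperture)

    def scenario(self, emitter_position=(0.0, 0.0)) -> Scenario:
        """Materialize the full forward model described by this config."""
        return Scenario(
            beam=self.beam(),
            sequence=self.sequence(),
            order=self.order,
            N=self.N,
            SBR=self.sbr_value,
            emitter_position=np.asarray(emitter_position, dtype=float),
        )

    def fingerprint(self) -> str:
        """Stable hash of the parameter set (order-independent)."""
        payload = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path, **overrides) -> RunConfig:
    """Load and validate a YAML run configuration.

    Keyword overrides (e.g. from CLI flags) take precedence over file values.
    Raises :class:`ConfigError` naming the offending key on any violation.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping of key: value pairs")
    raw.update({k: v for k, v in overrides.items() if v is not None})
    try:
        return RunConfig(**raw)
    except ValidationError as exc:
        problems = "; ".join(
            f"{'.'.join(str(p) for p in err['loc']) or '<root>'}: {err['msg']}"
            for err in exc.errors()
        )
        raise ConfigError(f"{path}: invalid configuration — {problems}") from exc
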