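"""Pipeline configuration: every tunable threshold, factor and bin in one
validated object, loadable from JSON or TOML.

Defaults reproduce the reference study conditions exactly; literature
variants (canonical rule-of-five, 1/eta softness, different H-bond bins)
are swapped in by overriding fields, never by editing code.
"""

from __future__ import annotations

import json
import tomllib
from pathlib import Path
from typing import Literal

from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .chem_graph import RSA_ANCHOR
from .errors import ConfigError

__all__ = [
    "ReactivityConfig",
    "ChemGraphConfig",
    "VibrationalConfig",
    "InteractionsConfig",
    "GeometryConfig",
    "PipelineConfig",
    "load_config",
]


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ReactivityConfig(_Section):
    softness_convention: Literal["inverse_2eta", "inverse_eta"] = "inverse_2eta"


class ChemGraphConfig(_Section):
    rsa_intercept: float = 0.0
    rsa_slope: float = RSA_ANCHOR
    #: set True to bypass the intercept+slope anchor check (literature variants)
    allow_custom_rsa: bool = False
    ro5_variant: Literal["oxygen_count", "canonical"] = "oxygen_count"

    @model_validator(mode="after")
    def _check_rsa_anchor(self):
        if not self.allow_custom_rsa:
            if abs(self.rsa_intercept + self.rsa_slope - RSA_ANCHOR) > 1e-6:
                raise ValueError(
                    f"RSA coefficients must satisfy intercept + slope == {RSA_ANCHOR}"
                )
        return self

    @property
    def rsa_coefficients(self) -> tuple[float, float]:
        return (self.rsa_intercept, self.rsa_slope)


class VibrationalConfig(_Section):
    boundary: float = Field(1800.0, gt=0)
    factor_low: float = Field(0.967, gt=0, le=1.2)
    factor_high: float = Field(0.955, gt=0, le=1.2)
    match_tolerance: float = Field(15.0, gt=0)
    fermi_target: float = Field(1615.0, gt=0)
    fermi_tolerance: float = Field(5.0, ge=0)
    max_overtone_order: int = Field(3, ge=2)


class InteractionsConfig(_Section):
    hbond_min: float = Field(2.0, gt=0)
    hbond_max: float = Field(4.1, gt=0)
    hydrophobic_cutoff: float = Field(5.5, gt=0)

    @model_validator(mode="after")
    def _check_window(self):
        if self.hbond_max <= self.hbond_min:
            raise ValueError("hbond_max must exceed hbond_min")
        return self


class GeometryConfig(_Section):
    planarity_threshold: float = Field(20.0, gt=0)


class PipelineConfig(_Section):
    seed: int = 0
    verbose: bool = False
    reactivity: ReactivityConfig = Field(default_factory=ReactivityConfig)
    chem_graph: ChemGraphConfig = Field(default_factory=ChemGraphConfig)
    vibrational: VibrationalConfig = Field(default_factory=VibrationalConfig)
    interactions: InteractionsConfig = Field(default_factory=InteractionsConfig)
    geometry: GeometryConfig = Field(default_factory=GeometryConfig)


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from a JSON or TOML file (or defaults
    when ``path`` is None).  Validation errors raise :class:`ConfigError`
    before any work is done."""
    if path is None:
        return PipelineConfig()
    p = Path(path)
    try:
        if p.suffix.lower() == ".toml":
            raw = tomllib.loads(p.read_text(encoding="utf-8"))
        else:
            raw = json.loads(p.read_text(encoding="utf-8"))
        return PipelineConfig(**raw)
    except (json.JSONDecodeError, tomllib.TOMLDecodeError) as exc:
        raise ConfigError(f"cannot parse config {p}: {exc}") from exc
    except ValidationError as exc:
        raise ConfigError(f"invalid config {p}: {exc}") from exc
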