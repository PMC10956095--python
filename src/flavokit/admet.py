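"""Threshold-based interpretation of predicted ADME/Tox panels.

This module does not predict anything from structure: it consumes the
numeric/boolean outputs of external predictors (pkCSM graph-signature
models, SwissADME) and maps each property onto the categorical call used in
flavonoid pharmacokinetics screening:

* water solubility: logS > -3 soluble; -4 <= logS <= -3 moderately soluble;
  logS < -4 poorly soluble (SwissADME convention; the moderate bin is closed
  so a value of exactly -3 or -4 stays moderate)
* Caco-2 permeability: > 0.90 readily permeable (raw predictor score,
  compared unit-free as the source narrative does)
* human intestinal absorption (HIA): > 30 % readily absorbed
* VDss: log(L/kg) < -0.15 low, > 0.45 high, otherwise intermediate
* fraction unbound (fu): acceptable when 0.2 <= fu <= 1.0
* total clearance: < 1 (log mL/min/kg) low
* MRTD: <= 0.477 log(mg/kg/day) low toxic dose
* booleans (P-gp, CYP isoform inhibition, OCT2, AMES, hERG, hepatotoxicity,
  skin sensitisation) map directly to their call phrasing

A known citation divergence: some sources describe VDss values inside the
intermediate band (e.g. 0.17) as "high" despite stating the 0.45 cutoff.
The interpreter follows the bins and attaches a divergence note to
intermediate VDss calls so that both readings stay visible.
"""

from __future__ import annotations

import json
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, field_validator

from ._util import data_path
from .errors import FlavokitError

__all__ = ["AdmetProfile", "PropertyCall", "AdmetReport", "interpret",
           "blumeatin_profile"]

_CYP_ISOFORMS = ("CYP1A2", "CYP2C19", "CYP2C9", "CYP2D6", "CYP3A4")

VDSS_DIVERGENCE_NOTE = (
    "cited interpretation calls values in this range 'high' despite the "
    "stated 0.45 log(L/kg) cutoff; the bin rule labels it 'intermediate'"
)


class AdmetProfile(BaseModel):
    """Externally predicted ADME/Tox values.  All fields optional; unknown
    fields are rejected."""

    model_config = ConfigDict(extra="forbid")

    log_s: Optional[float] = Field(None, description="aqueous solubility, log mol/L")
    caco2: Optional[float] = Field(None, description="Caco-2 permeability score")
    hia: Optional[float] = Field(None, description="human intestinal absorption, %")
    pgp_substrate: Optional[bool] = None
    pgp_i_inhibitor: Optional[bool] = None
    pgp_ii_inhibitor: Optional[bool] = None
    vdss_log: Optional[float] = Field(None, description="steady-state volume of distribution, log L/kg")
    fu: Optional[float] = Field(None, description="fraction unbound in plasma")
    cyp_inhibition: Optional[dict[str, bool]] = None
    total_clearance: Optional[float] = Field(None, description="log mL/min/kg")
    oct2_substrate: Optional[bool] = None
    ames: Optional[bool] = None
    mrtd_log: Optional[float] = Field(None, description="max recommended tolerated dose, log mg/kg/day")
    herg1: Optional[bool] = None
    herg2: Optional[bool] = None
    oral_rat_ld50: Optional[float] = Field(None, description="acute oral rat LD50, mol/kg")
    hepatotoxic: Optional[bool] = None
    skin_sensitising: Optional[bool] = None

    @field_validator("hia")
    @classmethod
    def _hia_range(cls, v):
        if v is not None and not 0 <= v <= 100:
            raise ValueError(f"HIA must be a percentage in [0, 100], got {v}")
        return v

    @field_validator("fu")
    @classmethod
    def _fu_range(cls, v):
        if v is not None and not 0 <= v <= 1:
            raise ValueError(f"fraction unbound must be in [0, 1], got {v}")
        return v

    @field_validator("cyp_inhibition")
    @classmethod
    def _cyp_keys(cls, v):
        if v is not None:
            unknown = set(v) - set(_CYP_ISOFORMS)
            if unknown:
                raise ValueError(f"unknown CYP isoforms: {sorted(unknown)}")
        return v


class PropertyCall(BaseModel):
    property: str
    value: object
    label: str
    rule: str
    note: Optional[str] = None


class AdmetReport(BaseModel):
    calls: list[PropertyCall]
    divergences: list[str]

    def label_for(self, prop: str) -> str:
        for call in self.calls:
            if call.property == prop:
                return call.label
        raise KeyError(prop)


def _bool_call(prop: str, value: bool, true_label: str, false_label: str,
               rule: str) -> PropertyCall:
    return PropertyCall(property=prop, value=value,
                        label=true_label if value else false_label, rule=rule)


def interpret(profile: AdmetProfile) -> AdmetReport:
    """Apply every threshold rule to the supplied properties.

    Every supplied property receives exactly one label; absent properties are
    omitted.  Raises when no property is supplied at all.
    """
    calls: list[PropertyCall] = []
    divergences: list[str] = []

    if profile.log_s is not None:
        v = profile.log_s
        if v > -3:
            label = "soluble"
        elif v >= -4:
            label = "moderately soluble"
        else:
            label = "poorly soluble"
        calls.append(PropertyCall(
            property="log_s", value=v, label=label,
            rule="logS > -3 soluble; -4 <= logS <= -3 moderately soluble; < -4 poorly soluble",
        ))
    if profile.caco2 is not None:
        calls.append(PropertyCall(
            property="caco2", value=profile.caco2,
            label="readily permeable" if profile.caco2 > 0.90 else "poor permeability",
            rule="Caco-2 score > 0.90 readily permeable",
        ))
    if profile.hia is not None:
        calls.append(PropertyCall(
            property="hia", value=profile.hia,
            label="readily absorbed (high absorption)" if profile.hia > 30
            else "poorly absorbed",
            rule="HIA > 30% readily absorbed",
        ))
    if profile.pgp_substrate is not None:
        calls.append(_bool_call(
            "pgp_substrate", profile.pgp_substrate,
            "P-glycoprotein substrate", "not a P-glycoprotein substrate",
            "boolean predictor output",
        ))
    for prop, label in (("pgp_i_inhibitor", "P-glycoprotein I"),
                        ("pgp_ii_inhibitor", "P-glycoprotein II")):
        value = getattr(profile, prop)
        if value is not None:
            calls.append(_bool_call(
                prop, value, f"{label} inhibitor", f"not a {label} inhibitor",
                "boolean predictor output",
            ))
    if profile.vdss_log is not None:
        v = profile.vdss_log
        if v < -0.15:
            label = "low"
        elif v > 0.45:
            label = "high"
        else:
            label = "intermediate"
        note = VDSS_DIVERGENCE_NOTE if label == "intermediate" else None
        if note:
            divergences.append(f"vdss_log={v}: {note}")
        calls.append(PropertyCall(
            property="vdss_log", value=v, label=label,
            rule="log VDss < -0.15 low; > 0.45 high; else intermediate",
            note=note,
        ))
    if profile.fu is not None:
        calls.append(PropertyCall(
            property="fu", value=profile.fu,
            label="acceptable unbound fraction" if 0.2 <= profile.fu <= 1.0
            else "low unbound fraction (highly plasma-bound)",
            rule="fraction unbound acceptable in [0.2, 1.0]",
        ))
    if profile.cyp_inhibition is not None:
        for isoform in _CYP_ISOFORMS:
            if isoform in profile.cyp_inhibition:
                calls.append(_bool_call(
                    f"cyp_inhibition.{isoform}", profile.cyp_inhibition[isoform],
                    f"{isoform} inhibitor", f"{isoform} non-inhibitor",
                    "boolean predictor output",
                ))
    if profile.total_clearance is not None:
        calls.append(PropertyCall(
            property="total_clearance", value=profile.total_clearance,
            label="low total clearance" if profile.total_clearance < 1
            else "total clearance not low",
            rule="total clearance < 1 low",
        ))
    if profile.oct2_substrate is not None:
        calls.append(_bool_call(
            "oct2_substrate", profile.oct2_substrate,
            "renal OCT2 substrate", "not a renal OCT2 substrate",
            "boolean predictor output",
        ))
    if profile.ames is not None:
        calls.append(_bool_call(
            "ames", profile.ames,
            "AMES positive (mutagenic)", "AMES negative (non-mutagenic, non-carcinogenic)",
            "boolean predictor output",
        ))
    if profile.mrtd_log is not None:
        calls.append(PropertyCall(
            property="mrtd_log", value=profile.mrtd_log,
            label="low maximum tolerated dose (low toxicity to humans)"
            if profile.mrtd_log <= 0.477 else "high maximum tolerated dose",
            rule="MRTD <= 0.477 log(mg/kg/day) low",
        ))
    for prop, name in (("herg1", "hERG I"), ("herg2", "hERG II")):
        value = getattr(profile, prop)
        if value is not None:
            calls.append(_bool_call(
                prop, value, f"{name} inhibitor", f"{name} non-inhibitor",
                "boolean predictor output",
            ))
    if profile.oral_rat_ld50 is not None:
        calls.append(PropertyCall(
            property="oral_rat_ld50", value=profile.oral_rat_ld50,
            label=f"oral rat acute LD50 {profile.oral_rat_ld50} mol/kg (reported value; no threshold rule)",
            rule="informational",
        ))
    if profile.hepatotoxic is not None:
        calls.append(_bool_call(
            "hepatotoxic", profile.hepatotoxic,
            "hepatotoxic", "non-hepatotoxic", "boolean predictor output",
        ))
    if profile.skin_sensitising is not None:
        calls.append(_bool_call(
            "skin_sensitising", profile.skin_sensitising,
            "skin sensitising", "non-skin-sensitising", "boolean predictor output",
        ))

    if not calls:
        raise FlavokitError("ADMET profile supplies no properties")
    return AdmetReport(calls=calls, divergences=divergences)


def blumeatin_profile() -> AdmetProfile:
    """The packaged blumeatin ADME/Tox panel (pkCSM/SwissADME outputs as
    reported; see the data file's notes for the one stand-in value)."""
    raw = json.loads(data_path("blumeatin_admet.json").read_text(encoding="utf-8"))
    raw.pop("_notes", None)
    return AdmetProfile(**raw)
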