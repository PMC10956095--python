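"""Combined per-compound profile report.

Runs every stage for which an input is supplied - structure perception and
RSA, reactivity descriptors, vibrational scaling and Fermi search,
protein-ligand contact analysis, ADME/Tox interpretation - and returns one
deterministic JSON-serialisable report.  Warnings (classification-bin
divergences, scope notes) are collected in a flat list so that human and
machine consumers see the same caveats.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

from . import admet, chem_graph, interactions, reactivity, vibrational
from .config import PipelineConfig
from .errors import FlavokitError

__all__ = ["ProfileInputs", "run_profile", "report_to_json"]

AROMATIC_TYPES_NOTE = (
    "typed aromatic interactions (pi-pi, pi-sigma, pi-alkyl, amide-pi, "
    "pi-sulfur) are out of scope for geometric detection; contacts are "
    "classified as hydrogen_bond or hydrophobic only"
)
NUMBERING_NOTE = (
    "substituent locants use standard IUPAC flavonoid numbering (C ring 2-4, "
    "A ring 5-8, B ring 2'-6'), not any source-specific sequential atom "
    "numbering scheme"
)


@dataclass(frozen=True)
class ProfileInputs:
    compound: str = "compound"
    smiles: str | None = None
    mlogp: float | None = None
    orbital_table: str | Path | None = None
    mode_table: str | Path | None = None
    complex_pdb: str | Path | None = None
    admet_profile: str | Path | None = None
    ligand_resname: str | None = None


def _require(path: str | Path) -> Path:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"input file not found: {p}")
    return p


def run_profile(inputs: ProfileInputs, config: PipelineConfig | None = None) -> dict:
    """Run all applicable stages and return a structured report dict."""
    cfg = config or PipelineConfig()
    report: dict = {"compound": inputs.compound, "stages": {}, "warnings": []}
    stages = report["stages"]
    warnings = report["warnings"]

    if inputs.smiles:
        mol = chem_graph.parse_smiles(inputs.smiles)
        annotation = chem_graph.annotate_flavonoid(mol)
        ro5 = chem_graph.rule_of_five(mol, inputs.mlogp,
                                      variant=cfg.chem_graph.ro5_variant)
        structure: dict = {
            "smiles": inputs.smiles,
            "heavy_atoms": mol.heavy_atom_count,
            "molecular_weight": chem_graph.molecular_weight(mol),
            "scaffold_class": annotation.scaffold_class,
            "substituents": sorted(map(list, annotation.substituents)),
            "flags": {
                "has_C2C3_double_bond": annotation.has_C2C3_double_bond,
                "has_3_OH": annotation.has_3_OH,
                "has_5_OH": annotation.has_5_OH,
                "has_3p4p_catechol": annotation.has_3p4p_catechol,
            },
            "hydroxyl_count": annotation.hydroxyl_count,
            "rule_of_five": {
                "mw": ro5.mw,
                "oxygen_count": ro5.oxygen_count,
                "nh_oh_count": ro5.nh_oh_count,
                "violations": list(ro5.violations),
                "not_evaluated": list(ro5.not_evaluated),
            },
        }
        warnings.append(NUMBERING_NOTE)
        if annotation.is_flavonoid:
            indicator = chem_graph.indicator_variable(annotation)
            structure["indicator_variable"] = indicator
            structure["rsa_percent"] = chem_graph.predict_rsa(
                indicator, cfg.chem_graph.rsa_coefficients
            )
        stages["structure"] = structure

    if inputs.orbital_table:
        records = reactivity.read_orbital_table(_require(inputs.orbital_table))
        desc_rows = {}
        for rec in records:
            desc = reactivity.descriptors_from_record(
                rec, softness_convention=cfg.reactivity.softness_convention
            )
            desc_rows[rec.compound] = {"route": desc.route, **desc.report()}
        stages["reactivity"] = {
            "descriptors_2dp": desc_rows,
            "gap_ranking": reactivity.rank_by_gap(records),
        }

    if inputs.mode_table:
        scheme = vibrational.ScalingScheme(
            boundary=cfg.vibrational.boundary,
            factor_low=cfg.vibrational.factor_low,
            factor_high=cfg.vibrational.factor_high,
        )
        modes = vibrational.read_mode_table(_require(inputs.mode_table))
        scaled = vibrational.scale_table(modes, scheme)
        bands = sorted({m.experimental for m in scaled if m.experimental is not None})
        combos = vibrational.find_combination_bands(
            bands, cfg.vibrational.fermi_target, cfg.vibrational.fermi_tolerance
        )
        overtones = vibrational.find_overtones(
            bands, cfg.vibrational.fermi_target, cfg.vibrational.fermi_tolerance,
            cfg.vibrational.max_overtone_order,
        )
        stages["vibrational"] = {
            "n_modes": len(scaled),
            "scaled": [[m.index, m.unscaled, m.scaled] for m in scaled],
            "fermi": {
                "target": cfg.vibrational.fermi_target,
                "combination_candidates": [list(c) for c in combos],
                "overtone_candidates": [list(o) for o in overtones],
            },
        }

    if inputs.complex_pdb:
        text = _require(inputs.complex_pdb).read_text(encoding="utf-8")
        cx = interactions.parse_pdb(text, inputs.ligand_resname)
        hbonds = interactions.detect_hbonds(
            cx.ligand_atoms, cx.protein_atoms,
            min_distance=cfg.interactions.hbond_min,
            max_distance=cfg.interactions.hbond_max,
        )
        hydrophobic = interactions.hydrophobic_contacts(
            cx.ligand_atoms, cx.protein_atoms, cfg.interactions.hydrophobic_cutoff
        )
        stages["interactions"] = {
            "ligand_resname": cx.ligand_resname,
            "hydrogen_bonds": [
                {"residue": c.residue, "distance": round(c.distance, 3),
                 "strength": c.strength_class.value,
                 "ligand_atom": c.ligand_atom, "protein_atom": c.protein_atom}
                for c in hbonds
            ],
            "hydrophobic": [
                {"residue": c.residue, "distance": round(c.distance, 3)}
                for c in hydrophobic
            ],
        }
        warnings.append(AROMATIC_TYPES_NOTE)
        warnings.extend(cx.warnings)

    if inputs.admet_profile:
        raw = json.loads(_require(inputs.admet_profile).read_text(encoding="utf-8"))
        raw.pop("_notes", None)
        admet_report = admet.interpret(admet.AdmetProfile(**raw))
        stages["admet"] = {
            "calls": [c.model_dump() for c in admet_report.calls],
        }
        warnings.extend(admet_report.divergences)

    if not stages:
        raise FlavokitError("no inputs supplied; nothing to profile")
    return report


def report_to_json(report: dict) -> str:
    """Canonical (byte-stable) JSON rendering of a profile report."""
    return json.dumps(report, indent=2, sort_keys=True)
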