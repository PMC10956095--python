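"""Seeded synthetic-input generators.

Every analysis stage in the toolkit can be exercised without downloads:

* :func:`gen_orbital_table` - frontier-orbital tables with guaranteed
  positive hardness (E_HOMO < E_LUMO),
* :func:`gen_spectrum` - computed/experimental wavenumber pairs related by a
  known scale factor plus Gaussian noise,
* :func:`gen_complex` - minimal PDB-format protein-ligand complexes with
  donor-acceptor or carbon-carbon contacts planted at requested distances,
* :func:`flavonoid_fixtures` - canonical flavonoid SMILES with hand-verified
  scaffold annotations.

All generators are pure functions of their arguments; the same seed yields
byte-identical output.  Randomness comes from :class:`numpy.random.default_rng`
with an explicit integer seed - there is no global random state.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import GenerationError
from .reactivity import FrontierOrbitalRecord

__all__ = [
    "GeneratorConfig",
    "gen_orbital_table",
    "gen_spectrum",
    "gen_complex",
    "flavonoid_fixtures",
    "FlavonoidFixture",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Bundled generator settings; identical config => identical output."""

    seed: int = 0
    e_homo_range: tuple[float, float] = (-7.5, -4.5)
    gap_range: tuple[float, float] = (0.5, 5.0)
    wavenumber_range: tuple[float, float] = (400.0, 1800.0)
    true_factor: float = 0.967
    noise_sd: float = 2.0


def gen_orbital_table(
    n: int,
    seed: int,
    *,
    e_homo_range: tuple[float, float] = (-7.5, -4.5),
    gap_range: tuple[float, float] = (0.5, 5.0),
) -> list[FrontierOrbitalRecord]:
    """``n`` synthetic frontier-orbital records with E_HOMO < E_LUMO (so the
    derived hardness is strictly positive)."""
    if n < 1:
        raise GenerationError("n must be >= 1")
    if gap_range[0] <= 0:
        raise GenerationError("gap range must be positive to guarantee eta > 0")
    rng = np.random.default_rng(seed)
    e_homo = rng.uniform(*e_homo_range, size=n)
    gap = rng.uniform(*gap_range, size=n)
    return [
        FrontierOrbitalRecord(
            compound=f"cmpd{i:03d}",
            e_homo=round(float(e_homo[i]), 4),
            e_lumo=round(float(e_homo[i] + gap[i]), 4),
            source="synthetic",
        )
        for i in range(n)
    ]


def gen_spectrum(
    n_modes: int,
    true_factor: float,
    noise_sd: float,
    seed: int,
    *,
    wavenumber_range: tuple[float, float] = (400.0, 1800.0),
) -> list[tuple[float, float]]:
    """(computed, experimental) pairs with experimental = factor * computed
    + N(0, noise_sd)."""
    if n_modes < 1:
        raise GenerationError("n_modes must be >= 1")
    if true_factor <= 0:
        raise GenerationError("true_factor must be positive")
    rng = np.random.default_rng(seed)
    computed = np.sort(rng.uniform(*wavenumber_range, size=n_modes))
    noise = rng.normal(0.0, noise_sd, size=n_modes) if noise_sd > 0 else np.zeros(n_modes)
    experimental = true_factor * computed + noise
    return [(float(c), float(e)) for c, e in zip(computed, experimental)]


# ---------------------------------------------------------------------------
# Synthetic PDB complexes

_RESIDUE_RE = re.compile(r"^([A-Za-z]{1,3})(\d+)$")

#: protein atom used for each planted contact type
_CONTACT_ATOM = {"hbond": ("OG1", "O"), "hydrophobic": ("CB", "C")}


def _pdb_line(record: str, serial: int, name: str, resname: str, chain: str,
              resnum: int, x: float, y: float, z: float, element: str) -> str:
    pad_name = name if len(name) >= 4 else f" {name:<3s}"
    return (
        f"{record:<6s}{serial:>5d} {pad_name} {resname:>3s} {chain:1s}"
        f"{resnum:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {element:>2s}"
    )


def gen_complex(
    planted: Sequence[tuple[str, str, float]],
    seed: int,
    *,
    ligand_resname: str = "LIG",
    decoys: int = 2,
) -> str:
    """PDB text for a minimal complex with contacts planted at exact distances.

    ``planted`` rows are (residue label, contact type, distance in A) with
    type ``"hbond"`` (measured from the ligand's single polar oxygen O1) or
    ``"hydrophobic"`` (from the ligand carbon C1).  Each planted residue
    carries exactly one contact atom so detection recovers exactly the
    planted list; decoy residues sit far beyond all cutoffs.  Coordinates are
    laid out in the z = 0 plane so that the 3-decimal PDB coordinate grid
    keeps each realised distance within 0.001 A of the request.
    """
    for label, kind, dist in planted:
        if kind not in _CONTACT_ATOM:
            raise GenerationError(f"unknown contact type {kind!r}")
        if dist <= 1.5:
            raise GenerationError(f"planted distance must exceed 1.5 A, got {dist}")
        if not _RESIDUE_RE.match(label):
            raise GenerationError(f"bad residue label {label!r}")
    labels = [label for label, _, _ in planted]
    if len(set(labels)) != len(labels):
        raise GenerationError("planted residue labels must be unique")

    rng = np.random.default_rng(seed)
    lines = ["HEADER    SYNTHETIC COMPLEX"]
    serial = 1

    # ligand: one polar oxygen at the origin, two carbons along +x
    ligand_atoms = [("O1", "O", 0.0, 0.0), ("C1", "C", 1.4, 0.0), ("C2", "C", -1.4, 0.0)]
    for name, elem, x, y in ligand_atoms:
        lines.append(_pdb_line("HETATM", serial, name, ligand_resname, "L", 1,
                               x, y, 0.0, elem))
        serial += 1

    # planted contacts fan out in the xy-plane; hydrophobic ones keep to the
    # +x half-plane so their minimal ligand distance is to C1, not C2
    n = len(planted)
    base = float(rng.uniform(0.0, 10.0))
    for k, (label, kind, dist) in enumerate(planted):
        resname, resnum = _RESIDUE_RE.match(label).groups()
        atom_name, element = _CONTACT_ATOM[kind]
        if kind == "hydrophobic":
            theta = math.radians(-75.0 + 150.0 * (k + 0.5) / n + base * 0.01)
            cx, cy = 1.4, 0.0
        else:
            theta = math.radians(base + 360.0 * k / max(n, 1))
            cx, cy = 0.0, 0.0
        x = cx + dist * math.cos(theta)
        y = cy + dist * math.sin(theta)
        lines.append(_pdb_line("ATOM", serial, atom_name, resname.upper(), "A",
                               int(resnum), x, y, 0.0, element))
        serial += 1

    for d in range(decoys):
        resnum = 9000 + d
        for name, elem, dx in (("N", "N", 0.0), ("CA", "C", 1.5), ("O", "O", 3.0)):
            lines.append(_pdb_line("ATOM", serial, name, "GLY", "A", resnum,
                                   60.0 + dx, 60.0 + 5.0 * d, 0.0, elem))
            serial += 1

    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Flavonoid fixtures


@dataclass(frozen=True)
class FlavonoidFixture:
    name: str
    smiles: str
    expected: dict = field(default_factory=dict)


_FIXTURES: tuple[FlavonoidFixture, ...] = (
    FlavonoidFixture(
        "blumeatin",
        "COC1=CC(=C2C(=O)CC(OC2=C1)C3=CC(=CC(=C3)O)O)O",
        {
            "scaffold_class": "flavanone",
            "substituents": {("4", "=O"), ("5", "OH"), ("7", "OMe"),
                             ("3'", "OH"), ("5'", "OH")},
            "has_C2C3_double_bond": False, "has_3_OH": False,
            "has_5_OH": True, "has_3p4p_catechol": False,
            "hydroxyl_count": 3, "indicator": 1,
        },
    ),
    FlavonoidFixture(
        "quercetin",
        "C1=CC(=C(C=C1C2=C(C(=O)C3=C(C=C(C=C3O2)O)O)O)O)O",
        {
            "scaffold_class": "flavonol",
            "substituents": {("3", "OH"), ("4", "=O"), ("5", "OH"),
                             ("7", "OH"), ("3'", "OH"), ("4'", "OH")},
            "has_C2C3_double_bond": True, "has_3_OH": True,
            "has_5_OH": True, "has_3p4p_catechol": True,
            "hydroxyl_count": 5, "indicator": 1,
        },
    ),
    FlavonoidFixture(
        "taxifolin",
        "C1=CC(=C(C=C1C2C(C(=O)C3=C(C=C(C=C3O2)O)O)O)O)O",
        {
            "scaffold_class": "flavanone",
            "substituents": {("3", "OH"), ("4", "=O"), ("5", "OH"),
                             ("7", "OH"), ("3'", "OH"), ("4'", "OH")},
            "has_C2C3_double_bond": False, "has_3_OH": True,
            "has_5_OH": True, "has_3p4p_catechol": True,
            "hydroxyl_count": 5, "indicator": 1,
        },
    ),
    FlavonoidFixture(
        "luteolin",
        "C1=CC(=C(C=C1C2=CC(=O)C3=C(C=C(C=C3O2)O)O)O)O",
        {
            "scaffold_class": "flavone",
            "substituents": {("4", "=O"), ("5", "OH"), ("7", "OH"),
                             ("3'", "OH"), ("4'", "OH")},
            "has_C2C3_double_bond": True, "has_3_OH": False,
            "has_5_OH": True, "has_3p4p_catechol": True,
            "hydroxyl_count": 4, "indicator": 1,
        },
    ),
    FlavonoidFixture(
        "naringenin",
        "C1C(OC2=CC(=CC(=C2C1=O)O)O)C3=CC=C(C=C3)O",
        {
            "scaffold_class": "flavanone",
            "substituents": {("4", "=O"), ("5", "OH"), ("7", "OH"), ("4'", "OH")},
            "has_C2C3_double_bond": False, "has_3_OH": False,
            "has_5_OH": True, "has_3p4p_catechol": False,
            "hydroxyl_count": 3, "indicator": 1,
        },
    ),
    FlavonoidFixture(
        "kaempferol",
        "C1=CC(=CC=C1C2=C(C(=O)C3=C(C=C(C=C3O2)O)O)O)O",
        {
            "scaffold_class": "flavonol",
            "substituents": {("3", "OH"), ("4", "=O"), ("5", "OH"),
                             ("7", "OH"), ("4'", "OH")},
            "has_C2C3_double_bond": True, "has_3_OH": True,
            "has_5_OH": True, "has_3p4p_catechol": False,
            "hydroxyl_count": 4, "indicator": 1,
        },
    ),
    FlavonoidFixture(
        "galangin",
        "C1=CC=C(C=C1)C2=C(C(=O)C3=C(C=C(C=C3O2)O)O)O",
        {
            "scaffold_class": "flavonol",
            "substituents": {("3", "OH"), ("4", "=O"), ("5", "OH"), ("7", "OH")},
            "has_C2C3_double_bond": True, "has_3_OH": True,
            "has_5_OH": True, "has_3p4p_catechol": False,
            "hydroxyl_count": 3, "indicator": 1,
        },
    ),
    FlavonoidFixture(
        "morin",
        "C1=CC(=CC(=C1C2=C(C(=O)C3=C(C=C(C=C3O2)O)O)O)O)O",
        {
            "scaffold_class": "flavonol",
            "substituents": {("3", "OH"), ("4", "=O"), ("5", "OH"),
                             ("7", "OH"), ("2'", "OH"), ("4'", "OH")},
            "has_C2C3_double_bond": True, "has_3_OH": True,
            "has_5_OH": True, "has_3p4p_catechol": False,
            "hydroxyl_count": 5, "indicator": 1,
        },
    ),
)


def flavonoid_fixtures() -> list[FlavonoidFixture]:
    """Eight canonical flavonoid SMILES with hand-verified annotations."""
    return list(_FIXTURES)
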