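"""Geometric protein-ligand contact detection and classification.

Works on PDB-format complexes (parsed with gemmi): hydrogen bonds are
detected as heavy-atom N/O...N/O pairs across the protein-ligand interface
and binned by donor-acceptor distance into

    very strong (almost covalent)   d < 2.2 A
    strong                          2.2 <= d < 2.5 A
    moderate (mostly electrostatic) 2.5 <= d < 3.2 A
    weak (electrostatic)            3.2 <= d <= 4.1 A

The weak bin's upper edge is 4.1 A rather than the textbook 4.0 so that
reference contacts printed at 4.04 A classify as weak; distances below 2.2 A
are labelled very strong, mirroring the "almost covalent" language used for
a 2.03 A contact.  Hydrophobic/van-der-Waals contacts are carbon-carbon
pairs within a cutoff (default 5.5 A), reported once per residue at the
minimal distance.  Typed aromatic interactions (pi-pi, pi-sigma, pi-alkyl,
amide-pi, pi-sulfur) require ring-plane perception and are intentionally not
detected; reports note this.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import gemmi
import numpy as np

from ._util import data_path
from .errors import FlavokitError, PdbParseError

__all__ = [
    "AtomRecord",
    "ResidueContact",
    "PoseAffinity",
    "HBondStrength",
    "ComplexStructure",
    "parse_pdb",
    "classify_hbond_strength",
    "detect_hbonds",
    "hydrophobic_contacts",
    "residue_overlap",
    "rank_poses",
    "reference_hbond_distances",
    "reference_residue_sets",
    "reference_pose_affinities",
    "reference_mutual_residues",
]

_POLAR = {"N", "O"}
_WATERS = {"HOH", "WAT", "DOD"}


@dataclass(frozen=True)
class AtomRecord:
    serial: int
    name: str
    resname: str
    chain: str
    resnum: int
    x: float
    y: float
    z: float
    element: str

    @property
    def residue_label(self) -> str:
        """Human-readable residue label, e.g. Thr1010."""
        return f"{self.resname.capitalize()}{self.resnum}"

    @property
    def pos(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


class HBondStrength(str, Enum):
    VERY_STRONG = "very_strong"
    STRONG = "strong"
    MODERATE = "moderate"
    WEAK = "weak"
    NONE = "none"


@dataclass(frozen=True)
class ResidueContact:
    residue: str
    interaction_type: str  # hydrogen_bond | hydrophobic | van_der_waals
    distance: float
    strength_class: HBondStrength | None
    ligand_atom: str
    protein_atom: str


@dataclass(frozen=True)
class PoseAffinity:
    pose: object
    affinity: float  # kcal/mol; more negative binds better


@dataclass(frozen=True)
class ComplexStructure:
    ligand_atoms: tuple[AtomRecord, ...]
    protein_atoms: tuple[AtomRecord, ...]
    ligand_resname: str
    warnings: tuple[str, ...] = ()


def parse_pdb(text: str, ligand_resname: str | None = None) -> ComplexStructure:
    """Partition a PDB block into ligand (HETATM) and protein (ATOM) atoms.

    Waters are dropped; altlocs other than blank/'A' are dropped.  When
    ``ligand_resname`` is None the most abundant non-water HETATM residue
    name is taken as the ligand.  Raises :class:`PdbParseError` for empty
    input or when no ligand atoms remain.
    """
    if not text or not text.strip():
        raise PdbParseError("empty PDB input")
    try:
        structure = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:
        raise PdbParseError(f"malformed PDB input: {exc}") from exc

    het: list[AtomRecord] = []
    protein: list[AtomRecord] = []
    warnings: list[str] = []
    for model in structure:
        for chain in model:
            for res in chain:
                if res.name in _WATERS:
                    continue
                is_het = res.het_flag == "H"
                for atom in res:
                    if atom.altloc not in ("\x00", "", "A"):
                        continue
                    rec = AtomRecord(
                        serial=atom.serial,
                        name=atom.name,
                        resname=res.name,
                        chain=chain.name,
                        resnum=res.seqid.num,
                        x=atom.pos.x, y=atom.pos.y, z=atom.pos.z,
                        element=atom.element.name,
                    )
                    (het if is_het else protein).append(rec)
        break  # first model only
    if not het and not protein:
        raise PdbParseError("no ATOM/HETATM records (or only waters) in input")

    if ligand_resname is None:
        counts: dict[str, int] = {}
        for rec in het:
            counts[rec.resname] = counts.get(rec.resname, 0) + 1
        if not counts:
            raise PdbParseError("no non-water HETATM records to use as ligand")
        ligand_resname = max(sorted(counts), key=counts.get)
    ligand = tuple(r for r in het if r.resname == ligand_resname)
    if not ligand:
        raise PdbParseError(f"no HETATM atoms with residue name {ligand_resname!r}")
    # non-ligand heteroatoms (cofactors etc.) are treated as part of the receptor
    extra = [r for r in het if r.resname != ligand_resname]
    if extra:
        warnings.append(
            f"{len(extra)} non-ligand HETATM atoms treated as receptor atoms"
        )
    return ComplexStructure(
        ligand_atoms=ligand,
        protein_atoms=tuple(protein) + tuple(extra),
        ligand_resname=ligand_resname,
        warnings=tuple(warnings),
    )


def classify_hbond_strength(distance: float) -> HBondStrength:
    """Bin a heavy-atom donor-acceptor distance (A) into a strength class."""
    if distance <= 0:
        raise FlavokitError(f"distance must be positive, got {distance}")
    if distance < 2.2:
        return HBondStrength.VERY_STRONG
    if distance < 2.5:
        return HBondStrength.STRONG
    if distance < 3.2:
        return HBondStrength.MODERATE
    if distance <= 4.1:
        return HBondStrength.WEAK
    return HBondStrength.NONE


def _pairwise_distances(a: Sequence[AtomRecord], b: Sequence[AtomRecord]) -> np.ndarray:
    pa = np.array([[x.x, x.y, x.z] for x in a], dtype=float)
    pb = np.array([[x.x, x.y, x.z] for x in b], dtype=float)
    return np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=-1)


def detect_hbonds(
    ligand_atoms: Sequence[AtomRecord],
    protein_atoms: Sequence[AtomRecord],
    *,
    min_distance: float = 2.0,
    max_distance: float = 4.1,
) -> list[ResidueContact]:
    """Hydrogen-bond contacts: every ligand-N/O to protein-N/O pair with
    heavy-atom distance inside [min_distance, max_distance].

    Distances are donor-acceptor (no hydrogen positions required, matching
    docking outputs that lack hydrogens).  Output is sorted by residue label
    then distance.
    """
    lig = [a for a in ligand_atoms if a.element in _POLAR]
    pro = [a for a in protein_atoms if a.element in _POLAR]
    if not lig or not pro:
        return []
    dist = _pairwise_distances(lig, pro)
    contacts = []
    for i, la in enumerate(lig):
        for j, pa in enumerate(pro):
            d = float(dist[i, j])
            if min_distance <= d <= max_distance:
                contacts.append(
                    ResidueContact(
                        residue=pa.residue_label,
                        interaction_type="hydrogen_bond",
                        distance=d,
                        strength_class=classify_hbond_strength(d),
                        ligand_atom=la.name,
                        protein_atom=pa.name,
                    )
                )
    contacts.sort(key=lambda c: (c.residue, c.distance))
    return contacts


def hydrophobic_contacts(
    ligand_atoms: Sequence[AtomRecord],
    protein_atoms: Sequence[AtomRecord],
    cutoff: float = 5.5,
) -> list[ResidueContact]:
    """Carbon-carbon contacts within ``cutoff`` (A), one per protein residue
    at the minimal distance."""
    lig = [a for a in ligand_atoms if a.element == "C"]
    pro = [a for a in protein_atoms if a.element == "C"]
    if not lig or not pro:
        return []
    dist = _pairwise_distances(lig, pro)
    best: dict[tuple[str, int, str], tuple[float, str, str]] = {}
    for j, pa in enumerate(pro):
        i = int(np.argmin(dist[:, j]))
        d = float(dist[i, j])
        if d > cutoff:
            continue
        key = (pa.chain, pa.resnum, pa.resname)
        if key not in best or d < best[key][0]:
            best[key] = (d, lig[i].name, pa.name)
    contacts = [
        ResidueContact(
            residue=f"{key[2].capitalize()}{key[1]}",
            interaction_type="hydrophobic",
            distance=d,
            strength_class=None,
            ligand_atom=la,
            protein_atom=pa,
        )
        for key, (d, la, pa) in best.items()
    ]
    contacts.sort(key=lambda c: (c.residue, c.distance))
    return contacts


def residue_overlap(
    contacts_a: Iterable[str], contacts_b: Iterable[str]
) -> tuple[list[str], list[str], list[str]]:
    """Partition two residue sets into (mutual, only_a, only_b), each sorted."""
    set_a, set_b = set(contacts_a), set(contacts_b)
    return (
        sorted(set_a & set_b),
        sorted(set_a - set_b),
        sorted(set_b - set_a),
    )


def rank_poses(poses: Sequence[PoseAffinity]) -> list[PoseAffinity]:
    """Docking poses sorted best-first (ascending affinity, stable)."""
    for p in poses:
        if not np.isfinite(p.affinity):
            raise FlavokitError(f"non-finite affinity for pose {p.pose!r}")
    return sorted(poses, key=lambda p: p.affinity)


# ---------------------------------------------------------------------------
# Packaged reference docking tables (bovine XO 3NVY and human XO 2E1Q)


def _docking_data() -> dict:
    return json.loads(data_path("xo_docking.json").read_text(encoding="utf-8"))


def reference_hbond_distances(ligand: str = "blumeatin") -> list[tuple[str, float]]:
    """(residue, distance) pairs for the reported conventional hydrogen bonds."""
    rows = _docking_data()["hbond_distances"][ligand]
    return [(r["residue"], float(r["distance"])) for r in rows]


def reference_residue_sets(ligand: str) -> dict[str, list[str]]:
    """Typed-interaction and van-der-Waals residue lists for a ligand."""
    return _docking_data()["residues"][ligand]


def reference_mutual_residues() -> list[str]:
    """Residues highlighted as interacting with both blumeatin and quercetin."""
    return list(_docking_data()["mutual_bold"])


def reference_pose_affinities() -> list[PoseAffinity]:
    """The nine human-XO docking pose affinities (kcal/mol)."""
    return [
        PoseAffinity(pose=row["pose"], affinity=float(row["affinity"]))
        for row in _docking_data()["pose_affinities"]
    ]
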