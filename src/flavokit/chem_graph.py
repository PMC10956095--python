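"""Molecular-graph perception for flavonoids.

Parses SMILES into molecular graphs (via RDKit), perceives the flavonoid
scaffold (flavanone / flavone / flavonol) by template matching, assigns
substituent locants in standard flavonoid numbering (C ring 2-4, A ring 5-8,
B ring 2'-6'), evaluates the structural indicator variable of the
radical-scavenging-activity (RSA) QSAR, and screens Lipinski's rule of five.

The rule-of-five screen implements the *oxygen-count* variant used in the
flavonoid pharmacokinetics narrative this package reproduces (MW < 500 g/mol,
MLOGP <= 4.15, O atoms < 10, NH+OH < 5) rather than the canonical N+O
acceptor count; the canonical variant is available via ``variant="canonical"``.

The RSA regression is the two-coefficient reduced indicator form
``RSA = intercept + slope * I``.  Only its value at I = 1 (88.403 %) is
anchored by a machine-readable source; the displayed regression itself was
published as an image, so the split between intercept and slope is a
transcription input.  Defaults are (0.0, 88.403) and the identity
``intercept + slope == 88.403`` is enforced whenever default checking is on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

from rdkit import Chem, RDLogger

from ._util import round_half_away
from .errors import FlavokitError, NonFlavonoidError, SmilesParseError

RDLogger.DisableLog("rdApp.*")  # parse failures are reported as exceptions

__all__ = [
    "Molecule",
    "FlavonoidAnnotation",
    "RuleOfFiveReport",
    "parse_smiles",
    "molecular_weight",
    "rule_of_five",
    "annotate_flavonoid",
    "indicator_variable",
    "predict_rsa",
    "DEFAULT_RSA_COEFFICIENTS",
    "RSA_ANCHOR",
    "check_rsa_coefficients",
    "BLUMEATIN_SMILES",
]

#: Blumeatin (5,3',5'-trihydroxy-7-methoxyflavanone), C16H14O6.
BLUMEATIN_SMILES = "COC1=CC(=C2C(=O)CC(OC2=C1)C3=CC(=CC(=C3)O)O)O"

#: Standard atomic weights (g/mol) for the organic subset handled here.
ATOMIC_WEIGHTS: Mapping[str, float] = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
    "F": 18.998, "P": 30.974, "S": 32.06, "Cl": 35.45, "Br": 79.904,
    "I": 126.904,
}

#: RSA QSAR anchor: the indicator-variable regression evaluates to this
#: percentage at I = 1.
RSA_ANCHOR = 88.403
DEFAULT_RSA_COEFFICIENTS: tuple[float, float] = (0.0, RSA_ANCHOR)


@dataclass(frozen=True)
class Molecule:
    """Light wrapper over an RDKit mol exposing a plain graph view.

    ``atoms`` is a list of (element symbol, formal charge, total H count);
    ``bonds`` is a list of (i, j, order) with order in {1, 2, 3, "ar"}.
    """

    rdkit_mol: Chem.Mol
    smiles: str = ""

    @property
    def atoms(self) -> list[tuple[str, int, int]]:
        return [
            (a.GetSymbol(), a.GetFormalCharge(), a.GetTotalNumHs())
            for a in self.rdkit_mol.GetAtoms()
        ]

    @property
    def bonds(self) -> list[tuple[int, int, object]]:
        order = {
            Chem.BondType.SINGLE: 1,
            Chem.BondType.DOUBLE: 2,
            Chem.BondType.TRIPLE: 3,
            Chem.BondType.AROMATIC: "ar",
        }
        return [
            (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order.get(b.GetBondType()))
            for b in self.rdkit_mol.GetBonds()
        ]

    @property
    def heavy_atom_count(self) -> int:
        return self.rdkit_mol.GetNumAtoms()

    @property
    def implicit_h_count(self) -> int:
        return sum(a.GetTotalNumHs() for a in self.rdkit_mol.GetAtoms())


def parse_smiles(smiles: str) -> Molecule:
    """Parse a SMILES string (organic subset, ring closures, branches,
    double/triple bonds, lowercase aromatics) into a :class:`Molecule`.

    Raises :class:`SmilesParseError` for empty input, unbalanced ring
    closures/parentheses or unknown elements.
    """
    if not smiles or not smiles.strip():
        raise SmilesParseError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles, sanitize=True)
    if mol is None:
        raise SmilesParseError(f"could not parse SMILES {smiles!r}")
    return Molecule(rdkit_mol=mol, smiles=smiles)


def _as_rdkit(mol: Molecule | Chem.Mol) -> Chem.Mol:
    return mol.rdkit_mol if isinstance(mol, Molecule) else mol


def molecular_weight(mol: Molecule | Chem.Mol) -> float:
    """Molecular weight (g/mol, 2 dp) from standard atomic weights over all
    atoms including implicit hydrogens."""
    m = _as_rdkit(mol)
    total = 0.0
    for atom in m.GetAtoms():
        symbol = atom.GetSymbol()
        if symbol not in ATOMIC_WEIGHTS:
            raise FlavokitError(f"no tabulated atomic weight for element {symbol!r}")
        total += ATOMIC_WEIGHTS[symbol] + ATOMIC_WEIGHTS["H"] * atom.GetTotalNumHs()
    return round_half_away(total, 2)


def _count_oxygens(m: Chem.Mol) -> int:
    return sum(1 for a in m.GetAtoms() if a.GetSymbol() == "O")


def _count_nh_oh(m: Chem.Mol) -> int:
    """Hydrogens on nitrogen or oxygen (the NH + OH donor count)."""
    return sum(a.GetTotalNumHs() for a in m.GetAtoms() if a.GetSymbol() in ("N", "O"))


@dataclass(frozen=True)
class RuleOfFiveReport:
    mw: float
    oxygen_count: int
    nh_oh_count: int
    mlogp: float | None
    violations: tuple[str, ...]
    not_evaluated: tuple[str, ...] = ()

    @property
    def passes(self) -> bool:
        return not self.violations


def rule_of_five(
    mol: Molecule | Chem.Mol,
    mlogp: float | None = None,
    *,
    variant: Literal["oxygen_count", "canonical"] = "oxygen_count",
) -> RuleOfFiveReport:
    """Lipinski rule-of-five screen.

    ``oxygen_count`` variant (default): MW >= 500, MLOGP > 4.15, O >= 10,
    NH+OH >= 5 are violations.  ``canonical``: N+O acceptor count >= 10
    replaces the oxygen count.  MLOGP is an externally supplied prediction
    (e.g. from SwissADME); when absent that rule is reported as not
    evaluated, never as a violation.
    """
    m = _as_rdkit(mol)
    mw = molecular_weight(m)
    n_o = _count_oxygens(m)
    nh_oh = _count_nh_oh(m)
    violations: list[str] = []
    not_evaluated: list[str] = []
    if mw >= 500:
        violations.append("MW>=500")
    if mlogp is None:
        not_evaluated.append("MLOGP>4.15")
    elif mlogp > 4.15:
        violations.append("MLOGP>4.15")
    if variant == "canonical":
        acceptors = n_o + sum(1 for a in m.GetAtoms() if a.GetSymbol() == "N")
        if acceptors >= 10:
            violations.append("N+O>=10")
    elif n_o >= 10:
        violations.append("O>=10")
    if nh_oh >= 5:
        violations.append("NH+OH>=5")
    return RuleOfFiveReport(
        mw=mw, oxygen_count=n_o, nh_oh_count=nh_oh, mlogp=mlogp,
        violations=tuple(violations), not_evaluated=tuple(not_evaluated),
    )


# ---------------------------------------------------------------------------
# Flavonoid scaffold perception

# 2-phenylchroman-4-one (flavanone) and 2-phenylchromen-4-one (flavone)
# templates.  Atom order in both SMILES fixes the locant map below.
_FLAVANONE = Chem.MolFromSmiles("O=C1CC(c2ccccc2)Oc2ccccc21")
_FLAVONE = Chem.MolFromSmiles("O=C1C=C(c2ccccc2)Oc2ccccc21")

# template atom index -> flavonoid locant
_LOCANTS: dict[int, str] = {
    0: "O4", 1: "4", 2: "3", 3: "2",
    4: "1'", 5: "2'", 6: "3'", 7: "4'", 8: "5'", 9: "6'",
    10: "O1", 11: "8a", 12: "8", 13: "7", 14: "6", 15: "5", 16: "4a",
}
_RING_C = ("O1", "2", "3", "4", "4a", "8a")
_RING_A = ("4a", "5", "6", "7", "8", "8a")
_RING_B = ("1'", "2'", "3'", "4'", "5'", "6'")
#: carbons that can carry a substituent, in canonical report order
_SUBSTITUTABLE = ("3", "5", "6", "7", "8", "2'", "3'", "4'", "5'", "6'")


@dataclass(frozen=True)
class FlavonoidAnnotation:
    scaffold_class: Literal["flavanone", "flavone", "flavonol", "non-flavonoid"]
    ring_atoms: Mapping[str, frozenset[int]] = field(default_factory=dict)
    substituents: tuple[tuple[str, str], ...] = ()
    has_C2C3_double_bond: bool = False
    has_3_OH: bool = False
    has_5_OH: bool = False
    has_3p4p_catechol: bool = False
    hydroxyl_count: int = 0

    @property
    def is_flavonoid(self) -> bool:
        return self.scaffold_class != "non-flavonoid"


def _classify_substituent(m: Chem.Mol, ring_atom: Chem.Atom,
                          scaffold: frozenset[int]) -> str | None:
    """Group label for the exocyclic substituent on one scaffold carbon."""
    for nbr in ring_atom.GetNeighbors():
        if nbr.GetIdx() in scaffold:
            continue
        if nbr.GetSymbol() == "O":
            bond = m.GetBondBetweenAtoms(ring_atom.GetIdx(), nbr.GetIdx())
            if bond.GetBondType() == Chem.BondType.DOUBLE:
                return "=O"
            if nbr.GetTotalNumHs() >= 1:
                return "OH"
            carbons = [x for x in nbr.GetNeighbors() if x.GetIdx() != ring_atom.GetIdx()]
            if (len(carbons) == 1 and carbons[0].GetSymbol() == "C"
                    and carbons[0].GetTotalNumHs() == 3):
                return "OMe"
            return "OR"
        return "other"
    return None


def _annotate_match(m: Chem.Mol, match: Sequence[int]) -> dict:
    locant_of = {_LOCANTS[t]: match[t] for t in range(len(match))}
    scaffold = frozenset(match)
    subs: list[tuple[str, str]] = [("4", "=O")]
    for loc in _SUBSTITUTABLE:
        atom = m.GetAtomWithIdx(locant_of[loc])
        group = _classify_substituent(m, atom, scaffold)
        if group is not None:
            subs.append((loc, group))
    return {"locant_of": locant_of, "substituents": tuple(subs)}


def _locant_sort_key(sub: tuple[str, str]):
    order = ("2", "3", "4", "5", "6", "7", "8",
             "2'", "3'", "4'", "5'", "6'")
    return (order.index(sub[0]), sub[1])


def annotate_flavonoid(mol: Molecule | Chem.Mol) -> FlavonoidAnnotation:
    """Perceive the flavonoid scaffold and annotate substituent locants.

    Returns ``scaffold_class="non-flavonoid"`` (with empty annotations, not an
    exception) when neither the flavanone nor the flavone template matches.
    The pendant B ring can map onto the template two ways; the mapping whose
    substituent locant list sorts first is reported, while symmetry-dependent
    flags (the 3',4'-catechol) are evaluated over *all* mappings.
    """
    m = _as_rdkit(mol)
    template, base_class = None, None
    for tmpl, cls in ((_FLAVONE, "flavone"), (_FLAVANONE, "flavanone")):
        if m.HasSubstructMatch(tmpl):
            template, base_class = tmpl, cls
            break
    hydroxyls = sum(
        a.GetTotalNumHs() for a in m.GetAtoms() if a.GetSymbol() == "O"
    )
    if template is None:
        return FlavonoidAnnotation(scaffold_class="non-flavonoid",
                                   hydroxyl_count=hydroxyls)

    matches = m.GetSubstructMatches(template, uniquify=False)
    annotated = [_annotate_match(m, mt) for mt in matches]
    catechol = any(
        {("3'", "OH"), ("4'", "OH")} <= set(a["substituents"]) for a in annotated
    )
    best = min(annotated,
               key=lambda a: sorted(map(_locant_sort_key, a["substituents"])))
    locant_of = best["locant_of"]
    subs = tuple(sorted(best["substituents"], key=_locant_sort_key))
    sub_set = set(subs)
    has_3_oh = ("3", "OH") in sub_set
    has_5_oh = ("5", "OH") in sub_set
    scaffold_class = base_class
    if base_class == "flavone" and has_3_oh:
        scaffold_class = "flavonol"
    ring_atoms = {
        "A": frozenset(locant_of[x] for x in _RING_A),
        "B": frozenset(locant_of[x] for x in _RING_B),
        "C": frozenset(locant_of[x] for x in _RING_C),
    }
    return FlavonoidAnnotation(
        scaffold_class=scaffold_class,
        ring_atoms=ring_atoms,
        substituents=subs,
        has_C2C3_double_bond=(base_class == "flavone"),
        has_3_OH=has_3_oh,
        has_5_OH=has_5_oh,
        has_3p4p_catechol=catechol,
        hydroxyl_count=hydroxyls,
    )


def indicator_variable(annotation: FlavonoidAnnotation) -> int:
    """Binary QSAR indicator: 1 iff the molecule has a 3',4'-catechol, a
    3-OH, a 5-OH, or the C2=C3 double bond.  Undefined for non-flavonoids."""
    if not annotation.is_flavonoid:
        raise NonFlavonoidError("indicator variable undefined for non-flavonoids")
    return int(
        annotation.has_3p4p_catechol
        or annotation.has_3_OH
        or annotation.has_5_OH
        or annotation.has_C2C3_double_bond
    )


def check_rsa_coefficients(coefficients: tuple[float, float],
                           *, tol: float = 1e-6) -> None:
    """Enforce the anchor identity intercept + slope == 88.403."""
    intercept, slope = coefficients
    if abs(intercept + slope - RSA_ANCHOR) > tol:
        raise FlavokitError(
            f"RSA coefficients {coefficients} violate intercept + slope "
            f"== {RSA_ANCHOR}"
        )


def predict_rsa(
    indicator: int,
    coefficients: tuple[float, float] = DEFAULT_RSA_COEFFICIENTS,
    *,
    check_anchor: bool = False,
) -> float:
    """Predicted radical scavenging activity (%) at 3 dp from the reduced
    indicator regression RSA = intercept + slope * I."""
    if check_anchor:
        check_rsa_coefficients(coefficients)
    intercept, slope = coefficients
    return round_half_away(intercept + slope * float(indicator), 3)
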