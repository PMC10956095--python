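"""Exception hierarchy used across the toolkit."""


class FlavokitError(Exception):
    """Base class for all toolkit errors."""


class IncompleteRecordError(FlavokitError):
    """A frontier-orbital record supplies neither a full (E_HOMO, E_LUMO) pair
    nor a full (I, A) pair."""


class DegenerateHardnessError(FlavokitError):
    """Chemical hardness is zero (I == A); softness, electrophilicity and
    nucleophilicity are undefined."""


class SmilesParseError(FlavokitError):
    """A SMILES string could not be parsed into a molecular graph."""


class NonFlavonoidError(FlavokitError):
    """An operation that requires a flavonoid scaffold was applied to a
    molecule that matched no flavonoid template."""


class PdbParseError(FlavokitError):
    """A PDB block could not be parsed, or contains no usable atoms."""


class DegenerateGeometryError(FlavokitError):
    """Three consecutive torsion points are collinear; the dihedral is
    undefined."""


class GenerationError(FlavokitError):
    """A synthetic-data generator received an unsatisfiable request."""


class ConfigError(FlavokitError):
    """A configuration file failed validation."""
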