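"""Conceptual-DFT global reactivity descriptors.

Scalar reactivity indices built from a compound's vertical ionization
potential ``I`` and electron affinity ``A`` (or, via the Koopmans
approximation, from its frontier-orbital energies ``E_HOMO``/``E_LUMO``):

    electronegativity   chi   = (I + A) / 2
    chemical potential  mu    = -chi
    global hardness     eta   = (I - A) / 2
    HOMO-LUMO gap       dE    = E_HOMO - E_LUMO  (== -(I - A) under Koopmans)
    electrophilicity    omega = mu**2 / (2 * eta)
    global softness     s     = 1 / (2 * eta)
    nucleophilicity     eps   = mu * eta

Two conventions for global softness circulate in the literature, ``1/(2*eta)``
and ``1/eta``; the default here is ``1/(2*eta)``, which is the convention the
reference flavonoid comparison table actually uses (e.g. s = 16.67 for a
compound with eta = 0.03 eV).  The ``1/eta`` variant is available through
``softness_convention="inverse_eta"``.

Nucleophilicity has no universally agreed closed form; ``mu * eta`` is the
relation consistent with every tabulated value we reproduce and is documented
as inferred.

All intermediates are kept at full float precision; rounding to the 2-dp
report view happens only in :meth:`ReactivityDescriptors.report`, with ties
away from zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import pandas as pd

from ._util import data_path, round_half_away
from .errors import DegenerateHardnessError, IncompleteRecordError

__all__ = [
    "FrontierOrbitalRecord",
    "ReactivityDescriptors",
    "koopmans_ia",
    "descriptors_from_ia",
    "descriptors_from_record",
    "rank_by_gap",
    "read_orbital_table",
    "write_descriptor_table",
    "reference_orbital_records",
]

SoftnessConvention = Literal["inverse_2eta", "inverse_eta"]


@dataclass(frozen=True)
class FrontierOrbitalRecord:
    """One compound's frontier-orbital input row.

    At least one of the pairs (``e_homo``, ``e_lumo``) or (``i``, ``a``) must
    be fully present.  Energies are in eV.
    """

    compound: str
    e_homo: float | None = None
    e_lumo: float | None = None
    i: float | None = None
    a: float | None = None
    source: str = ""

    @property
    def has_orbitals(self) -> bool:
        return self.e_homo is not None and self.e_lumo is not None

    @property
    def has_ia(self) -> bool:
        return self.i is not None and self.a is not None

    def validate(self) -> None:
        if not (self.has_orbitals or self.has_ia):
            raise IncompleteRecordError(
                f"{self.compound!r}: need a full (e_homo, e_lumo) or (i, a) pair"
            )
        for label, value in (
            ("e_homo", self.e_homo),
            ("e_lumo", self.e_lumo),
            ("i", self.i),
            ("a", self.a),
        ):
            if value is not None and not math.isfinite(value):
                raise IncompleteRecordError(
                    f"{self.compound!r}: non-finite {label} = {value}"
                )


@dataclass(frozen=True)
class ReactivityDescriptors:
    """Full-precision descriptor set for one compound.

    ``route`` records whether the values came from printed (I, A) or from the
    Koopmans approximation on orbital energies.
    """

    i: float
    a: float
    gap: float
    chi: float
    mu: float
    eta: float
    omega: float
    softness: float
    nucleophilicity: float
    route: Literal["printed_ia", "koopmans"] = "koopmans"

    _REPORT_FIELDS = ("i", "a", "gap", "chi", "mu", "eta", "omega",
                      "softness", "nucleophilicity")

    def report(self) -> dict[str, float]:
        """2-dp report view (ties away from zero)."""
        return {f: round_half_away(getattr(self, f), 2) for f in self._REPORT_FIELDS}


def koopmans_ia(e_homo: float, e_lumo: float) -> tuple[float, float]:
    """Koopmans approximation: I = -E_HOMO, A = -E_LUMO (eV)."""
    if e_homo is None or e_lumo is None or not (
        math.isfinite(e_homo) and math.isfinite(e_lumo)
    ):
        raise IncompleteRecordError("both orbital energies must be finite")
    return -e_homo, -e_lumo


def descriptors_from_ia(
    i: float,
    a: float,
    *,
    gap: float | None = None,
    route: Literal["printed_ia", "koopmans"] = "printed_ia",
    softness_convention: SoftnessConvention = "inverse_2eta",
) -> ReactivityDescriptors:
    """Compute the descriptor set from an (I, A) pair.

    ``gap`` overrides the reported HOMO-LUMO gap (used when orbital energies
    are available and the gap is E_HOMO - E_LUMO); by default -(I - A).
    """
    if not (math.isfinite(i) and math.isfinite(a)):
        raise IncompleteRecordError("I and A must be finite")
    chi = (i + a) / 2.0
    mu = -chi
    eta = (i - a) / 2.0
    if eta == 0.0:
        raise DegenerateHardnessError(
            f"eta = 0 for (I, A) = ({i}, {a}); omega, s, epsilon undefined"
        )
    omega = mu * mu / (2.0 * eta)
    softness = 1.0 / eta if softness_convention == "inverse_eta" else 1.0 / (2.0 * eta)
    nucleophilicity = mu * eta
    return ReactivityDescriptors(
        i=i,
        a=a,
        gap=-(i - a) if gap is None else gap,
        chi=chi,
        mu=mu,
        eta=eta,
        omega=omega,
        softness=softness,
        nucleophilicity=nucleophilicity,
        route=route,
    )


def descriptors_from_record(
    record: FrontierOrbitalRecord,
    *,
    softness_convention: SoftnessConvention = "inverse_2eta",
) -> ReactivityDescriptors:
    """Dispatch: printed (I, A) take precedence over Koopmans-derived values.

    Some literature rows print (I, A) pairs that are *not* the Koopmans
    negatives of the orbital energies in the same row (e.g. from a Delta-SCF
    calculation); the printed pair is treated as authoritative.  The reported
    gap is E_HOMO - E_LUMO only when the orbital path is taken (or when the
    printed pair is Koopmans-consistent, in which case the two coincide);
    otherwise it is -(I - A) so that the gap stays consistent with the
    hardness actually used.
    """
    record.validate()
    if record.has_ia:
        gap = None
        if record.has_orbitals:
            k_i, k_a = koopmans_ia(record.e_homo, record.e_lumo)
            if abs(k_i - record.i) < 1e-9 and abs(k_a - record.a) < 1e-9:
                gap = record.e_homo - record.e_lumo
        return descriptors_from_ia(
            record.i, record.a, gap=gap, route="printed_ia",
            softness_convention=softness_convention,
        )
    i, a = koopmans_ia(record.e_homo, record.e_lumo)
    return descriptors_from_ia(
        i, a, gap=record.e_homo - record.e_lumo, route="koopmans",
        softness_convention=softness_convention,
    )


def rank_by_gap(records: Iterable[FrontierOrbitalRecord]) -> list[str]:
    """Compound names sorted by |HOMO-LUMO gap| descending (hardest / least
    reactive first); ties broken alphabetically."""
    keyed = []
    for rec in records:
        desc = descriptors_from_record(rec)
        if not math.isfinite(desc.gap):
            raise IncompleteRecordError(f"{rec.compound!r}: non-finite gap")
        keyed.append((-abs(desc.gap), rec.compound))
    return [name for _, name in sorted(keyed)]


# ---------------------------------------------------------------------------
# CSV interface


def _cell(value) -> float | None:
    return None if pd.isna(value) else float(value)


def read_orbital_table(path) -> list[FrontierOrbitalRecord]:
    """Read a CSV/TSV with columns compound,e_homo,e_lumo,i,a,source
    (blank cells = absent)."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    records = []
    for row in df.itertuples(index=False):
        records.append(
            FrontierOrbitalRecord(
                compound=str(row.compound),
                e_homo=_cell(getattr(row, "e_homo", None)),
                e_lumo=_cell(getattr(row, "e_lumo", None)),
                i=_cell(getattr(row, "i", None)),
                a=_cell(getattr(row, "a", None)),
                source="" if pd.isna(getattr(row, "source", "")) else str(row.source),
            )
        )
    return records


def write_descriptor_table(
    records: Sequence[FrontierOrbitalRecord], path,
    *, softness_convention: SoftnessConvention = "inverse_2eta",
) -> pd.DataFrame:
    """Compute descriptors for every record and write a CSV with full-precision
    columns plus ``*_2dp`` report columns."""
    rows = []
    for rec in records:
        desc = descriptors_from_record(rec, softness_convention=softness_convention)
        row: dict[str, object] = {"compound": rec.compound, "source": rec.source,
                                  "route": desc.route}
        for f in ReactivityDescriptors._REPORT_FIELDS:
            row[f] = getattr(desc, f)
        for f, v in desc.report().items():
            row[f"{f}_2dp"] = v
        rows.append(row)
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, index=False)
    return df


def reference_orbital_records(
    *, quercetin_source: str | None = "ref78",
) -> list[FrontierOrbitalRecord]:
    """The packaged 11-row flavonoid comparison table.

    Quercetin appears twice (two literature sources); ``quercetin_source``
    selects which row to keep (None keeps both).  The gap-ordering narrative
    is consistent with the ref78 row, hence the default.
    """
    records = read_orbital_table(data_path("orbital_table.csv"))
    if quercetin_source is None:
        return records
    return [
        r for r in records
        if r.compound != "quercetin" or r.source == quercetin_source
    ]
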