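"""Small shared helpers: report-boundary rounding and packaged-data access."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from importlib import resources


def round_half_away(x: float, ndigits: int = 0) -> float | int:
    """Round to `ndigits` decimals with ties going away from zero.

    All descriptor arithmetic is done on unrounded floats; this is applied
    only at the report boundary (2 dp for energies, 3 dp for RSA percentages,
    integers for wavenumbers).  The value is first quantised at 9 dp so that
    exact decimal ties reached through float arithmetic (3.535 stored as
    3.5349999999999997) still round away from zero.
    """
    d = Decimal(repr(float(x))).quantize(Decimal("1e-9"), rounding=ROUND_HALF_UP)
    d = d.quantize(Decimal(1).scaleb(-ndigits), rounding=ROUND_HALF_UP)
    return int(d) if ndigits <= 0 else float(d)


def data_path(name: str):
    """Return a traversable handle to a packaged data file."""
    return resources.files("flavokit.data").joinpath(name)


def read_data_text(name: str) -> str:
    return data_path(name).read_text(encoding="utf-8")
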