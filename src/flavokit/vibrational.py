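"""Harmonic wavenumber scaling, peak assignment and Fermi-resonance search.

DFT harmonic wavenumbers systematically overestimate observed fundamentals;
an empirical multiplicative scale factor corrects them.  This module
implements a two-region scheme: one factor below a boundary wavenumber and a
second at/above it (defaults 0.967 below 1800 cm-1 and 0.955 above, the
values appropriate for B3LYP/6-311++G(d,p) chromone-type spectra).  The
boundary case itself is unobservable in the reference data (no mode falls
between 1744 and 2997 cm-1); the convention here is ``< boundary`` ->
``factor_low``.

Fermi resonance: a fundamental may split when an overtone (n*nu) or a
combination band (nu_i + nu_j) nearly coincides with it.  The searches here
enumerate candidates by wavenumber alone (no intensity model) against a
target band and tolerance.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from ._util import data_path, round_half_away
from .errors import FlavokitError

__all__ = [
    "ScalingScheme",
    "VibrationalMode",
    "DEFAULT_SCHEME",
    "scale",
    "scale_table",
    "match_peaks",
    "PeakMatch",
    "find_combination_bands",
    "find_overtones",
    "estimate_scale_factor",
    "read_mode_table",
    "write_mode_table",
    "blumeatin_modes",
    "blumeatin_experimental_bands",
    "EXTRA_OBSERVED_BANDS",
]


@dataclass(frozen=True)
class ScalingScheme:
    """Two-region multiplicative scaling with nearest-integer rounding
    (ties away from zero)."""

    boundary: float = 1800.0
    factor_low: float = 0.967
    factor_high: float = 0.955

    def __post_init__(self):
        if self.boundary <= 0:
            raise FlavokitError("scaling boundary must be positive")
        for f in (self.factor_low, self.factor_high):
            if not 0 < f <= 1.2:
                raise FlavokitError(f"implausible scale factor {f}")

    def factor_for(self, unscaled: float) -> float:
        return self.factor_low if unscaled < self.boundary else self.factor_high


DEFAULT_SCHEME = ScalingScheme()


@dataclass(frozen=True)
class VibrationalMode:
    """One normal mode.  ``assignment`` carries the PED text verbatim; it is
    annotation only and never enters computation."""

    index: int
    unscaled: float
    scaled: int | None = None
    experimental: float | None = None
    notation: str = ""
    assignment: str = ""


def scale(unscaled: float, scheme: ScalingScheme = DEFAULT_SCHEME) -> int:
    """Scaled wavenumber (integer cm-1) under the two-region scheme."""
    if unscaled <= 0:
        raise FlavokitError(f"wavenumber must be positive, got {unscaled}")
    return round_half_away(unscaled * scheme.factor_for(unscaled), 0)


def scale_table(
    modes: Sequence[VibrationalMode], scheme: ScalingScheme = DEFAULT_SCHEME
) -> list[VibrationalMode]:
    """Fill the scaled column for every mode, preserving order."""
    out = []
    for mode in modes:
        try:
            out.append(replace(mode, scaled=scale(mode.unscaled, scheme)))
        except FlavokitError as exc:
            raise FlavokitError(f"mode {mode.index}: {exc}") from exc
    return out


@dataclass(frozen=True)
class PeakMatch:
    pairs: tuple[tuple[float, float, float], ...]  # (computed, experimental, |delta|)
    unmatched_computed: tuple[float, ...]
    unmatched_experimental: tuple[float, ...]


def match_peaks(
    computed: Sequence[float],
    experimental: Sequence[float],
    tolerance: float = 15.0,
) -> PeakMatch:
    """Assign each experimental peak to at most one computed peak, minimising
    the total |computed - experimental| over all assignments within
    ``tolerance``; ties resolve toward the lower computed index.

    Solved as a rectangular linear assignment problem with forbidden cells
    for out-of-tolerance pairs.  Equal-total optima are common (crossing two
    pairs on the same side of their peaks leaves the total unchanged); a
    vanishing epsilon on the squared index offset (i - j)^2 resolves them
    deterministically toward the non-crossing assignment, which also sends
    ties toward the lower computed index.
    """
    if tolerance <= 0:
        raise FlavokitError("tolerance must be positive")
    if not computed or not experimental:
        return PeakMatch((), tuple(computed), tuple(experimental))
    comp = np.asarray(computed, dtype=float)
    expe = np.asarray(experimental, dtype=float)
    delta = np.abs(comp[:, None] - expe[None, :])
    feasible = delta <= tolerance
    big = 1e9
    idx_c = np.arange(len(comp))[:, None]
    idx_e = np.arange(len(expe))[None, :]
    eps = 1e-9 * (idx_c - idx_e) ** 2
    cost = np.where(feasible, delta + eps, big)
    rows, cols = linear_sum_assignment(cost)
    pairs, used_c, used_e = [], set(), set()
    for r, c in zip(rows, cols):
        if feasible[r, c]:
            pairs.append((float(comp[r]), float(expe[c]), float(delta[r, c])))
            used_c.add(r)
            used_e.add(c)
    pairs.sort(key=lambda p: (p[0], p[1]))
    return PeakMatch(
        pairs=tuple(pairs),
        unmatched_computed=tuple(float(c) for i, c in enumerate(comp) if i not in used_c),
        unmatched_experimental=tuple(float(e) for j, e in enumerate(expe) if j not in used_e),
    )


def find_combination_bands(
    bands: Iterable[float], target: float, tolerance: float
) -> list[tuple[float, float, float]]:
    """All unordered band pairs (b_i <= b_j, repetition allowed) with
    |b_i + b_j - target| <= tolerance, sorted by deviation then by b_i."""
    if tolerance < 0:
        raise FlavokitError("tolerance must be non-negative")
    values = sorted(float(b) for b in bands)
    hits = []
    for b_i, b_j in itertools.combinations_with_replacement(values, 2):
        s = b_i + b_j
        if abs(s - target) <= tolerance:
            hits.append((b_i, b_j, s))
    hits.sort(key=lambda h: (abs(h[2] - target), h[0]))
    return hits


def find_overtones(
    bands: Iterable[float], target: float, tolerance: float, max_order: int = 3
) -> list[tuple[float, int, float]]:
    """All (band, n, n*band) with 2 <= n <= max_order and
    |n*band - target| <= tolerance, sorted by deviation then band."""
    if max_order < 2:
        raise FlavokitError("max_order must be at least 2")
    hits = []
    for band in sorted(float(b) for b in bands):
        for n in range(2, max_order + 1):
            value = n * band
            if abs(value - target) <= tolerance:
                hits.append((band, n, value))
    hits.sort(key=lambda h: (abs(h[2] - target), h[0]))
    return hits


def estimate_scale_factor(pairs: Sequence[tuple[float, float]]) -> float:
    """Least-squares slope through the origin for (computed, experimental)
    pairs: sum(c*e) / sum(c**2)."""
    if len(pairs) < 2:
        raise FlavokitError("need at least two (computed, experimental) pairs")
    c = np.asarray([p[0] for p in pairs], dtype=float)
    e = np.asarray([p[1] for p in pairs], dtype=float)
    if np.any(c <= 0):
        raise FlavokitError("computed wavenumbers must be positive")
    denom = float(np.dot(c, c))
    if denom == 0.0:
        raise FlavokitError("all computed wavenumbers are zero")
    return float(np.dot(c, e) / denom)


# ---------------------------------------------------------------------------
# TSV interface and packaged reference spectrum


def read_mode_table(path) -> list[VibrationalMode]:
    """Read a TSV with columns mode,unscaled,scaled,experimental,notation,
    assignment (blank = absent)."""
    df = pd.read_csv(path, sep="\t")
    modes = []
    for row in df.itertuples(index=False):
        modes.append(
            VibrationalMode(
                index=int(row.mode),
                unscaled=float(row.unscaled),
                scaled=None if pd.isna(row.scaled) else int(row.scaled),
                experimental=None if pd.isna(row.experimental) else float(row.experimental),
                notation="" if pd.isna(row.notation) else str(row.notation),
                assignment="" if pd.isna(row.assignment) else str(row.assignment),
            )
        )
    return modes


def write_mode_table(modes: Sequence[VibrationalMode], path) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "mode": [m.index for m in modes],
            "unscaled": [m.unscaled for m in modes],
            "scaled": [m.scaled for m in modes],
            "experimental": [m.experimental for m in modes],
            "notation": [m.notation for m in modes],
            "assignment": [m.assignment for m in modes],
        }
    )
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df


def blumeatin_modes() -> list[VibrationalMode]:
    """The packaged 102-mode blumeatin assignment table (computed, scaled and
    observed FTIR wavenumbers with notation and PED text)."""
    return read_mode_table(data_path("blumeatin_modes.tsv"))


#: FTIR bands observed for blumeatin that do not appear in the assignment
#: table's experimental column: the 1089 cm-1 combination partner, the
#: 1635/1603 cm-1 Fermi satellites, the 3189 cm-1 C-H stretch and the
#: 3367 cm-1 O-H shoulder.
EXTRA_OBSERVED_BANDS: tuple[float, ...] = (1089.0, 1603.0, 1635.0, 3189.0, 3367.0)


def blumeatin_experimental_bands(*, include_extra: bool = True) -> list[float]:
    """Observed FTIR band list: the assignment table's experimental column,
    optionally augmented with the observed bands not listed there."""
    bands = [m.experimental for m in blumeatin_modes() if m.experimental is not None]
    if include_extra:
        bands.extend(EXTRA_OBSERVED_BANDS)
    return sorted(set(bands))
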