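"""Torsion (dihedral) angles and planarity classification.

The signed dihedral over an atom quadruple (p1, p2, p3, p4) is the angle
between the plane of (p1, p2, p3) and the plane of (p2, p3, p4), computed
with the standard two-normal atan2 construction and reported in degrees in
(-180, 180] with the IUPAC sign convention (positive = clockwise rotation of
p4 relative to p1 when sighting down p2 -> p3).

Planarity: a ring system is called coplanar when its defining torsion lies
within ``threshold`` degrees of 0 or 180.  The default threshold is 20 deg;
literature usage is inconsistent (a 16.29 deg ring-B torsion has been called
"twisted"), so reports should always show the raw angle alongside the class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DegenerateGeometryError

__all__ = ["torsion", "planarity_class", "TorsionReport", "DEFAULT_PLANARITY_THRESHOLD"]

DEFAULT_PLANARITY_THRESHOLD = 20.0


@dataclass(frozen=True)
class TorsionReport:
    labels: tuple[str, str, str, str]
    angle: float
    planarity_class: str
    threshold: float


def torsion(
    p1: Sequence[float],
    p2: Sequence[float],
    p3: Sequence[float],
    p4: Sequence[float],
) -> float:
    """Signed dihedral angle (degrees, (-180, 180]) over four points (A)."""
    a, b, c, d = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    for p in (a, b, c, d):
        if p.shape != (3,) or not np.all(np.isfinite(p)):
            raise DegenerateGeometryError("torsion points must be finite 3-vectors")
    b1 = b - a
    b2 = c - b
    b3 = d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    norm_b2 = np.linalg.norm(b2)
    if norm_b2 == 0 or np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12:
        raise DegenerateGeometryError("three consecutive points are collinear")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2) / norm_b2)
    angle = math.degrees(math.atan2(y, x))
    return 180.0 if angle == -180.0 else angle


def planarity_class(
    angle: float, threshold: float = DEFAULT_PLANARITY_THRESHOLD
) -> str:
    """'coplanar' iff the angle is within ``threshold`` degrees of 0 or 180
    (syn- or anti-planar), else 'twisted'."""
    if threshold <= 0:
        raise DegenerateGeometryError("planarity threshold must be positive")
    deviation = min(abs(angle), abs(180.0 - abs(angle)))
    return "coplanar" if deviation <= threshold else "twisted"
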