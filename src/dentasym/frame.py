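"""Constrained right-handed facial coordinate frame.

The frame is defined by three line-perpendicularity constraints on an
orthonormal basis (rows X transverse, Y sagittal, Z vertical):

* X is perpendicular to the line from labrale superius (LS) to nasion (N),
* Y is perpendicular to the line joining the two eye centres (CPR-CPL),
* Z is perpendicular to the line joining mid-porion and mid-orbitale
  (MP-MO, the Frankfort-horizontal direction),

with the origin at LS.  Orientation is fixed anatomically: +X points to
the patient's right (X.(CPR-CPL) > 0), +Z superior (Z.(N-LS) > 0), and
Y = Z x X completes a right-handed system, so +Y points anterior and a
negative x-coordinate means "to the patient's left".

Three perpendicularity constraints on three rotational degrees of
freedom generically determine the basis up to the discrete orientation
choices above.  The solver initialises by Gram-Schmidt and refines on
the rotation manifold; for anatomically plausible inputs the residual
converges to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from dentasym.io import Point3, RatingRecord

__all__ = [
    "GeometryError",
    "DerivedPoints",
    "FacialFrame",
    "derive_points",
    "solve_frame",
    "frame_from_landmarks",
    "to_frame",
    "from_frame",
]

#: Constraint pairs must subtend at least this angle (degrees); closer
#: collinearity indicates corrupt input rather than anatomy.
DEGENERACY_ANGLE_DEG = 5.0

#: Residual bound on the normalized perpendicularity constraints.
RESIDUAL_TOL = 1e-9


class GeometryError(ValueError):
    """Degenerate geometric configuration (collinear constraints etc.)."""


_MIDPOINT_PAIRS = {
    "CPR": ("EXR", "ENR"),
    "CPL": ("EXL", "ENL"),
    "MP": ("PR", "PL"),
    "MO": ("OR", "OL"),
    "dentMid": ("mes11", "mes21"),
}


@dataclass(frozen=True)
class DerivedPoints:
    """Midpoint constructions: eye centres, mid-porion/orbitale, dental midline."""

    CPR: Point3
    CPL: Point3
    MP: Point3
    MO: Point3
    dentMid: Point3


@dataclass(frozen=True)
class FacialFrame:
    """Origin (LS) plus a proper-rotation basis with rows X, Y, Z."""

    origin: Point3
    basis: np.ndarray  # (3, 3), rows are unit X/Y/Z

    def __post_init__(self) -> None:
        b = np.asarray(self.basis, dtype=float)
        if b.shape != (3, 3):
            raise ValueError("basis must be 3x3")
        if not np.allclose(b @ b.T, np.eye(3), atol=1e-9):
            raise ValueError("basis rows must be orthonormal")
        if np.linalg.det(b) < 0:
            raise ValueError("basis must be right-handed (det +1)")

    @property
    def x_axis(self) -> np.ndarray:
        return self.basis[0]

    @property
    def y_axis(self) -> np.ndarray:
        return self.basis[1]

    @property
    def z_axis(self) -> np.ndarray:
        return self.basis[2]


def derive_points(record: RatingRecord) -> DerivedPoints:
    """Construct the midpoint landmarks a record's frame and metrics need."""
    values = {}
    for name, (a, b) in _MIDPOINT_PAIRS.items():
        for constituent in (a, b):
            if constituent not in record.landmarks:
                raise KeyError(
                    f"landmark {constituent!r} (needed for {name}) missing "
                    f"from record {record.key}"
                )
        values[name] = Point3.midpoint(record.landmarks[a], record.landmarks[b])
    return DerivedPoints(**values)


def _unit(v: np.ndarray, what: str) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0.0:
        raise GeometryError(f"{what} constraint vector is zero")
    return v / n


def solve_frame(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    origin: Point3,
    degeneracy_angle_deg: float = DEGENERACY_ANGLE_DEG,
) -> FacialFrame:
    """Solve for the facial frame from the three constraint vectors.

    Parameters
    ----------
    a : LS -> N direction (X must be perpendicular to it; Z.a > 0).
    b : CPL -> CPR direction, i.e. CPR - CPL (Y perpendicular; X.b > 0).
    c : MO -> MP direction, i.e. MP - MO (Z perpendicular to it).
    origin : frame origin (LS).

    Raises :class:`GeometryError` if any pair of constraint vectors is
    within *degeneracy_angle_deg* of collinear, or if the refined
    solution leaves a constraint residual above ``1e-9``.
    """
    ah = _unit(np.asarray(a, dtype=float), "LS-N")
    bh = _unit(np.asarray(b, dtype=float), "CPR-CPL")
    ch = _unit(np.asarray(c, dtype=float), "MP-MO")

    min_cross = np.sin(np.deg2rad(degeneracy_angle_deg))
    for u, v, names in ((ah, bh, "LS-N/CPR-CPL"), (ah, ch, "LS-N/MP-MO"), (bh, ch, "CPR-CPL/MP-MO")):
        if np.linalg.norm(np.cross(u, v)) < min_cross:
            raise GeometryError(f"constraint vectors {names} are near-collinear")

    # Gram-Schmidt initializer: X from b orthogonalized against a,
    # Z from a orthogonalized against X, Y completing the triad.
    x0 = _unit(bh - (bh @ ah) * ah, "X init")
    z0 = _unit(ah - (ah @ x0) * x0, "Z init")
    y0 = np.cross(z0, x0)
    r0 = Rotation.from_matrix(np.vstack([x0, y0, z0]).T)  # columns = frame rows

    def residuals(rotvec: np.ndarray) -> np.ndarray:
        m = (r0 * Rotation.from_rotvec(rotvec)).as_matrix().T
        return np.array([m[0] @ ah, m[1] @ bh, m[2] @ ch])

    sol = least_squares(residuals, np.zeros(3), method="lm", xtol=1e-15, ftol=1e-15, gtol=1e-15)
    basis = (r0 * Rotation.from_rotvec(sol.x)).as_matrix().T

    # Orientation: +X toward patient's right, +Z superior.
    if basis[0] @ bh < 0:
        basis[0] = -basis[0]
    if basis[2] @ ah < 0:
        basis[2] = -basis[2]
    basis[1] = np.cross(basis[2], basis[0])

    res = np.array([basis[0] @ ah, basis[1] @ bh, basis[2] @ ch])
    if np.max(np.abs(res)) > RESIDUAL_TOL:
        raise GeometryError(
            f"frame solver residual {np.max(np.abs(res)):.3e} exceeds {RESIDUAL_TOL}"
        )
    return FacialFrame(origin=origin, basis=basis)


def frame_from_landmarks(record: RatingRecord) -> FacialFrame:
    """Build the facial frame of one rating from its own landmarks."""
    derived = derive_points(record)
    ls = record.landmarks.get("LS")
    n = record.landmarks.get("N")
    if ls is None or n is None:
        raise KeyError(f"LS and N required to build the frame for {record.key}")
    a = n.as_array() - ls.as_array()
    b = derived.CPR.as_array() - derived.CPL.as_array()
    c = derived.MP.as_array() - derived.MO.as_array()
    return solve_frame(a, b, c, origin=ls)


def to_frame(p: Point3, frame: FacialFrame) -> Point3:
    """Express *p* in frame coordinates: basis . (p - origin)."""
    return Point3.from_array(frame.basis @ (p.as_array() - frame.origin.as_array()))


def from_frame(p: Point3, frame: FacialFrame) -> Point3:
    """Inverse of :func:`to_frame`."""
    return Point3.from_array(frame.basis.T @ p.as_array() + frame.origin.as_array())
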