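"""Maxillary median plane fit and signed midline-deviation metrics.

All quantities are computed in facial-frame coordinates, where the
facial median plane (facMP) is exactly the plane x = 0 (it contains N
and LS by construction of the frame).  The maxillary median plane
(maxMP) is fitted through the six palatine-raphe landmarks RPM_1..RPM_6
by orthogonal (total) least squares.  Signed distances follow the frame
convention: negative = toward the patient's left.

The per-rating deviation profile consists of five signed distances and
one signed angle:

========================  =====================================================
``dentMid_facMP``         transverse offset of the dental midline from facMP
``dentMid_maxMP``         perpendicular distance of the dental midline to maxMP
``maxMP_facMP_at_dentMid``  transverse gap between the two planes at the
                          sagittal/vertical level of the dental midline
``angle_maxMP_facMP``     angle between the planes after projection onto the
                          horizontal plane (positive = anterior end to the left)
``PRN_facMP``             nose-tip deviation from facMP
``POG_facMP``, ``GN_facMP``  chin deviations from facMP
========================  =====================================================
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from dentasym.frame import GeometryError, frame_from_landmarks, to_frame
from dentasym.io import Point3, RatingRecord

__all__ = [
    "PlaneModel",
    "AsymmetryProfile",
    "PROFILE_PARAMETERS",
    "RPM_NAMES",
    "fit_plane",
    "dev_facmp",
    "dev_plane",
    "offset_at_point",
    "projected_angle",
    "compute_profile",
]

RPM_NAMES = ("RPM_1", "RPM_2", "RPM_3", "RPM_4", "RPM_5", "RPM_6")

#: Minimum |n_x| for the transverse inter-plane gap to be well defined
#: (the fitted plane must remain near-sagittal).
MIN_NORMAL_X = 0.5

#: |n_z| above this means the plane is nearly horizontal and has no
#: meaningful intersection line with the horizontal plane.
MAX_NORMAL_Z = 0.95

_COLLINEARITY_RATIO = 1e-8


@dataclass(frozen=True)
class PlaneModel:
    """Plane {v : normal . v = offset} with an orthogonal-fit residual (mm)."""

    normal: np.ndarray
    offset: float
    rms_residual: float

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=float)
        if abs(np.linalg.norm(n) - 1.0) > 1e-12:
            raise ValueError("plane normal must be unit length")
        if self.rms_residual < 0:
            raise ValueError("rms_residual must be >= 0")


@dataclass(frozen=True)
class AsymmetryProfile:
    """Signed deviation parameters of one rating (mm / degrees)."""

    dentMid_facMP: float
    dentMid_maxMP: float
    maxMP_facMP_at_dentMid: float
    angle_maxMP_facMP: float
    PRN_facMP: float
    POG_facMP: float
    GN_facMP: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


PROFILE_PARAMETERS = tuple(f.name for f in fields(AsymmetryProfile))


def fit_plane(points: np.ndarray) -> PlaneModel:
    """Total-least-squares plane through >= 3 non-collinear points.

    The normal is the eigenvector of the centred scatter matrix for its
    smallest eigenvalue; the plane passes through the centroid.  The
    normal sign is fixed so its x-component is >= 0 (ties broken on y,
    then z), which makes signed distances reproducible.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
        raise GeometryError("plane fit needs an (n>=3, 3) point array")
    centroid = pts.mean(axis=0)
    centred = pts - centroid
    scatter = centred.T @ centred
    eigvals, eigvecs = np.linalg.eigh(scatter)
    if eigvals[1] <= _COLLINEARITY_RATIO * max(eigvals[2], 1e-300):
        raise GeometryError("points are collinear; plane is not determined")
    normal = eigvecs[:, 0]
    for comp in normal:  # sign fix: first nonzero of (x, y, z) made positive
        if abs(comp) > 1e-12:
            if comp < 0:
                normal = -normal
            break
    rms = float(np.sqrt(max(eigvals[0], 0.0) / pts.shape[0]))
    return PlaneModel(normal=normal, offset=float(normal @ centroid), rms_residual=rms)


def dev_facmp(p: Point3) -> float:
    """Signed transverse deviation from the facial median plane (= p.x)."""
    return p.x


def dev_plane(p: Point3, plane: PlaneModel) -> float:
    """Signed perpendicular distance of *p* from *plane* (normal . p - offset)."""
    return float(np.asarray(plane.normal) @ p.as_array() - plane.offset)


def offset_at_point(plane: PlaneModel, p: Point3) -> float:
    """Transverse (x) position where *plane* crosses the line through
    (., p.y, p.z) parallel to the x-axis.

    Because facMP is the plane x = 0, this is the signed gap between the
    two planes at the sagittal/vertical level of *p*.  Requires the
    plane to be near-sagittal (|n_x| >= 0.5).
    """
    n = np.asarray(plane.normal)
    if abs(n[0]) < MIN_NORMAL_X:
        raise GeometryError(
            f"plane is too far from sagittal (|n_x| = {abs(n[0]):.3f} < {MIN_NORMAL_X})"
        )
    return float((plane.offset - n[1] * p.y - n[2] * p.z) / n[0])


def projected_angle(plane: PlaneModel) -> float:
    """Signed angle (degrees) between *plane* and facMP after projecting
    both onto the horizontal plane.

    Both planes intersect the horizontal plane in a line; the result is
    the rotation about +Z carrying the facMP line (the y-axis) onto the
    plane's line, reduced to (-90, 90].  Positive = the anterior end of
    the plane deviates to the patient's left.
    """
    n = np.asarray(plane.normal)
    if abs(n[2]) >= MAX_NORMAL_Z:
        raise GeometryError("plane is nearly horizontal; projected angle undefined")
    # Intersection direction with z=const is n x z = (n_y, -n_x, 0); the
    # rotation angle of that (undirected) line from the y-axis is
    # atan2(n_y, n_x) for the representative with n_x >= 0.
    nx, ny = n[0], n[1]
    if nx < 0 or (nx == 0 and ny < 0):
        nx, ny = -nx, -ny
    angle = float(np.degrees(np.arctan2(ny, nx)))
    if angle <= -90.0:  # undirected line: fold to (-90, 90]
        angle += 180.0
    return angle


def compute_profile(record: RatingRecord) -> AsymmetryProfile:
    """Build the record's own facial frame and compute its deviation profile."""
    try:
        frame = frame_from_landmarks(record)
        local = {
            name: to_frame(p, frame) for name, p in record.landmarks.items()
        }
        dent_mid = Point3.midpoint(local["mes11"], local["mes21"])
        max_mp = fit_plane(np.array([local[n].as_array() for n in RPM_NAMES]))
        return AsymmetryProfile(
            dentMid_facMP=dev_facmp(dent_mid),
            dentMid_maxMP=dev_plane(dent_mid, max_mp),
            maxMP_facMP_at_dentMid=offset_at_point(max_mp, dent_mid),
            angle_maxMP_facMP=projected_angle(max_mp),
            PRN_facMP=dev_facmp(local["PRN"]),
            POG_facMP=dev_facmp(local["POG"]),
            GN_facMP=dev_facmp(local["GN"]),
        )
    except (GeometryError, KeyError) as exc:
        raise type(exc)(
            f"{exc} [subject={record.subject_id} rater={record.rater_id} "
            f"repeat={record.repeat_index}]"
        ) from exc
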