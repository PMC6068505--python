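"""Stereo matching, triangulation and 3D pupil-circle reconstruction.

Each eye is observed by a rectified camera pair (22 mm baseline in the
reference hardware); corresponding points share image rows, so pupil-edge
correspondences are resolved by left-to-right ordering within each row —
the pupil boundary is textureless, making descriptor matching pointless.
Triangulation is the midpoint of the two back-projected rays; the pupil's
spatial circle is fitted by total-least-squares plane + in-plane algebraic
circle fit, giving the 3D pupil center and the metric pupil size
S = 2r (diameter, mm), which is invariant to the eye–camera distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateGeometryError, PartialRecordError

__all__ = [
    "CameraModel",
    "StereoRig",
    "PupilCircle3D",
    "EyeFeatureSet",
    "default_rig",
    "match_and_triangulate",
    "triangulate_pair",
    "fit_circle_3d",
    "assemble_features",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CameraModel:
    """Pinhole camera: ``x_cam = R @ X_rig + t`` then projection by K.

    Distortion coefficients are carried through from the calibration files
    but images are assumed rectified (all-zero coefficients) here.
    """

    K: np.ndarray
    R: np.ndarray
    t: np.ndarray
    dist: np.ndarray = field(default_factory=lambda: np.zeros(5))
    image_size: tuple[int, int] = (640, 580)   # (width m, height n) px

    def __post_init__(self):
        object.__setattr__(self, "K", np.asarray(self.K, dtype=float))
        object.__setattr__(self, "R", np.asarray(self.R, dtype=float))
        object.__setattr__(self, "t", np.asarray(self.t, dtype=float))
        object.__setattr__(self, "dist", np.asarray(self.dist, dtype=float))

    @property
    def center(self) -> np.ndarray:
        """Camera center in the rig frame."""
        return -self.R.T @ self.t

    def project(self, points) -> np.ndarray:
        """Project rig-frame points (..., 3) to pixel coordinates (..., 2)."""
        X = np.asarray(points, dtype=float)
        xc = X @ self.R.T + self.t
        uv = xc[..., :2] / xc[..., 2:3]
        fx, fy = self.K[0, 0], self.K[1, 1]
        cx, cy = self.K[0, 2], self.K[1, 2]
        skew = self.K[0, 1]
        u = fx * uv[..., 0] + skew * uv[..., 1] + cx
        v = fy * uv[..., 1] + cy
        return np.stack([u, v], axis=-1)

    def rays(self, pixels) -> tuple[np.ndarray, np.ndarray]:
        """Back-projected rays: (origin, unit direction) in the rig frame."""
        uv = np.asarray(pixels, dtype=float)
        ones = np.ones(uv.shape[:-1] + (1,))
        hom = np.concatenate([uv, ones], axis=-1)
        d_cam = hom @ np.linalg.inv(self.K).T
        d = d_cam @ self.R            # = R.T @ d_cam, rowwise
        d = d / np.linalg.norm(d, axis=-1, keepdims=True)
        origin = np.broadcast_to(self.center, d.shape)
        return origin, d


@dataclass(frozen=True)
class StereoRig:
    """Four-camera rig; the rig frame is the leftmost (L1) camera frame."""

    cameras: dict
    baseline: float
    pairs: dict = field(default_factory=lambda: {"left": ("L1", "L2"),
                                                 "right": ("R1", "R2")})

    def __post_init__(self):
        if self.baseline <= 0:
            raise ValueError("baseline must be positive")

    def pair(self, side: str) -> tuple[CameraModel, CameraModel]:
        a, b = self.pairs[side]
        return self.cameras[a], self.cameras[b]


def default_rig(focal_px: float = 600.0, baseline: float = 22.0,
                eye_separation: float = 54.0,
                image_size: tuple[int, int] = (640, 580)) -> StereoRig:
    """Reference rig: two rectified vertical-mirror camera pairs, 22 mm
    baseline, 3.6 mm lenses (≈600 px at the default pixel pitch), 640×580."""
    w, h = image_size
    K = np.array([[focal_px, 0.0, w / 2.0],
                  [0.0, focal_px, h / 2.0],
                  [0.0, 0.0, 1.0]])
    eye = np.eye(3)
    cams = {}
    xs = {"L1": 0.0, "L2": baseline,
          "R1": eye_separation, "R2": eye_separation + baseline}
    for cid, x in xs.items():
        cams[cid] = CameraModel(K=K, R=eye, t=np.array([-x, 0.0, 0.0]),
                                image_size=image_size)
    return StereoRig(cameras=cams, baseline=baseline)


def triangulate_pair(cam1: CameraModel, cam2: CameraModel,
                     pix1, pix2, min_disparity: float = 1e-9) -> np.ndarray:
    """Midpoint triangulation of matched pixel coordinates (..., 2).

    Raises :class:`DegenerateGeometryError` for (near-)parallel rays
    (zero disparity: point at infinity).
    """
    o1, d1 = cam1.rays(pix1)
    o2, d2 = cam2.rays(pix2)
    # closest points of the two rays: solve 2x2 system per point
    r = o2 - o1
    a = np.sum(d1 * d1, axis=-1)
    b = np.sum(d1 * d2, axis=-1)
    c = np.sum(d2 * d2, axis=-1)
    det = a * c - b * b
    if np.any(det <= min_disparity ** 2):
        raise DegenerateGeometryError("zero disparity: point at infinity")
    e = np.sum(d1 * r, axis=-1)
    f = np.sum(d2 * r, axis=-1)
    t1 = (c * e - b * f) / det
    t2 = (b * e - a * f) / det
    p1 = o1 + d1 * t1[..., None]
    p2 = o2 + d2 * t2[..., None]
    return (p1 + p2) / 2.0


def match_and_triangulate(points_cam1, points_cam2, cam1: CameraModel,
                          cam2: CameraModel, row_tol: float = 0.75) -> np.ndarray:
    """Row-order epipolar matching followed by midpoint triangulation.

    Points are grouped by (quantised) rectified row; within each row both
    sides are sorted left-to-right and paired in order.  Unmatched points
    are dropped with a log message.  Returns (N, 3) rig-frame mm.
    """
    p1 = np.asarray(points_cam1, dtype=float).reshape(-1, 2)
    p2 = np.asarray(points_cam2, dtype=float).reshape(-1, 2)
    if p1.size == 0 or p2.size == 0:
        return np.empty((0, 3))
    q = max(row_tol, 1e-6)
    rows1 = np.round(p1[:, 1] / q).astype(np.int64)
    rows2 = np.round(p2[:, 1] / q).astype(np.int64)
    m1, m2 = [], []
    dropped = 0
    for row in np.unique(rows1):
        i1 = np.where(rows1 == row)[0]
        i2 = np.where(rows2 == row)[0]
        if i2.size == 0:
            dropped += i1.size
            continue
        i1 = i1[np.argsort(p1[i1, 0])]
        i2 = i2[np.argsort(p2[i2, 0])]
        k = min(i1.size, i2.size)
        dropped += (i1.size - k)
        m1.append(i1[:k])
        m2.append(i2[:k])
    if dropped:
        logger.info("match_and_triangulate: dropped %d unmatched points", dropped)
    if not m1:
        return np.empty((0, 3))
    i1 = np.concatenate(m1)
    i2 = np.concatenate(m2)
    return triangulate_pair(cam1, cam2, p1[i1], p2[i2])


@dataclass(frozen=True)
class PupilCircle3D:
    """Spatial pupil circle; ``size`` is the diameter S = 2r in mm."""

    center: np.ndarray
    radius: float
    normal: np.ndarray
    rms: float

    @property
    def size(self) -> float:
        return 2.0 * self.radius


def fit_circle_3d(points, rms_tol: float | None = None) -> PupilCircle3D:
    """Least-squares 3D circle: TLS plane, in-plane algebraic circle fit.

    The plane is the best-fit (total least squares) plane through the
    points; the points are projected into it and a Kåsa circle fit run in
    plane coordinates; the center is lifted back to 3D.  The returned
    normal has a non-negative Z component.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if pts.shape[0] < 3:
        raise DegenerateGeometryError("need at least 3 points for a circle")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    if svals[1] <= 1e-9 * max(svals[0], 1.0):
        raise DegenerateGeometryError("collinear points: degenerate circle")
    normal = vt[2]
    if normal[2] < 0:
        normal = -normal
    e1, e2 = vt[0], vt[1]
    u = centered @ e1
    v = centered @ e2
    # Kåsa: x² + y² = 2ax + 2by + c
    A = np.stack([2 * u, 2 * v, np.ones_like(u)], axis=1)
    rhs = u ** 2 + v ** 2
    (a, b, c), *_ = np.linalg.lstsq(A, rhs, rcond=None)
    r2 = c + a ** 2 + b ** 2
    if r2 <= 0:
        raise DegenerateGeometryError("degenerate circle fit")
    radius = float(np.sqrt(r2))
    center = centroid + a * e1 + b * e2
    # residuals: in-plane radial + out-of-plane
    radial = np.sqrt((u - a) ** 2 + (v - b) ** 2) - radius
    off_plane = centered @ normal
    rms = float(np.sqrt(np.mean(radial ** 2 + off_plane ** 2)))
    if rms_tol is not None and rms > rms_tol:
        raise DegenerateGeometryError(
            f"circle-fit RMS {rms:.4g} mm exceeds tolerance {rms_tol:.4g} mm")
    return PupilCircle3D(center=center, radius=radius, normal=normal, rms=rms)


@dataclass(frozen=True)
class EyeFeatureSet:
    """Per-fixation binocular 3D features (mm, rig frame).

    ``pupil_left``/``pupil_right`` are the 3D pupil centers P_li / P_ri,
    ``size_*`` the pupil diameters S, ``corner_*`` the inner eye corners.
    ``fixation`` (1..4) and ``placement`` label calibration captures.
    """

    pupil_left: np.ndarray
    pupil_right: np.ndarray
    size_left: float
    size_right: float
    corner_left: np.ndarray
    corner_right: np.ndarray
    fixation: int | None = None
    placement: int | None = None

    def __post_init__(self):
        for name in ("pupil_left", "pupil_right", "corner_left", "corner_right"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        arrs = np.concatenate([self.pupil_left, self.pupil_right,
                               self.corner_left, self.corner_right])
        if not np.all(np.isfinite(arrs)):
            raise ValueError("non-finite feature coordinates")


def assemble_features(left_circle: PupilCircle3D | None,
                      right_circle: PupilCircle3D | None,
                      corner_left, corner_right,
                      fixation: int | None = None,
                      placement: int | None = None) -> EyeFeatureSet:
    """Bundle the two reconstructed pupil circles and corners into one record."""
    for side, circ in (("left", left_circle), ("right", right_circle)):
        if circ is None:
            raise PartialRecordError(f"missing {side} eye reconstruction")
    for side, corner in (("left", corner_left), ("right", corner_right)):
        if corner is None:
            raise PartialRecordError(f"missing {side} inner corner")
    return EyeFeatureSet(
        pupil_left=left_circle.center, pupil_right=right_circle.center,
        size_left=left_circle.size, size_right=right_circle.size,
        corner_left=corner_left, corner_right=corner_right,
        fixation=fixation, placement=placement)
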