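"""Corner-vector eye frame and calibration transfer.

The inner eye corners (medial canthi) are the most stable facial landmarks
visible to the rig, so calibrated convergence points are stored relative to
them: the eye coordinate system has its origin at the right inner corner,
axes parallel to the rig axes, and the *inner-corner vector*
``v = left corner − right corner`` serves as the orientation reference.

A single vector pair cannot observe head roll about ``v`` (nor, jointly with
the translation, pitch about it) — the device restricts head pitch; the
transfer below is exact for translations composed with minimal (geodesic)
rotations of the corner vector and degrades smoothly otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .convergence_calibration import ConvergencePair
from .errors import DegenerateGeometryError

__all__ = [
    "EyeFrame",
    "ConvergenceReference",
    "build_eye_frame",
    "minimal_rotation",
    "record_reference",
    "transfer_convergence",
    "point_to_reference",
    "point_to_current",
]


@dataclass(frozen=True)
class EyeFrame:
    """Eye coordinate system: origin at the right inner corner, rig axes."""

    origin: np.ndarray          # right inner corner, mm (rig frame)
    v: np.ndarray               # left corner − right corner, mm

    def __post_init__(self):
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        object.__setattr__(self, "v", np.asarray(self.v, dtype=float))


@dataclass(frozen=True)
class ConvergenceReference:
    """Calibrated convergence pair stored relative to the corner vector.

    ``rot_left``/``rot_right`` are the minimal rotations carrying the
    direction of ``v0`` onto the directions of the origin→convergence-point
    vectors; the vector norms are kept separately.
    """

    v0: np.ndarray
    origin0: np.ndarray
    rot_left: np.ndarray        # (3, 3)
    rot_right: np.ndarray
    norm_left: float
    norm_right: float


def build_eye_frame(corner_left, corner_right) -> EyeFrame:
    """Eye frame from the two inner corners (mm, rig frame)."""
    cl = np.asarray(corner_left, dtype=float)
    cr = np.asarray(corner_right, dtype=float)
    v = cl - cr
    if np.linalg.norm(v) <= 1e-9:
        raise DegenerateGeometryError("inner corners coincide")
    return EyeFrame(origin=cr, v=v)


def minimal_rotation(u, w) -> np.ndarray:
    """Minimal (geodesic) rotation matrix carrying direction u onto w.

    Rotation about ``u × w`` by the angle between the vectors; identity for
    parallel inputs.  Anti-parallel inputs rotate by π about a deterministic
    axis orthogonal to ``u`` (built from the lowest-index coordinate axis
    that is not aligned with ``u``).
    """
    u = np.asarray(u, dtype=float)
    w = np.asarray(w, dtype=float)
    nu = np.linalg.norm(u)
    nw = np.linalg.norm(w)
    if nu <= 0.0 or nw <= 0.0:
        raise DegenerateGeometryError("cannot rotate a zero vector")
    uh = u / nu
    wh = w / nw
    axis = np.cross(uh, wh)
    s = np.linalg.norm(axis)
    c = float(np.dot(uh, wh))
    if s <= 1e-15:
        if c > 0.0:
            return np.eye(3)
        # anti-parallel: π about the first basis axis not parallel to u
        for e in np.eye(3):
            if abs(np.dot(e, uh)) < 0.9:
                break
        axis = e - np.dot(e, uh) * uh
        axis /= np.linalg.norm(axis)
        angle = np.pi
    else:
        axis = axis / s
        angle = float(np.arctan2(s, c))
    # Rodrigues
    kx, ky, kz = axis
    k_cross = np.array([[0.0, -kz, ky], [kz, 0.0, -kx], [-ky, kx, 0.0]])
    return np.eye(3) + np.sin(angle) * k_cross + (1 - np.cos(angle)) * (k_cross @ k_cross)


def record_reference(frame: EyeFrame, pair: ConvergencePair) -> ConvergenceReference:
    """Store a calibrated pair relative to the corner-vector frame."""
    out = {}
    for side, point in (("left", pair.p_left), ("right", pair.p_right)):
        vec = np.asarray(point, dtype=float) - frame.origin
        norm = float(np.linalg.norm(vec))
        if norm <= 1e-9:
            raise DegenerateGeometryError(
                f"{side} convergence point coincides with the eye-frame origin")
        out[side] = (minimal_rotation(frame.v, vec), norm)
    return ConvergenceReference(
        v0=frame.v.copy(), origin0=frame.origin.copy(),
        rot_left=out["left"][0], rot_right=out["right"][0],
        norm_left=out["left"][1], norm_right=out["right"][1])


def transfer_convergence(ref: ConvergenceReference, frame: EyeFrame) -> ConvergencePair:
    """Re-express a calibrated convergence pair in the current eye frame.

    The corner-vector rotation ``R' = minimal_rotation(v0, v_i)`` is applied
    to each stored convergence vector, the result rescaled to its calibrated
    norm and anchored at the current right corner.  Exact for translations
    composed with minimal rotations of the corner vector.
    """
    if np.linalg.norm(frame.v) <= 1e-9:
        raise DegenerateGeometryError("degenerate current corner vector")
    r_prime = minimal_rotation(ref.v0, frame.v)
    points = {}
    for side, rot, norm in (("left", ref.rot_left, ref.norm_left),
                            ("right", ref.rot_right, ref.norm_right)):
        d = r_prime @ (rot @ ref.v0)
        points[side] = frame.origin + d * (norm / np.linalg.norm(d))
    return ConvergencePair(p_left=points["left"], p_right=points["right"])


def point_to_reference(point, frame: EyeFrame, v0, origin0=None) -> np.ndarray:
    """Coordinates of a rig-frame point in the initial corner-vector reference.

    Undoes the corner-vector rotation and the translation of ``frame``
    relative to the reference frame ``(v0, origin0)``.
    """
    r_prime = minimal_rotation(np.asarray(v0, dtype=float), frame.v)
    return r_prime.T @ (np.asarray(point, dtype=float) - frame.origin)


def point_to_current(point_ref, frame: EyeFrame, v0) -> np.ndarray:
    """Map reference-frame coordinates into the current rig frame."""
    r_prime = minimal_rotation(np.asarray(v0, dtype=float), frame.v)
    return frame.origin + r_prime @ np.asarray(point_ref, dtype=float)
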