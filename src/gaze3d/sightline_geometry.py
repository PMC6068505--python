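"""Nearest points of two skew sightlines and the midpoint point-of-regard.

A *sightline* is the infinite line through an eye's pupil center (anchor) and
its line-of-sight convergence point (through point).  Binocular fixation is
encoded by the pair of nearest points of the left and right sightlines; the
point-of-regard (PoR) is taken as the midpoint of the segment joining them,
and the residual gap between the two lines is kept as a quality indicator.

The closed form below constructs, for each line, the plane spanned by the
*other* line and the common normal ``n = a × b`` and intersects it with the
line.  With ``k_a = n × a`` and ``k_b = n × b`` the feet are

    P1 = P_L − a · ((P_L − Q_R) · k_b) / (a · k_b)
    P2 = P_R − b · ((P_R − Q_L) · k_a) / (b · k_a)

where ``a, b`` are the line directions, ``P_L, P_R`` the through points and
``Q_L, Q_R`` the anchors.  The denominators equal ∓‖n‖², so the form is
defined exactly when the lines are not parallel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateGeometryError

__all__ = [
    "SightLine",
    "NearestPointPair",
    "PoREstimate",
    "nearest_points",
    "nearest_points_batch",
    "midpoint_por",
]

#: dimensionless parallelism tolerance: ‖a×b‖ / (‖a‖‖b‖)
PARALLEL_TOL = 1e-12


def _as_vec3(x) -> np.ndarray:
    v = np.asarray(x, dtype=float)
    if v.shape != (3,):
        raise ValueError(f"expected a 3-vector, got shape {v.shape}")
    return v


@dataclass(frozen=True)
class SightLine:
    """Infinite line through ``anchor`` (pupil center) and ``through``
    (convergence point), both in mm in the rig frame."""

    anchor: np.ndarray
    through: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "anchor", _as_vec3(self.anchor))
        object.__setattr__(self, "through", _as_vec3(self.through))
        if np.linalg.norm(self.direction) <= 1e-12:
            raise DegenerateGeometryError("sightline anchor and through point coincide")

    @property
    def direction(self) -> np.ndarray:
        return self.through - self.anchor


@dataclass(frozen=True)
class NearestPointPair:
    """Feet of the common perpendicular of two sightlines."""

    p1: np.ndarray
    p2: np.ndarray
    gap: float
    normal: np.ndarray

    @property
    def midpoint(self) -> np.ndarray:
        return (self.p1 + self.p2) / 2.0


@dataclass(frozen=True)
class PoREstimate:
    """3D point-of-regard (mm) with its sightline gap quality metric."""

    point: np.ndarray
    gap: float
    fixation: int | None = field(default=None)


def nearest_points_batch(anchor_l, through_l, anchor_r, through_r,
                         parallel_tol: float = PARALLEL_TOL):
    """Vectorised nearest points for stacks of line pairs.

    All inputs broadcast to ``(..., 3)``.  Returns ``(p1, p2, gap, n)``;
    entries whose lines are parallel (within ``parallel_tol``) come back as
    NaN with ``gap = inf`` instead of raising, so that lattice searches can
    score them as worthless candidates.
    """
    ql = np.asarray(anchor_l, dtype=float)
    pl = np.asarray(through_l, dtype=float)
    qr = np.asarray(anchor_r, dtype=float)
    pr = np.asarray(through_r, dtype=float)

    a = pl - ql
    b = pr - qr
    n = np.cross(a, b)

    norm_a = np.linalg.norm(a, axis=-1)
    norm_b = np.linalg.norm(b, axis=-1)
    norm_n = np.linalg.norm(n, axis=-1)
    parallel = norm_n <= parallel_tol * norm_a * norm_b

    # k vectors of the closed form; identical to the componentwise polynomial
    # expansions of the two plane normals.
    k_a = np.cross(n, a)
    k_b = np.cross(n, b)

    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.sum((pl - qr) * k_b, axis=-1) / np.sum(a * k_b, axis=-1)
        t2 = np.sum((pr - ql) * k_a, axis=-1) / np.sum(b * k_a, axis=-1)
        p1 = pl - a * t1[..., None]
        p2 = pr - b * t2[..., None]

    gap = np.linalg.norm(p1 - p2, axis=-1)
    if np.any(parallel):
        p1 = np.where(parallel[..., None], np.nan, p1)
        p2 = np.where(parallel[..., None], np.nan, p2)
        gap = np.where(parallel, np.inf, gap)
    return p1, p2, gap, n


def nearest_points(line_l: SightLine, line_r: SightLine,
                   parallel_tol: float = PARALLEL_TOL) -> NearestPointPair:
    """Nearest points of two sightlines (closed form).

    Raises :class:`DegenerateGeometryError` when the lines are parallel
    (PoR at infinity).
    """
    a = line_l.direction
    b = line_r.direction
    n = np.cross(a, b)
    if np.linalg.norm(n) <= parallel_tol * np.linalg.norm(a) * np.linalg.norm(b):
        raise DegenerateGeometryError("parallel sightlines: PoR at infinity")
    p1, p2, gap, n = nearest_points_batch(
        line_l.anchor, line_l.through, line_r.anchor, line_r.through,
        parallel_tol=parallel_tol)
    return NearestPointPair(p1=p1, p2=p2, gap=float(gap), normal=n)


def midpoint_por(pair: NearestPointPair, fixation: int | None = None) -> PoREstimate:
    """PoR as the exact midpoint of the nearest-point segment."""
    return PoREstimate(point=pair.midpoint, gap=pair.gap, fixation=fixation)
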