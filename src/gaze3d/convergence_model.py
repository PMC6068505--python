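"""Pupil-size → convergence-point law and runtime PoR estimation.

Under fixed illumination the pupil diameter S tracks viewing distance
(the pupillary accommodation reflex: small pupil near, large pupil far), so
the calibrated line-of-sight convergence points, expressed in the initial
inner-corner-vector reference, lie essentially along a spatial straight
line parametrised by depth.  Per eye the model is

    Z = γ0 + γ1·S + γ2·S²        (depth vs pupil size, quadratic)
    X = α0 + α1·Z                (spatial line)
    Y = β0 + β1·Z

fitted by ordinary least squares, Z-on-S first because depth is the
coordinate sensitive to S.  At runtime the measured pupil sizes give the
per-eye convergence points, the corner vector carries them into the current
frame, and the PoR is the midpoint of the nearest points of the two
sightlines (pupil center → convergence point).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .convergence_calibration import ConvergencePair
from .errors import CalibrationError
from .eye_frame_alignment import EyeFrame, build_eye_frame, point_to_current
from .sightline_geometry import (PoREstimate, SightLine, midpoint_por,
                                 nearest_points)
from .stereo_reconstruction import EyeFeatureSet

__all__ = [
    "CalibrationSample",
    "EyeConvergenceLaw",
    "ConvergenceModel",
    "fit_convergence_model",
    "predict_convergence",
    "estimate_por",
    "average_por",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CalibrationSample:
    """One placement's pupil size and aligned convergence point (mm)."""

    size: float
    point: np.ndarray              # (3,) in the initial corner-vector reference
    placement: int | None = None

    def __post_init__(self):
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float))
        if self.size <= 0:
            raise ValueError("pupil size must be positive")


@dataclass(frozen=True)
class EyeConvergenceLaw:
    """Fitted per-eye coefficients with the calibrated pupil-size range."""

    gamma: np.ndarray              # (3,) depth quadratic
    alpha: np.ndarray              # (2,) X line
    beta: np.ndarray               # (2,) Y line
    s_range: tuple[float, float]

    def point(self, size: float) -> np.ndarray:
        g0, g1, g2 = self.gamma
        z = g0 + g1 * size + g2 * size ** 2
        x = self.alpha[0] + self.alpha[1] * z
        y = self.beta[0] + self.beta[1] * z
        return np.array([x, y, z])


@dataclass(frozen=True)
class ConvergenceModel:
    """Both eyes' laws plus the corner-vector reference they live in."""

    left: EyeConvergenceLaw
    right: EyeConvergenceLaw
    v0: np.ndarray
    origin0: np.ndarray
    extrapolation_margin: float = 0.10

    def __post_init__(self):
        object.__setattr__(self, "v0", np.asarray(self.v0, dtype=float))
        object.__setattr__(self, "origin0", np.asarray(self.origin0, dtype=float))


def _fit_law(samples) -> EyeConvergenceLaw:
    if len(samples) < 3:
        raise CalibrationError(
            f"insufficient calibration: {len(samples)} samples < 3")
    s = np.array([smp.size for smp in samples], dtype=float)
    pts = np.stack([smp.point for smp in samples])
    if np.ptp(s) <= 1e-12:
        raise CalibrationError("rank-deficient design: all pupil sizes equal")
    design = np.stack([np.ones_like(s), s, s ** 2], axis=1)
    gamma, *_ = np.linalg.lstsq(design, pts[:, 2], rcond=None)
    z = pts[:, 2]
    line = np.stack([np.ones_like(z), z], axis=1)
    if np.ptp(z) <= 1e-12:
        # constant-depth: lines reduce to intercepts
        alpha = np.array([pts[:, 0].mean(), 0.0])
        beta = np.array([pts[:, 1].mean(), 0.0])
    else:
        alpha, *_ = np.linalg.lstsq(line, pts[:, 0], rcond=None)
        beta, *_ = np.linalg.lstsq(line, pts[:, 1], rcond=None)
    return EyeConvergenceLaw(gamma=gamma, alpha=alpha, beta=beta,
                             s_range=(float(s.min()), float(s.max())))


def fit_convergence_model(samples_left, samples_right, v0, origin0,
                          extrapolation_margin: float = 0.10) -> ConvergenceModel:
    """Fit both eyes' laws from aligned calibration samples.

    ``samples_*`` are :class:`CalibrationSample` lists whose points are
    already expressed in the initial corner-vector reference ``(v0,
    origin0)``.
    """
    return ConvergenceModel(
        left=_fit_law(samples_left), right=_fit_law(samples_right),
        v0=v0, origin0=origin0, extrapolation_margin=extrapolation_margin)


def _check_range(size: float, law: EyeConvergenceLaw, margin: float, side: str):
    lo, hi = law.s_range
    pad = margin * max(hi - lo, 1e-9)
    if size < lo - pad or size > hi + pad:
        logger.warning(
            "%s pupil size %.3f mm outside calibrated range [%.3f, %.3f] mm "
            "(+/- %.0f%% margin); extrapolating", side, size, lo, hi,
            100 * margin)


def predict_convergence(size_left: float, size_right: float,
                        model: ConvergenceModel,
                        frame: EyeFrame) -> ConvergencePair:
    """Convergence points for the measured pupil sizes in the current frame."""
    _check_range(size_left, model.left, model.extrapolation_margin, "left")
    _check_range(size_right, model.right, model.extrapolation_margin, "right")
    p_left_ref = model.left.point(size_left)
    p_right_ref = model.right.point(size_right)
    p_left = point_to_current(p_left_ref, frame, model.v0)
    p_right = point_to_current(p_right_ref, frame, model.v0)
    return ConvergencePair(p_left=p_left, p_right=p_right)


def estimate_por(features: EyeFeatureSet, model: ConvergenceModel) -> PoREstimate:
    """3D PoR of one fixation: predict per-eye convergence points, intersect
    the two sightlines, return the nearest-point midpoint with its gap."""
    frame = build_eye_frame(features.corner_left, features.corner_right)
    pair = predict_convergence(features.size_left, features.size_right,
                               model, frame)
    line_l = SightLine(anchor=features.pupil_left, through=pair.p_left)
    line_r = SightLine(anchor=features.pupil_right, through=pair.p_right)
    return midpoint_por(nearest_points(line_l, line_r),
                        fixation=features.fixation)


def average_por(estimates) -> PoREstimate:
    """Mean PoR over a fixation window (the per-frame scatter of pupil size
    makes single-frame estimates noisy; short-window averaging is the
    intended reading mode)."""
    estimates = list(estimates)
    if not estimates:
        raise ValueError("no estimates to average")
    pts = np.stack([e.point for e in estimates])
    gaps = np.array([e.gap for e in estimates])
    return PoREstimate(point=pts.mean(axis=0), gap=float(gaps.mean()))
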