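"""Image → feature → model plumbing shared by the estimator and the CLI."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from . import eye_imaging as ei
from .errors import NoEyeFoundError
from .stereo_reconstruction import (StereoRig, assemble_features, fit_circle_3d,
                                    match_and_triangulate, triangulate_pair)

__all__ = [
    "DetectionResult",
    "detect_eye_features",
    "extract_feature_set",
    "pupil_crop_box",
]

logger = logging.getLogger(__name__)


def pupil_crop_box(frame: ei.ImageFrame, seed_xy,
                   threshold_offset: float = 40.0,
                   pad_frac: float = 0.45) -> tuple[int, int, int, int]:
    """Tight crop around the dark pupil blob containing ``seed_xy``.

    Threshold at (pupil minimum + offset), take the connected component at
    the seed, and pad its bounding box.  A tight crop keeps the iris/sclera
    boundary out of the edge map, so the adaptive gradient map sees only
    the pupil boundary.
    """
    img = frame.pixels.astype(float)
    sx, sy = int(round(seed_xy[0])), int(round(seed_xy[1]))
    sx = np.clip(sx, 0, frame.width - 1)
    sy = np.clip(sy, 0, frame.height - 1)
    # local minimum near the seed as the pupil gray level
    y0, y1 = max(0, sy - 10), min(frame.height, sy + 11)
    x0, x1 = max(0, sx - 10), min(frame.width, sx + 11)
    pupil_level = img[y0:y1, x0:x1].min()
    mask = img <= pupil_level + threshold_offset
    labels, _ = ndimage.label(mask)
    lab = labels[sy, sx]
    if lab == 0:
        # seed not on the blob: take the largest dark component
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        lab = int(np.argmax(sizes))
    ys, xs = np.nonzero(labels == lab)
    w = xs.max() - xs.min() + 1
    h = ys.max() - ys.min() + 1
    px = int(round(pad_frac * w)) + 2
    py = int(round(pad_frac * h)) + 2
    return (max(0, xs.min() - px), max(0, ys.min() - py),
            min(frame.width, xs.max() + px + 1),
            min(frame.height, ys.max() + py + 1))


def _corner_region(frame: ei.ImageFrame, eye_box, pupil_box,
                   dark_threshold: float = 100.0):
    """Corner search region by threshold segmentation of the eye box.

    The eyelid wedge is the largest dark component outside the pupil crop;
    its padded bounding box is returned.  Falls back to the eye box."""
    x0, y0, x1, y1 = eye_box
    img = frame.pixels.astype(float)
    mask = np.zeros_like(img, dtype=bool)
    mask[y0:y1, x0:x1] = img[y0:y1, x0:x1] <= dark_threshold
    mask[pupil_box[1]:pupil_box[3], pupil_box[0]:pupil_box[2]] = False
    labels, nlab = ndimage.label(mask)
    if nlab == 0:
        return eye_box
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    lab = int(np.argmax(sizes))
    ys, xs = np.nonzero(labels == lab)
    pad = 6
    return (max(0, xs.min() - pad), max(0, ys.min() - pad),
            min(frame.width, xs.max() + pad + 1),
            min(frame.height, ys.max() + pad + 1))


@dataclass(frozen=True)
class DetectionResult:
    """Per-camera 2D detection: pupil ellipse + inner corner."""

    camera_id: str
    ellipse: ei.Ellipse2D
    corner: ei.CornerPoint2D | None


def detect_eye_features(frame: ei.ImageFrame, seed: int | None = 0,
                        edge_cfg: ei.EdgeMapConfig | None = None,
                        fit_cfg: ei.EllipseFitConfig | None = None,
                        corner_cfg: ei.CornerConfig | None = None,
                        detect_corner: bool = True) -> DetectionResult:
    """Run the single-camera chain: eye box → pupil crop → edge map →
    two-step ellipse fit → multi-scale corner detection."""
    eye_box = ei.locate_eye_region(frame)
    img = frame.pixels
    sub = img[eye_box[1]:eye_box[3], eye_box[0]:eye_box[2]]
    dy, dx = np.unravel_index(np.argmin(sub), sub.shape)
    seed_xy = (eye_box[0] + dx, eye_box[1] + dy)
    box = pupil_crop_box(frame, seed_xy)
    crop = ei.ImageFrame(pixels=img[box[1]:box[3], box[0]:box[2]],
                         camera_id=frame.camera_id)
    edges = ei.pupil_edge_map(crop, edge_cfg)
    ell = ei.fit_pupil_ellipse(edges, rng_seed=seed, cfg=fit_cfg)
    ell = ei.Ellipse2D(x0=ell.x0 + box[0], y0=ell.y0 + box[1],
                       a=ell.a, b=ell.b, alpha=ell.alpha)
    corner = None
    if detect_corner:
        region = _corner_region(frame, eye_box, box)
        corner = ei.detect_inner_corner(frame, region, corner_cfg)
    return DetectionResult(camera_id=frame.camera_id, ellipse=ell, corner=corner)


def extract_feature_set(frames: dict, rig: StereoRig, seed: int | None = 0,
                        fixation: int | None = None,
                        placement: int | None = None):
    """Binocular EyeFeatureSet from the four camera frames of one fixation.

    Pupil boundaries are sampled as row chords of the fitted ellipses at the
    integer rows both views share (rectified geometry), matched by row
    order, triangulated and fitted with a 3D circle; corners are
    triangulated directly from the two sub-pixel detections.
    """
    circles = {}
    corners3d = {}
    for side in ("left", "right"):
        c1_id, c2_id = rig.pairs[side]
        det1 = detect_eye_features(frames[c1_id], seed=seed)
        det2 = detect_eye_features(frames[c2_id], seed=seed)
        cam1, cam2 = rig.cameras[c1_id], rig.cameras[c2_id]

        rows = _shared_rows(det1.ellipse, det2.ellipse)
        pts1, _ = ei.ellipse_row_chords(det1.ellipse, rows)
        pts2, _ = ei.ellipse_row_chords(det2.ellipse, rows)
        pts3d = match_and_triangulate(pts1.reshape(-1, 2), pts2.reshape(-1, 2),
                                      cam1, cam2)
        circles[side] = fit_circle_3d(pts3d)
        corners3d[side] = triangulate_pair(
            cam1, cam2,
            np.array([det1.corner.x, det1.corner.y]),
            np.array([det2.corner.x, det2.corner.y]))
    return assemble_features(circles["left"], circles["right"],
                             corners3d["left"], corners3d["right"],
                             fixation=fixation, placement=placement)


def _shared_rows(e1: ei.Ellipse2D, e2: ei.Ellipse2D,
                 inner_frac: float = 0.92) -> np.ndarray:
    """Integer rows where both ellipses have well-conditioned chords."""
    def span(e):
        h = np.sqrt((e.a * np.sin(e.alpha)) ** 2 + (e.b * np.cos(e.alpha)) ** 2)
        return e.y0 - inner_frac * h, e.y0 + inner_frac * h
    lo1, hi1 = span(e1)
    lo2, hi2 = span(e2)
    lo = int(np.ceil(max(lo1, lo2)))
    hi = int(np.floor(min(hi1, hi2)))
    if hi < lo:
        raise NoEyeFoundError("ellipses share no image rows")
    return np.arange(lo, hi + 1)
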