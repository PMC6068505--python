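"""Scikit-learn-style estimator for the full calibrate → estimate pipeline.

``GazePointEstimator.fit`` consumes one calibration session (five board
placements × four crosses of binocular 3D feature records), searches the
per-placement convergence pairs, aligns them into the initial inner-corner
reference and fits the per-eye pupil-size laws; ``predict`` maps feature
records of arbitrary fixations to 3D points of regard.
"""

from __future__ import annotations

import hashlib
import json

import numpy as np
from sklearn.base import BaseEstimator

from .convergence_calibration import ObjectiveConfig, run_search
from .convergence_model import (CalibrationSample, ConvergenceModel,
                                estimate_por, fit_convergence_model)
from .errors import CalibrationError
from .eye_frame_alignment import build_eye_frame, point_to_reference

__all__ = ["GazePointEstimator", "calibrate_session", "estimate_por_sequence"]


def _placements_from(session):
    """Accept a SimulatedSession, or a list of 4-fixation feature lists."""
    if hasattr(session, "calibration_features"):
        return session.calibration_features(noisy=True)
    return list(session)


def _mean_frame(features):
    cl = np.mean([np.asarray(f.corner_left, dtype=float) for f in features], axis=0)
    cr = np.mean([np.asarray(f.corner_right, dtype=float) for f in features], axis=0)
    return build_eye_frame(cl, cr)


class GazePointEstimator(BaseEstimator):
    """3D point-of-regard estimator from binocular eye features.

    Parameters mirror the calibration-search settings: board cross spacing
    ``spacing`` (mm), merged-objective sensitivity ``epsilon``, the initial
    +Z ``depth_offset`` of the search cubes (mm), cube ``half_width`` (mm),
    initial lattice step ``step0`` and cutoff ``step_min`` (mm), and the
    lattice coupling strategy ``search_mode``.

    Fitted attributes (per sklearn convention, trailing underscore):

    ``convergence_pairs_`` : list of per-placement ConvergencePair
    ``search_infos_``      : per-placement SearchInfo diagnostics
    ``reference_frame_``   : the initial corner-vector EyeFrame
    ``model_``             : the fitted :class:`ConvergenceModel`
    """

    def __init__(self, spacing: float = 150.0, epsilon: float = 10.0,
                 depth_offset: float = 10.0, half_width: float = 2.0,
                 step0: float = 0.2, step_min: float = 0.0005,
                 search_mode: str = "alternate", max_alternations: int = 8,
                 extrapolation_margin: float = 0.10):
        self.spacing = spacing
        self.epsilon = epsilon
        self.depth_offset = depth_offset
        self.half_width = half_width
        self.step0 = step0
        self.step_min = step_min
        self.search_mode = search_mode
        self.max_alternations = max_alternations
        self.extrapolation_margin = extrapolation_margin

    def _objective_config(self) -> ObjectiveConfig:
        return ObjectiveConfig(
            spacing=self.spacing, epsilon=self.epsilon,
            depth_offset=self.depth_offset, half_width=self.half_width,
            step0=self.step0, step_min=self.step_min,
            search_mode=self.search_mode,
            max_alternations=self.max_alternations)

    def fit(self, X, y=None):
        """Calibrate from a session (SimulatedSession or list of
        placements, each a list of 4 EyeFeatureSets in cross order)."""
        placements = _placements_from(X)
        if len(placements) < 3:
            raise CalibrationError(
                f"{len(placements)} placements < 3 needed for the quadratic law")
        cfg = self._objective_config()

        self.convergence_pairs_ = []
        self.search_infos_ = []
        self.reference_frame_ = _mean_frame(placements[0])
        ref = self.reference_frame_

        samples_l, samples_r = [], []
        for j, feats in enumerate(placements, start=1):
            pair, info = run_search(feats, cfg, placement=j)
            self.convergence_pairs_.append(pair)
            self.search_infos_.append(info)
            frame_j = _mean_frame(feats)
            p_l_ref = point_to_reference(pair.p_left, frame_j, ref.v, ref.origin)
            p_r_ref = point_to_reference(pair.p_right, frame_j, ref.v, ref.origin)
            s_l = float(np.mean([f.size_left for f in feats]))
            s_r = float(np.mean([f.size_right for f in feats]))
            samples_l.append(CalibrationSample(size=s_l, point=p_l_ref, placement=j))
            samples_r.append(CalibrationSample(size=s_r, point=p_r_ref, placement=j))

        self.model_ = fit_convergence_model(
            samples_l, samples_r, v0=ref.v, origin0=ref.origin,
            extrapolation_margin=self.extrapolation_margin)
        self.samples_left_ = samples_l
        self.samples_right_ = samples_r
        self.config_digest_ = hashlib.sha256(
            json.dumps(self.get_params(), sort_keys=True).encode()).hexdigest()[:16]
        return self

    def predict_record(self, X):
        """PoREstimate (point + gap) per feature record."""
        if not hasattr(self, "model_"):
            raise CalibrationError("estimator is not fitted")
        feats = X if isinstance(X, (list, tuple)) else [X]
        return [estimate_por(f, self.model_) for f in feats]

    def predict(self, X):
        """(n, 3) array of 3D points of regard (mm, rig frame)."""
        return np.stack([e.point for e in self.predict_record(X)])


def calibrate_session(session, **params) -> ConvergenceModel:
    """Functional wrapper: fit a GazePointEstimator, return its model."""
    est = GazePointEstimator(**params).fit(session)
    return est.model_


def estimate_por_sequence(features, model: ConvergenceModel):
    """Per-frame PoR estimates for a sequence of feature records."""
    return [estimate_por(f, model) for f in features]
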