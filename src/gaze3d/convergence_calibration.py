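"""Shrinking grid search for the binocular line-of-sight convergence points.

Per calibration-board placement the subject fixates the four crosses of a
gray board (cross spacing ``L`` = 150 mm).  A pair of convergence points
(P_L, P_R), one per eyeball, is sought such that the four estimated PoRs

  * reproduce the known square shape of the board (shape error: summed
    absolute deviations of the four consecutive cross-to-cross distances
    from L — the board diagonal is never used), and
  * come from sightline pairs that nearly intersect (total gap).

Both criteria are merged into a single score

    score = exp( − TotalGap / Dispersion − ShapeError / ε )

where Dispersion is the RMS (uncentered, n−1 divisor) of the shape errors of
all candidates evaluated in the current search region, and ε (default 10) is
a sensitivity constant.  The score lies in (0, 1]; 1 means a perfect
candidate.

The search starts from a 4 mm cube centred 10 mm behind (+Z) the mean of the
four pupil centers of each eye, with step 0.2 mm; each round keeps the best
candidate, then halves both the cube half-width and the step, terminating
when the step drops below 0.0005 mm (9 rounds under the defaults).

The two cubes are coupled: the objective depends jointly on (P_L, P_R).  The
default strategy alternates block-coordinate passes over the two lattices
until the winning pair is stable within a round; ``search_mode="product"``
evaluates the exact Cartesian product instead, which is only tractable for
coarse lattices and is guarded by ``max_product_pairs``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import CalibrationError, ConfigurationError
from .sightline_geometry import nearest_points_batch

__all__ = [
    "CalibrationBoard",
    "SearchRegion",
    "ConvergencePair",
    "ObjectiveConfig",
    "SearchInfo",
    "grid_candidates",
    "shape_error",
    "merged_objective",
    "search_convergence",
    "run_search",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CalibrationBoard:
    """Four-cross calibration board."""

    spacing: float = 150.0          # mm between consecutive crosses
    n_crosses: int = 4
    placement_range: tuple[float, float] = (400.0, 1200.0)  # mm

    def __post_init__(self):
        if self.spacing <= 0:
            raise ConfigurationError("board spacing must be positive")


@dataclass(frozen=True)
class SearchRegion:
    """Axis-aligned cube search region with a lattice step (all mm)."""

    center: np.ndarray
    half_width: float
    step: float

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        if self.half_width <= 0 or self.step <= 0:
            raise ConfigurationError("half_width and step must be positive")
        if self.step > 2.0 * self.half_width:
            raise ConfigurationError("step exceeds region side length")


@dataclass(frozen=True)
class ConvergencePair:
    """Left/right line-of-sight convergence points (mm, rig frame)."""

    p_left: np.ndarray
    p_right: np.ndarray
    score: float = 1.0
    placement: int | None = None

    def __post_init__(self):
        object.__setattr__(self, "p_left", np.asarray(self.p_left, dtype=float))
        object.__setattr__(self, "p_right", np.asarray(self.p_right, dtype=float))


@dataclass(frozen=True)
class ObjectiveConfig:
    """Tunables of the convergence-point search.

    All lengths in mm.  ``epsilon`` is the unitless shape-error sensitivity
    of the merged score.  ``depth_offset`` positions the initial guess on +Z
    from the mean pupil center (into the eyeball).
    """

    spacing: float = 150.0
    epsilon: float = 10.0
    depth_offset: float = 10.0
    half_width: float = 2.0
    step0: float = 0.2
    step_min: float = 0.0005
    search_mode: str = "alternate"      # "alternate" | "product"
    max_alternations: int = 8
    max_product_pairs: int = 2_000_000

    def __post_init__(self):
        for name in ("spacing", "epsilon", "depth_offset", "half_width",
                     "step0", "step_min"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.search_mode not in ("alternate", "product"):
            raise ConfigurationError(f"unknown search_mode {self.search_mode!r}")


@dataclass
class SearchInfo:
    """Diagnostics of one convergence-point search."""

    rounds: int = 0
    best_scores: list = field(default_factory=list)
    evaluations: int = 0
    mode: str = "alternate"


def grid_candidates(region: SearchRegion) -> np.ndarray:
    """Inclusive lattice of a cubic search region, shape (N, 3).

    Each axis carries ``floor(side/step) + 1`` points with both boundaries
    included; e.g. a 4 mm cube at 1 mm step yields 5³ = 125 candidates.
    Ordering is deterministic (x slowest, z fastest) so argmax tie-breaking
    by lowest index is well defined.
    """
    side = 2.0 * region.half_width
    k = int(np.floor(side / region.step + 1e-9))
    offsets = region.step * np.arange(k + 1) - region.half_width
    xs, ys, zs = np.meshgrid(offsets, offsets, offsets, indexing="ij")
    lattice = np.stack([xs.ravel(), ys.ravel(), zs.ravel()], axis=1)
    return lattice + region.center


def shape_error(por_points, spacing: float) -> np.ndarray | float:
    """Board-shape statistic of four PoRs in cross order 1..4.

    ``Σ_{i=1..3} | ‖P_ei − P_e,i+1‖ − L | + | ‖P_e1 − P_e4‖ − L |`` — the
    four consecutive sides of the cross square; the diagonal is never used.
    Accepts a stack ``(..., 4, 3)``.
    """
    p = np.asarray(por_points, dtype=float)
    if p.shape[-2:] != (4, 3):
        raise ValueError("expected four PoRs of dimension 3")
    d12 = np.linalg.norm(p[..., 0, :] - p[..., 1, :], axis=-1)
    d23 = np.linalg.norm(p[..., 1, :] - p[..., 2, :], axis=-1)
    d34 = np.linalg.norm(p[..., 2, :] - p[..., 3, :], axis=-1)
    d41 = np.linalg.norm(p[..., 0, :] - p[..., 3, :], axis=-1)
    err = (np.abs(d12 - spacing) + np.abs(d23 - spacing)
           + np.abs(d34 - spacing) + np.abs(d41 - spacing))
    return err if err.ndim else float(err)


def merged_objective(total_gap, shape_err, epsilon: float = 10.0) -> np.ndarray:
    """Merged score of every candidate of one search region.

    ``total_gap[j]`` is Σ_i ‖P_1i − P_2i‖ over the four fixations and
    ``shape_err[j]`` the board-shape error of candidate j.  The dispersion
    normaliser is the RMS of all candidates' shape errors (n−1 divisor);
    a zero dispersion with a positive gap scores 0 by convention.
    """
    gap = np.asarray(total_gap, dtype=float)
    se = np.asarray(shape_err, dtype=float)
    n = se.size
    if n < 2:
        raise ConfigurationError("merged objective needs at least two candidates")
    dispersion = np.sqrt(np.sum(se ** 2) / (n - 1))
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        if dispersion == 0.0:
            logger.debug("zero shape-error dispersion in region")
            ratio = np.where(gap == 0.0, 0.0, np.inf)
        else:
            ratio = gap / dispersion
        scores = np.exp(-ratio - se / epsilon)
    scores = np.where(np.isfinite(scores), scores, 0.0)
    return scores


def _features_arrays(features):
    if len(features) != 4:
        raise CalibrationError("a placement must provide exactly 4 fixations")
    pl = np.stack([np.asarray(f.pupil_left, dtype=float) for f in features])
    pr = np.stack([np.asarray(f.pupil_right, dtype=float) for f in features])
    return pl, pr


def _evaluate_pairs(pupils_l, pupils_r, cand_l, cand_r, cfg: ObjectiveConfig):
    """Score N candidate pairs against the placement's 4 fixations.

    ``cand_l``/``cand_r``: (N, 3).  Returns (scores, total_gap, shape_err).
    """
    n = cand_l.shape[0]
    por = np.empty((n, 4, 3))
    gaps = np.empty((n, 4))
    for i in range(4):
        p1, p2, gap, _ = nearest_points_batch(
            pupils_l[i], cand_l, pupils_r[i], cand_r)
        por[:, i, :] = (p1 + p2) / 2.0
        gaps[:, i] = gap
    total_gap = gaps.sum(axis=1)
    se = shape_error(por, cfg.spacing)
    scores = merged_objective(total_gap, se, cfg.epsilon)
    return scores, total_gap, se


def run_search(features, cfg: ObjectiveConfig | None = None,
               placement: int | None = None):
    """Full shrinking grid search; returns ``(ConvergencePair, SearchInfo)``.

    ``features`` are the four :class:`~gaze3d.stereo_reconstruction.EyeFeatureSet`
    records of one board placement, in cross order.
    """
    cfg = cfg or ObjectiveConfig()
    pupils_l, pupils_r = _features_arrays(features)

    center_l = pupils_l.mean(axis=0) + np.array([0.0, 0.0, cfg.depth_offset])
    center_r = pupils_r.mean(axis=0) + np.array([0.0, 0.0, cfg.depth_offset])
    cur_l, cur_r = center_l, center_r

    info = SearchInfo(mode=cfg.search_mode)
    half = cfg.half_width
    st = cfg.step0
    score = 0.0

    while True:
        region_l = SearchRegion(cur_l, half, st)
        region_r = SearchRegion(cur_r, half, st)
        cand_l = grid_candidates(region_l)
        cand_r = grid_candidates(region_r)

        if cfg.search_mode == "product":
            n_pairs = cand_l.shape[0] * cand_r.shape[0]
            if n_pairs > cfg.max_product_pairs:
                raise ConfigurationError(
                    f"product lattice has {n_pairs} pairs "
                    f"(> max_product_pairs={cfg.max_product_pairs}); "
                    "use a coarser step or search_mode='alternate'")
            pl = np.repeat(cand_l, cand_r.shape[0], axis=0)
            pr = np.tile(cand_r, (cand_l.shape[0], 1))
            scores, _, _ = _evaluate_pairs(pupils_l, pupils_r, pl, pr, cfg)
            info.evaluations += n_pairs
            best = int(np.argmax(scores))
            cur_l, cur_r = pl[best], pr[best]
            score = float(scores[best])
        else:
            # Block-coordinate passes over the two cubes until stable.
            score = None
            for _ in range(cfg.max_alternations):
                moved = False
                # left-cube pass, right point held
                pr_rep = np.broadcast_to(cur_r, cand_l.shape)
                scores, _, _ = _evaluate_pairs(pupils_l, pupils_r,
                                               cand_l, pr_rep, cfg)
                info.evaluations += cand_l.shape[0]
                best = int(np.argmax(scores))
                if not np.array_equal(cand_l[best], cur_l):
                    moved = True
                cur_l = cand_l[best]
                # right-cube pass, left point held
                pl_rep = np.broadcast_to(cur_l, cand_r.shape)
                scores, _, _ = _evaluate_pairs(pupils_l, pupils_r,
                                               pl_rep, cand_r, cfg)
                info.evaluations += cand_r.shape[0]
                best = int(np.argmax(scores))
                if not np.array_equal(cand_r[best], cur_r):
                    moved = True
                cur_r = cand_r[best]
                score = float(scores[best])
                if not moved:
                    break

        if score <= 0.0:
            raise CalibrationError(
                f"convergence search failed: all candidate scores zero "
                f"(round {info.rounds + 1}, step {st} mm)")
        info.rounds += 1
        info.best_scores.append(score)
        st /= 2.0
        half /= 2.0
        if st < cfg.step_min:
            break

    pair = ConvergencePair(p_left=cur_l, p_right=cur_r, score=score,
                           placement=placement)
    return pair, info


def search_convergence(features, cfg: ObjectiveConfig | None = None,
                       placement: int | None = None) -> ConvergencePair:
    """Convenience wrapper around :func:`run_search` returning only the pair."""
    pair, _ = run_search(features, cfg, placement)
    return pair
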