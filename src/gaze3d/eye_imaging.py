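"""Single-camera eye feature extraction.

Dark-pupil near-infrared imaging: the pupil is the darkest structure in the
eye region, so the eye is localised by the minima of smoothed row/column
intensity projections.  The pupil boundary is extracted by an adaptive
gray-gradient edge map (gradient magnitude, center/corner margin zeroing,
3×3-block mean thresholding, specular-spot suppression, neighborhood-sum
thresholding), then fitted by a two-step ellipse procedure: RANSAC consensus
fit followed by removal of points farther than one eighth of the major axis
from the consensus ellipse and a final least-squares fit.  The inner eye
corner is found by weighted multi-scale Harris response with sub-pixel
quadratic refinement.

Pixel conventions: 0-based, x = column, y = row; image width is ``m``
(columns) and height ``n`` (rows).  Gradients use central differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.feature import corner_harris
from skimage.measure import EllipseModel
from skimage.morphology import disk

from .errors import (FitFailedError, InsufficientEdgeSupportError,
                     NoCornerError, NoEyeFoundError)


def _estimate_ellipse(points):
    """Algebraic least-squares conic fit via skimage; None on failure.

    Wraps both the pre- and post-0.26 ``EllipseModel`` interfaces and
    returns ``(xc, yc, a, b, theta)``.
    """
    import warnings

    pts = np.asarray(points, dtype=float)
    params = None
    try:
        with warnings.catch_warnings(), np.errstate(all="ignore"):
            warnings.simplefilter("ignore")
            model = EllipseModel.from_estimate(pts)
        if model:
            xc, yc = model.center
            a, b = model.axis_lengths
            params = (xc, yc, a, b, model.theta)
    except AttributeError:      # scikit-image < 0.26
        pass
    except (TypeError, ValueError):
        # from_estimate can fail on exactly-circular data; retry below
        params = None
    if params is None:
        params = _fit_conic_ellipse(pts)
        if params is None:
            return None
    params = tuple(float(np.real(v)) for v in params)
    if not np.all(np.isfinite(params)):
        return None
    return params


def _fit_conic_ellipse(pts):
    """Direct algebraic conic fit (SVD nullspace) with geometric conversion.

    Stable for exactly-circular data, where the generic eigen solver can
    produce complex intermediate angles.
    """
    x, y = pts[:, 0], pts[:, 1]
    mx, my = x.mean(), y.mean()
    xs, ys = x - mx, y - my
    D = np.stack([xs ** 2, xs * ys, ys ** 2, xs, ys, np.ones_like(xs)], axis=1)
    try:
        _, _, vt = np.linalg.svd(D, full_matrices=False)
    except np.linalg.LinAlgError:
        return None
    A, B, C, Dc, E, F = vt[-1]
    disc = B * B - 4 * A * C
    if disc >= 0:
        return None
    # center of the centered conic
    xc = (2 * C * Dc - B * E) / disc
    yc = (2 * A * E - B * Dc) / disc
    # constant term at the center
    Fc = F + A * xc ** 2 + B * xc * yc + C * yc ** 2 + Dc * xc + E * yc
    if Fc == 0:
        return None
    M = np.array([[A, B / 2], [B / 2, C]]) / (-Fc)
    evals, evecs = np.linalg.eigh(M)
    if np.any(evals <= 0):
        return None
    axes = 1.0 / np.sqrt(evals)          # descending axis for ascending eval
    a, b = float(axes[0]), float(axes[1])
    theta = float(np.arctan2(evecs[1, 0], evecs[0, 0]))
    return (xc + mx, yc + my, a, b, theta)


__all__ = [
    "ImageFrame",
    "EdgeMap",
    "Ellipse2D",
    "CornerPoint2D",
    "EdgeMapConfig",
    "EllipseFitConfig",
    "CornerConfig",
    "locate_eye_region",
    "pupil_edge_map",
    "fit_pupil_ellipse",
    "detect_inner_corner",
    "point_ellipse_distance",
    "ellipse_points",
    "ellipse_row_chords",
]


@dataclass(frozen=True)
class ImageFrame:
    """8-bit grayscale frame with its camera label."""

    pixels: np.ndarray
    camera_id: str = ""

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a non-empty 2D array")
        object.__setattr__(self, "pixels", px)

    @property
    def width(self) -> int:        # m
        return self.pixels.shape[1]

    @property
    def height(self) -> int:       # n
        return self.pixels.shape[0]


@dataclass(frozen=True)
class EdgeMap:
    """Adaptive gradient edge map of a pupil region."""

    amplitude: np.ndarray          # surviving gradient magnitudes g(x, y)
    retained: np.ndarray           # binary map GG(x, y)
    block_grid: tuple              # ((row bounds), (col bounds)) of the 3×3 blocks

    def points(self) -> np.ndarray:
        """Retained edge points as (N, 2) float (x, y) coordinates."""
        ys, xs = np.nonzero(self.retained)
        return np.stack([xs, ys], axis=1).astype(float)


@dataclass(frozen=True)
class Ellipse2D:
    """Canonical image-plane ellipse: A ≥ B > 0, tilt α ∈ (−π/2, π/2]."""

    x0: float
    y0: float
    a: float
    b: float
    alpha: float

    @property
    def center(self) -> np.ndarray:
        return np.array([self.x0, self.y0])


@dataclass(frozen=True)
class CornerPoint2D:
    """Sub-pixel inner-corner location with its combined Harris score."""

    x: float
    y: float
    score: float


@dataclass(frozen=True)
class EyeRegionConfig:
    smooth_frac: float = 0.02      # projection smoothing σ as fraction of dim
    box_half_frac: float = 0.25    # half-size of the returned box
    min_range: float = 5.0         # minimum projection peak-to-peak (gray levels)


@dataclass(frozen=True)
class EdgeMapConfig:
    center_margin_frac: float = 0.05
    corner_margin_frac: float = 0.05
    spot_threshold: float = 250.0
    spot_dilation_px: int = 3
    threshold_scale: float = 0.6


@dataclass(frozen=True)
class EllipseFitConfig:
    min_points: int = 5
    ransac_iterations: int = 500
    inlier_threshold: float = 1.5   # px, metric point-to-ellipse distance
    outlier_axis_fraction: float = 1.0 / 8.0   # the A/8 rule


@dataclass(frozen=True)
class CornerConfig:
    scales: tuple = (1.0, 2.0, 4.0)
    weights: tuple = (0.5, 0.3, 0.2)
    harris_k: float = 0.05
    min_response: float = 1e-6     # on images normalised to [0, 1]
    border_margin: int = 16        # px excluded from the arg-max (4·max σ;
                                   # crop/frame edges produce spurious responses)


# ---------------------------------------------------------------------------
# eye region localisation


def locate_eye_region(frame: ImageFrame,
                      cfg: EyeRegionConfig | None = None) -> tuple[int, int, int, int]:
    """Axis-aligned eye box (x_min, y_min, x_max, y_max), exclusive maxima.

    The box is centred on the global minima of the gaussian-smoothed
    horizontal and vertical intensity projections (the dark pupil).
    Raises :class:`NoEyeFoundError` when either projection is too flat.
    """
    cfg = cfg or EyeRegionConfig()
    img = frame.pixels.astype(float)
    col_proj = img.mean(axis=0)    # function of x
    row_proj = img.mean(axis=1)    # function of y
    sx = max(1.0, cfg.smooth_frac * frame.width)
    sy = max(1.0, cfg.smooth_frac * frame.height)
    col_s = ndimage.gaussian_filter1d(col_proj, sx)
    row_s = ndimage.gaussian_filter1d(row_proj, sy)
    if (col_s.max() - col_s.min() < cfg.min_range
            or row_s.max() - row_s.min() < cfg.min_range):
        raise NoEyeFoundError("projection profiles too flat: no eye found")
    x0 = int(np.argmin(col_s))
    y0 = int(np.argmin(row_s))
    wx = max(2, int(round(cfg.box_half_frac * frame.width)))
    wy = max(2, int(round(cfg.box_half_frac * frame.height)))
    x_min = max(0, x0 - wx)
    y_min = max(0, y0 - wy)
    x_max = min(frame.width, x0 + wx + 1)
    y_max = min(frame.height, y0 + wy + 1)
    return (x_min, y_min, x_max, y_max)


# ---------------------------------------------------------------------------
# adaptive gradient edge map


def _block_bounds(size: int) -> tuple[int, int, int, int]:
    return (0, size // 3, (2 * size) // 3, size)


def pupil_edge_map(frame: ImageFrame,
                   cfg: EdgeMapConfig | None = None) -> EdgeMap:
    """Adaptive gray-gradient pupil edge map of an eye-region crop.

    Pipeline: central-difference gradient magnitude; zero the amplitude in
    the configured center and four-corner margins; within each of the 3×3
    blocks keep only values above the block mean (of the surviving nonzero
    values); zero inside the dilated specular-spot mask; finally a pixel is
    retained iff the 3×3 neighborhood sum of surviving values exceeds
    ``threshold_scale`` times the global mean neighborhood sum.
    """
    cfg = cfg or EdgeMapConfig()
    img = frame.pixels.astype(float)
    n, m = img.shape               # n rows (height), m cols (width)

    gy, gx = np.gradient(img)
    g = np.sqrt(gx ** 2 + gy ** 2)

    # center margin
    cmx = int(round(cfg.center_margin_frac * m))
    cmy = int(round(cfg.center_margin_frac * n))
    cx, cy = m // 2, n // 2
    if cmx > 0 and cmy > 0:
        g[max(0, cy - cmy):cy + cmy + 1, max(0, cx - cmx):cx + cmx + 1] = 0.0
    # four corner margins
    kx = int(round(cfg.corner_margin_frac * m))
    ky = int(round(cfg.corner_margin_frac * n))
    if kx > 0 and ky > 0:
        g[:ky, :kx] = 0.0
        g[:ky, m - kx:] = 0.0
        g[n - ky:, :kx] = 0.0
        g[n - ky:, m - kx:] = 0.0

    # 3×3 blocks: keep values above the block mean of surviving values
    rb = _block_bounds(n)
    cb = _block_bounds(m)
    for i in range(3):
        for j in range(3):
            block = g[rb[i]:rb[i + 1], cb[j]:cb[j + 1]]
            nz = block[block > 0]
            if nz.size == 0:
                continue
            mean = nz.sum() / nz.size
            block[block <= mean] = 0.0

    # specular spots: bright components dilated, amplitude zeroed inside
    spots = frame.pixels.astype(float) >= cfg.spot_threshold
    if spots.any() and cfg.spot_dilation_px > 0:
        spots = ndimage.binary_dilation(spots, structure=disk(cfg.spot_dilation_px))
    g[spots] = 0.0

    # 3×3 neighborhood sums (zero padding), fixed shift-add order
    padded = np.pad(g, 1, mode="constant")
    neigh = np.zeros_like(g)
    for dy in (-1, 0, 1):
        for dx in (-1, 0, 1):
            neigh = neigh + padded[1 + dy:1 + dy + n, 1 + dx:1 + dx + m]
    threshold = cfg.threshold_scale * neigh.sum() / (m * n)
    retained = neigh > threshold

    return EdgeMap(amplitude=g, retained=retained, block_grid=(rb, cb))


# ---------------------------------------------------------------------------
# ellipse model utilities


def _canonical(x0, y0, a, b, alpha) -> Ellipse2D:
    if b > a:
        a, b = b, a
        alpha = alpha + np.pi / 2.0
    alpha = np.remainder(alpha, np.pi)
    if alpha > np.pi / 2.0:
        alpha -= np.pi
    if alpha <= -np.pi / 2.0:       # map −π/2 to +π/2
        alpha += np.pi
    return Ellipse2D(x0=float(x0), y0=float(y0), a=float(a), b=float(b),
                     alpha=float(alpha))


def ellipse_points(ellipse: Ellipse2D, thetas) -> np.ndarray:
    """Parametric points (x, y) = center + Rot(α) · (A cosθ, B sinθ)."""
    th = np.asarray(thetas, dtype=float)
    ca, sa = np.cos(ellipse.alpha), np.sin(ellipse.alpha)
    px = ellipse.a * np.cos(th)
    py = ellipse.b * np.sin(th)
    x = ellipse.x0 + ca * px - sa * py
    y = ellipse.y0 + sa * px + ca * py
    return np.stack([x, y], axis=-1)


def point_ellipse_distance(ellipse: Ellipse2D, points,
                           iterations: int = 60) -> np.ndarray:
    """Metric (orthogonal) distance from points to the ellipse boundary.

    Solved per point by safeguarded bisection on the parametric foot angle
    in the first quadrant of the ellipse frame; accurate to ~1e-12·A.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    ca, sa = np.cos(ellipse.alpha), np.sin(ellipse.alpha)
    dx = pts[:, 0] - ellipse.x0
    dy = pts[:, 1] - ellipse.y0
    # rotate into the ellipse frame, fold into the first quadrant
    px = np.abs(ca * dx + sa * dy)
    py = np.abs(-sa * dx + ca * dy)
    a, b = ellipse.a, ellipse.b

    # root of f(θ) = (a²−b²) cosθ sinθ − px·a·sinθ + py·b·cosθ on [0, π/2];
    # f(0) = py·b ≥ 0 and f(π/2) = −px·a ≤ 0
    lo = np.zeros(px.shape)
    hi = np.full(px.shape, np.pi / 2.0)

    def f(th):
        c, s = np.cos(th), np.sin(th)
        return (a * a - b * b) * c * s - px * a * s + py * b * c

    for _ in range(iterations):
        mid = 0.5 * (lo + hi)
        fm = f(mid)
        neg = fm < 0.0
        hi = np.where(neg, mid, hi)
        lo = np.where(neg, lo, mid)
    th = 0.5 * (lo + hi)
    d = np.hypot(a * np.cos(th) - px, b * np.sin(th) - py)
    return d


def _lsq_ellipse(points) -> Ellipse2D:
    params = _estimate_ellipse(points)
    if params is None:
        raise FitFailedError("least-squares ellipse fit failed")
    xc, yc, a, b, theta = params
    if not (a > 0 and b > 0):
        raise FitFailedError("degenerate conic: non-elliptical solution")
    return _canonical(xc, yc, a, b, theta)


def fit_pupil_ellipse(edge, rng_seed: int | None = 0,
                      cfg: EllipseFitConfig | None = None) -> Ellipse2D:
    """Two-step pupil ellipse fit.

    Step 1 finds a RANSAC consensus ellipse (5-point minimal conic samples,
    metric inlier distance) and refits it on the consensus set.  Step 2
    discards points whose metric distance to the step-1 ellipse exceeds
    one eighth of its major axis and runs a final least-squares fit on the
    survivors.  ``edge`` is an :class:`EdgeMap` or an (N, 2) point array.
    """
    cfg = cfg or EllipseFitConfig()
    pts = edge.points() if isinstance(edge, EdgeMap) else \
        np.asarray(edge, dtype=float).reshape(-1, 2)
    if pts.shape[0] < cfg.min_points:
        raise InsufficientEdgeSupportError(
            f"{pts.shape[0]} edge points < {cfg.min_points} required")

    rng = np.random.default_rng(rng_seed)
    n = pts.shape[0]
    span = np.ptp(pts, axis=0).max() + 1.0
    best_inliers = None
    best_count = -1
    best_score = np.inf
    max_trials = cfg.ransac_iterations
    trial = 0
    while trial < max_trials:
        trial += 1
        sample = rng.choice(n, size=cfg.min_points, replace=False)
        params = _estimate_ellipse(pts[sample])
        if params is None:
            continue
        xc, yc, a, b, theta = params
        if a <= 0 or b <= 0 or max(a, b) > 4.0 * span:
            continue
        # a pupil candidate must be centred within the edge cloud; arcs of
        # occluding structures (eyelid rim) produce far-off centres
        lo = pts.min(axis=0) - 0.25 * span
        hi = pts.max(axis=0) + 0.25 * span
        if not (lo[0] <= xc <= hi[0] and lo[1] <= yc <= hi[1]):
            continue
        cand = _canonical(xc, yc, a, b, theta)
        d = point_ellipse_distance(cand, pts)
        inliers = d <= cfg.inlier_threshold
        count = int(inliers.sum())
        # MSAC consensus: truncated squared distance (lower is better);
        # discriminates mixtures that tie on raw inlier counts
        tau2 = cfg.inlier_threshold ** 2
        score = float(np.minimum(d ** 2, tau2).sum())
        if best_inliers is None or score < best_score:
            best_score = score
            best_count = count
            best_inliers = inliers
            # standard adaptive trial bound (99.99% confidence)
            w = count / n
            if w > 0:
                denom = np.log1p(-min(w ** cfg.min_points, 1 - 1e-12))
                if denom < 0:
                    max_trials = min(cfg.ransac_iterations,
                                     int(np.ceil(np.log(1e-4) / denom)))
    if best_inliers is None or best_count < cfg.min_points:
        raise FitFailedError("RANSAC found no elliptical consensus")

    # consensus ellipse with local refinement (refit on inliers, recompute
    # the inlier set; two passes suffice)
    step1 = _lsq_ellipse(pts[best_inliers])
    for _ in range(2):
        d = point_ellipse_distance(step1, pts)
        inliers = d <= cfg.inlier_threshold
        if inliers.sum() < cfg.min_points:
            break
        step1 = _lsq_ellipse(pts[inliers])

    # the A/8 outlier rule against the consensus ellipse
    d = point_ellipse_distance(step1, pts)
    survivors = pts[d <= cfg.outlier_axis_fraction * step1.a]
    if survivors.shape[0] < cfg.min_points:
        raise InsufficientEdgeSupportError(
            "fewer than 5 points survive the major-axis/8 filter")
    return _lsq_ellipse(survivors)


def ellipse_row_chords(ellipse: Ellipse2D, rows) -> tuple[np.ndarray, np.ndarray]:
    """Intersections of the ellipse with horizontal image rows.

    Returns ``(points, valid_rows)`` where points is (K, 2, 2): for each
    valid row the left and right boundary x at that y.  Rows that miss the
    ellipse are dropped.  Used to build row-aligned stereo correspondences
    on the textureless pupil boundary.
    """
    ys = np.atleast_1d(np.asarray(rows, dtype=float))
    ca, sa = np.cos(ellipse.alpha), np.sin(ellipse.alpha)
    a2, b2 = ellipse.a ** 2, ellipse.b ** 2
    # implicit conic in centered coords: c_xx x² + c_xy xy + c_yy y² = 1
    cxx = ca ** 2 / a2 + sa ** 2 / b2
    cxy = 2 * ca * sa * (1.0 / a2 - 1.0 / b2)
    cyy = sa ** 2 / a2 + ca ** 2 / b2
    dy = ys - ellipse.y0
    disc = (cxy * dy) ** 2 - 4 * cxx * (cyy * dy ** 2 - 1.0)
    valid = disc > 0
    dyv = dy[valid]
    sq = np.sqrt(disc[valid])
    x_lo = ellipse.x0 + (-cxy * dyv - sq) / (2 * cxx)
    x_hi = ellipse.x0 + (-cxy * dyv + sq) / (2 * cxx)
    pts = np.empty((dyv.size, 2, 2))
    pts[:, 0, 0] = x_lo
    pts[:, 1, 0] = x_hi
    pts[:, 0, 1] = ys[valid]
    pts[:, 1, 1] = ys[valid]
    return pts, ys[valid]


# ---------------------------------------------------------------------------
# inner eye corner


def detect_inner_corner(frame: ImageFrame,
                        region: tuple[int, int, int, int] | None = None,
                        cfg: CornerConfig | None = None) -> CornerPoint2D:
    """Weighted multi-scale Harris corner with sub-pixel refinement.

    The Harris response is computed at each configured smoothing scale,
    scale-normalised (×σ²) and combined with the configured weights; the
    arg-max is refined by fitting a 2D quadratic to its 3×3 neighborhood.
    Raises :class:`NoCornerError` when the best response is below threshold.
    """
    cfg = cfg or CornerConfig()
    if len(cfg.scales) != len(cfg.weights):
        raise ValueError("scales and weights must have equal length")
    if region is None:
        region = (0, 0, frame.width, frame.height)
    x_min, y_min, x_max, y_max = region
    if x_max <= x_min or y_max <= y_min:
        raise NoCornerError("empty corner search region")
    # expand the crop so crop-boundary gradient artefacts fall outside the
    # searched region
    pad = cfg.border_margin
    ex0, ey0 = max(0, x_min - pad), max(0, y_min - pad)
    ex1 = min(frame.width, x_max + pad)
    ey1 = min(frame.height, y_max + pad)
    crop = frame.pixels[ey0:ey1, ex0:ex1].astype(float) / 255.0
    if crop.size == 0:
        raise NoCornerError("empty corner search region")

    combined = np.zeros_like(crop)
    for s, w in zip(cfg.scales, cfg.weights):
        combined += w * (s ** 2) * corner_harris(crop, method="k",
                                                 k=cfg.harris_k, sigma=s)
    # searched area: the requested region, kept `pad` away from the frame
    # borders as well (gaussian border artefacts)
    ix0 = max(x_min, pad) - ex0
    iy0 = max(y_min, pad) - ey0
    ix1 = min(x_max, frame.width - pad) - ex0
    iy1 = min(y_max, frame.height - pad) - ey0
    if ix1 <= ix0 or iy1 <= iy0:    # region too close to the border
        ix0, iy0 = x_min - ex0, y_min - ey0
        ix1, iy1 = x_max - ex0, y_max - ey0
    inner = combined[iy0:iy1, ix0:ix1]
    peak = float(inner.max())
    if peak <= cfg.min_response:
        raise NoCornerError("no corner response above threshold")
    iy, ix = np.unravel_index(np.argmax(inner), inner.shape)
    iy += iy0
    ix += ix0

    # sub-pixel quadratic interpolation on the 3×3 neighborhood
    sx = sy = 0.0
    if 0 < iy < combined.shape[0] - 1 and 0 < ix < combined.shape[1] - 1:
        nb = combined[iy - 1:iy + 2, ix - 1:ix + 2]
        gx = (nb[1, 2] - nb[1, 0]) / 2.0
        gy = (nb[2, 1] - nb[0, 1]) / 2.0
        hxx = nb[1, 2] - 2 * nb[1, 1] + nb[1, 0]
        hyy = nb[2, 1] - 2 * nb[1, 1] + nb[0, 1]
        hxy = (nb[2, 2] - nb[2, 0] - nb[0, 2] + nb[0, 0]) / 4.0
        det = hxx * hyy - hxy * hxy
        if abs(det) > 1e-18:
            sx = -(hyy * gx - hxy * gy) / det
            sy = -(hxx * gy - hxy * gx) / det
            if not (abs(sx) <= 1.0 and abs(sy) <= 1.0):
                sx = sy = 0.0
    x = ex0 + ix + sx
    y = ey0 + iy + sy
    return CornerPoint2D(x=float(x), y=float(y), score=peak)
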