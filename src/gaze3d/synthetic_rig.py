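"""Ground-truthed synthetic binocular rig.

Two levels of synthesis:

* **Feature level** — :func:`simulate_session` plants per-eye convergence
  laws and a pupil-size-vs-distance law, places a four-cross calibration
  board at five distances (40–120 cm), and emits exact and noise-corrupted
  3D feature tracks plus held-out test fixations.  Exact sightlines pass
  through their targets by construction.

* **Image level** — :func:`render_fixation` renders dark-pupil eye images
  (projected 3D pupil circle, iris/sclera shading, optional eyelid wedge,
  occlusion band and specular spots, Gaussian pixel noise) for all four
  cameras together with per-camera ground-truth ellipses and corner pixels.

Geometry: rig frame = leftmost camera, +Z from the cameras toward the face.
The eyes sit ≈70–85 mm in front of the cameras (the folded mirror path);
gaze targets are on the far side of the cameras, at negative Z.  Viewing
distance d is measured from the inner-corner midpoint to the board plane.
The planted pupil-size law is strictly increasing in d (pupil constricts
for near targets — the accommodation reflex under fixed illumination).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from .convergence_calibration import CalibrationBoard, ConvergencePair
from .errors import ScenarioError
from .eye_imaging import Ellipse2D, ImageFrame, _estimate_ellipse
from .stereo_reconstruction import CameraModel, EyeFeatureSet, StereoRig, default_rig

__all__ = [
    "PlantedLaw",
    "RigScenario",
    "FixationTruth",
    "PlacementTruth",
    "SimulatedSession",
    "AppearanceConfig",
    "simulate_session",
    "simulate_fixation",
    "render_fixation",
    "render_eye_pair",
]


@dataclass(frozen=True)
class PlantedLaw:
    """Planted per-eye convergence law (initial corner-reference mm)."""

    gamma: tuple = (8.0, -0.6, 0.02)
    alpha: tuple = (0.0, 0.4)
    beta: tuple = (-4.0, 0.15)

    def point(self, size: float) -> np.ndarray:
        g0, g1, g2 = self.gamma
        z = g0 + g1 * size + g2 * size ** 2
        x = self.alpha[0] + self.alpha[1] * z
        y = self.beta[0] + self.beta[1] * z
        return np.array([x, y, z])


@dataclass(frozen=True)
class RigScenario:
    """Study conditions of a synthetic calibration session.

    Distances in mm.  ``feature_noise`` is the σ of additive Gaussian noise
    on every 3D feature coordinate and on the pupil size.  The pupil-size
    law is linear between ``(400 mm, s_near)`` and ``(1200 mm, s_far)`` and
    must be strictly increasing with distance.
    """

    corner_left: tuple = (24.0, 3.0, 74.0)
    corner_right: tuple = (52.0, 3.0, 74.0)
    law_left: PlantedLaw = field(default_factory=lambda: PlantedLaw(
        gamma=(8.0, -0.6, 0.02), alpha=(-43.5, 0.4), beta=(-4.0, 0.15)))
    law_right: PlantedLaw = field(default_factory=lambda: PlantedLaw(
        gamma=(8.3, -0.65, 0.025), alpha=(10.5, 0.4), beta=(-4.0, 0.15)))
    s_near: float = 2.2            # pupil diameter at 400 mm
    s_far: float = 4.6             # pupil diameter at 1200 mm
    pupil_offset: float = 10.0     # anatomical convergence→pupil distance
    board_distances: tuple = (400.0, 600.0, 800.0, 1000.0, 1200.0)
    cross_spacing: float = 150.0
    test_distances: tuple = (500.0, 700.0, 900.0, 1100.0)
    n_test_per_distance: int = 1
    feature_noise: float = 0.0     # mm

    def __post_init__(self):
        if self.s_far <= self.s_near:
            raise ScenarioError(
                "pupil-size law must strictly increase with distance "
                "(accommodation reflex: small pupil near, large pupil far)")
        if self.feature_noise < 0:
            raise ScenarioError("feature noise must be non-negative")

    def pupil_size(self, distance: float) -> float:
        """Planted accommodation law S(d), linear in d (mm)."""
        frac = (distance - 400.0) / 800.0
        return self.s_near + (self.s_far - self.s_near) * frac

    @property
    def corner_midpoint(self) -> np.ndarray:
        return (np.asarray(self.corner_left) + np.asarray(self.corner_right)) / 2.0

    @property
    def reference_origin(self) -> np.ndarray:
        return np.asarray(self.corner_right, dtype=float)


@dataclass(frozen=True)
class FixationTruth:
    """Everything known about one synthetic fixation."""

    target: np.ndarray
    distance: float
    convergence: ConvergencePair
    exact: EyeFeatureSet
    noisy: EyeFeatureSet
    placement: int | None = None
    fixation: int | None = None


@dataclass(frozen=True)
class PlacementTruth:
    distance: float
    fixations: tuple               # 4 FixationTruth in cross order


@dataclass(frozen=True)
class SimulatedSession:
    """A full synthetic calibration session plus held-out test fixations."""

    scenario: RigScenario
    board: CalibrationBoard
    placements: tuple
    tests: tuple
    seed: int | None = None

    def calibration_features(self, noisy: bool = True):
        """Per-placement lists of 4 EyeFeatureSets (the capture records)."""
        attr = "noisy" if noisy else "exact"
        return [[getattr(f, attr) for f in p.fixations] for p in self.placements]

    @property
    def n_captures(self) -> int:
        return sum(len(p.fixations) for p in self.placements)


def _noisy_features(exact: EyeFeatureSet, sigma: float, rng) -> EyeFeatureSet:
    if sigma == 0.0:
        return exact
    def jig(v):
        return np.asarray(v, dtype=float) + rng.normal(0.0, sigma, size=3)
    return EyeFeatureSet(
        pupil_left=jig(exact.pupil_left), pupil_right=jig(exact.pupil_right),
        size_left=max(exact.size_left + rng.normal(0.0, sigma), 0.1),
        size_right=max(exact.size_right + rng.normal(0.0, sigma), 0.1),
        corner_left=jig(exact.corner_left), corner_right=jig(exact.corner_right),
        fixation=exact.fixation, placement=exact.placement)


def simulate_fixation(scenario: RigScenario, target, distance: float, rng,
                      placement: int | None = None,
                      fixation: int | None = None) -> FixationTruth:
    """One fixation: planted convergence pair, pupil centers on the
    convergence→target segment, pupil size from the planted S(d)."""
    target = np.asarray(target, dtype=float)
    if target[2] >= scenario.corner_midpoint[2]:
        raise ScenarioError("target behind the eyes")
    size = scenario.pupil_size(distance)
    origin0 = scenario.reference_origin
    conv_l = origin0 + scenario.law_left.point(size)
    conv_r = origin0 + scenario.law_right.point(size)
    pupils = {}
    for side, conv in (("left", conv_l), ("right", conv_r)):
        direction = target - conv
        pupils[side] = conv + scenario.pupil_offset * direction / np.linalg.norm(direction)
    exact = EyeFeatureSet(
        pupil_left=pupils["left"], pupil_right=pupils["right"],
        size_left=size, size_right=size,
        corner_left=np.asarray(scenario.corner_left, dtype=float),
        corner_right=np.asarray(scenario.corner_right, dtype=float),
        fixation=fixation, placement=placement)
    noisy = _noisy_features(exact, scenario.feature_noise, rng)
    return FixationTruth(
        target=target, distance=distance,
        convergence=ConvergencePair(p_left=conv_l, p_right=conv_r,
                                    placement=placement),
        exact=exact, noisy=noisy, placement=placement, fixation=fixation)


#: cross order around the board: a closed square loop, each side = spacing
_CROSS_OFFSETS = ((-0.5, -0.5), (0.5, -0.5), (0.5, 0.5), (-0.5, 0.5))


def simulate_session(scenario: RigScenario | None = None,
                     seed: int | None = 0) -> SimulatedSession:
    """Simulate the full calibration protocol (5 placements × 4 crosses)
    plus held-out test fixations at the scenario's test distances."""
    scenario = scenario or RigScenario()
    rng = np.random.default_rng(seed)
    mid = scenario.corner_midpoint
    L = scenario.cross_spacing

    placements = []
    for j, d in enumerate(scenario.board_distances, start=1):
        board_center = mid + np.array([0.0, 0.0, -d])
        fixations = []
        for i, (ox, oy) in enumerate(_CROSS_OFFSETS, start=1):
            target = board_center + np.array([ox * L, oy * L, 0.0])
            fixations.append(simulate_fixation(scenario, target, d, rng,
                                               placement=j, fixation=i))
        placements.append(PlacementTruth(distance=d, fixations=tuple(fixations)))

    tests = []
    for d in scenario.test_distances:
        for _ in range(scenario.n_test_per_distance):
            lateral = rng.uniform(-40.0, 40.0, size=2)
            target = mid + np.array([lateral[0], lateral[1], -d])
            tests.append(simulate_fixation(scenario, target, d, rng))

    return SimulatedSession(
        scenario=scenario,
        board=CalibrationBoard(spacing=L,
                               placement_range=(min(scenario.board_distances),
                                                max(scenario.board_distances))),
        placements=tuple(placements), tests=tuple(tests), seed=seed)


# ---------------------------------------------------------------------------
# image rendering


@dataclass(frozen=True)
class AppearanceConfig:
    """Shading and artefact settings of the dark-pupil renderer."""

    sclera: float = 185.0
    iris: float = 115.0
    pupil: float = 28.0
    lid: float = 70.0
    iris_radius: float = 5.5       # mm
    edge_softness: float = 1.0     # px, anti-aliased boundary width
    corner_wedge: bool = True
    wedge_half_angle: float = 0.9  # rad (wide-open lid junction)
    wedge_length: float = 45.0     # px
    specular_spot: bool = False
    spot_offset: tuple = (5.0, -4.0)   # px from pupil center
    spot_radius: float = 3.0       # px
    spot_value: float = 255.0
    lid_cover_frac: float = 0.0    # fraction of pupil vertical extent occluded
    noise_sigma: float = 0.0       # gray levels


def _fill_conic(img, ellipse: Ellipse2D, value: float, softness: float):
    """Soft-edged fill of an ellipse interior (first-order distance blend)."""
    n, m = img.shape
    pad = max(ellipse.a, ellipse.b) + 3.0
    x0 = max(0, int(ellipse.x0 - pad))
    x1 = min(m, int(ellipse.x0 + pad) + 1)
    y0 = max(0, int(ellipse.y0 - pad))
    y1 = min(n, int(ellipse.y0 + pad) + 1)
    if x0 >= x1 or y0 >= y1:
        return
    xs, ys = np.meshgrid(np.arange(x0, x1), np.arange(y0, y1))
    ca, sa = np.cos(ellipse.alpha), np.sin(ellipse.alpha)
    dx = xs - ellipse.x0
    dy = ys - ellipse.y0
    u = ca * dx + sa * dy
    v = -sa * dx + ca * dy
    q = (u / ellipse.a) ** 2 + (v / ellipse.b) ** 2
    # signed distance approximation: (q − 1) / |∇q|
    gu = 2 * u / ellipse.a ** 2
    gv = 2 * v / ellipse.b ** 2
    grad = np.sqrt(gu ** 2 + gv ** 2)
    grad[grad < 1e-12] = 1e-12
    d = (q - 1.0) / grad
    w = np.clip(0.5 - d / max(softness, 1e-6), 0.0, 1.0)
    roi = img[y0:y1, x0:x1]
    roi[:] = roi * (1.0 - w) + value * w


def _project_circle(center, radius, normal, cam: CameraModel, n_points=720):
    """Project a 3D circle and fit the exact image ellipse."""
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, normal)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(normal, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    th = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    pts3 = (np.asarray(center, dtype=float)
            + radius * (np.outer(np.cos(th), e1) + np.outer(np.sin(th), e2)))
    pix = cam.project(pts3)
    params = _estimate_ellipse(pix)
    if params is None:
        raise ScenarioError("projected circle did not fit an ellipse")
    xc, yc, a, b, theta = params
    if b > a:
        a, b = b, a
        theta += np.pi / 2.0
    theta = np.remainder(theta, np.pi)
    if theta > np.pi / 2.0:
        theta -= np.pi
    return Ellipse2D(x0=xc, y0=yc, a=a, b=b, alpha=theta)


def render_fixation(fix: FixationTruth, rig: StereoRig | None = None,
                    appearance: AppearanceConfig | None = None,
                    seed: int | None = 0) -> dict:
    """Render all four camera views of one fixation.

    Returns ``{camera_id: (ImageFrame, truth)}`` where ``truth`` holds the
    exact projected pupil/iris ellipses and corner pixel.  Raises
    :class:`ScenarioError` when a feature falls outside a camera frustum.
    """
    rig = rig or default_rig()
    appearance = appearance or AppearanceConfig()
    rng = np.random.default_rng(seed)
    out = {}
    for side in ("left", "right"):
        cams = rig.pairs[side]
        pupil = getattr(fix.exact, f"pupil_{side}")
        size = getattr(fix.exact, f"size_{side}")
        conv = getattr(fix.convergence, f"p_{side}")
        corner = getattr(fix.exact, f"corner_{side}")
        normal = fix.target - conv
        normal = normal / np.linalg.norm(normal)
        for cid in cams:
            cam = rig.cameras[cid]
            w, h = cam.image_size
            img = np.full((h, w), appearance.sclera, dtype=float)
            pupil_ell = _project_circle(pupil, size / 2.0, normal, cam)
            iris_ell = _project_circle(pupil, appearance.iris_radius, normal, cam)
            corner_px = cam.project(corner)
            for px in (pupil_ell.center, corner_px):
                if not (0 <= px[0] < w and 0 <= px[1] < h):
                    raise ScenarioError(
                        f"feature outside frustum of camera {cid}")
            _fill_conic(img, iris_ell, appearance.iris, appearance.edge_softness)
            _fill_conic(img, pupil_ell, appearance.pupil, appearance.edge_softness)

            if appearance.corner_wedge:
                _draw_wedge(img, corner_px, pupil_ell.center, appearance)
            if appearance.lid_cover_frac > 0.0:
                _draw_lid_band(img, pupil_ell, appearance)
            if appearance.specular_spot:
                cxs = pupil_ell.x0 + appearance.spot_offset[0]
                cys = pupil_ell.y0 + appearance.spot_offset[1]
                spot = Ellipse2D(x0=cxs, y0=cys, a=appearance.spot_radius,
                                 b=appearance.spot_radius, alpha=0.0)
                _fill_conic(img, spot, appearance.spot_value, 0.5)
            if appearance.noise_sigma > 0.0:
                img = img + rng.normal(0.0, appearance.noise_sigma, img.shape)
            frame = ImageFrame(pixels=np.clip(np.round(img), 0, 255).astype(np.uint8),
                               camera_id=cid)
            out[cid] = (frame, {"pupil_ellipse": pupil_ell,
                                "iris_ellipse": iris_ell,
                                "corner": np.asarray(corner_px, dtype=float),
                                "side": side})
    return out


def render_eye_pair(fix: FixationTruth, rig: StereoRig | None = None,
                    appearance: AppearanceConfig | None = None,
                    seed: int | None = 0) -> dict:
    """Alias of :func:`render_fixation` (all four frames + ground truth)."""
    return render_fixation(fix, rig, appearance, seed)


def _draw_wedge(img, apex, toward, appearance: AppearanceConfig):
    """Dark eyelid wedge whose tip is the inner corner (an L-junction).

    The fill fades out smoothly with distance from the apex so the only
    sharp two-edge junction in the patch is the apex itself (the outer rim
    would otherwise create spurious corner responses).
    """
    n, m = img.shape
    ax, ay = float(apex[0]), float(apex[1])
    direction = np.array([float(toward[0]) - ax, float(toward[1]) - ay])
    nd = np.linalg.norm(direction)
    if nd < 1e-9:
        direction = np.array([1.0, 0.0])
    else:
        direction = direction / nd
    base_angle = np.arctan2(direction[1], direction[0])
    xs, ys = np.meshgrid(np.arange(m), np.arange(n))
    dx = xs - ax + 1e-9
    dy = ys - ay
    dist = np.hypot(dx, dy)
    ang = np.arctan2(dy, dx)
    dang = np.remainder(ang - base_angle + np.pi, 2 * np.pi) - np.pi
    inside = np.abs(dang) <= appearance.wedge_half_angle
    fade = np.clip(1.0 - dist / appearance.wedge_length, 0.0, 1.0)
    w = np.where(inside, fade, 0.0)
    img[:] = img * (1.0 - w) + appearance.lid * w


def _draw_lid_band(img, pupil_ell: Ellipse2D, appearance: AppearanceConfig):
    """Occlude the top of the pupil with a dark eyelid wedge.

    The wedge apex sits ``lid_cover_frac`` of the pupil's vertical extent
    below the pupil top and opens upward, so the occluding boundary is two
    short straight edges through the pupil cap (the eyelid-corner intrusion
    of a half-closed lid), not an image-wide edge.
    """
    n, m = img.shape
    b_eff = np.sqrt((pupil_ell.a * np.sin(pupil_ell.alpha)) ** 2
                    + (pupil_ell.b * np.cos(pupil_ell.alpha)) ** 2)
    ay = pupil_ell.y0 - b_eff + 2.0 * b_eff * appearance.lid_cover_frac
    ax = pupil_ell.x0
    xs, ys = np.meshgrid(np.arange(m), np.arange(n))
    dx = xs - ax + 1e-9
    dy = ys - ay
    ang = np.arctan2(dy, dx)
    # wedge opens upward (−y in image coordinates)
    dang = np.remainder(ang + np.pi / 2.0 + np.pi, 2 * np.pi) - np.pi
    dist = np.hypot(dx, dy)
    inside = np.abs(dang) <= 1.1
    fade = np.clip(1.0 - dist / (4.0 * b_eff), 0.0, 1.0)
    w = np.where(inside, fade, 0.0)
    img[:] = img * (1.0 - w) + appearance.lid * w
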