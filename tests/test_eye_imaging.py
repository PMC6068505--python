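"""Pupil edge map, two-step ellipse fit, eye localisation, corner detection."""

import numpy as np
import pytest

from gaze3d import eye_imaging as ei
from gaze3d.errors import (FitFailedError, InsufficientEdgeSupportError,
                           NoCornerError, NoEyeFoundError)

from _oracles import literal_edge_map


def dark_disk_image(size=128, center=(64, 64), radius=40, dark=30, bright=200):
    yy, xx = np.mgrid[0:size, 0:size]
    img = np.full((size, size), float(bright))
    d = np.hypot(xx - center[0], yy - center[1])
    img[d <= radius] = dark
    # 1 px soft edge for a localised gradient
    edge = (d > radius) & (d <= radius + 1)
    img[edge] = (dark + bright) / 2.0
    return img.astype(np.uint8)


# ---------------------------------------------------------------------------
# edge map


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_edge_map_bit_identical_to_literal_oracle(seed):
    """On 64×64 images the edge map must equal an independent per-pixel
    re-evaluation of the whole pipeline, bit for bit."""
    rng = np.random.default_rng(seed)
    img = rng.integers(0, 256, size=(64, 64), dtype=np.uint8)
    em = ei.pupil_edge_map(ei.ImageFrame(pixels=img))
    g_ref, gg_ref = literal_edge_map(img)
    np.testing.assert_array_equal(em.retained, gg_ref)
    np.testing.assert_array_equal(em.amplitude, g_ref)


def test_edge_map_bit_identical_on_structured_image():
    img = dark_disk_image(size=64, center=(30, 34), radius=15)
    img[5:8, 50:55] = 255     # a specular spot
    em = ei.pupil_edge_map(ei.ImageFrame(pixels=img))
    g_ref, gg_ref = literal_edge_map(img)
    np.testing.assert_array_equal(em.retained, gg_ref)


def test_edge_map_constant_image_empty():
    em = ei.pupil_edge_map(ei.ImageFrame(pixels=np.full((40, 40), 90, np.uint8)))
    assert not em.retained.any()


def test_edge_map_disk_boundary_localised():
    """≥90% of retained pixels must lie within 2 px of the disk boundary."""
    img = dark_disk_image()
    em = ei.pupil_edge_map(ei.ImageFrame(pixels=img))
    pts = em.points()
    assert len(pts) > 50
    d = np.abs(np.hypot(pts[:, 0] - 64, pts[:, 1] - 64) - 40)
    assert (d <= 2.0).mean() >= 0.90


def test_edge_map_zero_inside_dilated_spot():
    img = dark_disk_image()
    img[60:64, 60:64] = 255
    em = ei.pupil_edge_map(ei.ImageFrame(pixels=img))
    # nothing retained within the dilated spot mask
    from scipy import ndimage
    from skimage.morphology import disk as disk_se
    mask = ndimage.binary_dilation(img >= 250, structure=disk_se(3))
    assert not em.retained[mask].any()
    assert not em.amplitude[mask].any()


# ---------------------------------------------------------------------------
# ellipse fitting


def test_noiseless_circle_recovered_exactly():
    th = np.linspace(0, 2 * np.pi, 60, endpoint=False)
    pts = np.stack([50 + 30 * np.cos(th), 55 + 30 * np.sin(th)], axis=1)
    ell = ei.fit_pupil_ellipse(pts, rng_seed=0)
    assert ell.x0 == pytest.approx(50, abs=1e-6)
    assert ell.y0 == pytest.approx(55, abs=1e-6)
    assert ell.a == pytest.approx(30, abs=1e-6)
    assert ell.b == pytest.approx(30, abs=1e-6)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_ellipse_recovery_with_uniform_outliers(seed):
    """A=40, B=25, α=0.3 with 20% uniform outliers → 0.5 px / 0.02 rad."""
    rng = np.random.default_rng(seed)
    truth = ei.Ellipse2D(x0=100.0, y0=90.0, a=40.0, b=25.0, alpha=0.3)
    pts = ei.ellipse_points(truth, rng.uniform(0, 2 * np.pi, 100))
    outliers = rng.uniform(40, 160, size=(20, 2))
    cloud = np.vstack([pts, outliers])
    ell = ei.fit_pupil_ellipse(cloud, rng_seed=seed)
    assert np.hypot(ell.x0 - truth.x0, ell.y0 - truth.y0) < 0.5
    assert abs(ell.a - truth.a) < 0.5 and abs(ell.b - truth.b) < 0.5
    assert abs(ell.alpha - truth.alpha) < 0.02


def test_canonical_form_swaps_axes():
    """Generator labelled with B > A must come back with A ≥ B and
    α ∈ (−π/2, π/2]."""
    gen = ei.Ellipse2D(x0=0.0, y0=0.0, a=10.0, b=22.0, alpha=0.2)
    pts = ei.ellipse_points(gen, np.linspace(0, 2 * np.pi, 80, endpoint=False))
    ell = ei.fit_pupil_ellipse(pts, rng_seed=0)
    assert ell.a >= ell.b
    assert -np.pi / 2 < ell.alpha <= np.pi / 2
    assert ell.a == pytest.approx(22.0, abs=1e-6)
    assert ell.b == pytest.approx(10.0, abs=1e-6)


def test_ellipse_roundtrip_property():
    """Sampling ≥10 parametric points and refitting recovers parameters to
    1e-6 relative."""
    rng = np.random.default_rng(99)
    for _ in range(25):
        a = rng.uniform(8, 60)
        b = rng.uniform(5, a)
        truth = ei.Ellipse2D(x0=rng.uniform(-50, 50), y0=rng.uniform(-50, 50),
                             a=a, b=b, alpha=rng.uniform(-1.4, 1.4))
        pts = ei.ellipse_points(truth, np.linspace(0, 2 * np.pi, 24,
                                                   endpoint=False))
        ell = ei.fit_pupil_ellipse(pts, rng_seed=0)
        assert np.hypot(ell.x0 - truth.x0, ell.y0 - truth.y0) < 1e-6 * max(a, 1)
        assert abs(ell.a - truth.a) < 1e-6 * a
        assert abs(ell.b - truth.b) < 1e-6 * a


def test_monotone_outlier_robustness():
    """Mean center error does not increase as the outlier fraction drops."""
    truth = ei.Ellipse2D(x0=80.0, y0=75.0, a=35.0, b=28.0, alpha=-0.4)
    seeds = range(6)
    means = []
    for frac in (0.3, 0.2, 0.1, 0.0):
        errs = []
        for seed in seeds:
            rng = np.random.default_rng(1234 + seed)
            pts = ei.ellipse_points(truth, rng.uniform(0, 2 * np.pi, 120))
            pts += rng.normal(0, 0.2, pts.shape)
            n_out = int(len(pts) * frac / (1 - frac))
            cloud = np.vstack([pts, rng.uniform(20, 140, size=(n_out, 2))])
            ell = ei.fit_pupil_ellipse(cloud, rng_seed=seed)
            errs.append(np.hypot(ell.x0 - truth.x0, ell.y0 - truth.y0))
        means.append(np.mean(errs))
    for higher, lower in zip(means[:-1], means[1:]):
        assert lower <= higher + 0.05


def test_insufficient_points_raise():
    with pytest.raises(InsufficientEdgeSupportError):
        ei.fit_pupil_ellipse(np.zeros((4, 2)), rng_seed=0)


def test_collinear_points_fail():
    pts = np.stack([np.arange(20.0), np.arange(20.0)], axis=1)
    with pytest.raises((FitFailedError, InsufficientEdgeSupportError)):
        ei.fit_pupil_ellipse(pts, rng_seed=0)


def test_point_ellipse_distance_circle_and_axes():
    circ = ei.Ellipse2D(x0=0.0, y0=0.0, a=10.0, b=10.0, alpha=0.0)
    pts = np.array([[15.0, 0.0], [0.0, 3.0], [7.0, 0.0]])
    np.testing.assert_allclose(ei.point_ellipse_distance(circ, pts),
                               [5.0, 7.0, 3.0], atol=1e-9)
    ell = ei.Ellipse2D(x0=0.0, y0=0.0, a=5.0, b=2.0, alpha=0.0)
    np.testing.assert_allclose(
        ei.point_ellipse_distance(ell, np.array([[8.0, 0.0], [0.0, -6.0]])),
        [3.0, 4.0], atol=1e-9)


# ---------------------------------------------------------------------------
# eye region and corners


def test_locate_eye_region_contains_dark_disk():
    img = dark_disk_image(size=200, center=(140, 60), radius=20)
    frame = ei.ImageFrame(pixels=img)
    x0, y0, x1, y1 = ei.locate_eye_region(frame)
    assert 0 <= x0 < 140 < x1 <= 200
    assert 0 <= y0 < 60 < y1 <= 200


def test_locate_eye_region_flat_image_raises():
    with pytest.raises(NoEyeFoundError):
        ei.locate_eye_region(ei.ImageFrame(pixels=np.full((50, 60), 128,
                                                          np.uint8)))


def l_junction_image(size=96, corner=(40, 50), bright=220, dark=40):
    """Two perpendicular straight edges meeting at a corner."""
    img = np.full((size, size), float(bright))
    cx, cy = corner
    img[:cy, :cx] = dark
    return img.astype(np.uint8)


def test_l_junction_detected_within_one_pixel():
    img = l_junction_image()
    pt = ei.detect_inner_corner(ei.ImageFrame(pixels=img))
    # the junction of the two edges is at the block corner (40, 50); the
    # intensity edge sits between pixels 39/40 and 49/50
    assert abs(pt.x - 39.5) <= 1.0
    assert abs(pt.y - 49.5) <= 1.0


def test_flat_region_has_no_corner():
    with pytest.raises(NoCornerError):
        ei.detect_inner_corner(ei.ImageFrame(pixels=np.full((60, 60), 100,
                                                            np.uint8)))


def test_corner_requires_matching_scale_weights():
    img = l_junction_image()
    with pytest.raises(ValueError):
        ei.detect_inner_corner(ei.ImageFrame(pixels=img),
                               cfg=ei.CornerConfig(scales=(1, 2),
                                                   weights=(1.0,)))
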