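"""Synthetic binocular rig: feature-level sessions and rendered images."""

import numpy as np
import pytest

from gaze3d.errors import ScenarioError
from gaze3d.estimator import GazePointEstimator
from gaze3d.pipeline import detect_eye_features, extract_feature_set
from gaze3d.stereo_reconstruction import default_rig
from gaze3d.synthetic_rig import (AppearanceConfig, RigScenario,
                                  render_fixation, simulate_fixation,
                                  simulate_session)


# ---------------------------------------------------------------------------
# feature-level simulation


def test_same_seed_reproduces_session():
    a = simulate_session(RigScenario(feature_noise=0.05), seed=42)
    b = simulate_session(RigScenario(feature_noise=0.05), seed=42)
    for pa, pb in zip(a.placements, b.placements):
        for fa, fb in zip(pa.fixations, pb.fixations):
            np.testing.assert_array_equal(fa.noisy.pupil_left,
                                          fb.noisy.pupil_left)
            assert fa.noisy.size_left == fb.noisy.size_left


def test_protocol_has_five_placements_of_four_crosses(default_session):
    assert len(default_session.placements) == 5
    assert all(len(p.fixations) == 4 for p in default_session.placements)
    assert default_session.n_captures == 20


def test_exact_sightlines_contain_their_targets(default_session):
    for p in default_session.placements:
        for fix in p.fixations:
            for side in ("left", "right"):
                conv = getattr(fix.convergence, f"p_{side}")
                pupil = getattr(fix.exact, f"pupil_{side}")
                u = (pupil - conv) / np.linalg.norm(pupil - conv)
                w = fix.target - conv
                # distance from the target to the infinite sightline
                assert np.linalg.norm(np.cross(u, w)) / max(
                    np.linalg.norm(w), 1.0) < 1e-12


def test_cross_spacing_is_150mm(default_session):
    for p in default_session.placements:
        t = [f.target for f in p.fixations]
        for i in range(4):
            assert np.linalg.norm(t[i] - t[(i + 1) % 4]) == pytest.approx(150.0)


def test_pupil_size_strictly_increases_with_distance(default_session):
    """Accommodation under fixed illumination: small pupil near, large far."""
    sc = default_session.scenario
    sizes = [sc.pupil_size(d) for d in sorted(sc.board_distances)]
    assert all(b > a for a, b in zip(sizes[:-1], sizes[1:]))
    by_distance = [(p.distance, p.fixations[0].exact.size_left)
                   for p in default_session.placements]
    by_distance.sort()
    assert all(b[1] > a[1] for a, b in zip(by_distance[:-1], by_distance[1:]))


def test_target_behind_eyes_rejected():
    sc = RigScenario()
    with pytest.raises(ScenarioError):
        simulate_fixation(sc, sc.corner_midpoint + [0, 0, 100.0], 500.0,
                          np.random.default_rng(0))


def test_nonincreasing_pupil_law_rejected():
    with pytest.raises(ScenarioError):
        RigScenario(s_near=4.0, s_far=3.0)


def test_noise_fields_populated():
    sim = simulate_session(RigScenario(feature_noise=0.05), seed=3)
    fix = sim.placements[0].fixations[0]
    assert not np.array_equal(fix.exact.pupil_left, fix.noisy.pupil_left)
    sim0 = simulate_session(RigScenario(), seed=3)
    fix0 = sim0.placements[0].fixations[0]
    np.testing.assert_array_equal(fix0.exact.pupil_left, fix0.noisy.pupil_left)


# ---------------------------------------------------------------------------
# rendering + detection


@pytest.fixture(scope="module")
def rendered_fixture():
    sim = simulate_session(RigScenario(), seed=3)
    rig = default_rig()
    fix = sim.placements[1].fixations[0]
    return sim, rig, fix


def test_rendered_clean_pupil_recovered(rendered_fixture):
    """Two-step fit recovers the projected ground-truth ellipse to sub-pixel
    accuracy on clean renders (mean ≤ 0.5 px over the four cameras)."""
    _, rig, fix = rendered_fixture
    out = render_fixation(fix, rig, AppearanceConfig(), seed=0)
    errs = []
    for cid, (frame, truth) in out.items():
        det = detect_eye_features(frame, seed=0)
        te = truth["pupil_ellipse"]
        errs.append(np.hypot(det.ellipse.x0 - te.x0, det.ellipse.y0 - te.y0))
        assert abs(det.ellipse.a - te.a) < 1.0
    assert np.mean(errs) <= 0.5
    assert max(errs) < 1.0


def test_rendered_occluded_pupil_recovered(rendered_fixture):
    """30% eyelid-wedge occlusion still keeps the fit within 1.5 px."""
    sim, rig, _ = rendered_fixture
    errs = []
    for p in sim.placements[::2]:
        fix = p.fixations[0]
        out = render_fixation(fix, rig,
                              AppearanceConfig(lid_cover_frac=0.3,
                                               corner_wedge=False), seed=0)
        frame, truth = out["L1"]
        det = detect_eye_features(frame, seed=0, detect_corner=False)
        te = truth["pupil_ellipse"]
        errs.append(np.hypot(det.ellipse.x0 - te.x0, det.ellipse.y0 - te.y0))
    assert max(errs) <= 1.5


def test_rendered_corner_apex_localised(rendered_fixture):
    _, rig, fix = rendered_fixture
    out = render_fixation(fix, rig, AppearanceConfig(), seed=0)
    for cid, (frame, truth) in out.items():
        det = detect_eye_features(frame, seed=0)
        err = np.hypot(det.corner.x - truth["corner"][0],
                       det.corner.y - truth["corner"][1])
        assert err < 1.5


def test_edge_pixels_hug_projected_boundary(rendered_fixture):
    """Zero-noise, spot-free render: retained edge pixels concentrate on the
    projected pupil boundary."""
    from gaze3d import eye_imaging as ei
    from gaze3d.pipeline import pupil_crop_box

    _, rig, fix = rendered_fixture
    out = render_fixation(fix, rig, AppearanceConfig(corner_wedge=False),
                          seed=0)
    frame, truth = out["L1"]
    te = truth["pupil_ellipse"]
    box = pupil_crop_box(frame, (te.x0, te.y0))
    crop = ei.ImageFrame(pixels=frame.pixels[box[1]:box[3], box[0]:box[2]])
    pts = ei.pupil_edge_map(crop).points() + [box[0], box[1]]
    d = ei.point_ellipse_distance(te, pts)
    assert (d <= 2.0).mean() >= 0.90
    assert d.max() <= 3.0


def test_specular_spot_masked_out(rendered_fixture):
    _, rig, fix = rendered_fixture
    out = render_fixation(fix, rig, AppearanceConfig(specular_spot=True),
                          seed=0)
    frame, truth = out["L1"]
    det = detect_eye_features(frame, seed=0)
    te = truth["pupil_ellipse"]
    assert np.hypot(det.ellipse.x0 - te.x0, det.ellipse.y0 - te.y0) < 1.0


def test_feature_out_of_frustum_rejected():
    sc = RigScenario(corner_left=(500.0, 3, 74), corner_right=(528.0, 3, 74),
                     law_left=RigScenario().law_left,
                     law_right=RigScenario().law_right)
    sim = simulate_session(sc, seed=0)
    with pytest.raises(ScenarioError):
        render_fixation(sim.placements[0].fixations[0], default_rig(),
                        AppearanceConfig(), seed=0)


def test_reconstruction_error_does_not_shrink_with_more_pixel_noise(
        rendered_fixture):
    """Doubling pixel noise must not reduce the pupil reconstruction error
    (fixed seeds)."""
    _, rig, fix = rendered_fixture
    errs = []
    for sigma in (1.0, 4.0):
        per = []
        for seed in (0, 1, 2):
            out = render_fixation(fix, rig,
                                  AppearanceConfig(noise_sigma=sigma),
                                  seed=seed)
            frames = {cid: f for cid, (f, _) in out.items()}
            fs = extract_feature_set(frames, rig, seed=0)
            per.append(np.linalg.norm(fs.pupil_left - fix.exact.pupil_left))
        errs.append(np.median(per))
    assert errs[1] >= 0.5 * errs[0]


def test_closed_loop_detect_reconstruct_calibrate_estimate():
    """End-to-end run on rendered images: feature reconstruction is tight;
    the PoR inherits the calibration-search floor (lateral ≪ depth error,
    both bounded by the geometry analysis)."""
    sc = RigScenario(test_distances=(800.0,), n_test_per_distance=2)
    sim = simulate_session(sc, seed=3)
    rig = default_rig()

    def features_of(fix):
        frames = {cid: f for cid, (f, _) in
                  render_fixation(fix, rig, AppearanceConfig(), seed=0).items()}
        return extract_feature_set(frames, rig, seed=0)

    placements = []
    recon_errs = []
    for p in sim.placements:
        feats = []
        for fix in p.fixations:
            fs = features_of(fix)
            recon_errs.append(np.linalg.norm(fs.pupil_left
                                             - fix.exact.pupil_left))
            feats.append(fs)
        placements.append(feats)
    assert max(recon_errs) < 0.3       # mm: stereo reconstruction is tight

    est = GazePointEstimator().fit(placements)
    pred = est.predict([features_of(f) for f in sim.tests])
    err = np.abs(pred - np.stack([f.target for f in sim.tests]))
    # lateral errors stay small; depth carries the vergence amplification
    assert err[:, 0].max() < 200.0
    assert err[:, 1].max() < 200.0
    assert err[:, 2].max() < 4000.0
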