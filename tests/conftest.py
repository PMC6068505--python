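import numpy as np
import pytest

from gaze3d.stereo_reconstruction import EyeFeatureSet
from gaze3d.synthetic_rig import RigScenario, simulate_session


@pytest.fixture(scope="session")
def default_session():
    """One noiseless default calibration session shared across tests."""
    return simulate_session(RigScenario(), seed=1)


@pytest.fixture(scope="session")
def noisy_session():
    return simulate_session(RigScenario(feature_noise=0.05), seed=2)


def make_exact_placement(conv_left, conv_right, board_center_x=39.0,
                         board_z=-700.0, spacing=150.0, offset=10.0):
    """Placement whose planted pair coincides exactly with the search's
    initial guess (mean pupil center + offset on Z).

    Pupil centers lie on the convergence→target segments with per-fixation
    distances r_i chosen so that Σ r_i u_i = −4·offset·ẑ.
    """
    conv_left = np.asarray(conv_left, dtype=float)
    conv_right = np.asarray(conv_right, dtype=float)
    half = spacing / 2.0
    targets = [np.array([board_center_x + ox, oy, board_z])
               for ox, oy in ((-half, -half), (half, -half),
                              (half, half), (-half, half))]

    def pupils_for(conv):
        U = np.stack([(t - conv) / np.linalg.norm(t - conv) for t in targets])
        A = U.T
        goal = np.array([0.0, 0.0, -4.0 * offset])
        r0 = np.full(4, offset)
        r = r0 + A.T @ np.linalg.solve(A @ A.T, goal - A @ r0)
        assert (r > 0).all()
        return conv + U * r[:, None]

    pl = pupils_for(conv_left)
    pr = pupils_for(conv_right)
    feats = [EyeFeatureSet(pupil_left=pl[i], pupil_right=pr[i],
                           size_left=3.0, size_right=3.0,
                           corner_left=(24.0, 3.0, 74.0),
                           corner_right=(52.0, 3.0, 74.0), fixation=i + 1)
             for i in range(4)]
    return feats, targets
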