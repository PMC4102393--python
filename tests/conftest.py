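import numpy as np
import pytest

from nemaswim.geometry import Centerline, CurvatureMap, SEGMENT_MIDPOINTS


def make_wave_map(
    f=1.5, n=1.5, A=3.0, fps=18.0, T=540, bias=0.0, alpha=0.0, L=100.0
) -> CurvatureMap:
    """Closed-form traveling-wave kymograph (plateau-ramp envelope)."""
    t = np.arange(T) / fps
    s = SEGMENT_MIDPOINTS
    g = np.clip((0.75 - s) / 0.5, 0.0, 1.0)
    env = 1.0 - alpha * g
    vals = A * env[:, None] * np.sin(2 * np.pi * (n * s[:, None] + f * t[None, :])) + bias
    return CurvatureMap(vals, fps, np.ones(T, bool), np.full(T, L))


def circle_centerline(R=50.0, L=100.0, n_pts=200, center=(0.0, 0.0)) -> Centerline:
    """Worm of arc length L lying on a circle of radius R."""
    theta = np.linspace(0.0, L / R, n_pts)
    pts = np.column_stack(
        [center[0] + R * np.cos(theta), center[1] + R * np.sin(theta)]
    )
    return Centerline(pts, np.full(n_pts, 2.0))


def sinusoid_centerline(alpha=0.5, L=100.0, n_pts=400) -> Centerline:
    """Centerline with tangent angle theta(s) = alpha * sin(2*pi*s)."""
    s = np.linspace(0.0, 1.0, n_pts)
    th = alpha * np.sin(2 * np.pi * s)
    x = np.concatenate([[0], np.cumsum(np.cos(th[:-1]) * np.diff(s) * L)])
    y = np.concatenate([[0], np.cumsum(np.sin(th[:-1]) * np.diff(s) * L)])
    return Centerline(np.column_stack([x, y]), np.full(n_pts, 2.0))


@pytest.fixture(scope="session")
def default_scenario_fit():
    """Fitted results for the default synthetic swimmer (shared, read-only)."""
    from nemaswim.synthgen import SwimScenario
    from nemaswim.trial import SwimTrial

    scn = SwimScenario(seed=1, drift_v=0.1, reverse_episodes=((216, 324),))
    res = SwimTrial.from_scenario(scn).fit()
    return scn, res
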