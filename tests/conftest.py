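import numpy as np
import pandas as pd
import pytest

from fixdur import SceneImage, compute_feature_maps
from fixdur.feature_maps import FeatureMapConfig


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def mixed_scene():
    from fixdur.synthetic import make_scene

    return make_scene(seed=7, size=(96, 128), px_per_deg=5.0, texture_spec="mixed")


@pytest.fixture(scope="session")
def mixed_maps(mixed_scene):
    return compute_feature_maps(
        mixed_scene, FeatureMapConfig(ms_spatial_bandwidth=5, ms_max_iter=5)
    )


@pytest.fixture(scope="session")
def quadrant_scene():
    """Four well-separated solid-color quadrants."""
    img = np.zeros((40, 40, 3), dtype=np.uint8)
    img[:20, :20] = (255, 0, 0)
    img[:20, 20:] = (0, 255, 0)
    img[20:, :20] = (0, 0, 255)
    img[20:, 20:] = (255, 255, 0)
    return SceneImage(pixels=img, px_per_deg=5.0, scene_id="quadrants")


def make_trial(
    xy,
    durations=None,
    subject="s01",
    scene="scene01",
    task="memorization",
    trial=1,
    blink=None,
    onset_step=280.0,
    features=True,
):
    """Helper: build a fixation table for one trial from (x, y) pairs."""
    k = len(xy)
    durations = durations if durations is not None else [250.0] * k
    onsets = np.cumsum([0.0] + [d + 30.0 for d in durations[:-1]])
    df = pd.DataFrame(
        {
            "subject_id": subject,
            "scene_id": scene,
            "task": task,
            "trial_index": trial,
            "fixation_index": np.arange(1, k + 1),
            "x": [p[0] for p in xy],
            "y": [p[1] for p in xy],
            "duration_ms": durations,
            "onset_ms": onsets,
            "blink": blink if blink is not None else [False] * k,
            "response_time_ms": np.nan,
        }
    )
    if features:
        rs = np.random.default_rng(hash((subject, scene, trial)) % (2**31))
        df["luminance"] = rs.uniform(0.2, 0.8, k)
        df["contrast"] = rs.uniform(0.1, 1.0, k)
        df["edge_density"] = rs.normal(-1.3, 0.3, k)
        df["clutter"] = rs.uniform(0.1, 0.9, k)
        df["n_segments"] = rs.integers(1, 9, k).astype(float)
    return df
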