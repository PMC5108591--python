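import numpy as np
import pytest

from myoquant import SceneParams, generate_scene


def rasterize_disk(radius: int, pad: int = 4) -> np.ndarray:
    n = 2 * radius + 2 * pad
    yy, xx = np.mgrid[:n, :n]
    c = n / 2.0
    return (yy - c) ** 2 + (xx - c) ** 2 <= radius**2


@pytest.fixture(scope="session")
def clean_scene():
    """A noiseless, artifact-free mononucleated scene (exact truth)."""
    params = SceneParams(
        n_cells=50, myotube_fraction=0.0, background_amplitude=0.0,
        speckle_density=0.0, noise_sd=0.0, seed=42,
    )
    return generate_scene(params)


@pytest.fixture(scope="session")
def noisy_scene():
    """A mixed myoblast/myotube scene with background, speckles and noise."""
    params = SceneParams(
        n_cells=80, myotube_fraction=0.15, marker_probs={"myhc": 0.1},
        background_amplitude=0.3, speckle_density=5.0, seed=7,
    )
    return generate_scene(params)
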