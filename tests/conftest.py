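import numpy as np
import pytest

import woundspeed as ws


def rasterized_disk(r: int, margin: int = 20) -> np.ndarray:
    """Boolean disk mask of radius r centred in a square image."""
    from skimage import draw

    n = 2 * r + 2 * margin
    mask = np.zeros((n, n), bool)
    rr, cc = draw.disk(((n - 1) / 2, (n - 1) / 2), r, shape=mask.shape)
    mask[rr, cc] = True
    return mask


@pytest.fixture(scope="session")
def disk_spec() -> ws.SyntheticWoundSpec:
    """Standard shrinking-disk fixture: r0=100 px, v=5 px/h, 16 frames at
    1 h interval, 1% intensity noise."""
    return ws.SyntheticWoundSpec(
        shape="disk", size=(100.0,), velocity=5.0, dt=1.0, n_frames=16, seed=3
    )


@pytest.fixture(scope="session")
def disk_sequence(disk_spec):
    return ws.generate_sequence(disk_spec)


@pytest.fixture(scope="session")
def synthetic_config() -> ws.RunConfig:
    """Pipeline configuration matched to the texture-free fixtures."""
    return ws.RunConfig(params=ws.DetectionParams.for_synthetic(), seed=1)


@pytest.fixture(scope="session")
def disk_result(disk_sequence, synthetic_config):
    """End-to-end analysis of the standard disk fixture (shared: expensive)."""
    seq, truth = disk_sequence
    return ws.run_sequence(seq, synthetic_config), truth
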