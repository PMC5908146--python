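import numpy as np
import pytest

from pachymap.io import load_chromosome_records, load_marker_records
from pachymap.simulate import SyntheticSpec, make_image


@pytest.fixture(scope="session")
def records():
    return load_chromosome_records()


@pytest.fixture(scope="session")
def markers():
    return load_marker_records()


@pytest.fixture(scope="session")
def curved_image():
    """One curved synthetic chromosome with FISH channels, moderate noise."""
    L = 30.0
    spec = SyntheticSpec(
        length_um=L,
        chromomere_positions_um=list(np.linspace(1.0, L - 1.0, 20)),
        centromere_um=0.4 * L,
        fish_spots={"probe": [(0.25 * L, 200.0)],
                    "pericent": [(0.4 * L, 150.0)]},
        noise_sd=5.0,
        seed=2,
        axis={"kind": "sinusoid", "amplitude_um": 2.5, "period_um": 12.0},
    )
    img, truth = make_image(spec)
    return img, truth
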