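import numpy as np
import pandas as pd
import pytest

from xenospot.simulate import CohortDesign, FragmentModel, simulate_fragments


@pytest.fixture(scope="session")
def default_pairs():
    """A mid-size mixed sample with truth labels, shared across tests."""
    pairs, manifest = simulate_fragments(50_000, true_xtf=0.3, seed=11)
    return pairs, manifest


@pytest.fixture
def fragment_frame():
    """Tiny hand-built classified fragment table."""
    return pd.DataFrame(
        {
            "fragment_id": [f"f{i}" for i in range(6)],
            "category": [
                "human_specific",
                "human_specific",
                "mouse_specific",
                "mouse_specific",
                "unresolved",
                "unmapped",
            ],
            "chromosome": ["hchr1", "hchr1", "mchr1", "mchr2", None, None],
            "start": [100.0, 5000.0, 200.0, 300.0, np.nan, np.nan],
            "end": [250.0, 5160.0, 360.0, 460.0, np.nan, np.nan],
            "fragment_length": [150.0, 160.0, 160.0, 160.0, np.nan, np.nan],
        }
    )


@pytest.fixture
def noiseless_design():
    return CohortDesign(tau=0.0, sigma_treated=0.0, sigma_control=0.0, xtf_noise_sd=0.0, seed=7)
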