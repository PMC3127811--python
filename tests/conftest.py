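import numpy as np
import pandas as pd
import pytest

from mitonet.synthworld import WorldConfig, generate_world


def make_links(rows):
    """Build a link table from (a, b, confidence, channel) tuples."""
    return pd.DataFrame(rows, columns=["protein_a", "protein_b", "confidence", "channel"])


@pytest.fixture(scope="session")
def small_world():
    """A compact synthetic study shared by read-only tests."""
    return generate_world(
        WorldConfig(
            seed=7,
            n_up_modules=2,
            n_down_modules=3,
            module_size=12,
            n_background=60,
            n_contaminants=25,
        )
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
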