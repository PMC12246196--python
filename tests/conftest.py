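import numpy as np
import pandas as pd
import pytest

from glycoscreen import pipeline
from glycoscreen.synth import SynthConfig, make_demo_screen


@pytest.fixture(scope="session")
def demo():
    """A small complete synthetic screen: 20 compounds, 1 pool, 2 enzymes."""
    return make_demo_screen(SynthConfig(seed=11, n_compounds=20), n_enzymes=2)


@pytest.fixture(scope="session")
def screened(demo):
    """Pipeline output on the demo screen: (calls, reports, matches_df)."""
    manifest = pd.DataFrame(demo["manifest_rows"])
    by_id = {c.compound_id: c for c in demo["compounds"]}
    return pipeline.screen(
        demo["runs"], manifest, demo["pools"], by_id, demo["library"]
    )


def random_spectrum(rng: np.random.Generator, n_peaks: int, mz_range=(50.0, 500.0)):
    """A random peak list (sorted m/z, positive intensities)."""
    mz = np.sort(rng.uniform(*mz_range, size=n_peaks))
    intensity = rng.uniform(0.01, 1.0, size=n_peaks)
    return mz, intensity
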