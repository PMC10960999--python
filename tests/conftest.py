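import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import ricelwc as rl
from ricelwc.records import SpectraCollection

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def campaign():
    """One default synthetic campaign shared by read-only tests."""
    return rl.simulate_campaign(rl.SimulationDesign(seed=11))


@pytest.fixture(scope="session")
def campaign_index(campaign):
    """Index table joined to the derived observations of the campaign."""
    idx = rl.index_table(campaign.spectra, nd_pair=tuple(campaign.truth["planted_pair"]))
    return idx.merge(campaign.observations,
                     on=["plot_id", "year", "site", "cultivar", "treatment", "stage"])


def make_random_collection(n_samples, wavelengths, seed=0, low=0.05, high=0.6):
    """Small random spectra fixture on an arbitrary integer grid."""
    rng = np.random.default_rng(seed)
    wavelengths = np.asarray(wavelengths)
    meta = pd.DataFrame({
        "plot_id": [f"p{i}" for i in range(n_samples)],
        "year": 2022, "site": "S1", "cultivar": "C1",
        "treatment": "CK", "stage": "flowering", "n_scans": 1})
    refl = rng.uniform(low, high, (n_samples, wavelengths.size))
    return SpectraCollection(meta, refl, wavelengths)
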