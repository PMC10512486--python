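import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from astroquant import (
    SegmentationParams,
    generate_field,
    populate_field,
)
from astroquant.deconv import SignatureMatrix


@pytest.fixture(scope="session")
def small_field():
    """Noiseless mixed field of 2 stellate + 2 flat cells with truth."""
    specs = populate_field({"stellate": 2, "flat": 2}, (512, 512), seed=11)
    return generate_field(specs, (512, 512), noise_sd=0.0, seed=12)


@pytest.fixture(scope="session")
def recovery_params():
    """Segmentation settings used for synthetic recovery experiments.

    Half-range fixed threshold on the Vimentin channel (background 100,
    plateau 3000) and sigma 1 so that 3-px processes survive smoothing.
    """
    return SegmentationParams(
        smoothing_sigma_px=1.0,
        threshold_mode="fixed",
        fixed_threshold=1550.0,
    )


@pytest.fixture(scope="session")
def toy_signature():
    """Four well-separated cell-type profiles over 60 genes, columns sum 1."""
    rng = np.random.default_rng(42)
    genes = [f"g{i}" for i in range(60)]
    profile = rng.lognormal(0.0, 1.0, size=(60, 4))
    profile /= profile.sum(axis=0)
    mean = pd.DataFrame(profile, index=genes,
                        columns=["astro", "neuron", "oligo", "microglia"])
    return SignatureMatrix(mean_profile=mean)
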