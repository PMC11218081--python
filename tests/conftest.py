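import numpy as np
import pandas as pd
import pytest

import fgtmicro as fg


@pytest.fixture
def small_counts():
    """4 taxa x 3 samples with hand-checkable values."""
    return fg.CountTable(
        ["Otu001", "Otu002", "Otu003", "Otu004"],
        ["s1", "s2", "s3"],
        np.array([[3, 0, 10], [1, 0, 10], [0, 5, 0], [0, 5, 0]]),
    )


@pytest.fixture
def small_meta():
    return pd.DataFrame(
        {
            "sample_id": ["s1", "s2", "s3"],
            "patient_id": ["p1", "p1", "p2"],
            "site": ["higher_vagina", "endometrium_higher", "higher_vagina"],
            "group": ["benign", "benign", "cancer"],
            "control_type": ["none", "none", "none"],
            "material": ["swab", "tissue", "swab"],
        }
    )


@pytest.fixture(scope="session")
def default_dataset():
    """One simulated study at the default conditions, shared across tests."""
    return fg.simulate_dataset(8, 8, seed=42, controls_per_type=2)


@pytest.fixture(scope="session")
def decontam_dataset():
    """40 true samples + 8 pooled controls, the contaminant-recovery design."""
    return fg.simulate_dataset(
        5,
        5,
        seed=7,
        controls_per_type=2,
        sites=("lower_vagina", "cervix", "endometrium_lower", "rectum"),
    )


@pytest.fixture(scope="session")
def perfect_curve():
    """Noiseless 100%-efficiency standard curve."""
    std = fg.make_standard_series()
    return fg.fit_standard_curve(std["copies"], std["ct"])
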