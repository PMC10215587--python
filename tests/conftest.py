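import numpy as np
import pytest

from gamcross.simulate import (
    CrossDesign,
    TraitParameters,
    TrueParameters,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def small_dataset():
    """A reduced reciprocal cross shared across read-only tests."""
    design = CrossDesign(
        n_sires_E=8,
        n_dams_E=16,
        n_sires_R=8,
        n_dams_R=20,
        n_er_sows=40,
        n_re_sows=40,
    )
    return simulate_dataset(
        n_founders_E=24, n_founders_R=24, n_snp=300, design=design, seed=42
    )


@pytest.fixture
def rng():
    return np.random.default_rng(7)


def table4_params(r_E: float = 0.5, r_R: float = 0.5) -> TrueParameters:
    """Generating parameters at the litter-size magnitudes of the study."""
    cE = r_E * np.sqrt(0.206 * 0.197)
    cR = r_R * np.sqrt(0.224 * 0.163)
    tp = TraitParameters(
        V_E=np.array([[0.206, cE], [cE, 0.197]]),
        V_R=np.array([[0.224, cR], [cR, 0.163]]),
    )
    return TrueParameters(tnb=tp, nba=tp)
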