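import numpy as np
import pandas as pd
import pytest

from apicomp.simulate import StudyConfig, generate_study


def small_config(seed: int = 11, **overrides) -> StudyConfig:
    """A scaled-down study (4 queens per cell, modest depths) for fast tests."""
    cfg = StudyConfig(
        n_queens_per_cell={("young", "CA"): 4, ("old", "CA"): 4,
                           ("young", "AZ"): 4, ("old", "AZ"): 4},
        depth_mean={n: 2000.0 for n in ("mouth", "midgut", "ileum", "rectum")},
        n_rare_otus=12,
        seed=seed,
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


@pytest.fixture(scope="session")
def small_study():
    return generate_study(small_config())


@pytest.fixture(scope="session")
def default_study():
    """The full 63-queen x 4-niche synthetic study at the design defaults."""
    return generate_study(StudyConfig(seed=1))


@pytest.fixture
def tiny_counts():
    return pd.DataFrame(
        [[10, 5, 0], [3, 0, 7]],
        index=pd.Index(["s1", "s2"], name="sample_id"),
        columns=["otuA", "otuB", "otuC"],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)
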