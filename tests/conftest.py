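import numpy as np
import pytest

import metastrat as ms


@pytest.fixture
def tiny_table() -> ms.PeakTable:
    """3 features x 4 samples, fully observed."""
    return ms.PeakTable(
        mz=[100.0, 200.0, 300.0],
        rt=[10.0, 20.0, 30.0],
        intensities=np.array([
            [1.0, 2.0, 3.0, 4.0],
            [5.0, 6.0, 7.0, 8.0],
            [9.0, 10.0, 11.0, 12.0],
        ]),
        sample_ids=["s1", "s2", "s3", "s4"],
        groups=["case", "case", "control", "control"],
        experiments=["E1", "E1", "E1", "E1"],
    )


@pytest.fixture(scope="session")
def default_pair():
    """Session-wide generated pair with the shipped defaults (seed 1)."""
    cfg = ms.SyntheticConfig(seed=1)
    a, b, lib, gt = ms.generate_pair(cfg)
    return cfg, a, b, lib, gt


@pytest.fixture(scope="session")
def small_pair():
    """A cheaper pair for pipeline-level tests."""
    cfg = ms.SyntheticConfig(
        n_features_shared=80, n_features_unique=10, n_case=20, n_control=20,
        n_true_markers=10, effect_size=1.5, seed=7,
    )
    a, b, lib, gt = ms.generate_pair(cfg)
    return cfg, a, b, lib, gt
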