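import numpy as np
import pytest

import silobayes as sb


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture()
def tiny_table():
    """3 taxa x 2 samples, one grain, hand-written counts."""
    meta = {
        "s1": sb.SampleMeta("s1", "corn", "CTRL", 0, 1),
        "s2": sb.SampleMeta("s2", "corn", "Inoc1", 0, 1),
    }
    records = [
        ("otuA", "s1", 5), ("otuA", "s2", 3),
        ("otuB", "s1", 0), ("otuB", "s2", 7),
        ("otuC", "s1", 2), ("otuC", "s2", 2),
    ]
    return sb.CountTable(records=records, metadata=meta)


@pytest.fixture(scope="session")
def full_grid_table():
    """Balanced 6-taxa x 3-inoculant x 6-period x 3-replicate dataset."""
    b = np.concatenate([[1.6], [0.3, 0.2, -0.2, 0.1, -0.1], [-0.2, -0.15]])
    truth = sb.TruthRecord(
        b_true=b, sigma2_true={"u1": 1.0, "e": 0.25}, family="poisson", seed=77
    )
    table, truth = sb.simulate_dataset(6, 3, truth)
    return table, truth


@pytest.fixture(scope="session")
def fitted_chain(full_grid_table):
    """One moderately long Poisson fit shared by diagnostics/summary tests."""
    table, _ = full_grid_table
    spec = sb.ModelSpec(
        family="poisson", include_blocks=("u1",), hyper={"e": (0.001, 0.001)}
    )
    cfg = sb.SamplerConfig(iterations=12_000, burn_in=3_000, thin=5, seed=5)
    return sb.run_chain(table, spec, cfg)
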