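import numpy as np
import pandas as pd
import pytest

from cohescan.simulate import CohortConfig, SyntheticCohort


def random_intervals(rng, n, chroms=("chr1", "chr2"), max_pos=100_000, max_len=500):
    starts = rng.integers(0, max_pos, size=n)
    lengths = rng.integers(1, max_len, size=n)
    return pd.DataFrame(
        {
            "chrom": rng.choice(chroms, size=n),
            "start": starts,
            "end": starts + lengths,
        }
    )


@pytest.fixture(scope="session")
def small_cohort() -> SyntheticCohort:
    """One small multi-tissue cohort shared by read-only tests."""
    cfg = CohortConfig(seed=42, n_sites=1500, n_tissues=2)
    return SyntheticCohort.generate(cfg, n_genes=2000)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
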