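import numpy as np
import pandas as pd
import pytest

from methylkin.io import SampleCallSet


def make_callset(records, sample_id="s1", group="control", cohort="custom"):
    """Build a SampleCallSet from (chrom, pos, strand, meth, cov) tuples."""
    df = pd.DataFrame(records, columns=["chrom", "pos", "strand", "meth", "cov"])
    return SampleCallSet.from_frame(sample_id, df, group=group, cohort=cohort)


def uniform_callset(rng, n_sites=200, chrom="chr1", cov=20, p=0.5,
                    sample_id="s1", group="control", spacing=30):
    """Random single-chromosome callset with binomial counts."""
    pos = np.cumsum(rng.integers(2, spacing, size=n_sites)) + 1
    covs = np.full(n_sites, cov)
    meth = rng.binomial(covs, p)
    records = [(chrom, int(pp), "+", int(m), int(c))
               for pp, m, c in zip(pos, meth, covs)]
    return make_callset(records, sample_id=sample_id, group=group)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def toy_sim():
    """Small shared simulation used by several module tests."""
    from methylkin.simulate import (SimulationConfig, simulate_annotation,
                                    simulate_methylomes)

    config = SimulationConfig(seed=5, n_chroms=1, chrom_length=250_000,
                              n_planted=25, delta_min=25, delta_max=35)
    annotation, truth = simulate_annotation(config)
    methylomes = simulate_methylomes(annotation, truth, config)
    return {"config": config, "annotation": annotation, "truth": truth,
            "methylomes": methylomes}
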