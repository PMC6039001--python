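import numpy as np
import pytest

from helixenv import alignment, datamarts, synthetic


@pytest.fixture(scope="session")
def signal_cohort():
    """30 single-helix chains, L=12, inside effect 1 SD, 5 descriptors."""
    config = synthetic.SyntheticConfig(
        n_chains=30, helix_length=12, inside_effect=1.0,
        n_descriptors=5, seed=42)
    records, table = synthetic.generate_cohort(config)
    return config, records, table


@pytest.fixture(scope="session")
def signal_ensemble(signal_cohort):
    config, records, table = signal_cohort
    marts = datamarts.build_datamarts(records)
    instances = marts["DM"].instances_of_length(config.helix_length)
    return alignment.align_ensemble(
        instances, {r.chain_id: r for r in records}, table)


@pytest.fixture(scope="session")
def null_cohort():
    """Zero-effect cohort for null-distribution checks."""
    config = synthetic.SyntheticConfig(
        n_chains=25, helix_length=12, inside_effect=0.0,
        n_descriptors=4, seed=7)
    records, table = synthetic.generate_cohort(config)
    return config, records, table


@pytest.fixture
def rng():
    return np.random.default_rng(0)
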