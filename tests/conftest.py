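import pytest

from mppme import QtlTruth, SimConfig, simulate_experiment


@pytest.fixture(scope="session")
def small_experiment():
    """A small NAM experiment with one strong environment-specific QTL on
    chromosome 1 at 40 cM (effect only in the second environment)."""
    cfg = SimConfig(
        n_parents=4,
        cross_sizes=50,
        n_chromosomes=2,
        chrom_length_cM=80.0,
        marker_density=0.2,
        n_environments=2,
        qtls=[
            QtlTruth(
                1, 40.0,
                effects={"P1": [0.0, 8.0], "P2": [0.0, 8.0], "P3": [0.0, 8.0]},
            )
        ],
        seed=11,
    )
    return simulate_experiment(cfg)
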