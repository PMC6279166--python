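import pytest

from supergene.simulate import DeletionPlan, SimulatorConfig


@pytest.fixture(scope="session")
def tiny_config():
    """Small, fast scenario used by several module tests."""
    return SimulatorConfig(
        n_genes=12,
        gene_length=80,
        n_samples_a=4,
        n_samples_b=4,
        cluster_genes=10,
        deletion_plan=(DeletionPlan(4, 2, "B", 1.0),),
        n_ct_samples=6,
        seed=42,
    )


@pytest.fixture(scope="session")
def study_scale_config():
    """The full study-scale scenario (331 genes x 390 codons)."""
    return SimulatorConfig(seed=20240101 % (2**31))
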