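import numpy as np
import pytest

from tmbsubtype.io_cohort import MutationRecord, VariantClass
from tmbsubtype.synthetic import SimulationParams, generate_cohort


def tiny_params(**overrides) -> SimulationParams:
    """Small, fast cohort parameters for unit tests."""
    defaults = dict(
        n_samples=12,
        tmb_low_logmu=3.0,
        tmb_high_logmu=4.5,
        n_background_genes=40,
    )
    defaults.update(overrides)
    return SimulationParams(**defaults)


@pytest.fixture(scope="session")
def default_cohort():
    """One default-parameter cohort shared by read-only tests."""
    return generate_cohort(seed=424242)


@pytest.fixture(scope="session")
def tiny_cohort():
    return generate_cohort(tiny_params(), seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


def snv(sample="S1", gene="G1", pos=100, ref="C", alt="T",
        vclass=VariantClass.MISSENSE, context=None):
    return MutationRecord(
        sample_id=sample, gene=gene, chrom="chr1", pos=pos, ref=ref, alt=alt,
        variant_class=vclass, context=context,
    )
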