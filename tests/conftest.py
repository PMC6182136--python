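import pytest

from transposim.model_core import (
    Architecture,
    ArchetypeName,
    GenomeContext,
    MutantSpec,
    RateConstants,
)
from transposim.synthetic_data import make_archetype_params


@pytest.fixture
def plasmid_genome() -> GenomeContext:
    """The in-vitro-like context: 4 kb substrate, 1 fL reference volume."""
    return GenomeContext(genome_length_bp=4000)


@pytest.fixture
def simple_rates() -> RateConstants:
    """Small, fast network without non-specific binding."""
    return RateConstants(k_bind=1e7, k_unbind=0.05, k_synapsis=0.5, k_post=0.1)


@pytest.fixture
def hsmar1_rates() -> RateConstants:
    return make_archetype_params(ArchetypeName.HSMAR1)


@pytest.fixture
def tn5_rates() -> RateConstants:
    return make_archetype_params(ArchetypeName.TN5_SCD)


@pytest.fixture
def scd_wt() -> MutantSpec:
    return MutantSpec.wild_type(Architecture.SINGLE_CHAIN_DIMER)


@pytest.fixture
def monomer_wt() -> MutantSpec:
    return MutantSpec.wild_type(Architecture.MONOMER)
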