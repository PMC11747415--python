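import pytest

from synchrom.design_rules import DesignPolicy
from synchrom.fixtures import FixtureSpec, make_mini_chromosome
from synchrom.genome_model import ChromosomeAnnotation, OrfFeature
from synchrom.pipeline import design_chromosome


@pytest.fixture(scope="session")
def v1_policy():
    return DesignPolicy.v1()


@pytest.fixture(scope="session")
def v2_policy():
    return DesignPolicy.v2()


@pytest.fixture(scope="session")
def mini():
    """Default 60 kb mini-chromosome with ground truth."""
    return make_mini_chromosome(FixtureSpec(seed=1))


@pytest.fixture(scope="session")
def mini_v1(mini, v1_policy):
    return design_chromosome(mini[0], v1_policy)


@pytest.fixture(scope="session")
def mini_v2(mini, v2_policy):
    return design_chromosome(mini[0], v2_policy)


def toy_annotation(sequence: str, orfs=(), **kwargs) -> ChromosomeAnnotation:
    return ChromosomeAnnotation(name="toy", sequence=sequence,
                                orfs=list(orfs), **kwargs)


def plus_orf(orf_id: str, start: int, cds: str, **kwargs) -> OrfFeature:
    return OrfFeature(id=orf_id, strand="+",
                      exons=((start, start + len(cds)),), **kwargs)
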