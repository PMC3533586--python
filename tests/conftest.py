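import pytest

from ontosim.fixtures import FixtureSpec, random_dag, toy_T0
from ontosim.graph import build_taxonomy
from ontosim.ic import intrinsic_ic


@pytest.fixture(scope="session")
def t0():
    return build_taxonomy(toy_T0())


@pytest.fixture(scope="session")
def t0_ic(t0):
    return intrinsic_ic(t0)


def make_taxonomy(seed, n_concepts=20, max_parents=3, p_extra_edge=0.0):
    return build_taxonomy(
        random_dag(
            FixtureSpec(
                seed=seed,
                n_concepts=n_concepts,
                max_parents=max_parents,
                p_extra_edge=p_extra_edge,
            )
        )
    )


@pytest.fixture(scope="session")
def random_taxonomies():
    """A handful of seeded DAG taxonomies reused across property tests."""
    return [make_taxonomy(seed, n_concepts=5 + 3 * seed) for seed in range(1, 11)]
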