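import numpy as np
import pytest

from oads.ontology import OntologyDAG, OntologyTerm
from oads.synthgen import SyntheticScenario, gen_annotations, gen_ontology


@pytest.fixture(scope="session")
def chain_dag():
    """Three-term is_a chain R <- A <- B with factor 0.8."""
    return OntologyDAG(
        [
            OntologyTerm("R"),
            OntologyTerm("A", parents=[("R", "is_a")]),
            OntologyTerm("B", parents=[("A", "is_a")]),
        ]
    )


@pytest.fixture(scope="session")
def sibling_dag():
    """Siblings A, B under root R with factor 0.8."""
    return OntologyDAG(
        [
            OntologyTerm("R"),
            OntologyTerm("A", parents=[("R", "is_a")]),
            OntologyTerm("B", parents=[("R", "is_a")]),
        ]
    )


@pytest.fixture(scope="session")
def random_dag():
    """Medium synthetic single-rooted DAG for property sampling."""
    return gen_ontology(150, max_parents=2, seed=7)


@pytest.fixture(scope="session")
def default_scenario():
    """The default planted-community scenario used end to end."""
    return SyntheticScenario(seed=3)


@pytest.fixture(scope="session")
def default_scenario_data(default_scenario):
    """Profiles, planted community labels, and ontology for the default scenario."""
    profiles, planted, dag = gen_annotations(default_scenario)
    return profiles, planted, dag


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
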