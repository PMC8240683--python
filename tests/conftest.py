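import pytest

from commfit import fitness
from commfit.graph_store import graph_from_edges
from commfit.synthetic import PlantedSpec, make_clique_toy, make_labeled_fixture


@pytest.fixture()
def toy():
    """Ten disjoint unit-weight cliques, sizes 3-8."""
    return make_clique_toy(10, [3, 4, 5, 6, 7, 8, 3, 4, 5, 6])


@pytest.fixture()
def triangle_graph():
    return graph_from_edges([("a", "b", 1.0), ("b", "c", 1.0), ("a", "c", 1.0)])


@pytest.fixture(scope="session")
def planted():
    """Planted benchmark run through prep + features, with a trained model."""
    graph, train, test, split = make_labeled_fixture(PlantedSpec(rng_seed=0))
    model = fitness.train_model(train, rng_seed=0)
    return {"graph": graph, "train": train, "test": test, "split": split, "model": model}
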