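import networkx as nx
import pytest

from salign.ontology_eval import AnnotationSet, GoDag
from salign.synthetic import make_bundle


@pytest.fixture(scope="session")
def noisy_bundle():
    """Medium synthetic study at the generator defaults (rewire 0.1, sd 0.25)."""
    return make_bundle(n_nodes=80, seed=11)


@pytest.fixture(scope="session")
def clean_bundle():
    """Perturbation-free study: rewire 0, noiseless similarity."""
    return make_bundle(n_nodes=80, rewire_fraction=0.0, noise_sd=0.0, seed=12)


@pytest.fixture()
def toy_dag():
    """Hand-built DAG: root <- x <- {a, b} over is_a, plus an unrelated island."""
    terms = {"GO:0000001", "GO:0000002", "GO:0000003", "GO:0000004", "GO:0000009"}
    parents = {
        "GO:0000002": {("GO:0000001", "is_a")},  # x -> root
        "GO:0000003": {("GO:0000002", "is_a")},  # a -> x
        "GO:0000004": {("GO:0000002", "is_a")},  # b -> x
    }
    namespace = {t: "MF" for t in terms}
    dag = GoDag(terms=terms, parents=parents, namespace=namespace)
    dag.validate()
    return dag


@pytest.fixture()
def path_graph():
    g = nx.Graph(name="path")
    g.add_edges_from([("a", "b"), ("b", "c")])
    return g


@pytest.fixture()
def star_graph():
    """K1,4 whose leaves sort lexicographically before the hub."""
    g = nx.Graph(name="star")
    g.add_edges_from([("h", leaf) for leaf in "abcd"])
    return g


@pytest.fixture()
def identical_annotations():
    shared = {"MF": {"GO:0000003"}, "BP": set()}
    ann1 = AnnotationSet(annotations={"u1": {k: set(v) for k, v in shared.items()}})
    ann2 = AnnotationSet(annotations={"v1": {k: set(v) for k, v in shared.items()}})
    return ann1, ann2
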