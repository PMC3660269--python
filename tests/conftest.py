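import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from goslimpred.ontology_labels import GoDag


def make_dag(edges, slim=(), namespace="molecular_function"):
    """Build a GoDag from (child, parent) pairs; nodes inferred."""
    nodes = set()
    for c, p in edges:
        nodes.update((c, p))
    parents = {n: set() for n in nodes}
    for c, p in edges:
        parents[c].add(p)
    terms = {
        n: {"name": n, "namespace": namespace, "parents": frozenset(parents[n])}
        for n in sorted(nodes)
    }
    return GoDag(terms=terms, slim=frozenset(slim))


@pytest.fixture
def diamond_dag():
    """A -> root of a diamond: D has parents B and C, both under A."""
    return make_dag([("B", "A"), ("C", "A"), ("D", "B"), ("D", "C")])


@pytest.fixture
def chain_dag():
    return make_dag([("B", "A"), ("C", "B")])


@pytest.fixture
def rng():
    return np.random.default_rng(42)
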