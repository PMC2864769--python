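import random

import pytest

from eqannot import fixtures
from eqannot.ontology import Ontology


@pytest.fixture(scope="session")
def anatomy() -> Ontology:
    return fixtures.anatomy_ontology()


@pytest.fixture(scope="session")
def pato() -> Ontology:
    return fixtures.quality_ontology()


@pytest.fixture(scope="session")
def merged() -> Ontology:
    return fixtures.merged_ontology()


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20260923)


def bfs_ancestors(edges, start, relations):
    """Independent closure oracle: plain-dict breadth-first search over the
    subject->object adjacency restricted to the given relations."""
    adjacency = {}
    for s, p, o in edges:
        if p in relations:
            adjacency.setdefault(s, []).append(o)
    seen = set()
    frontier = [start]
    while frontier:
        node = frontier.pop()
        for nxt in adjacency.get(node, []):
            if nxt not in seen:
                seen.add(nxt)
                frontier.append(nxt)
    seen.discard(start)
    return seen
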