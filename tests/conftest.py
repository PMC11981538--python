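import pytest

from trophoweb import FoodWeb, NodeAttributes


def make_web(edges, categories=None, directed=True, biomass=None, body_mass=None,
             label="test"):
    """Build a FoodWeb from prey->predator edge pairs and optional attribute maps."""
    names = sorted({n for e in edges for n in e})
    categories = categories or {}
    biomass = biomass or {}
    body_mass = body_mass or {}
    nodes = [
        NodeAttributes(
            name=n,
            category=categories.get(n, "animal"),
            biomass=biomass.get(n),
            body_mass=body_mass.get(n),
        )
        for n in names
    ]
    return FoodWeb(nodes, edges, directed=directed, label=label)


@pytest.fixture
def chain_web():
    """basal -> herbivore -> predator."""
    return make_web(
        [("plant", "grazer"), ("grazer", "fish")],
        categories={"plant": "producer"},
    )


@pytest.fixture
def star_web():
    """Undirected star: centre linked to 4 leaves (N=5, L=4)."""
    return make_web(
        [("hub", f"leaf{i}") for i in range(4)],
        directed=False,
    )


@pytest.fixture
def triangle_web():
    return make_web([("a", "b"), ("b", "c"), ("a", "c")], directed=False)


@pytest.fixture
def path_web():
    """Undirected path a - b - c."""
    return make_web([("a", "b"), ("b", "c")], directed=False)
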