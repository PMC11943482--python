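import pytest

from flavopred import (
    MolecularGraph,
    fixture_operator_library,
    pathway_reaction_pairs,
)
from flavopred.vocab import assign_atom_types


def make_graph(elements, bonds, name=""):
    """Small helper: elements {idx: symbol}, bonds [(i, j, order)]."""
    g = MolecularGraph(name=name)
    for idx, el in elements.items():
        g.add_atom(el, index=idx)
    for i, j, order in bonds:
        g.add_bond(i, j, order)
    assign_atom_types(g)
    return g


def benzene():
    return make_graph(
        {i: "C" for i in range(1, 7)},
        [(i, i % 6 + 1, "aromatic") for i in range(1, 7)],
        name="benzene",
    )


@pytest.fixture(scope="session")
def pathway_pairs():
    return pathway_reaction_pairs()


@pytest.fixture(scope="session")
def full_library():
    return fixture_operator_library()
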