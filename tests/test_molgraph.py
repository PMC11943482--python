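"""Graph model, KCF/SMILES parsing, canonical keys and isomorphism."""

import pytest
from hypothesis import given, settings, strategies as st

from flavopred import (
    KCFParseError,
    MolecularGraph,
    SmilesParseError,
    brute_force_isomorphic,
    canonical_key,
    compound,
    graphs_isomorphic,
    parse_kcf,
    parse_linear,
    write_kcf,
)
from conftest import benzene, make_graph

BENZENE_KCF = """ENTRY       benzene
ATOM        6
            1   C.ar.h  C
            2   C.ar.h  C
            3   C.ar.h  C
            4   C.ar.h  C
            5   C.ar.h  C
            6   C.ar.h  C
BOND        6
            1   1 2 ar
            2   2 3 ar
            3   3 4 ar
            4   4 5 ar
            5   5 6 ar
            6   6 1 ar
///
"""


class TestKCF:
    def test_two_atom_record(self):
        g = parse_kcf("ATOM 2\n 1 O.oh O\n 2 C.sp3 C\nBOND 1\n 1 1 2 1\n///")
        assert g.n_atoms == 2 and g.n_bonds == 1
        assert g.atom_type(1) == "O.oh"  # labels preserved verbatim

    def test_benzene_record(self):
        g = parse_kcf(BENZENE_KCF)
        assert g.n_atoms == 6 and g.n_bonds == 6
        assert all(b.order == "aromatic" for b in g.bonds())
        assert graphs_isomorphic(g, benzene())

    @pytest.mark.parametrize(
        "name,g",
        [
            ("empty", MolecularGraph()),
            ("benzene", benzene()),
            ("naringenin", compound("naringenin")),
            ("two-frag", make_graph({1: "O", 2: "C"}, [])),
        ],
    )
    def test_round_trip(self, name, g):
        again = parse_kcf(write_kcf(g))
        assert graphs_isomorphic(g, again)
        assert canonical_key(g) == canonical_key(again)

    def test_empty_graph_record(self):
        text = write_kcf(MolecularGraph())
        assert "ATOM        0" in text and "BOND        0" in text

    @pytest.mark.parametrize(
        "text,fragment",
        [
            ("ATOM x\n///", "malformed ATOM header"),
            ("ATOM 1\n 1 C.sp3 C\n 2 C.sp3 C\nBOND 0\n///", "ATOM count"),
            ("ATOM 2\n 1 C.sp3 C\n 1 C.sp3 C\nBOND 0\n///", "duplicate atom index"),
            ("ATOM 1\n 1 C.sp3 C\nBOND 1\n 1 1 9 1\n///", "dangling bond"),
            ("ATOM 1\n 1 C.sp3 C\nBOND 2\n///", "BOND count"),
            ("BOND 0\n///", "missing ATOM block"),
        ],
    )
    def test_malformed_records_rejected(self, text, fragment):
        with pytest.raises(KCFParseError, match=fragment):
            parse_kcf(text)

    def test_count_mutations_rejected(self):
        # every count-breaking mutation of a valid record must fail
        base = BENZENE_KCF
        for bad in (
            base.replace("ATOM        6", "ATOM        5"),
            base.replace("ATOM        6", "ATOM        7"),
            base.replace("BOND        6", "BOND        5"),
        ):
            with pytest.raises(KCFParseError):
                parse_kcf(bad)


class TestSmiles:
    def test_water(self):
        g = parse_linear("O")
        assert g.n_atoms == 1 and g.implicit_h(1) == 2

    def test_benzene(self):
        g = parse_linear("c1ccccc1")
        assert g.n_atoms == 6 and g.n_bonds == 6
        assert {b.order for b in g.bonds()} == {"aromatic"}
        assert graphs_isomorphic(g, benzene())

    def test_naringenin_heavy_atom_count(self):
        assert compound("naringenin").n_atoms == 20

    def test_invalid_smiles(self):
        with pytest.raises(SmilesParseError):
            parse_linear("c1ccc")  # unclosed ring


class TestCanonicalKey:
    def test_permutation_invariance(self):
        g = compound("quercetin")
        n = g.n_atoms
        shifted = g.relabeled({i: (i % n) + 1 for i in g.atom_indices()})
        assert canonical_key(g) == canonical_key(shifted)

    def test_different_molecules_differ(self):
        assert canonical_key(benzene()) != canonical_key(compound("phenol"))

    def test_positional_isomers_differ(self):
        # same formula, hydroxyl/methoxy swapped between B-ring positions
        assert canonical_key(compound("isorhamnetin")) != canonical_key(
            compound("tamarixetin")
        )
        assert graphs_isomorphic(
            compound("isorhamnetin"), compound("tamarixetin")
        ) is False

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.data())
    def test_key_iff_isomorphic_on_random_small_graphs(self, data):
        """canonical_key(a) == canonical_key(b) <=> isomorphic (n <= 7)."""
        import itertools
        import random

        seed = data.draw(st.integers(0, 10**6))
        rng = random.Random(seed)

        def random_graph():
            n = rng.randint(2, 7)
            g = MolecularGraph()
            for i in range(1, n + 1):
                g.add_atom(rng.choice("CO"))
            pairs = list(itertools.combinations(range(1, n + 1), 2))
            for i, j in pairs:
                if rng.random() < 0.4:
                    g.add_bond(i, j, rng.choice(["single", "double"]))
            from flavopred.vocab import assign_atom_types

            assign_atom_types(g)
            return g

        a, b = random_graph(), random_graph()
        assert (canonical_key(a) == canonical_key(b)) == brute_force_isomorphic(a, b)


class TestIsomorphism:
    def test_self(self):
        g = compound("catechol")
        assert graphs_isomorphic(g, g)

    def test_different_sizes(self):
        assert not graphs_isomorphic(benzene(), compound("naringenin"))

    def test_random_relabeling_of_12_atom_fixture(self):
        import random

        g = compound("3,4-HPPA")  # 12 heavy atoms
        rng = random.Random(7)
        idx = g.atom_indices()
        perm = idx[:]
        rng.shuffle(perm)
        h = g.relabeled(dict(zip(idx, perm)))
        assert graphs_isomorphic(g, h)
        assert canonical_key(g) == canonical_key(h)

    def test_vf2_agrees_with_permutation_oracle(self):
        g = compound("catechol")  # 8 atoms: exhaustive check is feasible
        h = g.relabeled({i: 9 - i for i in g.atom_indices()})
        assert brute_force_isomorphic(g, h) is graphs_isomorphic(g, h) is True
        assert brute_force_isomorphic(g, compound("guaiacol")) is False
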