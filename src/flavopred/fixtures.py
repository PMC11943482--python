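"""Named compound fixtures and the worked flavonoid degradation pathway.

The package ships a small panel of flavonoid structures: the flavanone
naringenin and its gut-bacterial C-ring-cleavage pathway (naringenin →
naringenin chalcone → phloretin → 3-(4-hydroxyphenyl)propionic acid +
phloroglucinol), the quercetin methylation products isorhamnetin and
tamarixetin, small oracle compounds (benzene, phenol, catechol, guaiacol),
fifteen dietary flavonoid aglycones spanning the flavanone / flavone /
flavonol / isoflavone subclasses, and four glucoside conjugates.

The pathway is also encoded as explicit reactant–product pairs with
conserved-atom mappings (a shared atom numbering runs through the whole
pathway, so the mappings are identity maps on the conserved atoms), from
which the fixture operator library — C-ring opening, chalcone C2–C3
reduction, direct flavanone-cleaving reduction, retro-Claisen hydrolysis
of phloretin, and aromatic hydroxyl O-methylation — is *derived* through
the same mining engine used for any reaction corpus.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Optional

from .graph import MolecularGraph
from .operators import (
    FilterPolicy,
    OperatorLibrary,
    ReactionPair,
    derive_operators,
)
from .smiles import parse_linear
from .vocab import assign_atom_types

# -- SMILES panel ----------------------------------------------------------

#: Fifteen flavonoid aglycones (subclass in comment).
AGLYCONE_SMILES = {
    "naringenin": "O=C1CC(c2ccc(O)cc2)Oc2cc(O)cc(O)c12",          # flavanone
    "apigenin": "O=C1C=C(c2ccc(O)cc2)Oc2cc(O)cc(O)c12",           # flavone
    "luteolin": "O=C1C=C(c2ccc(O)c(O)c2)Oc2cc(O)cc(O)c12",        # flavone
    "baicalein": "O=C1C=C(c2ccccc2)Oc2cc(O)c(O)c(O)c12",          # flavone
    "chrysin": "O=C1C=C(c2ccccc2)Oc2cc(O)cc(O)c12",               # flavone
    "kaempferol": "O=C1C(O)=C(c2ccc(O)cc2)Oc2cc(O)cc(O)c12",      # flavonol
    "quercetin": "O=C1C(O)=C(c2ccc(O)c(O)c2)Oc2cc(O)cc(O)c12",    # flavonol
    "myricetin": "O=C1C(O)=C(c2cc(O)c(O)c(O)c2)Oc2cc(O)cc(O)c12", # flavonol
    "morin": "O=C1C(O)=C(c2ccc(O)cc2O)Oc2cc(O)cc(O)c12",          # flavonol
    "fisetin": "O=C1C(O)=C(c2ccc(O)c(O)c2)Oc2cc(O)ccc12",         # flavonol
    "robinetin": "O=C1C(O)=C(c2cc(O)c(O)c(O)c2)Oc2cc(O)ccc12",    # flavonol
    "gossypetin": "O=C1C(O)=C(c2ccc(O)c(O)c2)Oc2c(O)c(O)cc(O)c12",# flavonol
    "galangin": "O=C1C(O)=C(c2ccccc2)Oc2cc(O)cc(O)c12",           # flavonol
    "genistein": "O=C1C(c2ccc(O)cc2)=COc2cc(O)cc(O)c12",          # isoflavone
    "daidzein": "O=C1C(c2ccc(O)cc2)=COc2cc(O)ccc12",              # isoflavone
}

#: Four glucoside conjugates completing the 19-compound dietary panel.
GLUCOSIDE_SMILES = {
    "naringenin-7-O-glucoside":
        "O=C1CC(c2ccc(O)cc2)Oc2cc(OC3OC(CO)C(O)C(O)C3O)cc(O)c12",
    "apigenin-7-O-glucoside":
        "O=C1C=C(c2ccc(O)cc2)Oc2cc(OC3OC(CO)C(O)C(O)C3O)cc(O)c12",
    "genistein-7-O-glucoside":
        "O=C1C(c2ccc(O)cc2)=COc2cc(OC3OC(CO)C(O)C(O)C3O)cc(O)c12",
    "quercetin-3-O-glucoside":
        "O=C1C(OC3OC(CO)C(O)C(O)C3O)=C(c2ccc(O)c(O)c2)Oc2cc(O)cc(O)c12",
}

OTHER_SMILES = {
    "naringenin chalcone": "O=C(C=Cc1ccc(O)cc1)c1c(O)cc(O)cc1O",
    "phloretin": "O=C(CCc1ccc(O)cc1)c1c(O)cc(O)cc1O",
    "3,4-HPPA": "OC(=O)CCc1ccc(O)cc1",
    "phloroglucinol": "Oc1cc(O)cc(O)c1",
    "isorhamnetin": "O=C1C(O)=C(c2ccc(O)c(OC)c2)Oc2cc(O)cc(O)c12",
    "tamarixetin": "O=C1C(O)=C(c2ccc(OC)c(O)c2)Oc2cc(O)cc(O)c12",
    "benzene": "c1ccccc1",
    "phenol": "Oc1ccccc1",
    "catechol": "Oc1ccccc1O",
    "guaiacol": "COc1ccccc1O",
    "water": "O",
    "carbon dioxide": "O=C=O",
    "glucose": "OCC1OC(O)C(O)C(O)C1O",
}

COMPOUND_SMILES = {**AGLYCONE_SMILES, **GLUCOSIDE_SMILES, **OTHER_SMILES}


@lru_cache(maxsize=None)
def compound(name: str) -> MolecularGraph:
    """Parse a named fixture compound (cached)."""
    return parse_linear(COMPOUND_SMILES[name], name=name)


def aglycones() -> list[MolecularGraph]:
    """The 15-aglycone structural panel, in a fixed order."""
    return [compound(n) for n in AGLYCONE_SMILES]


# -- explicit pathway graphs ----------------------------------------------
#
# One atom numbering runs through the flavanone pathway so conserved-atom
# mappings between consecutive intermediates are identity maps:
#
#   1  O1   C-ring oxygen (becomes the 2'-hydroxyl of the chalcone)
#   2  C2   flavanone C2 (bears the B ring)       3  C3   flavanone C3
#   4  C4   carbonyl carbon                       5  O    carbonyl oxygen
#   6  C4a  A-ring fusion carbon                  7  C5 (OH: 8)
#   9  C6   10 C7 (OH: 11)   12 C8   13 C8a (bonded to O1)
#   14 C1'  B ring: 15 C2', 16 C3', 17 C4' (OH: 18), 19 C5', 20 C6'
#   21 O    carboxyl hydroxyl introduced by hydrolytic C-ring cleavage

_A_RING = [(6, 7), (7, 9), (9, 10), (10, 12), (12, 13), (13, 6)]
_B_RING = [(14, 15), (15, 16), (16, 17), (17, 19), (19, 20), (20, 14)]

_PATHWAY_ELEMENTS = {
    1: "O", 2: "C", 3: "C", 4: "C", 5: "O", 6: "C", 7: "C", 8: "O",
    9: "C", 10: "C", 11: "O", 12: "C", 13: "C", 14: "C", 15: "C",
    16: "C", 17: "C", 18: "O", 19: "C", 20: "C",
}

_COMMON_BONDS = (
    [(2, 3, "single"), (3, 4, "single"), (4, 5, "double"), (4, 6, "single"),
     (7, 8, "single"), (10, 11, "single"), (13, 1, "single"),
     (2, 14, "single"), (17, 18, "single")]
    + [(a, b, "aromatic") for a, b in _A_RING + _B_RING]
)


def _pathway_graph(
    name: str,
    extra_bonds: Iterable[tuple[int, int, str]] = (),
    drop_bonds: Iterable[tuple[int, int]] = (),
    bond_orders: Optional[dict[tuple[int, int], str]] = None,
    extra_atoms: Iterable[tuple[int, str]] = (),
) -> MolecularGraph:
    g = MolecularGraph(name=name)
    for idx, el in _PATHWAY_ELEMENTS.items():
        g.add_atom(el, index=idx)
    for idx, el in extra_atoms:
        g.add_atom(el, index=idx)
    dropped = {tuple(sorted(p)) for p in drop_bonds}
    orders = {tuple(sorted(k)): v for k, v in (bond_orders or {}).items()}
    for a, b, order in list(_COMMON_BONDS) + list(extra_bonds):
        key = tuple(sorted((a, b)))
        if key in dropped:
            continue
        g.add_bond(a, b, orders.get(key, order))
    assign_atom_types(g)
    g.validate()
    return g


@lru_cache(maxsize=None)
def pathway_graphs() -> dict[str, MolecularGraph]:
    """Pathway intermediates on the shared atom numbering."""
    naringenin = _pathway_graph(
        "naringenin", extra_bonds=[(1, 2, "single")]
    )
    chalcone = _pathway_graph(
        "naringenin chalcone", bond_orders={(2, 3): "double"}
    )
    phloretin = _pathway_graph("phloretin")
    cleaved = _pathway_graph(
        "3,4-HPPA + phloroglucinol",
        drop_bonds=[(4, 6)],
        extra_atoms=[(21, "O")],
        extra_bonds=[(4, 21, "single")],
    )
    return {
        "naringenin": naringenin,
        "naringenin chalcone": chalcone,
        "phloretin": phloretin,
        "cleaved": cleaved,
        "3,4-HPPA": cleaved.subgraph(
            [2, 3, 4, 5, 14, 15, 16, 17, 18, 19, 20, 21], name="3,4-HPPA"
        ),
        "phloroglucinol": cleaved.subgraph(
            [1, 6, 7, 8, 9, 10, 11, 12, 13], name="phloroglucinol"
        ),
    }


def _catechol_pair() -> ReactionPair:
    catechol = MolecularGraph(name="catechol")
    for i in range(1, 7):
        catechol.add_atom("C", index=i)
    for a, b in [(1, 2), (2, 3), (3, 4), (4, 5), (5, 6), (6, 1)]:
        catechol.add_bond(a, b, "aromatic")
    catechol.add_atom("O", index=7)
    catechol.add_bond(1, 7, "single")
    catechol.add_atom("O", index=8)
    catechol.add_bond(2, 8, "single")
    assign_atom_types(catechol)
    guaiacol = catechol.copy(name="guaiacol")
    guaiacol.add_atom("C", index=9)
    guaiacol.add_bond(7, 9, "single")
    assign_atom_types(guaiacol)
    return ReactionPair(
        id="hydroxyl-O-methylation",
        reactant=catechol,
        product=guaiacol,
        atom_map={i: i for i in range(1, 9)},
        ec_numbers=["2.1.1.6"],
    )


#: Reaction class declared per fixture pair (forward direction).
PATHWAY_CLASSES = {
    "C-ring-opening": "C-ring cleavage",
    "chalcone-reduction": "hydrogenation",
    "direct-flavanone-reduction": "C-ring cleavage",
    "retro-claisen-hydrolysis": "hydrolysis",
    "hydroxyl-O-methylation": "methylation",
}


@lru_cache(maxsize=None)
def pathway_reaction_pairs() -> dict[str, ReactionPair]:
    """The fixture reactant–product pairs behind the operator library."""
    g = pathway_graphs()
    ident20 = {i: i for i in range(1, 21)}
    return {
        "C-ring-opening": ReactionPair(
            id="C-ring-opening",
            reactant=g["naringenin"],
            product=g["naringenin chalcone"],
            atom_map=dict(ident20),
            ec_numbers=["5.5.1.6"],
        ),
        "chalcone-reduction": ReactionPair(
            id="chalcone-reduction",
            reactant=g["naringenin chalcone"],
            product=g["phloretin"],
            atom_map=dict(ident20),
            ec_numbers=["1.3.1.77"],
        ),
        "direct-flavanone-reduction": ReactionPair(
            id="direct-flavanone-reduction",
            reactant=g["naringenin"],
            product=g["phloretin"],
            atom_map=dict(ident20),
            ec_numbers=["1.3.1.-"],
        ),
        "retro-claisen-hydrolysis": ReactionPair(
            id="retro-claisen-hydrolysis",
            reactant=g["phloretin"],
            product=g["cleaved"],
            atom_map=dict(ident20),
            ec_numbers=["2.3.1.74"],  # CHS-like polyketide synthase, reverse sense
        ),
        "hydroxyl-O-methylation": _catechol_pair(),
    }


def fixture_operator_library(
    names: Optional[Iterable[str]] = None,
) -> OperatorLibrary:
    """Operator library derived from the fixture pairs.

    ``names`` selects a subset of :data:`PATHWAY_CLASSES` keys; by default
    all five fixture transformations are included (both directions each,
    since the pairs are reversible).
    """
    pairs = pathway_reaction_pairs()
    if names is None:
        names = sorted(pairs)
    ops = []
    for name in names:
        for op in derive_operators(pairs[name]):
            op.reaction_class = PATHWAY_CLASSES[name]
            ops.append(op)
    return OperatorLibrary(ops, provenance="flavonoid pathway fixtures")


def trivial_blocklist() -> FilterPolicy:
    """Blocklist of trivial products: water, CO2, simple sugars."""
    from .graph import canonical_key

    keys = frozenset(
        canonical_key(compound(n)) for n in ("water", "carbon dioxide", "glucose")
    )
    return FilterPolicy(blocklist=keys)


@dataclass
class FixtureSet:
    """Everything :func:`flavonoid_fixtures` returns, bundled."""

    compounds: dict[str, MolecularGraph]
    aglycone_names: list[str]
    pathway_pairs: dict[str, ReactionPair]
    library: OperatorLibrary
    trivial_policy: FilterPolicy


def flavonoid_fixtures() -> FixtureSet:
    """Named compound set, pathway pairs and fixture operator library."""
    return FixtureSet(
        compounds={n: compound(n) for n in COMPOUND_SMILES},
        aglycone_names=list(AGLYCONE_SMILES),
        pathway_pairs=pathway_reaction_pairs(),
        library=fixture_operator_library(),
        trivial_policy=trivial_blocklist(),
    )
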