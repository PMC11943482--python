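"""Atom-type vocabulary and valence bookkeeping.

Transformation operators match substrates on *atom types*: categorical labels
that encode an element together with its local bonding environment, in the
spirit of the environment-aware atom classes used by reaction databases
(aromatic carbon, carbonyl carbon, hydroxyl oxygen, ...). Because operator
matching is exact on these labels, the vocabulary is part of the package
contract: it is a closed, documented enumeration, and every structure built
or parsed by the package is typed by the same rules
(:func:`assign_atom_types`).

Hydrogens are implicit throughout. Each element carries a default valence;
the implicit hydrogen count of an atom is the default valence (adjusted by
formal charge) minus the sum of its heavy-bond orders, clamped at zero.
Aromatic bonds contribute 1.5 to the valence sum, so a benzene carbon
(2 aromatic bonds) keeps one hydrogen and a fused aromatic carbon
(3 aromatic bonds) keeps none.
"""

from __future__ import annotations

import logging
import math
from typing import TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover
    from .graph import MolecularGraph

logger = logging.getLogger(__name__)

#: Bond-order labels used throughout the package. Aromatic bonds are a
#: distinct order, not alternating single/double, so that matching is
#: independent of any particular Kekulé assignment.
BOND_ORDERS = ("single", "double", "triple", "aromatic")

#: Numeric contribution of each bond order to an atom's valence sum.
BOND_VALENCE = {"single": 1.0, "double": 2.0, "triple": 3.0, "aromatic": 1.5}

#: Default (maximum) valence per element, heavy bonds + implicit hydrogens.
DEFAULT_VALENCE = {
    "C": 4,
    "N": 3,
    "O": 2,
    "S": 2,
    "P": 5,
    "F": 1,
    "Cl": 1,
    "Br": 1,
    "I": 1,
    "H": 1,
}

#: The closed atom-type vocabulary. Unknown labels in parsed input are
#: accepted but flagged in logs (see :func:`check_atom_type`).
ATOM_TYPES = frozenset(
    {
        # carbon
        "C.ar.h",   # aromatic C with two heavy neighbours (ring CH)
        "C.ar.s",   # substituted or fused aromatic C (>= 3 heavy neighbours)
        "C.co",     # carbonyl C (one double-bonded O, no single-bonded O)
        "C.oo",     # carboxyl/ester C (double-bonded O plus single-bonded O)
        "C.sp",     # triple-bonded C
        "C.sp2",    # non-aromatic C with a double bond (not to O)
        "C.sp3",    # saturated C
        # oxygen
        "O.ar",     # aromatic ring O
        "O.co",     # double-bonded O (carbonyl / carboxyl oxo)
        "O.et",     # ether/ester O (two heavy neighbours)
        "O.oh",     # hydroxyl O (at most one heavy neighbour; includes water)
        # nitrogen
        "N.ar",     # aromatic N
        "N.am",     # amide N (bonded to a carbonyl C)
        "N.sp",     # triple-bonded N
        "N.sp2",    # double-bonded N
        "N.sp3",    # amine N
        # sulfur / phosphorus / halogens
        "S.ar",
        "S.ox",     # S with double-bonded O (sulfoxide/sulfone-like)
        "S.sp3",
        "P",
        "F",
        "Cl",
        "Br",
        "I",
    }
)


def check_atom_type(label: str) -> str:
    """Return *label*, logging a warning if it is outside the vocabulary."""
    if label not in ATOM_TYPES:
        logger.warning("atom type %r is outside the shipped vocabulary", label)
    return label


def implicit_hydrogens(element: str, charge: int, bond_orders) -> int:
    """Implicit H count from the element's default valence table."""
    valence = DEFAULT_VALENCE.get(element)
    if valence is None:
        return 0
    used = sum(BOND_VALENCE[o] for o in bond_orders)
    free = valence + charge - used
    return max(0, int(math.floor(free + 1e-9)))


def max_valence(element: str, charge: int) -> float:
    """Maximum allowed heavy-bond order sum for valence validation."""
    base = DEFAULT_VALENCE.get(element)
    if base is None:
        return float("inf")  # unknown elements are not valence-checked
    return base + max(0, charge)


def _type_carbon(g: "MolecularGraph", i: int) -> str:
    orders = []
    dbl_o = sgl_o = False
    for j in g.neighbors(i):
        o = g.bond_order(i, j)
        orders.append(o)
        if g.element(j) == "O":
            if o == "double":
                dbl_o = True
            elif o == "single":
                sgl_o = True
    if "aromatic" in orders:
        return "C.ar.s" if len(orders) >= 3 else "C.ar.h"
    if dbl_o:
        return "C.oo" if sgl_o else "C.co"
    if "triple" in orders:
        return "C.sp"
    if "double" in orders:
        return "C.sp2"
    return "C.sp3"


def _type_oxygen(g: "MolecularGraph", i: int) -> str:
    orders = [g.bond_order(i, j) for j in g.neighbors(i)]
    if "aromatic" in orders:
        return "O.ar"
    if "double" in orders:
        return "O.co"
    if len(orders) >= 2:
        return "O.et"
    return "O.oh"


def _type_nitrogen(g: "MolecularGraph", i: int) -> str:
    orders = [g.bond_order(i, j) for j in g.neighbors(i)]
    if "aromatic" in orders:
        return "N.ar"
    if "triple" in orders:
        return "N.sp"
    if "double" in orders:
        return "N.sp2"
    for j in g.neighbors(i):
        if g.element(j) == "C" and any(
            g.element(k) == "O" and g.bond_order(j, k) == "double"
            for k in g.neighbors(j)
        ):
            return "N.am"
    return "N.sp3"


def _type_sulfur(g: "MolecularGraph", i: int) -> str:
    orders = [g.bond_order(i, j) for j in g.neighbors(i)]
    if "aromatic" in orders:
        return "S.ar"
    if any(
        g.element(j) == "O" and g.bond_order(i, j) == "double"
        for j in g.neighbors(i)
    ):
        return "S.ox"
    return "S.sp3"


def atom_type_of(g: "MolecularGraph", i: int) -> str:
    """Compute the vocabulary label of atom *i* from its environment."""
    el = g.element(i)
    if el == "C":
        return _type_carbon(g, i)
    if el == "O":
        return _type_oxygen(g, i)
    if el == "N":
        return _type_nitrogen(g, i)
    if el == "S":
        return _type_sulfur(g, i)
    if el in ("P", "F", "Cl", "Br", "I"):
        return el
    return el  # unknown elements: element symbol, accepted but flagged


def assign_atom_types(g: "MolecularGraph") -> None:
    """(Re)compute atom types for every atom of *g* in place.

    Typing depends only on an atom's element, incident bond orders and
    neighbour *elements* (never neighbour types), so the assignment is a
    single local pass with no fixed point to iterate.
    """
    for i in g.atom_indices():
        g.set_atom_type(i, atom_type_of(g, i))
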