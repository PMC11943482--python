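"""Molecular graph data model, canonical labeling and isomorphism tests.

A :class:`MolecularGraph` is a simple undirected graph whose nodes are heavy
atoms (element, categorical atom type, formal charge; hydrogens implicit)
and whose edges carry one of four bond orders. It is the substrate every
other module of the package consumes: transformation operators rewrite it,
atom-pair descriptors are computed over it, and product sets are
deduplicated through its canonical key.

Canonicalization is an in-package iterative-refinement / individualization
labeling (the standard scheme behind graph-canonicalization tools): equal
keys are guaranteed for isomorphic graphs and, because branching explores
every refinement tie, distinct keys are guaranteed for non-isomorphic ones.
Stereochemistry is ignored throughout — the transformation patterns this
package mines are constitutional.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from itertools import permutations
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import networkx as nx
from networkx.algorithms import isomorphism as nxiso

from .vocab import BOND_ORDERS, check_atom_type, implicit_hydrogens, max_valence


class MolecularGraphError(ValueError):
    """Invalid molecular-graph construction or mutation."""


@dataclass(frozen=True)
class Atom:
    """Immutable view of one heavy atom."""

    index: int
    element: str
    atom_type: str
    charge: int = 0
    implicit_h: int = 0


@dataclass(frozen=True)
class Bond:
    """Immutable view of one bond; endpoints are an unordered pair."""

    endpoints: tuple[int, int]
    order: str

    def __post_init__(self):
        a, b = self.endpoints
        object.__setattr__(self, "endpoints", (min(a, b), max(a, b)))


class MolecularGraph:
    """Labeled simple graph of heavy atoms and bonds.

    Parameters
    ----------
    name:
        Free-text compound name.
    external_id:
        Optional catalog identifier.
    """

    def __init__(self, name: str = "", external_id: Optional[str] = None):
        self._g = nx.Graph()
        self.name = name
        self.external_id = external_id
        self._canon_cache: Optional[tuple[str, tuple[int, ...]]] = None

    # -- construction -----------------------------------------------------

    def add_atom(
        self,
        element: str,
        atom_type: Optional[str] = None,
        charge: int = 0,
        index: Optional[int] = None,
    ) -> int:
        if index is None:
            index = max(self._g.nodes, default=0) + 1
        if index < 1:
            raise MolecularGraphError(f"atom index must be >= 1, got {index}")
        if index in self._g:
            raise MolecularGraphError(f"duplicate atom index {index}")
        if atom_type is not None:
            check_atom_type(atom_type)
        self._g.add_node(
            index, element=element, atom_type=atom_type or element, charge=charge
        )
        self._invalidate()
        return index

    def add_bond(self, i: int, j: int, order: str = "single") -> None:
        if i == j:
            raise MolecularGraphError(f"self-bond on atom {i}")
        for k in (i, j):
            if k not in self._g:
                raise MolecularGraphError(f"bond references missing atom {k}")
        if self._g.has_edge(i, j):
            raise MolecularGraphError(f"duplicate bond {i}-{j}")
        if order not in BOND_ORDERS:
            raise MolecularGraphError(f"unknown bond order {order!r}")
        self._g.add_edge(i, j, order=order)
        self._invalidate()

    # -- mutation (used by operator application) --------------------------

    def remove_atom(self, i: int) -> None:
        self._g.remove_node(i)
        self._invalidate()

    def remove_bond(self, i: int, j: int) -> None:
        self._g.remove_edge(i, j)
        self._invalidate()

    def set_bond_order(self, i: int, j: int, order: str) -> None:
        if order not in BOND_ORDERS:
            raise MolecularGraphError(f"unknown bond order {order!r}")
        self._g.edges[i, j]["order"] = order
        self._invalidate()

    def set_atom_type(self, i: int, atom_type: str) -> None:
        self._g.nodes[i]["atom_type"] = atom_type
        self._invalidate()

    def set_charge(self, i: int, charge: int) -> None:
        self._g.nodes[i]["charge"] = charge
        self._invalidate()

    def _invalidate(self) -> None:
        self._canon_cache = None

    # -- queries ----------------------------------------------------------

    def __contains__(self, i: int) -> bool:
        return i in self._g

    def __len__(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_atoms(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_bonds(self) -> int:
        return self._g.number_of_edges()

    def atom_indices(self) -> list[int]:
        return sorted(self._g.nodes)

    def element(self, i: int) -> str:
        return self._g.nodes[i]["element"]

    def atom_type(self, i: int) -> str:
        return self._g.nodes[i]["atom_type"]

    def charge(self, i: int) -> int:
        return self._g.nodes[i]["charge"]

    def neighbors(self, i: int) -> list[int]:
        return sorted(self._g.neighbors(i))

    def degree(self, i: int) -> int:
        return self._g.degree(i)

    def has_bond(self, i: int, j: int) -> bool:
        return self._g.has_edge(i, j)

    def bond_order(self, i: int, j: int) -> str:
        return self._g.edges[i, j]["order"]

    def implicit_h(self, i: int) -> int:
        orders = [self.bond_order(i, j) for j in self._g.neighbors(i)]
        return implicit_hydrogens(self.element(i), self.charge(i), orders)

    def atom(self, i: int) -> Atom:
        d = self._g.nodes[i]
        return Atom(i, d["element"], d["atom_type"], d["charge"], self.implicit_h(i))

    def atoms(self) -> list[Atom]:
        return [self.atom(i) for i in self.atom_indices()]

    def bonds(self) -> list[Bond]:
        return sorted(
            (Bond((i, j), d["order"]) for i, j, d in self._g.edges(data=True)),
            key=lambda b: b.endpoints,
        )

    def valence_ok(self, i: int) -> bool:
        from .vocab import BOND_VALENCE

        used = sum(
            BOND_VALENCE[self.bond_order(i, j)] for j in self._g.neighbors(i)
        )
        return used <= max_valence(self.element(i), self.charge(i)) + 1e-9

    def validate(self) -> None:
        """Raise :class:`MolecularGraphError` on any broken invariant."""
        for i in self.atom_indices():
            if not self.valence_ok(i):
                raise MolecularGraphError(
                    f"valence exceeded at atom {i} ({self.element(i)})"
                )

    def connected_components(self) -> list[list[int]]:
        return sorted(
            (sorted(c) for c in nx.connected_components(self._g)),
            key=lambda c: c[0],
        )

    def subgraph(self, atoms: Iterable[int], name: str = "") -> "MolecularGraph":
        """Copy of the induced subgraph on *atoms* (indices preserved)."""
        sub = MolecularGraph(name=name or self.name)
        atoms = sorted(atoms)
        for i in atoms:
            sub.add_atom(
                self.element(i), self.atom_type(i), self.charge(i), index=i
            )
        for i in atoms:
            for j in self._g.neighbors(i):
                if j in sub and j > i:
                    sub.add_bond(i, j, self.bond_order(i, j))
        return sub

    def copy(self, name: Optional[str] = None) -> "MolecularGraph":
        dup = MolecularGraph(
            name=self.name if name is None else name, external_id=self.external_id
        )
        dup._g = self._g.copy()
        return dup

    def relabeled(self, mapping: Mapping[int, int]) -> "MolecularGraph":
        """Copy with atom indices renamed through *mapping* (a bijection)."""
        dup = MolecularGraph(name=self.name, external_id=self.external_id)
        dup._g = nx.relabel_nodes(self._g, dict(mapping), copy=True)
        return dup

    def to_networkx(self) -> nx.Graph:
        return self._g

    # -- canonicalization -------------------------------------------------

    def canonical_order(self) -> tuple[int, ...]:
        """Canonical ordering of atom indices (isomorphism-invariant)."""
        return self._canonical()[1]

    def canonical_rank(self) -> dict[int, int]:
        order = self.canonical_order()
        return {a: r for r, a in enumerate(order)}

    def _canonical(
        self, extra: Optional[Mapping[int, str]] = None
    ) -> tuple[str, tuple[int, ...]]:
        if extra is None and self._canon_cache is not None:
            return self._canon_cache
        result = _canonical_certificate(self._g, extra or {})
        if extra is None:
            self._canon_cache = result
        return result

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<MolecularGraph {self.name!r}: {self.n_atoms} atoms, "
            f"{self.n_bonds} bonds>"
        )


# -- canonical labeling (refinement + individualization) -------------------


def _initial_colors(g: nx.Graph, extra: Mapping[int, str]) -> dict[int, int]:
    keys = {
        v: (
            d["atom_type"],
            d["element"],
            d["charge"],
            extra.get(v, ""),
        )
        for v, d in g.nodes(data=True)
    }
    palette = {k: i for i, k in enumerate(sorted(set(keys.values())))}
    return {v: palette[k] for v, k in keys.items()}


def _refine(g: nx.Graph, colors: dict[int, int]) -> dict[int, int]:
    n_classes = len(set(colors.values()))
    while True:
        sig = {
            v: (
                colors[v],
                tuple(
                    sorted(
                        (g.edges[v, u]["order"], colors[u]) for u in g.neighbors(v)
                    )
                ),
            )
            for v in g.nodes
        }
        palette = {s: i for i, s in enumerate(sorted(set(sig.values())))}
        colors = {v: palette[s] for v, s in sig.items()}
        new_n = len(palette)
        if new_n == n_classes:
            return colors
        n_classes = new_n


def _certificate_string(g: nx.Graph, order: Sequence[int]) -> str:
    pos = {v: i for i, v in enumerate(order)}
    nodes = ";".join(
        "{atom_type},{element},{charge}".format(**g.nodes[v]) for v in order
    )
    edges = ",".join(
        f"{a}-{b}:{o}"
        for a, b, o in sorted(
            (min(pos[u], pos[v]), max(pos[u], pos[v]), d["order"])
            for u, v, d in g.edges(data=True)
        )
    )
    return nodes + "|" + edges


def _search(g: nx.Graph, colors: dict[int, int]) -> tuple[str, tuple[int, ...]]:
    colors = _refine(g, colors)
    cells: dict[int, list[int]] = {}
    for v, c in colors.items():
        cells.setdefault(c, []).append(v)
    target = None
    for c in sorted(cells):
        if len(cells[c]) > 1:
            target = sorted(cells[c])
            break
    if target is None:
        order = tuple(sorted(g.nodes, key=lambda v: colors[v]))
        return _certificate_string(g, order), order
    best: Optional[tuple[str, tuple[int, ...]]] = None
    for v in target:
        branched = dict(colors)
        branched[v] = -1  # individualize: unique smallest color
        cand = _search(g, branched)
        if best is None or cand[0] < best[0]:
            best = cand
    assert best is not None
    return best


def _canonical_certificate(
    g: nx.Graph, extra: Mapping[int, str]
) -> tuple[str, tuple[int, ...]]:
    if g.number_of_nodes() == 0:
        return "", ()
    # disconnected graphs: canonicalize per component, join sorted parts
    comps = list(nx.connected_components(g))
    if len(comps) > 1:
        parts = []
        for comp in comps:
            sub = g.subgraph(comp)
            parts.append(_search(sub, _initial_colors(sub, extra)))
        parts.sort(key=lambda p: p[0])
        cert = "||".join(p[0] for p in parts)
        order = tuple(v for p in parts for v in p[1])
        return cert, order
    return _search(g, _initial_colors(g, extra))


def canonical_key(g: MolecularGraph, extra: Optional[Mapping[int, str]] = None) -> str:
    """Opaque string equal for isomorphic graphs, distinct otherwise.

    ``extra`` optionally adds per-atom marker labels (used to compare
    *marked sites* up to automorphism); marked and unmarked keys are
    unrelated values.

    The key is a SHA-1 digest of the canonical certificate, so it is stable
    across runs and compact enough to serve as a dictionary key in
    prediction tables.
    """
    cert = g._canonical(extra)[0]
    return hashlib.sha1(cert.encode()).hexdigest()


def graphs_isomorphic(a: MolecularGraph, b: MolecularGraph) -> bool:
    """True iff a label- and bond-order-preserving bijection exists."""
    nm = nxiso.categorical_node_match(
        ["atom_type", "element", "charge"], [None, None, None]
    )
    em = nxiso.categorical_edge_match("order", None)
    return nx.is_isomorphic(a.to_networkx(), b.to_networkx(), nm, em)


def brute_force_isomorphic(a: MolecularGraph, b: MolecularGraph) -> bool:
    """Exhaustive permutation check; an oracle for small graphs only."""
    na, nb = a.atom_indices(), b.atom_indices()
    if len(na) != len(nb):
        return False

    def profile(g: MolecularGraph, i: int):
        return (g.element(i), g.atom_type(i), g.charge(i))

    for perm in permutations(nb):
        m = dict(zip(na, perm))
        if any(profile(a, i) != profile(b, m[i]) for i in na):
            continue
        ok = True
        for bond in a.bonds():
            i, j = bond.endpoints
            if not b.has_bond(m[i], m[j]) or b.bond_order(m[i], m[j]) != bond.order:
                ok = False
                break
        if ok and a.n_bonds == b.n_bonds:
            return True
    return False
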