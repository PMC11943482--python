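"""Transformation-operator mining and application (the prediction engine).

An enzymatic reactant–product pair with a conserved-atom mapping is mined
for *atom-group transformation operators*: for every connected region of
chemical change, the changed atom with the largest conserved neighbourhood
becomes the reaction center, the conserved atoms one and two bonds away
form the first and second shells of the matching pattern, and the
difference between the two sides is recorded as an explicit edit script
(add/remove atom, add/remove bond, change bond order, change atom type)
expressed relative to the pattern. Reactions are treated as reversible by
default, so each pair also yields reverse-direction operators.

Applying an operator to a non-natural substrate means finding embeddings of
the pattern whose center, first-shell and edited atoms reproduce their full
bonding environment exactly (promiscuity enters only beyond the second
shell), replaying the edit script, and validating valences. Prediction runs
at most two rounds — mirroring the activation/metabolism two-phase view of
xenobiotic transformation — with trivial-product and catalog filtering and
canonical-key deduplication in between.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
from networkx.algorithms import isomorphism as nxiso

from .graph import MolecularGraph, canonical_key
from .kcf import parse_kcf, write_kcf

logger = logging.getLogger(__name__)

OPERATOR_SCHEMA_VERSION = 1


class OperatorError(ValueError):
    pass


class OperatorApplicationError(OperatorError):
    """Edit would produce an invalid structure (e.g. valence violation)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ReactionPair:
    """One reactant–product pair with a conserved-atom mapping.

    ``atom_map`` is a partial injective mapping from reactant atom indices
    to product atom indices over the conserved atoms. Unmapped reactant
    atoms are removed by the reaction; unmapped product atoms are added.
    """

    id: str
    reactant: MolecularGraph
    product: MolecularGraph
    atom_map: dict[int, int]
    ec_numbers: list[str]
    reversible: bool = True

    def __post_init__(self):
        if not self.ec_numbers:
            raise OperatorError(f"pair {self.id}: ec_numbers must be nonempty")
        if len(set(self.atom_map.values())) != len(self.atom_map):
            raise OperatorError(f"pair {self.id}: atom_map is not injective")
        for i, j in self.atom_map.items():
            if i not in self.reactant or j not in self.product:
                raise OperatorError(
                    f"pair {self.id}: mapped atoms {i}->{j} missing from graphs"
                )

    def reversed(self) -> "ReactionPair":
        return ReactionPair(
            id=self.id,
            reactant=self.product,
            product=self.reactant,
            atom_map={j: i for i, j in self.atom_map.items()},
            ec_numbers=list(self.ec_numbers),
            reversible=self.reversible,
        )


@dataclass
class TransformationOperator:
    """Reaction-center pattern plus the edit script converting matches.

    The pattern is a small typed graph whose atoms are identified by dense
    ids 0..m-1 (``pattern_atoms``/``pattern_bonds``); edit-script references
    use these ids, with fresh ids for atoms the edit introduces.
    ``exact_ids`` marks pattern atoms whose full substrate neighbourhood
    must be reproduced by a match (center, first shell, and every edited
    atom); remaining second-shell atoms may carry further substituents —
    this is where substrate promiscuity is admitted.
    """

    id: str
    center: int  # pattern id of the reaction-center atom
    pattern_atoms: dict[int, tuple[str, str, int]]  # id -> (element, type, charge)
    pattern_bonds: dict[tuple[int, int], str]  # (id<id) -> order
    shell1: list[tuple[str, str]]  # sorted multiset of (order, atom_type)
    shell2: list[tuple[str, str]]
    exact_ids: frozenset[int]
    edit_script: list[dict]
    ec_numbers: list[str]
    source_pair: str
    direction: str  # "forward" | "reverse"
    reaction_class: Optional[str] = None
    #: pattern id -> source-reactant atom index at the derivation site;
    #: transient (set by derive_operators, not serialized)
    source_site: Optional[dict[int, int]] = None

    @property
    def center_type(self) -> str:
        return self.pattern_atoms[self.center][1]

    def pattern_graph(self) -> nx.Graph:
        g = nx.Graph()
        for pid, (el, typ, chg) in self.pattern_atoms.items():
            g.add_node(pid, element=el, atom_type=typ, charge=chg)
        for (a, b), order in self.pattern_bonds.items():
            g.add_edge(a, b, order=order)
        return g

    def signature(self) -> str:
        """Canonical key of the pattern decorated with its edit, per direction.

        Two operators mined from different source reactions that encode the
        same transformation (same pattern up to isomorphism, same edit)
        share a signature; the planted-operator recovery checks and the
        deduplicated library reports compare these.
        """
        g = MolecularGraph()
        node_map: dict[int, int] = {}
        for pid, (el, typ, chg) in sorted(self.pattern_atoms.items()):
            node_map[pid] = g.add_atom(el, typ, chg, index=pid + 1)
        for (a, b), order in self.pattern_bonds.items():
            g.add_bond(node_map[a], node_map[b], order)
        marks: dict[int, list[str]] = {i: [] for i in node_map.values()}
        marks[node_map[self.center]].append("center")
        for pid in sorted(self.exact_ids):
            marks[node_map[pid]].append("exact")
        added: dict[int, int] = {}
        for step in self.edit_script:
            op = step["op"]
            if op == "add_atom":
                idx = g.add_atom(step["element"], step["atom_type"], step["charge"])
                added[step["atom"]] = idx
                marks[idx] = ["added"]
            elif op == "add_bond":
                a = added.get(step["a"], node_map.get(step["a"]))
                b = added.get(step["b"], node_map.get(step["b"]))
                g.add_bond(a, b, "single")
                # annotate the new bond's order on both endpoints (edge-level
                # extras are folded into node marks for canonicalization)
                marks[a].append(f"addb:{step['order']}")
                marks[b].append(f"addb:{step['order']}")
            elif op == "remove_bond":
                marks[node_map[step["a"]]].append("rmb")
                marks[node_map[step["b"]]].append("rmb")
            elif op == "change_bond":
                marks[node_map[step["a"]]].append(f"chb:{step['order']}")
                marks[node_map[step["b"]]].append(f"chb:{step['order']}")
            elif op == "change_atom":
                marks[node_map[step["atom"]]].append(
                    f"cha:{step['atom_type']}:{step['charge']}"
                )
            elif op == "remove_atom":
                marks[node_map[step["atom"]]].append("rma")
        extra = {i: "+".join(sorted(m)) for i, m in marks.items()}
        return f"{self.direction}:{canonical_key(g, extra)}"

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "center": self.center,
            "pattern_atoms": [
                [pid, el, typ, chg]
                for pid, (el, typ, chg) in sorted(self.pattern_atoms.items())
            ],
            "pattern_bonds": [
                [a, b, order] for (a, b), order in sorted(self.pattern_bonds.items())
            ],
            "shell1": [list(t) for t in self.shell1],
            "shell2": [list(t) for t in self.shell2],
            "exact_ids": sorted(self.exact_ids),
            "edit_script": self.edit_script,
            "ec_numbers": self.ec_numbers,
            "source_pair": self.source_pair,
            "direction": self.direction,
            "reaction_class": self.reaction_class,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TransformationOperator":
        return cls(
            id=d["id"],
            center=d["center"],
            pattern_atoms={
                pid: (el, typ, chg) for pid, el, typ, chg in d["pattern_atoms"]
            },
            pattern_bonds={
                (a, b): order for a, b, order in d["pattern_bonds"]
            },
            shell1=[tuple(t) for t in d["shell1"]],
            shell2=[tuple(t) for t in d["shell2"]],
            exact_ids=frozenset(d["exact_ids"]),
            edit_script=d["edit_script"],
            ec_numbers=list(d["ec_numbers"]),
            source_pair=d["source_pair"],
            direction=d["direction"],
            reaction_class=d.get("reaction_class"),
        )


@dataclass
class OperatorLibrary:
    operators: list[TransformationOperator] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self):
        ids = [op.id for op in self.operators]
        if len(set(ids)) != len(ids):
            raise OperatorError("operator ids must be unique within a library")

    def __len__(self) -> int:
        return len(self.operators)

    def __iter__(self):
        return iter(sorted(self.operators, key=lambda o: o.id))

    def get(self, op_id: str) -> TransformationOperator:
        for op in self.operators:
            if op.id == op_id:
                return op
        raise KeyError(op_id)

    def subset(self, ids: Iterable[str]) -> "OperatorLibrary":
        ids = set(ids)
        return OperatorLibrary(
            [op for op in self.operators if op.id in ids], self.provenance
        )

    def unique_signatures(self) -> dict[str, list[str]]:
        """Deduplicated pattern+edit signatures -> contributing operator ids.

        Operators are kept per source pair in the library itself;
        deduplication by (pattern, edit script) happens only in reports
        such as this one.
        """
        out: dict[str, list[str]] = {}
        for op in sorted(self.operators, key=lambda o: o.id):
            out.setdefault(op.signature(), []).append(op.id)
        return out

    def to_json(self) -> str:
        return json.dumps(
            {
                "schema_version": OPERATOR_SCHEMA_VERSION,
                "provenance": self.provenance,
                "operators": [op.to_dict() for op in self],
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "OperatorLibrary":
        d = json.loads(text)
        if d.get("schema_version") != OPERATOR_SCHEMA_VERSION:
            raise OperatorError(
                f"unsupported operator-library schema {d.get('schema_version')!r}"
            )
        return cls(
            [TransformationOperator.from_dict(o) for o in d["operators"]],
            d.get("provenance", ""),
        )


@dataclass(frozen=True)
class FilterPolicy:
    """Trivial-product blocklist and optional catalog allow-list.

    The blocklist wins: a key present in both is removed. An empty policy
    passes every record through.
    """

    blocklist: frozenset = frozenset()
    catalog: Optional[frozenset] = None

    def allows(self, key: str) -> bool:
        if key in self.blocklist:
            return False
        if self.catalog is not None and key not in self.catalog:
            return False
        return True


@dataclass
class PredictionRecord:
    substrate_key: str
    operator_id: str
    product: MolecularGraph
    product_key: str
    round: int
    ec_numbers: list[str]

    def sort_key(self) -> tuple:
        return (self.round, self.substrate_key, self.operator_id, self.product_key)


# ---------------------------------------------------------------------------
# operator derivation
# ---------------------------------------------------------------------------


def _changed_reactant_atoms(rp: ReactionPair) -> set[int]:
    """Reactant atoms whose type/charge or bond environment differs."""
    R, P, amap = rp.reactant, rp.product, rp.atom_map
    mapped_p = set(amap.values())
    changed: set[int] = set()
    for i in R.atom_indices():
        if i not in amap:
            changed.add(i)  # removed
            continue
        j = amap[i]
        if (R.atom_type(i), R.charge(i)) != (P.atom_type(j), P.charge(j)):
            changed.add(i)
            continue
        # bond environment: compare through the map
        diff = False
        for n in R.neighbors(i):
            if n not in amap:
                diff = True  # bond to a removed atom
                break
            pn = amap[n]
            if not P.has_bond(j, pn) or P.bond_order(j, pn) != R.bond_order(i, n):
                diff = True
                break
        if not diff:
            for pn in P.neighbors(j):
                if pn not in mapped_p:
                    diff = True  # gains a bond to an added atom
                    break
                # new bond between two conserved atoms
                rn = next(k for k, v in amap.items() if v == pn)
                if not R.has_bond(i, rn):
                    diff = True
                    break
        if diff:
            changed.add(i)
    return changed


def _change_regions(rp: ReactionPair, changed_r: set[int]) -> list[dict]:
    """Connected regions of change, each with reactant and added atoms."""
    R, P, amap = rp.reactant, rp.product, rp.atom_map
    inv = {j: i for i, j in amap.items()}
    added_p = [j for j in P.atom_indices() if j not in inv]
    # union adjacency over ("r", i) and ("p", j) nodes
    u = nx.Graph()
    for i in changed_r:
        u.add_node(("r", i))
    for j in added_p:
        u.add_node(("p", j))
    for i in changed_r:
        for n in R.neighbors(i):
            if n in changed_r:
                u.add_edge(("r", i), ("r", n))
    for i in changed_r:
        if i not in amap:
            continue
        for pn in P.neighbors(amap[i]):
            if pn in inv:
                if inv[pn] in changed_r:
                    u.add_edge(("r", i), ("r", inv[pn]))
            else:
                u.add_edge(("r", i), ("p", pn))
    for j in added_p:
        for pn in P.neighbors(j):
            if pn not in inv:
                u.add_edge(("p", j), ("p", pn))
    regions = []
    for comp in nx.connected_components(u):
        r_atoms = sorted(i for kind, i in comp if kind == "r")
        p_added = sorted(j for kind, j in comp if kind == "p")
        regions.append({"r": r_atoms, "p_added": p_added})
    regions.sort(key=lambda reg: (reg["r"] or [10**9])[0])
    # orphan regions (pure added fragments with no reactant anchor) are
    # co-products of the transformation; fold them into the first anchored
    # region so their emission is part of that operator's edit script.
    anchored = [r for r in regions if r["r"]]
    orphans = [r for r in regions if not r["r"]]
    if orphans:
        if not anchored:
            raise OperatorError(
                f"pair {rp.id}: product adds atoms with no mapped anchor"
            )
        for o in orphans:
            anchored[0]["p_added"].extend(o["p_added"])
            anchored[0]["p_added"].sort()
    return anchored


def _conserved_neighborhood(R: MolecularGraph, i: int, changed: set[int]) -> int:
    """Number of unchanged atoms within two bonds of *i* in the reactant."""
    seen = {i}
    frontier = [i]
    count = 0
    for _ in range(2):
        nxt = []
        for a in frontier:
            for n in R.neighbors(a):
                if n not in seen:
                    seen.add(n)
                    nxt.append(n)
                    if n not in changed:
                        count += 1
        frontier = nxt
    return count


def derive_operators(rp: ReactionPair) -> list[TransformationOperator]:
    """Mine transformation operators from one reactant–product pair.

    One forward operator is emitted per connected change region; if the
    pair is reversible, reverse-direction operators are derived from the
    swapped pair as well. Every emitted operator satisfies the round-trip
    invariant: replayed at its source site it regenerates the recorded
    product region (verified for single-region pairs; composite application
    is verified for multi-region pairs).
    """
    if not rp.atom_map:
        raise OperatorError(f"unmappable pair {rp.id}: empty atom_map")
    ops = _derive_one_direction(rp, "forward")
    _verify_round_trip(rp, ops)
    if rp.reversible:
        swapped = rp.reversed()
        rev = _derive_one_direction(swapped, "reverse")
        _verify_round_trip(swapped, rev)
        ops += rev
    return ops


def _derive_one_direction(
    rp: ReactionPair, direction: str
) -> list[TransformationOperator]:
    R, P, amap = rp.reactant, rp.product, rp.atom_map
    changed = _changed_reactant_atoms(rp)
    if not changed:
        return []
    regions = _change_regions(rp, changed)
    ranks = R.canonical_rank()
    tag = "f" if direction == "forward" else "r"
    out = []
    for k, region in enumerate(regions):
        region_r = set(region["r"])
        center = min(
            region_r,
            key=lambda i: (-_conserved_neighborhood(R, i, changed), ranks[i]),
        )
        # pattern atoms: distance <= 2 from center plus all region atoms
        seen = {center}
        frontier = [center]
        for _ in range(2):
            nxt = []
            for a in frontier:
                for n in R.neighbors(a):
                    if n not in seen:
                        seen.add(n)
                        nxt.append(n)
            frontier = nxt
        pat_atoms = sorted(seen | region_r)
        dist = {
            a: d
            for a, d in nx.single_source_shortest_path_length(
                R.to_networkx(), center
            ).items()
            if a in seen
        }
        order_key = sorted(pat_atoms, key=lambda a: (dist.get(a, 99), ranks[a]))
        pid_of = {a: pid for pid, a in enumerate(order_key)}
        pattern_atoms = {
            pid_of[a]: (R.element(a), R.atom_type(a), R.charge(a)) for a in pat_atoms
        }
        pattern_bonds = {}
        for a in pat_atoms:
            for b in R.neighbors(a):
                if b in pid_of:
                    key = (min(pid_of[a], pid_of[b]), max(pid_of[a], pid_of[b]))
                    pattern_bonds[key] = R.bond_order(a, b)
        shell1 = sorted(
            (R.bond_order(center, n), R.atom_type(n)) for n in R.neighbors(center)
        )
        shell2 = sorted(
            (R.bond_order(n1, n2), R.atom_type(n2))
            for n1 in R.neighbors(center)
            for n2 in R.neighbors(n1)
            if dist.get(n2) == 2
        )
        exact = {pid_of[center]}
        exact.update(pid_of[n] for n in R.neighbors(center))
        exact.update(pid_of[a] for a in region_r)
        edits = _edit_script(rp, region, pid_of)
        out.append(
            TransformationOperator(
                id=f"{rp.id}.{tag}{k}",
                center=pid_of[center],
                pattern_atoms=pattern_atoms,
                pattern_bonds=pattern_bonds,
                shell1=shell1,
                shell2=shell2,
                exact_ids=frozenset(exact),
                edit_script=edits,
                ec_numbers=list(rp.ec_numbers),
                source_pair=rp.id,
                direction=direction,
                source_site={pid: a for a, pid in pid_of.items()},
            )
        )
    return out


def _edit_script(rp: ReactionPair, region: dict, pid_of: dict[int, int]) -> list[dict]:
    R, P, amap = rp.reactant, rp.product, rp.atom_map
    inv = {j: i for i, j in amap.items()}
    region_r = set(region["r"])
    mapped_region = [i for i in region["r"] if i in amap]
    removed = [i for i in region["r"] if i not in amap]
    added = region["p_added"]
    new_pid = {}
    next_pid = max(pid_of.values(), default=-1) + 1
    for j in added:
        new_pid[j] = next_pid
        next_pid += 1

    change_bond, remove_bond, add_bond = [], [], []
    done_pairs = set()
    for i in mapped_region:
        ji = amap[i]
        for n in R.neighbors(i):
            if n not in amap or n not in region_r:
                continue
            key = (min(i, n), max(i, n))
            if key in done_pairs:
                continue
            done_pairs.add(key)
            jn = amap[n]
            a, b = sorted((pid_of[i], pid_of[n]))
            if not P.has_bond(ji, jn):
                remove_bond.append({"op": "remove_bond", "a": a, "b": b})
            elif P.bond_order(ji, jn) != R.bond_order(i, n):
                change_bond.append(
                    {"op": "change_bond", "a": a, "b": b,
                     "order": P.bond_order(ji, jn)}
                )
        # product-side bonds absent from the reactant
        for pn in P.neighbors(ji):
            if pn in inv:
                n = inv[pn]
                if n not in region_r:
                    continue
                key = ("pb", min(i, n), max(i, n))
                if key in done_pairs or R.has_bond(i, n):
                    continue
                done_pairs.add(key)
                a, b = sorted((pid_of[i], pid_of[n]))
                add_bond.append(
                    {"op": "add_bond", "a": a, "b": b,
                     "order": P.bond_order(ji, pn)}
                )

    change_atom = [
        {
            "op": "change_atom",
            "atom": pid_of[i],
            "atom_type": P.atom_type(amap[i]),
            "charge": P.charge(amap[i]),
        }
        for i in mapped_region
        if (R.atom_type(i), R.charge(i))
        != (P.atom_type(amap[i]), P.charge(amap[i]))
    ]
    add_atom = [
        {
            "op": "add_atom",
            "atom": new_pid[j],
            "element": P.element(j),
            "atom_type": P.atom_type(j),
            "charge": P.charge(j),
        }
        for j in added
    ]
    for j in added:
        for pn in P.neighbors(j):
            if pn in inv:
                other = pid_of[inv[pn]]
            elif pn in new_pid and pn > j:
                other = new_pid[pn]
            else:
                continue
            a, b = sorted((new_pid[j], other))
            add_bond.append(
                {"op": "add_bond", "a": a, "b": b, "order": P.bond_order(j, pn)}
            )
    remove_atom = [{"op": "remove_atom", "atom": pid_of[i]} for i in removed]

    def ordered(steps):
        return sorted(steps, key=lambda s: json.dumps(s, sort_keys=True))

    return (
        ordered(change_bond)
        + ordered(remove_bond)
        + ordered(change_atom)
        + ordered(add_atom)
        + ordered(add_bond)
        + ordered(remove_atom)
    )


def _verify_round_trip(rp: ReactionPair, forward_ops) -> None:
    """Replay forward operators at their source sites; must give product."""
    if not forward_ops:
        return
    g = rp.reactant.copy()
    for op in forward_ops:
        # conserved atom indices are stable across edits, so the recorded
        # source site remains valid when regions are applied in sequence
        g, _ = _apply_edits(g, op, op.source_site)
    if canonical_key(g) != canonical_key(rp.product):
        raise OperatorError(
            f"pair {rp.id}: derived operators fail the round-trip invariant"
        )


# ---------------------------------------------------------------------------
# matching and application
# ---------------------------------------------------------------------------


def match_sites(
    substrate: MolecularGraph, op: TransformationOperator
) -> list[dict[int, int]]:
    """Embeddings of the operator pattern into *substrate*.

    Each site maps pattern ids to distinct substrate atoms with exact
    agreement of atom types, charges and bond orders; atoms flagged
    ``exact`` (center, first shell, edited atoms) must reproduce their full
    neighbourhood. Sites equivalent under a substrate automorphism are
    deduplicated; the returned list is deterministically ordered.
    """
    pat = op.pattern_graph()
    if pat.number_of_nodes() == 0:
        return []
    nm = nxiso.categorical_node_match(
        ["atom_type", "element", "charge"], [None, None, None]
    )
    em = nxiso.categorical_edge_match("order", None)
    gm = nxiso.GraphMatcher(substrate.to_networkx(), pat, nm, em)
    sites = []
    seen_keys = set()
    raw = []
    for mapping in gm.subgraph_monomorphisms_iter():
        site = {pid: atom for atom, pid in mapping.items()}
        raw.append(site)
    raw.sort(key=lambda s: tuple(s[pid] for pid in sorted(s)))
    pat_nbrs = {pid: set(pat.neighbors(pid)) for pid in pat.nodes}
    for site in raw:
        ok = True
        for pid in op.exact_ids:
            img_nbrs = set(substrate.neighbors(site[pid]))
            if img_nbrs != {site[q] for q in pat_nbrs[pid]}:
                ok = False
                break
        if not ok:
            continue
        marks = {site[pid]: f"site{pid}" for pid in site}
        key = canonical_key(substrate, marks)
        if key in seen_keys:
            continue
        seen_keys.add(key)
        sites.append(site)
    return sites


def _apply_edits(
    substrate: MolecularGraph, op: TransformationOperator, site: dict[int, int]
) -> tuple[MolecularGraph, dict[int, int]]:
    g = substrate.copy(name=f"{substrate.name}|{op.id}" if substrate.name else "")
    loc = dict(site)  # pattern id -> atom index in g
    next_index = max(g.atom_indices(), default=0) + 1
    touched: set[int] = set()
    for step in op.edit_script:
        kind = step["op"]
        if kind == "change_bond":
            g.set_bond_order(loc[step["a"]], loc[step["b"]], step["order"])
            touched.update((loc[step["a"]], loc[step["b"]]))
        elif kind == "remove_bond":
            g.remove_bond(loc[step["a"]], loc[step["b"]])
            touched.update((loc[step["a"]], loc[step["b"]]))
        elif kind == "change_atom":
            g.set_atom_type(loc[step["atom"]], step["atom_type"])
            g.set_charge(loc[step["atom"]], step["charge"])
        elif kind == "add_atom":
            idx = g.add_atom(
                step["element"], step["atom_type"], step["charge"], index=next_index
            )
            next_index += 1
            loc[step["atom"]] = idx
            touched.add(idx)
        elif kind == "add_bond":
            a, b = loc[step["a"]], loc[step["b"]]
            if g.has_bond(a, b):
                raise OperatorApplicationError(
                    f"{op.id}: add_bond {a}-{b} already bonded"
                )
            g.add_bond(a, b, step["order"])
            touched.update((a, b))
        elif kind == "remove_atom":
            idx = loc[step["atom"]]
            touched.discard(idx)
            g.remove_atom(idx)
        else:  # pragma: no cover
            raise OperatorError(f"unknown edit {kind!r}")
    for i in touched:
        if i in g and not g.valence_ok(i):
            raise OperatorApplicationError(
                f"{op.id}: valence violated at atom {i} ({g.element(i)})"
            )
    return g, loc


def apply_operator(
    substrate: MolecularGraph, op: TransformationOperator, site: dict[int, int]
) -> MolecularGraph:
    """Apply *op* at *site*; raises on valence-violating edits.

    Only atoms and bonds named by the edit script differ from the
    substrate; the product may be disconnected (co-product fragments).
    """
    product, _ = _apply_edits(substrate, op, site)
    return product


def apply_operator_mapped(
    substrate: MolecularGraph, op: TransformationOperator, site: dict[int, int]
) -> tuple[MolecularGraph, dict[int, int]]:
    """Like :func:`apply_operator` but also return the conserved-atom map."""
    product, loc = _apply_edits(substrate, op, site)
    removed = {
        site[step["atom"]] for step in op.edit_script if step["op"] == "remove_atom"
    }
    amap = {i: i for i in substrate.atom_indices() if i not in removed}
    return product, amap


# ---------------------------------------------------------------------------
# prediction pipeline
# ---------------------------------------------------------------------------


def _products_of(
    substrate: MolecularGraph, lib: OperatorLibrary, round_no: int
) -> list[PredictionRecord]:
    s_key = canonical_key(substrate)
    records = []
    for op in lib:
        for site in match_sites(substrate, op):
            try:
                product = apply_operator(substrate, op, site)
            except OperatorApplicationError as exc:
                logger.info("dropped invalid product: %s", exc)
                continue
            for comp in product.connected_components():
                frag = product.subgraph(comp, name=product.name)
                records.append(
                    PredictionRecord(
                        substrate_key=s_key,
                        operator_id=op.id,
                        product=frag,
                        product_key=canonical_key(frag),
                        round=round_no,
                        ec_numbers=list(op.ec_numbers),
                    )
                )
    return records


def _dedup(records: list[PredictionRecord]) -> list[PredictionRecord]:
    seen = set()
    out = []
    for rec in sorted(records, key=PredictionRecord.sort_key):
        key = rec.sort_key()
        if key not in seen:
            seen.add(key)
            out.append(rec)
    return out


def filter_products(
    records: Sequence[PredictionRecord], policy: FilterPolicy
) -> list[PredictionRecord]:
    """Apply the blocklist (and catalog, if given) to prediction records."""
    return [r for r in records if policy.allows(r.product_key)]


def predict_metabolites(
    substrate: MolecularGraph,
    lib: OperatorLibrary,
    rounds: int = 2,
    policy: FilterPolicy = FilterPolicy(),
) -> list[PredictionRecord]:
    """Two-round, filtered metabolite prediction for one substrate.

    Round-1 records come from the substrate itself; the deduplicated
    (and policy-filtered) round-1 products seed round 2. Deeper recursion
    is deliberately excluded — without a reasoning engine to rank
    reactions, the product space explodes beyond two rounds.
    """
    if rounds not in (1, 2):
        raise OperatorError(f"rounds must be 1 or 2, got {rounds}")
    round1 = filter_products(_dedup(_products_of(substrate, lib, 1)), policy)
    if rounds == 1:
        return round1
    seeds: dict[str, MolecularGraph] = {}
    for rec in round1:
        seeds.setdefault(rec.product_key, rec.product)
    round2: list[PredictionRecord] = []
    for key in sorted(seeds):
        round2.extend(_products_of(seeds[key], lib, 2))
    round2 = filter_products(_dedup(round2), policy)
    return round1 + round2


# ---------------------------------------------------------------------------
# corpus and prediction I/O
# ---------------------------------------------------------------------------


def reaction_pair_to_dict(rp: ReactionPair) -> dict:
    return {
        "id": rp.id,
        "reactant": write_kcf(rp.reactant),
        "product": write_kcf(rp.product),
        "atom_map": sorted([i, j] for i, j in rp.atom_map.items()),
        "ec_numbers": rp.ec_numbers,
        "reversible": rp.reversible,
    }


def reaction_pair_from_dict(d: dict) -> ReactionPair:
    return ReactionPair(
        id=d["id"],
        reactant=parse_kcf(d["reactant"]),
        product=parse_kcf(d["product"]),
        atom_map={i: j for i, j in d["atom_map"]},
        ec_numbers=list(d["ec_numbers"]),
        reversible=bool(d.get("reversible", True)),
    )


def write_corpus(pairs: Sequence[ReactionPair]) -> str:
    """Serialize pairs as JSON lines (graphs inline as KCF records)."""
    return "".join(
        json.dumps(reaction_pair_to_dict(rp), sort_keys=True) + "\n" for rp in pairs
    )


def read_corpus(text: str) -> list[ReactionPair]:
    return [
        reaction_pair_from_dict(json.loads(line))
        for line in text.splitlines()
        if line.strip()
    ]


def predictions_to_tsv(records: Sequence[PredictionRecord]) -> str:
    lines = ["substrate_key\toperator_id\tproduct_key\tround\tec_numbers"]
    for r in sorted(records, key=PredictionRecord.sort_key):
        lines.append(
            f"{r.substrate_key}\t{r.operator_id}\t{r.product_key}\t{r.round}\t"
            + ";".join(r.ec_numbers)
        )
    return "\n".join(lines) + "\n"
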