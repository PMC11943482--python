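"""Chemical-similarity machinery: atom-pair descriptors, Tanimoto
coefficients, single-linkage clustering, classical MDS and a Mantel-style
correlation between dissimilarity matrices.

An atom-pair descriptor is the binary set of (atom type, atom type,
topological distance) features over all heavy-atom pairs up to a distance
cap (default 7 bonds). Structures are compared by the Tanimoto coefficient
of these sets, reactions by the Jaccard similarity of their applicable-
operator sets; both are turned into dissimilarities (1 - similarity) for
clustering and multidimensional scaling. Reaction pairs are clustered by
single linkage so that pairs resembling a query substrate can be pulled
out as candidate enzymes for a predicted transformation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
from scipy import stats

from .graph import MolecularGraph


class SimilarityError(ValueError):
    pass


# ---------------------------------------------------------------------------
# descriptors
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AtomPairDescriptor:
    """Binary atom-pair feature set of one structure."""

    features: frozenset  # of (type_i, type_j, distance), type_i <= type_j
    cap: int


def atom_pair_descriptor(g: MolecularGraph, cap: int = 7) -> AtomPairDescriptor:
    """All heavy-atom pairs of *g* with shortest-path distance <= *cap*.

    Raises on disconnected graphs: topological distance is undefined
    across components.
    """
    if cap < 1:
        raise SimilarityError("distance cap must be >= 1")
    if g.n_atoms > 1 and len(g.connected_components()) > 1:
        raise SimilarityError(
            f"{g.name or 'graph'}: atom-pair distances undefined on a "
            "disconnected graph"
        )
    dists = dict(nx.all_pairs_shortest_path_length(g.to_networkx(), cutoff=cap))
    feats = set()
    for i, dmap in dists.items():
        for j, d in dmap.items():
            if j <= i or d < 1:
                continue
            ti, tj = sorted((g.atom_type(i), g.atom_type(j)))
            feats.add((ti, tj, d))
    return AtomPairDescriptor(frozenset(feats), cap)


def tanimoto(a: AtomPairDescriptor, b: AtomPairDescriptor) -> float:
    """|a ∩ b| / |a ∪ b|; 1.0 when both descriptors are empty."""
    if a.cap != b.cap:
        raise SimilarityError(
            f"descriptor caps differ ({a.cap} vs {b.cap}); not comparable"
        )
    union = a.features | b.features
    if not union:
        return 1.0
    return len(a.features & b.features) / len(union)


# ---------------------------------------------------------------------------
# dissimilarity matrices
# ---------------------------------------------------------------------------


@dataclass
class DissimilarityMatrix:
    labels: list[str]
    values: np.ndarray  # symmetric, zero diagonal, entries in [0, 1]

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise SimilarityError("matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise SimilarityError("matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise SimilarityError("diagonal must be zero")
        if v.min() < -1e-9 or v.max() > 1.0 + 1e-9:
            raise SimilarityError("entries must lie in [0, 1]")
        self.values = v

    def __getitem__(self, pair):
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return self.values[i, j]

    def to_tsv(self) -> str:
        lines = ["\t" + "\t".join(self.labels)]
        for lab, row in zip(self.labels, self.values):
            lines.append(lab + "\t" + "\t".join(f"{x:.10g}" for x in row))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str) -> "DissimilarityMatrix":
        rows = [line.split("\t") for line in text.splitlines() if line]
        labels = rows[0][1:]
        values = np.array([[float(x) for x in r[1:]] for r in rows[1:]])
        return cls(labels, values)


def pairwise_dissimilarity(
    items: Sequence[MolecularGraph],
    cap: int = 7,
    labels: Optional[Sequence[str]] = None,
) -> DissimilarityMatrix:
    """1 - Tanimoto over atom-pair descriptors for every item pair."""
    if len(items) < 2:
        raise SimilarityError("need at least two items")
    if labels is None:
        labels = [g.name or f"item{i}" for i, g in enumerate(items)]
    descs = [atom_pair_descriptor(g, cap) for g in items]
    n = len(items)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = 1.0 - tanimoto(descs[i], descs[j])
    return DissimilarityMatrix(list(labels), d)


def reaction_profile(
    profiles: Mapping[str, Iterable[str]]
) -> DissimilarityMatrix:
    """1 - Jaccard over per-item applicable-operator id sets."""
    labels = sorted(profiles)
    if len(labels) < 2:
        raise SimilarityError("need at least two items")
    sets = {k: set(profiles[k]) for k in labels}
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = sets[labels[i]], sets[labels[j]]
            union = a | b
            jac = 1.0 if not union else len(a & b) / len(union)
            d[i, j] = d[j, i] = 1.0 - jac
    return DissimilarityMatrix(labels, d)


# ---------------------------------------------------------------------------
# single-linkage clustering
# ---------------------------------------------------------------------------


@dataclass
class Dendrogram:
    """Agglomeration history in the usual linkage convention.

    ``merges`` holds (cluster_a, cluster_b, height, size) with original
    items numbered 0..n-1 and the k-th merge creating cluster n+k; heights
    are non-decreasing under single linkage.
    """

    n_items: int
    labels: list[str]
    merges: list[tuple[int, int, float, int]]

    def to_linkage(self) -> np.ndarray:
        """SciPy-style (n-1) × 4 linkage matrix."""
        return np.array([[a, b, h, s] for a, b, h, s in self.merges], dtype=float)

    def to_merge_tsv(self) -> str:
        lines = ["cluster_a\tcluster_b\theight\tsize"]
        for a, b, h, s in self.merges:
            lines.append(f"{a}\t{b}\t{h:.10g}\t{s}")
        return "\n".join(lines) + "\n"

    def to_newick(self) -> str:
        node: dict[int, str] = {i: self.labels[i] for i in range(self.n_items)}
        height: dict[int, float] = {i: 0.0 for i in range(self.n_items)}
        for k, (a, b, h, _s) in enumerate(self.merges):
            la = height[a]
            lb = height[b]
            nid = self.n_items + k
            node[nid] = (
                f"({node[a]}:{(h - la) / 2:.10g},{node[b]}:{(h - lb) / 2:.10g})"
            )
            height[nid] = h
        root = self.n_items + len(self.merges) - 1 if self.merges else 0
        return node[root] + ";"

    def cut(self, cut_height: float) -> list[frozenset]:
        """Flat clusters from merges with height <= *cut_height*.

        The threshold is inclusive so that a cut at 0 groups exact
        duplicates (dissimilarity 0) and a cut at 1 yields one cluster.
        """
        parent = list(range(self.n_items + len(self.merges)))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for k, (a, b, h, _s) in enumerate(self.merges):
            if h <= cut_height:
                nid = self.n_items + k
                parent[find(a)] = nid
                parent[find(b)] = nid
        groups: dict[int, set[int]] = {}
        for i in range(self.n_items):
            groups.setdefault(find(i), set()).add(i)
        return sorted(
            (frozenset(g) for g in groups.values()), key=lambda g: min(g)
        )


def single_linkage(d: DissimilarityMatrix) -> Dendrogram:
    """Single-linkage agglomeration with a deterministic tie rule.

    At each step the pair of clusters with minimal inter-cluster
    dissimilarity merges; ties break on the smallest (label-index) pair.
    Heights therefore equal the sorted edge weights of a minimum spanning
    tree of the dissimilarity graph.
    """
    n = len(d.labels)
    size = {i: 1 for i in range(n)}
    rep = {i: i for i in range(n)}  # cluster id -> smallest original item
    # Lance-Williams single-linkage: inter-cluster distance of a merged
    # cluster to any other is the min of its parents' distances
    dist: dict[tuple[int, int], float] = {
        (i, j): float(d.values[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    active = set(range(n))
    merges = []
    next_id = n
    while len(active) > 1:
        best = None
        for (a, b), dd in dist.items():
            key = (dd, min(rep[a], rep[b]), max(rep[a], rep[b]))
            if best is None or key < best[0]:
                best = (key, a, b)
        (_key, a, b) = best
        h = _key[0]
        merges.append((a, b, h, size[a] + size[b]))
        active.discard(a)
        active.discard(b)
        new_dist = {}
        for k in active:
            da = dist[(min(a, k), max(a, k))]
            db = dist[(min(b, k), max(b, k))]
            new_dist[(k, next_id)] = min(da, db)
        dist = {
            pair: v for pair, v in dist.items() if a not in pair and b not in pair
        }
        dist.update(new_dist)
        size[next_id] = size[a] + size[b]
        rep[next_id] = min(rep[a], rep[b])
        active.add(next_id)
        next_id += 1
    return Dendrogram(n, list(d.labels), merges)


def cocluster_candidates(
    query: MolecularGraph,
    rpairs: Sequence,
    cut_height: float,
    side: str = "reactant",
    cap: int = 7,
) -> list[str]:
    """Reaction-pair ids falling in the query's single-linkage cluster.

    Reaction pairs are represented by the atom-pair descriptor of their
    reactant (default) or product; the query structure joins the pool, the
    pooled dissimilarities are clustered by single linkage, and the ids
    sharing the query's flat cluster at *cut_height* are returned. Whether
    a candidate's reaction truly resembles the predicted transformation is
    a judgement left downstream.
    """
    if side not in ("reactant", "product"):
        raise SimilarityError(f"unknown side {side!r}")
    items = [query]
    labels = ["__query__"]
    for rp in rpairs:
        items.append(getattr(rp, side))
        labels.append(rp.id)
    d = pairwise_dissimilarity(items, cap=cap, labels=labels)
    dendro = single_linkage(d)
    for cluster in dendro.cut(cut_height):
        if 0 in cluster:
            return sorted(labels[i] for i in cluster if i != 0)
    return []


# ---------------------------------------------------------------------------
# classical MDS and matrix correlation
# ---------------------------------------------------------------------------


@dataclass
class MdsEmbedding:
    labels: list[str]
    coordinates: np.ndarray  # (n, dim), centroid at origin
    eigenvalues: np.ndarray  # descending

    def to_tsv(self) -> str:
        dim = self.coordinates.shape[1]
        lines = ["id\t" + "\t".join(f"dim{k + 1}" for k in range(dim))]
        for lab, row in zip(self.labels, self.coordinates):
            lines.append(lab + "\t" + "\t".join(f"{x:.10g}" for x in row))
        return "\n".join(lines) + "\n"


def classical_mds(d: DissimilarityMatrix, dim: int = 2) -> MdsEmbedding:
    """Torgerson double-centering eigendecomposition of a dissimilarity
    matrix.

    Negative eigenvalues (non-Euclidean structure) are truncated; axes
    with (near-)zero eigenvalues contribute zero coordinates, so a fully
    degenerate all-zero matrix embeds every item at the origin.
    """
    if dim < 1:
        raise SimilarityError("dim must be >= 1")
    n = len(d.labels)
    if dim > n - 1:
        raise SimilarityError(f"dim {dim} exceeds item count - 1 ({n - 1})")
    D2 = d.values**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(1e-12, 1e-9 * max(abs(evals[0]), 1.0))
    positive = int(np.sum(evals > tol))
    degenerate = bool(np.all(np.abs(evals) <= tol))
    if not degenerate and dim > positive:
        raise SimilarityError(
            f"dim {dim} exceeds positive-eigenvalue count {positive}"
        )
    coords = np.zeros((n, dim))
    for k in range(min(dim, positive)):
        coords[:, k] = evecs[:, k] * np.sqrt(evals[k])
    coords -= coords.mean(axis=0)  # numerically re-center
    return MdsEmbedding(list(d.labels), coords, evals)


def dissimilarity_correlation(
    a: DissimilarityMatrix,
    b: DissimilarityMatrix,
    n_permutations: int = 9999,
    seed: Optional[int] = None,
) -> dict:
    """Pearson correlation between two dissimilarity matrices.

    The coefficient, fit slope and intercept are computed over the strict
    upper triangles; significance comes from a Mantel-style permutation
    test (items relabeled jointly in one matrix), two-sided, seeded.
    """
    if a.labels != b.labels:
        raise SimilarityError("matrices must share labels and order")
    if seed is None:
        raise SimilarityError("a seed is mandatory for the permutation test")
    n = len(a.labels)
    iu = np.triu_indices(n, k=1)
    x, y = a.values[iu], b.values[iu]
    if np.std(x) == 0 or np.std(y) == 0:
        raise SimilarityError("degenerate (constant) dissimilarities")
    r = float(stats.pearsonr(x, y).statistic)
    fit = stats.linregress(x, y)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        bp = b.values[np.ix_(perm, perm)]
        rp = float(stats.pearsonr(x, bp[iu]).statistic)
        if abs(rp) >= abs(r) - 1e-12:
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return {
        "r": r,
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "p_value": p,
        "n_permutations": n_permutations,
    }
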