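"""Seeded generators for every input the pipeline consumes.

Real operator mining runs over licensed reaction databases and genome
annotations that cannot be redistributed, so the package generates its own
study inputs: reaction corpora with *planted* transformation operators
(each reaction is constructed by applying a known operator to a decorated
scaffold at a matched site, recording the exact conserved-atom map),
organism × EC matrices with planted enzyme carriers and taxonomy labels,
and homolog sequence sets mutated to controlled percent identity. Every
generator is a pure function of its seed and specification, and each
generated artifact is accompanied by a ground-truth record sufficient to
verify downstream recovery.

Scaffolds are the planted operators' exemplar contexts grown with random
aliphatic decorations at designated anchor atoms; decorations stay at
least one bond outside the operators' two-shell patterns, so chemical
plausibility is enforced only at the valence level — the pipeline's
contracts are graph-level.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .graph import MolecularGraph
from .homologs import ProteinSequence
from .microbiome import OrganismEnzymeMatrix
from .operators import (
    OperatorError,
    ReactionPair,
    TransformationOperator,
    apply_operator_mapped,
    derive_operators,
    match_sites,
)
from .vocab import assign_atom_types


class SyntheticError(ValueError):
    pass


# ---------------------------------------------------------------------------
# planted transformations
# ---------------------------------------------------------------------------


@dataclass
class PlantedTransform:
    """One generator transformation: exemplar pair + decoration anchors."""

    name: str
    pair: ReactionPair
    anchors: list[int]  # sp3 atoms safe to decorate (pattern-invariant)
    forward_op: TransformationOperator = field(init=False)
    reverse_op: TransformationOperator = field(init=False)

    def __post_init__(self):
        ops = derive_operators(self.pair)
        fwd = [o for o in ops if o.direction == "forward"]
        rev = [o for o in ops if o.direction == "reverse"]
        if len(fwd) != 1 or len(rev) != 1:
            raise SyntheticError(
                f"planted transform {self.name} must be single-region"
            )
        self.forward_op = fwd[0]
        self.reverse_op = rev[0]

    def signatures(self) -> dict[str, str]:
        return {
            "forward": self.forward_op.signature(),
            "reverse": self.reverse_op.signature(),
        }


def _aromatic_ring(g: MolecularGraph, start: int = 1) -> list[int]:
    ring = [g.add_atom("C", index=start + k) for k in range(6)]
    for k in range(6):
        g.add_bond(ring[k], ring[(k + 1) % 6], "aromatic")
    return ring


def _methylation_exemplar() -> PlantedTransform:
    # catechol-like head with an aliphatic tail for decoration anchors
    r = MolecularGraph(name="methylation-exemplar")
    ring = _aromatic_ring(r)
    o7 = r.add_atom("O", index=7)
    r.add_bond(ring[0], o7, "single")
    o8 = r.add_atom("O", index=8)
    r.add_bond(ring[1], o8, "single")
    c9 = r.add_atom("C", index=9)
    r.add_bond(ring[3], c9, "single")
    c10 = r.add_atom("C", index=10)
    r.add_bond(c9, c10, "single")
    assign_atom_types(r)
    p = r.copy(name="methylation-exemplar-product")
    c11 = p.add_atom("C", index=11)
    p.add_bond(o7, c11, "single")
    assign_atom_types(p)
    pair = ReactionPair(
        id="planted-methylation",
        reactant=r,
        product=p,
        atom_map={i: i for i in range(1, 11)},
        ec_numbers=["2.1.1.6"],
    )
    return PlantedTransform("methylation", pair, anchors=[9, 10])


def _hydroxylation_exemplar() -> PlantedTransform:
    r = MolecularGraph(name="hydroxylation-exemplar")
    ring = _aromatic_ring(r)
    c7 = r.add_atom("C", index=7)
    r.add_bond(ring[3], c7, "single")
    c8 = r.add_atom("C", index=8)
    r.add_bond(c7, c8, "single")
    assign_atom_types(r)
    p = r.copy(name="hydroxylation-exemplar-product")
    o9 = p.add_atom("O", index=9)
    p.add_bond(ring[0], o9, "single")
    assign_atom_types(p)
    pair = ReactionPair(
        id="planted-hydroxylation",
        reactant=r,
        product=p,
        atom_map={i: i for i in range(1, 9)},
        ec_numbers=["1.14.13.39"],
    )
    return PlantedTransform("hydroxylation", pair, anchors=[7, 8])


def _hydrogenation_exemplar() -> PlantedTransform:
    r = MolecularGraph(name="hydrogenation-exemplar")
    for i in range(1, 5):
        r.add_atom("C", index=i)
    r.add_bond(1, 2, "single")
    r.add_bond(2, 3, "single")
    r.add_bond(3, 4, "double")
    assign_atom_types(r)
    p = r.copy(name="hydrogenation-exemplar-product")
    p.set_bond_order(3, 4, "single")
    assign_atom_types(p)
    pair = ReactionPair(
        id="planted-hydrogenation",
        reactant=r,
        product=p,
        atom_map={i: i for i in range(1, 5)},
        ec_numbers=["1.3.1.77"],
    )
    return PlantedTransform("hydrogenation", pair, anchors=[1])


def default_planted() -> list[PlantedTransform]:
    """The three default planted transformation patterns."""
    return [
        _methylation_exemplar(),
        _hydroxylation_exemplar(),
        _hydrogenation_exemplar(),
    ]


# ---------------------------------------------------------------------------
# reaction corpus
# ---------------------------------------------------------------------------


@dataclass
class CorpusSpec:
    seed: int
    n_scaffolds: int = 20
    n_reactions: int = 50
    planted: Optional[list[PlantedTransform]] = None
    decoy_fraction: float = 0.0
    max_decorations: int = 4

    def __post_init__(self):
        if self.n_scaffolds < 1 or self.n_reactions < 1:
            raise SyntheticError("counts must be >= 1")
        if not 0.0 <= self.decoy_fraction <= 1.0:
            raise SyntheticError("decoy_fraction must lie in [0, 1]")
        if self.planted is None:
            self.planted = default_planted()


def _decorate(
    template: PlantedTransform, rng: np.random.Generator, max_decorations: int
) -> tuple[MolecularGraph, list[int]]:
    """Grow random aliphatic decorations at the template's anchor atoms."""
    g = template.pair.reactant.copy()
    grown: list[int] = []
    frontier = list(template.anchors)
    n_dec = int(rng.integers(0, max_decorations + 1))
    for _ in range(n_dec):
        candidates = [a for a in frontier if g.implicit_h(a) >= 1]
        if not candidates:
            break
        a = candidates[int(rng.integers(len(candidates)))]
        if rng.random() < 0.25:
            new = g.add_atom("O")
            g.add_bond(a, new, "single")  # terminal hydroxyl, not extendable
        else:
            new = g.add_atom("C")
            g.add_bond(a, new, "single")
            frontier.append(new)
        grown.append(new)
    assign_atom_types(g)
    return g, grown


def _decoy_pair(
    pair_id: str,
    template: PlantedTransform,
    rng: np.random.Generator,
    ec_pool: Sequence[str],
    max_decorations: int,
) -> ReactionPair:
    """A label-shuffled non-instance: an aliphatic hydroxylation decoy."""
    scaffold, _grown = _decorate(template, rng, max_decorations)
    # hydroxylate a saturated carbon: distinct from every planted pattern
    # (the planted hydroxylation is aromatic); every exemplar keeps at
    # least one free sp3 valence, so candidates is never empty
    candidates = [
        a
        for a in scaffold.atom_indices()
        if scaffold.atom_type(a) == "C.sp3" and scaffold.implicit_h(a) >= 1
    ]
    site = candidates[int(rng.integers(len(candidates)))]
    product = scaffold.copy()
    o = product.add_atom("O")
    product.add_bond(site, o, "single")
    assign_atom_types(product)
    ec = ec_pool[int(rng.integers(len(ec_pool)))]
    return ReactionPair(
        id=pair_id,
        reactant=scaffold,
        product=product,
        atom_map={i: i for i in scaffold.atom_indices()},
        ec_numbers=[ec],
    )


def gen_reaction_corpus(
    spec: CorpusSpec,
) -> tuple[list[ReactionPair], dict]:
    """Generate a mock reaction corpus with planted operators.

    Returns the reaction pairs and a ground-truth record: per-pair planted
    operator name, decoy flag and application site, plus the planted
    pattern signatures per direction. Fully reproducible from the seed.
    """
    rng = np.random.default_rng(spec.seed)
    planted = list(spec.planted)
    ec_pool = sorted({ec for p in planted for ec in p.pair.ec_numbers})
    scaffolds = []
    for s in range(spec.n_scaffolds):
        template = planted[s % len(planted)]
        g, _ = _decorate(template, rng, spec.max_decorations)
        g.name = f"S{s:04d}"
        scaffolds.append((template, g))
    pairs: list[ReactionPair] = []
    truth_pairs: dict[str, dict] = {}
    for i in range(spec.n_reactions):
        pair_id = f"R{i:04d}"
        template, scaffold = scaffolds[int(rng.integers(len(scaffolds)))]
        if rng.random() < spec.decoy_fraction:
            rp = _decoy_pair(pair_id, template, rng, ec_pool, spec.max_decorations)
            pairs.append(rp)
            truth_pairs[pair_id] = {"planted": None, "decoy": True, "site": None}
            continue
        sites = match_sites(scaffold, template.forward_op)
        if not sites:
            raise SyntheticError(
                f"planted pattern {template.name} matches no site on "
                f"scaffold {scaffold.name}"
            )
        site = sites[int(rng.integers(len(sites)))]
        product, amap = apply_operator_mapped(
            scaffold, template.forward_op, site
        )
        product.name = f"{scaffold.name}-prod"
        rp = ReactionPair(
            id=pair_id,
            reactant=scaffold.copy(name=scaffold.name),
            product=product,
            atom_map=amap,
            ec_numbers=list(template.pair.ec_numbers),
        )
        pairs.append(rp)
        truth_pairs[pair_id] = {
            "planted": template.name,
            "decoy": False,
            "site": {int(k): int(v) for k, v in site.items()},
        }
    truth = {
        "seed": spec.seed,
        "pairs": truth_pairs,
        "planted_signatures": {p.name: p.signatures() for p in planted},
    }
    return pairs, truth


def derived_signature_set(pairs: Sequence[ReactionPair]) -> set[str]:
    """Deduplicated pattern+edit signatures derived from *pairs*."""
    sigs = set()
    for rp in pairs:
        for op in derive_operators(rp):
            sigs.add(op.signature())
    return sigs


# ---------------------------------------------------------------------------
# organism-enzyme matrix
# ---------------------------------------------------------------------------

DEFAULT_PHYLA = (
    "Firmicutes",
    "Bacteroidetes",
    "Actinobacteria",
    "Proteobacteria",
)

# background EC pool; none shares a 3-digit prefix with another pool entry
_BACKGROUND_ECS = [
    "1.1.1.1", "1.2.1.3", "2.4.1.1", "2.6.1.2", "2.7.1.1",
    "3.1.3.1", "3.2.1.4", "3.5.1.5", "4.1.1.1", "4.2.1.2",
    "5.3.1.9", "6.3.1.2",
]


def gen_organism_matrix(
    seed: int,
    n_strains: int = 12,
    phyla: Sequence[str] = DEFAULT_PHYLA,
    planted_ec_assignments: Optional[dict[str, Sequence[int]]] = None,
    background_density: float = 0.25,
) -> tuple[OrganismEnzymeMatrix, dict]:
    """Generate a strain × EC incidence matrix with taxonomy labels.

    ``planted_ec_assignments`` maps an EC number to the strain indices
    (0-based) that carry it; background ECs are sampled from a pool whose
    3-digit prefixes are disjoint from the planted ones, so planted
    carriers remain exactly recoverable. Genus and family labels nest
    deterministically inside phyla.
    """
    if n_strains < 1:
        raise SyntheticError("n_strains must be >= 1")
    rng = np.random.default_rng(seed)
    planted = planted_ec_assignments or {}
    planted_prefixes = {tuple(ec.split(".")[:3]) for ec in planted}
    pool = [
        ec
        for ec in _BACKGROUND_ECS
        if tuple(ec.split(".")[:3]) not in planted_prefixes
    ]
    strains, ec_sets, taxonomy = [], {}, {}
    for i in range(n_strains):
        sid = f"strain{i:03d}"
        strains.append(sid)
        phylum = phyla[i % len(phyla)]
        taxonomy[sid] = {
            "phylum": phylum,
            "family": f"{phylum}_fam{(i // len(phyla)) % 2}",
            "genus": f"{phylum}_gen{(i // len(phyla)) % 3}",
        }
        ecs = {ec for ec in pool if rng.random() < background_density}
        ec_sets[sid] = ecs
    for ec, carriers in planted.items():
        for idx in carriers:
            ec_sets[strains[idx]].add(ec)
    matrix = OrganismEnzymeMatrix(strains, ec_sets, taxonomy)
    truth = {
        "seed": seed,
        "planted": {
            ec: sorted(strains[i] for i in idxs) for ec, idxs in planted.items()
        },
    }
    return matrix, truth


# ---------------------------------------------------------------------------
# homolog sequence sets
# ---------------------------------------------------------------------------

_AA20 = "ACDEFGHIKLMNPQRSTVWY"


def gen_homolog_set(
    seed: int,
    reference_length: int = 300,
    target_identities: Sequence[float] = (95.0, 85.0, 70.0),
) -> tuple[list[ProteinSequence], dict]:
    """Random reference protein plus point-mutated candidates.

    Each candidate is produced by substituting ``round(L * (1 - t/100))``
    positions of the reference with different residues, so the gapless
    identity to the reference is exactly the realized fraction; global
    alignment recovers it up to its own optimal-alignment tolerance.
    """
    for t in target_identities:
        if not 0 < t <= 100:
            raise SyntheticError("target identities must lie in (0, 100]")
    rng = np.random.default_rng(seed)
    ref = "".join(_AA20[int(k)] for k in rng.integers(0, 20, reference_length))
    seqs = [ProteinSequence("REF", ref)]
    truth = {"seed": seed, "reference_length": reference_length, "targets": {}}
    for t in target_identities:
        n_sub = int(round(reference_length * (1.0 - t / 100.0)))
        positions = rng.choice(reference_length, size=n_sub, replace=False)
        residues = list(ref)
        for pos in positions:
            current = residues[pos]
            options = [a for a in _AA20 if a != current]
            residues[pos] = options[int(rng.integers(len(options)))]
        sid = f"mut{t:g}"
        seqs.append(ProteinSequence(sid, "".join(residues)))
        truth["targets"][sid] = {
            "target_identity": float(t),
            "realized_identity": 100.0
            * (reference_length - n_sub)
            / reference_length,
            "n_substitutions": n_sub,
        }
    return seqs, truth


def truth_to_json(truth: dict) -> str:
    return json.dumps(truth, indent=2, sort_keys=True)
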