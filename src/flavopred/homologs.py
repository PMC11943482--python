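"""Protein homolog screening and distance-tree construction.

Candidate enzymes for a predicted transformation can be prioritized by
screening bacterial proteomes for homologs of a reference enzyme (e.g. a
plant chalcone synthase with strong flavanone binding). "Sequence
similarity" is operationalized as global percent identity from a
Needleman–Wunsch alignment (BLOSUM62, affine gaps, defaults documented in
:data:`ALIGN_DEFAULTS`); hits above a strict identity threshold are kept
and summarized as a neighbor-joining tree over 100 - identity distances.
The alignment itself is delegated to Biopython's ``PairwiseAligner`` and
the tree to scikit-bio's neighbor joining; this module fixes the scoring
conventions and the identity/distance definitions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from io import StringIO
from typing import Optional, Sequence

import numpy as np
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from skbio import DistanceMatrix
from skbio.tree import TreeNode, nj

AMINO_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

#: Global-alignment scoring defaults (substitution matrix and affine gaps).
ALIGN_DEFAULTS = {
    "matrix": "BLOSUM62",
    "open_gap_score": -11.0,
    "extend_gap_score": -1.0,
}


class SequenceError(ValueError):
    pass


@dataclass(frozen=True)
class ProteinSequence:
    id: str
    residues: str

    def __post_init__(self):
        if not self.residues:
            raise SequenceError(f"sequence {self.id!r} is empty")
        bad = set(self.residues.upper()) - AMINO_ALPHABET
        if bad:
            raise SequenceError(
                f"sequence {self.id!r} contains invalid residues {sorted(bad)}"
            )
        object.__setattr__(self, "residues", self.residues.upper())

    def __len__(self) -> int:
        return len(self.residues)


def read_fasta(text: str) -> list[ProteinSequence]:
    return [
        ProteinSequence(rec.id, str(rec.seq))
        for rec in SeqIO.parse(StringIO(text), "fasta")
    ]


def write_fasta(seqs: Sequence[ProteinSequence]) -> str:
    out = StringIO()
    SeqIO.write(
        [SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs],
        out,
        "fasta",
    )
    return out.getvalue()


def _aligner(**overrides) -> Align.PairwiseAligner:
    cfg = {**ALIGN_DEFAULTS, **overrides}
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(cfg["matrix"])
    aligner.open_gap_score = cfg["open_gap_score"]
    aligner.extend_gap_score = cfg["extend_gap_score"]
    return aligner


def global_identity(
    a: ProteinSequence, b: ProteinSequence, **scoring_overrides
) -> float:
    """Percent identity of an optimal global alignment of *a* and *b*.

    Identity = identical columns / alignment columns (gap columns count
    toward the denominator) × 100, taken from the aligner's first optimal
    alignment, which is deterministic for fixed scoring.
    """
    aligner = _aligner(**scoring_overrides)
    aln = aligner.align(a.residues, b.residues)[0]
    counts = aln.counts()
    return 100.0 * counts.identities / aln.length


def global_alignment_score(
    a: ProteinSequence, b: ProteinSequence, **scoring_overrides
) -> float:
    """Optimal global alignment score under the configured scoring."""
    return float(_aligner(**scoring_overrides).score(a.residues, b.residues))


@dataclass
class IdentityMatrix:
    labels: list[str]
    values: np.ndarray  # symmetric percent identities, diagonal 100

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise SequenceError("matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise SequenceError("identity matrix is not symmetric")
        if not np.allclose(np.diag(v), 100.0):
            raise SequenceError("identity diagonal must be 100")
        self.values = v

    def to_tsv(self) -> str:
        lines = ["\t" + "\t".join(self.labels)]
        for lab, row in zip(self.labels, self.values):
            lines.append(lab + "\t" + "\t".join(f"{x:.6g}" for x in row))
        return "\n".join(lines) + "\n"

    def to_distance(self) -> DistanceMatrix:
        return DistanceMatrix(100.0 - self.values, ids=self.labels)


def identity_matrix(seqs: Sequence[ProteinSequence]) -> IdentityMatrix:
    n = len(seqs)
    v = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            v[i, j] = v[j, i] = global_identity(seqs[i], seqs[j])
    return IdentityMatrix([s.id for s in seqs], v)


def screen_homologs(
    reference: ProteinSequence,
    candidates: Sequence[ProteinSequence],
    threshold: float = 80.0,
) -> list[tuple[str, float]]:
    """Candidates with identity to *reference* strictly above *threshold*.

    Returns (id, identity) sorted by descending identity (id as
    tie-break). The inequality is strict: a candidate at exactly the
    threshold is excluded.
    """
    if not 0 < threshold <= 100:
        raise SequenceError("threshold must lie in (0, 100]")
    hits = [
        (c.id, global_identity(reference, c))
        for c in candidates
    ]
    kept = [(cid, ident) for cid, ident in hits if ident > threshold]
    return sorted(kept, key=lambda t: (-t[1], t[0]))


def nj_tree(im: IdentityMatrix) -> TreeNode:
    """Neighbor-joining tree over 100 - identity distances.

    Requires at least three leaves; the Newick serialization of the
    returned tree round-trips through scikit-bio. Negative branch lengths
    (possible for non-additive inputs under the standard algorithm) are
    preserved as computed.
    """
    if len(im.labels) < 3:
        raise SequenceError("neighbor joining needs at least 3 sequences")
    return nj(im.to_distance())


def tree_to_newick(tree: TreeNode) -> str:
    out = StringIO()
    tree.write(out, format="newick")
    return out.getvalue().strip()


def newick_to_tree(text: str) -> TreeNode:
    return TreeNode.read(StringIO(text), format="newick")
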