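# Methods

This note documents the models, conventions and numerical choices behind
`flavopred`, and what its synthetic study conditions do and do not show
about real data.

## Molecular graph model

Molecules are simple undirected graphs of heavy atoms; hydrogens are
implicit. Each atom carries an element, a formal charge and a
categorical *atom type* from a closed vocabulary (`flavopred.vocab`)
that encodes the local environment: aromatic CH (`C.ar.h`) vs
substituted/fused aromatic C (`C.ar.s`), carbonyl vs carboxyl C,
hydroxyl vs ether vs carbonyl O, and so on. Bond orders are single,
double, triple and a distinct *aromatic* order — never an alternating
Kekulé assignment — so pattern matching is independent of resonance
representation. SMILES input is parsed by RDKit and retyped by the
package's own rules; KCF-style records preserve their type labels
verbatim (labels outside the vocabulary are accepted and logged).
Implicit hydrogen counts follow a fixed element→valence table
(C 4, N 3, O 2, S 2, P 5, halogens 1), with aromatic bonds contributing
1.5 to the valence sum. Stereochemistry is ignored throughout: the
transformation patterns the package mines are constitutional.

Typing is a single local pass — an atom's type depends only on its
element, incident bond orders and neighbour *elements* — which is what
makes operator edit scripts transportable: an edit that retypes an atom
is valid on any substrate site whose matched environment is identical.

### Canonicalization

Product deduplication and deterministic ordering rest on a canonical
key: an iterative-refinement/individualization labeling (initial colors
from atom attributes, refinement by neighbour color multisets,
branching on the first non-singleton cell, lexicographically smallest
certificate). Unlike hash-based graph fingerprints this is exact:
equal keys if and only if isomorphic. Disconnected graphs are
canonicalized per component and joined in sorted order. The certificate
is SHA-1–digested for compact keys; canonical ranks also provide the
deterministic tie-breaks used elsewhere.

## Operator derivation

Given a reactant–product pair with a partial injective conserved-atom
map:

1. A reactant atom is *changed* if it is unmapped (removed), its
   type/charge differs across the map, or its bond environment differs
   (including bonds to removed or newly added atoms).
2. Changed reactant atoms and added product atoms form *change
   regions*: connected components of the union adjacency over both
   sides. One operator is emitted per region and direction. Added
   fragments with no mapped anchor (detached co-products) are folded
   into the first anchored region; a pair that is *only* an unanchored
   addition is rejected.
3. The *reaction center* of a region is its changed reactant atom with
   the most unchanged atoms within two bonds; ties break on canonical
   rank. The pattern is the induced reactant subgraph on atoms within
   two bonds of the center plus all region atoms; the first/second
   shells are recorded as (bond order, atom type) multisets.
4. The edit script lists bond-order changes, bond removals, atom-type/
   charge changes, atom additions (with their bonds) and atom removals,
   each relative to pattern atom ids, in a fixed category-then-
   lexicographic order.

Every derivation is verified by replaying the forward (and, for
reversible pairs, reverse) operators at their source sites and
comparing canonical keys with the recorded product; for multi-region
pairs the composite application is verified, since no single region
regenerates the whole product. Operators are kept per source pair;
deduplication by (pattern, edit) happens in reports via a canonical
*signature* — the canonical key of the pattern graph decorated with
center/exactness/edit marks, plus the direction.

## Matching and application

A site is an embedding (monomorphism with exact atom-type, charge and
bond-order agreement) of the pattern into the substrate, subject to an
*exactness* rule: the center, every first-shell atom and every edited
atom must reproduce their full bonding environment within the matched
image. Second-shell atoms may carry additional substituents — this is
the only place substrate promiscuity is admitted, mirroring a fixed
two-level pattern with no wildcard relaxation. Sites equivalent under a
substrate automorphism are deduplicated by canonicalizing the substrate
with site-role marks. A consequence of the exactness rule is that
operators whose pattern is disconnected (e.g. the condensation
direction of a bond-cleaving hydrolysis, whose reactant is two
fragments) never match a single-molecule substrate; this is the
intended conservative behaviour.

Application copies the substrate, replays the edit script and validates
valences on touched atoms; valence-violating products are dropped and
logged, not raised to the caller. Products may be disconnected; the
prediction pipeline splits them into connected components, so
co-products (the A-ring fragment of a C-ring cleavage, or trivial
leaving groups) become separate records and can be filtered.

Prediction runs one or two rounds — two mirrors the activation/
metabolism two-phase view of xenobiotic transformation, and deeper
recursion is excluded because the method has no reasoning engine to
rank reactions, so the product space explodes. Round-2 substrates are
the deduplicated, policy-filtered round-1 products. The filter policy
is a blocklist of canonical keys (default: water, CO₂, glucose) plus an
optional catalog allow-list; the blocklist wins. All outputs are sorted
by (round, substrate key, operator id, product key) and are therefore
bit-reproducible.

## Organism mapping

EC numbers are validated as `d.d.d.(d|-)`; a wildcard is legal only in
the fourth field, which three-digit matching ignores anyway. Capability
tables count strain–enzyme *incidences*: a strain carrying k distinct
matching ECs contributes k to the numerator (an enzyme count, not a
strain count), normalized by the taxon's strain count. This makes
genus-level tables aggregate exactly to phylum level when weighted by
strain counts — an arithmetic identity the tests assert. Reaction
classes (methylation, hydroxylation, dihydroxylation, hydrogenation,
C-ring cleavage, hydrolysis, with ring-position variants where needed)
are declared on operators, not inferred from edits.

## Similarity and statistics

Atom-pair descriptors are *binary* sets of (type, type, shortest-path
distance) triples with a default distance cap of 7 bonds — presence,
not counts, is the reproducible choice given that binned count
descriptors vary between toolkits; the cap is a parameter. Tanimoto of
two empty descriptors is defined as 1. Descriptors require connected
graphs (topological distance is undefined across components).

Single linkage is implemented directly (Lance–Williams min-update) so
the tie rule is explicit: minimal height first, then the smallest pair
of original item indices. Merge heights equal sorted MST edge weights —
the package asserts this against independent MST and SciPy-linkage
oracles. Flat clusters use an *inclusive* height threshold (merges with
height ≤ h), so a cut at 0 groups exact-descriptor duplicates and a cut
at 1 yields one cluster. Reaction-pair clustering around a query uses
reactant-side descriptors by default (configurable); the judgement of
whether a co-clustered reaction truly resembles the predicted
transformation stays a downstream, human step.

Classical MDS is the Torgerson double-centering eigendecomposition;
negative eigenvalues are truncated, axes with near-zero eigenvalues
contribute zero coordinates (so a fully degenerate all-zero matrix
embeds at the origin), and requesting more axes than there are positive
eigenvalues is an error. Coordinates are re-centered numerically. The
association between two dissimilarity matrices is a Pearson correlation
over strict upper triangles with slope/intercept from a least-squares
fit; significance comes from a two-sided Mantel permutation test
(default 9999 permutations; a seed is mandatory, and seeded runs are
bit-reproducible).

## Homolog screening

"Sequence similarity" is operationalized as global percent identity:
Needleman–Wunsch with BLOSUM62, gap open −11 / extend −1 (Biopython's
`PairwiseAligner`; identity = identical columns / alignment columns,
from the aligner's first optimal alignment, which is deterministic for
fixed scoring). The screen threshold is *strict* (> 80% by default).
Trees are neighbor joining (scikit-bio) over 100 − identity distances —
chosen as the standard distance method where no specific tree method is
dictated; NJ realizes additive matrices exactly, which the tests check
in closed form for three leaves and on an additive four-leaf matrix.

## Synthetic study conditions

The generators define the package's study conditions:

* **Reaction corpora** — default 50 reactions over 20 scaffolds, three
  planted transformations (aromatic O-methylation, aromatic
  hydroxylation, alkene C=C hydrogenation), decoy fraction 0. Scaffolds
  are the planted operators' exemplar contexts grown with 0–4 random
  aliphatic decorations (C chains, terminal hydroxyls) at anchor atoms
  chosen so decorations never enter the two-shell pattern or alter
  anchor types; every reaction is constructed by applying a planted
  operator at a matched site with the conserved-atom map recorded
  exactly. Decoys, when requested, are sp3-carbon hydroxylations with
  shuffled EC labels — structurally disjoint from all planted patterns
  and flagged in the ground truth.
* **Organism matrices** — default 12 strains over four phyla
  (Firmicutes, Bacteroidetes, Actinobacteria, Proteobacteria, assigned
  round-robin with genus/family labels nested inside phyla), planted EC
  carriers plus background ECs drawn at density 0.25 from a pool whose
  three-digit prefixes are disjoint from the planted ones, keeping
  planted carriers exactly recoverable.
* **Homolog sets** — a random 300-residue reference and substitution-
  only mutants at 95/85/70% target identity, so realized gapless
  identity is exact by construction.

Everything is a pure function of its seed. What passing tests show:
the mining/matching/application machinery is internally consistent
(round-trips, planted-pattern recovery, oracle agreement) under
valence-valid but chemically idealized structures. What they do not
show: performance on real reaction databases — real corpora contain
ambiguous atom mappings, cofactor conventions, tautomers and atom-type
vocabularies richer than the shipped one, and real operator libraries
are three orders of magnitude larger. The fixture pathway and aglycone
panel are real structures, but the fixture operator library contains
only the five pathway transformations.

## Known limitations and open choices

* Edit transportability assumes every retyped atom's distance-1
  environment is pinned by the match; region atoms whose unchanged
  neighbours fall outside the pattern (possible for sprawling regions)
  could in principle be retyped incorrectly on exotic substrates.
* Which side of a reaction pair feeds the clustering descriptors
  (reactant vs product) is a parameter; reactant-side is the default.
* The atom-type vocabulary is a documented approximation to
  environment-aware typing schemes used by reaction databases; no
  specific external version is emulated.
* Products are not ranked: every valence-valid application is reported.
* The structural-similarity stage accepts any externally supplied
  dissimilarity matrix; the built-in atom-pair Tanimoto is a substitute
  for, not an emulation of, maximal-common-subgraph similarity scores.
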