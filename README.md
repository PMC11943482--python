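# flavopred

Enzyme-promiscuity prediction of gut-bacterial flavonoid metabolism.

Dietary flavonoids (naringenin, quercetin, apigenin, ...) are transformed
by intestinal bacteria into metabolites with distinct bioactivities, but
for most flavonoid/organism combinations no experimental data exist.
`flavopred` implements the desk half of a prediction–validation workflow
for this problem: it mines *atom-group transformation operators* from
atom-mapped enzymatic reactant–product pairs, applies them promiscuously
to non-natural flavonoid substrates, and maps the candidate enzymes back
to bacterial strains and taxa. It is a library for computational
microbiologists and cheminformaticians, used from Python (see
`examples/`) or through a thin `flavopred` command-line pipeline.

## The method

**Operator mining.** For a reactant–product pair with a conserved-atom
mapping, the connected regions of chemical change are located. For each
region, the changed atom with the largest conserved neighbourhood is the
*reaction center*; the atoms one and two bonds away form the first and
second shells of a matching pattern over environment-aware atom types
(aromatic-C, carbonyl-C, hydroxyl-O, ...); the reactant→product
difference is recorded as an explicit edit script (add/remove atom or
bond, change bond order or atom type). Reactions are reversible by
default, so each pair yields forward and reverse operators.

**Promiscuous application.** An operator applies to a new substrate
wherever its pattern embeds with exact type and bond-order agreement
(the center, first shell and edited atoms must reproduce their entire
bonding environment; substituents beyond the second shell are free —
this is where promiscuity enters). Prediction runs at most two rounds,
mirroring the activation/metabolism two-phase view of xenobiotic
transformation, filters trivial products (water, CO₂, simple sugars) and
optionally restricts to a metabolite catalog, deduplicating products by
a canonical graph key.

**Organism mapping.** Operators carry the EC numbers of their source
enzymes. A strain × EC incidence matrix with taxonomy labels turns
predictions into candidate organisms by matching at *three-digit* EC
resolution (the fourth field encodes the natural substrate, which the
promiscuity premise deliberately ignores), and into per-taxon capability
tables: matching strain–enzyme incidences normalized by strain count.

**Similarity machinery.** Structures are compared by the Tanimoto
coefficient of binary atom-pair descriptors (atom-type pairs × shortest-
path distance, capped at 7 bonds), reaction profiles by Jaccard over
applicable-operator sets. Single-linkage clustering (with merge heights
provably equal to sorted minimum-spanning-tree edge weights) pulls out
reaction pairs resembling a query substrate; classical (Torgerson) MDS
maps dissimilarity matrices — including externally supplied ones — into
the plane, and a seeded Mantel permutation test quantifies the
association between structural and reaction dissimilarities.

**Homolog screening.** Candidate enzymes can be cross-checked by
screening proteomes for homologs of a reference enzyme: global
Needleman–Wunsch percent identity (BLOSUM62, affine gaps), a strict
\>80% threshold, and a neighbor-joining tree over 100 − identity.

Because the licensed reaction databases and genome annotations behind
the original analysis cannot be redistributed, the package ships seeded
generators (`flavopred.synthetic`) for every input — reaction corpora
with planted operators and exact ground truth, organism matrices,
homolog sets — plus a named fixture panel: the naringenin C-ring
cleavage pathway (naringenin → naringenin chalcone → phloretin →
3-(4-hydroxyphenyl)propionic acid + phloroglucinol), 15 flavonoid
aglycones and 4 glucosides.

## Worked example

```sh
python examples/01_predict_naringenin.py
```

prints

```
round  operator                        product
    1  C-ring-opening.f0               naringenin chalcone
    1  direct-flavanone-reduction.f0   phloretin
    2  chalcone-reduction.r0           naringenin chalcone
    2  retro-claisen-hydrolysis.f0     phloroglucinol
    2  retro-claisen-hydrolysis.f0     3,4-HPPA
    2  chalcone-reduction.f0           phloretin
```

Round 1 opens naringenin's heterocyclic C ring to the chalcone (and,
via the direct flavanone-cleaving reduction, to phloretin); round 2
hydrolyzes phloretin's retro-Claisen bond into the B-ring phenolic acid
3,4-HPPA and the A-ring product phloroglucinol. Without the direct
reduction operator the pathway stops at phloretin after two rounds —
3,4-HPPA needs a third step, which the two-round cap deliberately does
not take. The same machinery applied to quercetin's B-ring hydroxyls
yields the known methylated metabolites isorhamnetin and tamarixetin
(`tests/test_acceptance.py`).

The remaining examples mine operators from a synthetic corpus
(`02_mine_operators.py`), map enzymes to taxa (`03_map_taxa.py`),
compare structural and reaction similarity of the aglycone panel
(`04_similarity_and_mds.py`), and screen homolog sets
(`05_screen_homologs.py`).

## Command-line pipeline

```sh
flavopred simulate --seed 1 --out run/sim
flavopred derive   --corpus run/sim/corpus.jsonl --out run/lib
flavopred predict  --substrate naringenin --library fixtures --out run/pred
flavopred match-taxa --matrix run/sim/organism_matrix.tsv --out run/taxa
flavopred cluster  --corpus run/sim/corpus.jsonl --query naringenin --cut 0.8 --out run/clu
flavopred mds      --matrix dissimilarity.tsv --out run/mds
flavopred screen   --fasta run/sim/homologs.fasta --out run/scr
```

Each stage writes its outputs and a `manifest.json`; reruns with the
same configuration and seed are byte-identical.

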