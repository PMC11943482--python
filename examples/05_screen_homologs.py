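"""Screen mutated sequences for reference homologs and build an NJ tree.

Generates a random 300-residue reference protein (standing in for a
chalcone synthase of known flavanone affinity) plus candidates mutated to
95, 85 and 70 percent identity, screens them at the strict >80% global
identity threshold, and prints the neighbor-joining tree over
100 - identity distances.
"""

from flavopred import (
    gen_homolog_set,
    global_identity,
    identity_matrix,
    nj_tree,
    screen_homologs,
    tree_to_newick,
)

seqs, truth = gen_homolog_set(seed=1, reference_length=300,
                              target_identities=(95.0, 85.0, 70.0))
reference, candidates = seqs[0], seqs[1:]

print("global percent identity to the reference (Needleman-Wunsch,")
print("BLOSUM62, gap open -11 / extend -1):")
for c in candidates:
    print(f"  {c.id:<8} {global_identity(reference, c):6.2f}")

hits = screen_homologs(reference, candidates, threshold=80.0)
print()
print(f"homologs above the strict 80% threshold: "
      f"{', '.join(cid for cid, _ in hits)}")
print("(the 70% mutant falls below and is excluded)")

tree = nj_tree(identity_matrix(seqs))
print()
print("neighbor-joining tree (newick):")
print(tree_to_newick(tree))
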