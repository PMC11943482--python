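"""Match predicted enzymes to organisms and tabulate taxon capabilities.

Generates a 12-strain organism x EC matrix (four phyla, planted carriers
of the methylation EC), matches the fixture operators' EC annotations at
three-digit resolution, and prints the strain-normalized capability table
per phylum — the desk-scale analogue of a reaction-by-phylum heatmap.
"""

from flavopred import (
    capability_table,
    class_ec_map,
    fixture_operator_library,
    gen_organism_matrix,
    organisms_for,
)

matrix, truth = gen_organism_matrix(
    seed=1,
    n_strains=12,
    planted_ec_assignments={"2.1.1.6": [0, 4, 8], "5.5.1.6": [1, 2]},
)
lib = fixture_operator_library()

print("operator EC annotations -> candidate strains (3-digit EC match):")
for op in lib:
    if op.direction != "forward":
        continue
    hits = organisms_for(op.ec_numbers, matrix)
    print(f"  {op.id:<32} {';'.join(op.ec_numbers):<12} -> "
          f"{', '.join(hits) if hits else '(none)'}")

table = capability_table(class_ec_map(lib), matrix, level="phylum")
print()
print("capability table (matching enzymes per strain, by phylum):")
print(table.to_matrix().to_string(float_format=lambda v: f"{v:.2f}"))
print()
print("A cell is the count of (strain, EC) incidences in the phylum that")
print("match the reaction class, divided by the phylum's strain count.")
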