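"""Two-round metabolite prediction for naringenin.

Builds the fixture operator library (C-ring opening, chalcone reduction,
retro-Claisen hydrolysis, plus the direct flavanone-cleaving reduction)
and predicts gut-bacterial metabolites of the flavanone naringenin. The
expected degradation pathway appears: naringenin chalcone in round 1,
phloretin in rounds 1-2, and the C-ring cleavage end products
3-(4-hydroxyphenyl)propionic acid (3,4-HPPA) and phloroglucinol in
round 2.
"""

from flavopred import (
    canonical_key,
    compound,
    fixture_operator_library,
    predict_metabolites,
    trivial_blocklist,
)

lib = fixture_operator_library(
    ["C-ring-opening", "chalcone-reduction", "retro-claisen-hydrolysis",
     "direct-flavanone-reduction"]
)
naringenin = compound("naringenin")
records = predict_metabolites(naringenin, lib, rounds=2,
                              policy=trivial_blocklist())

names = {
    canonical_key(compound(n)): n
    for n in ("naringenin", "naringenin chalcone", "phloretin", "3,4-HPPA",
              "phloroglucinol")
}
print("round  operator                        product")
for r in records:
    label = names.get(r.product_key, r.product_key[:12] + "...")
    print(f"{r.round:>5}  {r.operator_id:<30}  {label}")
print()
print(f"{len(records)} prediction records; each row is one (operator, site)")
print("application surviving the trivial-product blocklist. Round-2 rows")
print("start from the deduplicated round-1 products.")
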