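"""Operator derivation, matching, application and two-round prediction."""

import pytest

from flavopred import (
    FilterPolicy,
    OperatorError,
    OperatorLibrary,
    ReactionPair,
    apply_operator,
    canonical_key,
    compound,
    derive_operators,
    filter_products,
    fixture_operator_library,
    graphs_isomorphic,
    match_sites,
    pathway_graphs,
    predict_metabolites,
    read_corpus,
    trivial_blocklist,
    write_corpus,
)
from conftest import benzene, make_graph


def _phenol_pair():
    b = benzene()
    p = b.copy(name="phenol")
    o = p.add_atom("O")
    p.add_bond(1, o, "single")
    from flavopred.vocab import assign_atom_types

    assign_atom_types(p)
    return ReactionPair(
        id="hydrox",
        reactant=b,
        product=p,
        atom_map={i: i for i in range(1, 7)},
        ec_numbers=["1.14.13.39"],
    )


class TestDerive:
    def test_identity_pair_yields_nothing(self):
        g = compound("catechol")
        rp = ReactionPair(
            "noop", g, g.copy(), {i: i for i in g.atom_indices()}, ["1.1.1.1"]
        )
        assert derive_operators(rp) == []

    def test_empty_atom_map_rejected(self):
        with pytest.raises(OperatorError, match="unmappable"):
            derive_operators(
                ReactionPair("bad", benzene(), benzene(), {}, ["1.1.1.1"])
            )

    def test_benzene_hydroxylation(self):
        ops = derive_operators(_phenol_pair())
        fwd = [o for o in ops if o.direction == "forward"]
        rev = [o for o in ops if o.direction == "reverse"]
        assert len(fwd) == 1 and len(rev) == 1
        op = fwd[0]
        assert op.center_type == "C.ar.h"
        added = [s for s in op.edit_script if s["op"] == "add_atom"]
        assert len(added) == 1 and added[0]["atom_type"] == "O.oh"
        # round trip: forward applied at a benzene site gives phenol
        site = match_sites(benzene(), op)[0]
        product = apply_operator(benzene(), op, site)
        assert canonical_key(product) == canonical_key(compound("phenol"))

    def test_chalcone_opening_regenerates_product(self, pathway_pairs):
        rp = pathway_pairs["C-ring-opening"]
        fwd = [o for o in derive_operators(rp) if o.direction == "forward"][0]
        nar = compound("naringenin")
        sites = match_sites(nar, fwd)
        assert len(sites) == 1
        product = apply_operator(nar, fwd, sites[0])
        assert canonical_key(product) == canonical_key(
            compound("naringenin chalcone")
        )

    def test_round_trip_holds_for_all_fixture_pairs(self, pathway_pairs):
        # derive_operators verifies the invariant internally and raises on
        # failure; deriving every fixture pair is the assertion
        for rp in pathway_pairs.values():
            ops = derive_operators(rp)
            assert ops


class TestMatchSites:
    def test_no_label_match(self, full_library):
        op = full_library.get("hydroxyl-O-methylation.f0")
        assert match_sites(benzene(), op) == []

    def test_catechol_symmetric_site_deduplicated(self, full_library):
        op = full_library.get("hydroxyl-O-methylation.f0")
        assert len(match_sites(compound("catechol"), op)) == 1

    def test_quercetin_one_site_per_hydroxyl_environment(self, full_library):
        op = full_library.get("hydroxyl-O-methylation.f0")
        sites = match_sites(compound("quercetin"), op)
        # 3'-OH, 4'-OH and 5-OH share the pattern environment; 3-OH and
        # 7-OH do not
        assert len(sites) == 3


class TestApply:
    def test_catechol_methylation_gives_guaiacol(self, full_library):
        op = full_library.get("hydroxyl-O-methylation.f0")
        c = compound("catechol")
        product = apply_operator(c, op, match_sites(c, op)[0])
        assert graphs_isomorphic(product, compound("guaiacol"))

    def test_quercetin_methylation_gives_known_metabolites(self, full_library):
        op = full_library.get("hydroxyl-O-methylation.f0")
        q = compound("quercetin")
        products = {
            canonical_key(apply_operator(q, op, s)) for s in match_sites(q, op)
        }
        assert canonical_key(compound("isorhamnetin")) in products
        assert canonical_key(compound("tamarixetin")) in products

    def test_inverse_edit_identity(self, full_library):
        fwd = full_library.get("hydroxyl-O-methylation.f0")
        rev = full_library.get("hydroxyl-O-methylation.r0")
        c = compound("catechol")
        methylated = apply_operator(c, fwd, match_sites(c, fwd)[0])
        back = {
            canonical_key(apply_operator(methylated, rev, s))
            for s in match_sites(methylated, rev)
        }
        assert canonical_key(c) in back

    def test_only_named_atoms_change(self, full_library):
        op = full_library.get("hydroxyl-O-methylation.f0")
        q = compound("quercetin")
        site = match_sites(q, op)[0]
        product = apply_operator(q, op, site)
        # heavy-atom delta equals the net adds/removes of the edit script
        adds = sum(1 for s in op.edit_script if s["op"] == "add_atom")
        removes = sum(1 for s in op.edit_script if s["op"] == "remove_atom")
        assert product.n_atoms - q.n_atoms == adds - removes


class TestPredict:
    def test_empty_library(self):
        recs = predict_metabolites(compound("naringenin"), OperatorLibrary([]), 2)
        assert recs == []

    def test_rounds_capped_at_two(self, full_library):
        with pytest.raises(OperatorError):
            predict_metabolites(compound("naringenin"), full_library, 3)

    def test_naringenin_pathway_base_library(self):
        lib = fixture_operator_library(
            ["C-ring-opening", "chalcone-reduction", "retro-claisen-hydrolysis"]
        )
        recs = predict_metabolites(
            compound("naringenin"), lib, 2, trivial_blocklist()
        )
        by_key = {}
        for r in recs:
            by_key.setdefault(r.product_key, set()).add(r.round)
        chalc = canonical_key(compound("naringenin chalcone"))
        phlor = canonical_key(compound("phloretin"))
        hppa = canonical_key(compound("3,4-HPPA"))
        assert by_key[chalc] == {1}
        assert by_key[phlor] == {2}
        assert hppa not in by_key  # needs a third step

    def test_direct_reduction_unlocks_hppa_in_round_two(self):
        lib = fixture_operator_library(
            [
                "C-ring-opening",
                "chalcone-reduction",
                "retro-claisen-hydrolysis",
                "direct-flavanone-reduction",
            ]
        )
        recs = predict_metabolites(
            compound("naringenin"), lib, 2, trivial_blocklist()
        )
        rounds = {}
        for r in recs:
            rounds.setdefault(r.product_key, set()).add(r.round)
        assert 1 in rounds[canonical_key(compound("phloretin"))]
        assert rounds[canonical_key(compound("3,4-HPPA"))] == {2}
        assert rounds[canonical_key(compound("phloroglucinol"))] == {2}

    def test_blocklist_removes_records(self, full_library):
        recs = predict_metabolites(compound("naringenin"), full_library, 2)
        assert recs
        victim = recs[0].product_key
        policy = FilterPolicy(blocklist=frozenset({victim}))
        filtered = predict_metabolites(
            compound("naringenin"), full_library, 2, policy
        )
        assert all(r.product_key != victim for r in filtered)

    def test_composition_of_rounds(self):
        lib = fixture_operator_library(
            ["C-ring-opening", "chalcone-reduction", "hydroxyl-O-methylation"]
        )
        nar = compound("naringenin")
        two = predict_metabolites(nar, lib, 2)
        one = predict_metabolites(nar, lib, 1)
        seeds = {}
        for r in one:
            seeds.setdefault(r.product_key, r.product)
        manual = {(r.round, r.substrate_key, r.operator_id, r.product_key)
                  for r in one}
        for key in sorted(seeds):
            for r in predict_metabolites(seeds[key], lib, 1):
                manual.add((2, r.substrate_key, r.operator_id, r.product_key))
        auto = {(r.round, r.substrate_key, r.operator_id, r.product_key)
                for r in two}
        assert auto == manual

    def test_monotonicity(self):
        nar = compound("naringenin")
        small = fixture_operator_library(["C-ring-opening"])
        big = fixture_operator_library(["C-ring-opening", "chalcone-reduction"])
        keys_small = {r.sort_key() for r in predict_metabolites(nar, small, 2)}
        keys_big = {r.sort_key() for r in predict_metabolites(nar, big, 2)}
        assert keys_small <= keys_big  # adding operators never removes
        loose = predict_metabolites(nar, big, 2)
        tight = predict_metabolites(
            nar, big, 2, FilterPolicy(blocklist=frozenset({loose[0].product_key}))
        )
        assert {r.sort_key() for r in tight} <= {r.sort_key() for r in loose}


class TestFilter:
    def test_empty_policy_is_identity(self, full_library):
        recs = predict_metabolites(compound("catechol"), full_library, 1)
        assert filter_products(recs, FilterPolicy()) == recs

    def test_blocklist_and_catalog(self, full_library):
        recs = predict_metabolites(compound("naringenin"), full_library, 1)
        keys = sorted({r.product_key for r in recs})
        assert len(keys) >= 2
        keep, drop = keys[0], keys[1]
        catalog_only = filter_products(
            recs, FilterPolicy(catalog=frozenset({keep}))
        )
        assert {r.product_key for r in catalog_only} == {keep}
        # blocklist wins over catalog
        both = filter_products(
            recs,
            FilterPolicy(
                blocklist=frozenset({keep}), catalog=frozenset({keep, drop})
            ),
        )
        assert {r.product_key for r in both} == {drop}


class TestCorpusIO:
    def test_corpus_round_trip(self, pathway_pairs):
        pairs = list(pathway_pairs.values())
        text = write_corpus(pairs)
        again = read_corpus(text)
        assert [rp.id for rp in again] == [rp.id for rp in pairs]
        for a, b in zip(pairs, again):
            assert graphs_isomorphic(a.reactant, b.reactant)
            assert graphs_isomorphic(a.product, b.product)
            assert a.atom_map == b.atom_map

    def test_library_json_round_trip(self, full_library):
        again = OperatorLibrary.from_json(full_library.to_json())
        assert {o.id for o in again} == {o.id for o in full_library}
        for op in full_library:
            assert again.get(op.id).signature() == op.signature()
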