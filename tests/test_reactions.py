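"""Reaction parsing: SMILES, SMIRKS/SMARTS rules, MDL .rxn, id resolution."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from enzselect import (
    Molecule,
    parse_reaction_smiles,
    parse_rxn_file,
    parse_smirks_rule,
    reaction_similarity,
    resolve_id_query,
    write_rxn,
)
from enzselect.errors import (
    NotFoundError,
    ReactionFormatError,
    ReactionParseError,
    ValidationError,
)
from enzselect.reactions import canonical_smiles, ec_matches

PAL_SMILES = "N[C@@H](Cc1ccccc1)C(=O)O>>OC(=O)/C=C/c1ccccc1.N"


class TestParseReactionSmiles:
    def test_minimal_two_compound_reaction(self):
        r = parse_reaction_smiles("CCO>>CC=O")
        assert len(r.substrates.members) == 1
        assert len(r.products.members) == 1
        assert r.substrates.members[0][1] == 1
        assert r.preferred_direction == "unknown"

    def test_pal_reaction_has_one_substrate_two_products(self):
        r = parse_reaction_smiles(PAL_SMILES)
        assert len(r.substrates.members) == 1
        assert len(r.products.members) == 2
        # deamination: ammonia is one of the products
        assert Molecule("N") in [m for m, _ in r.products.members]

    def test_duplicate_compounds_merge_into_coefficient(self):
        r = parse_reaction_smiles("CCO.CCO>>CC=O")
        assert len(r.substrates.members) == 1
        assert r.substrates.members[0][1] == 2

    @pytest.mark.parametrize(
        "text,n_components",
        [("CCO.OCC.CC(=O)O>>O", 4), ("CCO.CCO.CCO.C>>O", 5), ("C.C.N.N.N>>O.O", 7)],
    )
    def test_merging_conserves_total_molecule_count(self, text, n_components):
        r = parse_reaction_smiles(text)
        assert r.substrates.total_count + r.products.total_count == n_components

    @settings(max_examples=50, derandomize=True)
    @given(
        subs=st.lists(st.sampled_from(["CCO", "CC=O", "N", "O", "CC(=O)O"]), min_size=1, max_size=5),
        prods=st.lists(st.sampled_from(["CCO", "CC=O", "N", "O", "CC(=O)O"]), min_size=1, max_size=5),
    )
    def test_merge_conserves_count_property(self, subs, prods):
        r = parse_reaction_smiles(".".join(subs) + ">>" + ".".join(prods))
        assert r.substrates.total_count == len(subs)
        assert r.products.total_count == len(prods)

    def test_agents_are_discarded(self):
        r = parse_reaction_smiles("CCO>O>CC=O")
        assert len(r.substrates.members) == 1
        assert len(r.products.members) == 1

    def test_malformed_smiles_names_offender(self):
        with pytest.raises(ReactionParseError, match="not_a_smiles"):
            parse_reaction_smiles("CCO.not_a_smiles>>CC=O")

    @pytest.mark.parametrize("bad", ["CCO>>", ">>CCO", "CCO", "CCO>>C>>O"])
    def test_missing_side_or_separator_rejected(self, bad):
        with pytest.raises((ValidationError, ReactionParseError)):
            parse_reaction_smiles(bad)


class TestCanonicalization:
    def test_idempotent_on_fixture_molecules(self, db):
        seen = {
            m.smiles
            for r in db.reactions.values()
            for m, _ in r.substrates.members + r.products.members
        }
        assert seen
        for s in seen:
            assert canonical_smiles(s) == s

    def test_equal_molecules_compare_equal(self):
        assert Molecule(canonical_smiles("OCC")) == Molecule(canonical_smiles("CCO"))
        assert hash(Molecule("CCO")) == hash(Molecule("CCO", name="ethanol"))


class TestRxnFile:
    def test_cross_parser_consistency(self):
        r1 = parse_reaction_smiles("CCO>>CC=O")
        r2 = parse_rxn_file(write_rxn(r1))
        assert r1.substrates == r2.substrates and r1.products == r2.products

    def test_cross_parser_consistency_on_fixture_reactions(self, db):
        rids = sorted(db.reactions)[:10]
        for rid in rids:
            r = db.reactions[rid]
            rt = parse_rxn_file(write_rxn(r))
            assert rt.substrates == r.substrates
            assert rt.products == r.products

    def test_round_trip_identity(self):
        r = parse_reaction_smiles(PAL_SMILES)
        once = parse_rxn_file(write_rxn(r))
        twice = parse_rxn_file(write_rxn(once))
        assert once.substrates == twice.substrates and once.products == twice.products

    def test_count_mismatch_is_format_error(self):
        text = write_rxn(parse_reaction_smiles("CCO>>CC=O"))
        lines = text.splitlines()
        lines[4] = "  2  1"
        with pytest.raises(ReactionFormatError, match="2\\+1"):
            parse_rxn_file("\n".join(lines))

    def test_missing_header_rejected(self):
        with pytest.raises(ReactionFormatError, match="RXN"):
            parse_rxn_file("not an rxn file")

    def test_v3000_rejected(self):
        text = write_rxn(parse_reaction_smiles("CCO>>CC=O"))
        bad = text.replace("V2000", "V3000", 1)
        with pytest.raises(ReactionFormatError, match="V3000"):
            parse_rxn_file(bad)


class TestSmirksRules:
    def test_pattern_flag_set_on_both_sides(self):
        r = parse_smirks_rule("[C:1](=O)[OH]>>[C:1](=O)[O-]")
        assert all(m.is_pattern for m, _ in r.substrates.members)
        assert all(m.is_pattern for m, _ in r.products.members)

    def test_pattern_free_smarts_degenerates_to_smiles(self):
        rule = parse_smirks_rule("CCO>>CC=O")
        smiles = parse_reaction_smiles("CCO>>CC=O")
        sim = reaction_similarity(rule, smiles)
        assert sim.score == 1.0

    def test_wildcard_pattern_is_fingerprintable(self):
        r = parse_smirks_rule("[#6][OX2H]>>[#6][CX3]=O")
        sim = reaction_similarity(r, r)
        assert sim.score == 1.0

    def test_empty_product_side_rejected(self):
        with pytest.raises(ValidationError):
            parse_smirks_rule("*>>")

    def test_invalid_smarts_rejected(self):
        with pytest.raises(ReactionParseError):
            parse_smirks_rule("[C!>>[C]")


class TestEcMatching:
    @pytest.mark.parametrize(
        "stored,query,match",
        [
            ("1.1.1.1", "1.1.1", True),
            ("1.1.1.1", "1.1.1.1", True),
            ("1.1.2.1", "1.1.1", False),
            ("1.1.-.-", "1.1.1", True),  # '-' in the store is a wildcard
            ("1.1.1.1", "1.1.-", True),  # '-' in the query is a wildcard
            ("1.1", "1.1.1.1", False),  # query more specific than store
        ],
    )
    def test_prefix_semantics(self, stored, query, match):
        assert ec_matches(stored, query) is match


class TestResolveIdQuery:
    def test_exact_ec_returns_pal(self, db):
        hits = resolve_id_query("4.3.1.24", db)
        assert [r.id for r in hits] == ["RX_PAL"]

    def test_ec_prefix_fans_out(self, db):
        hits = resolve_id_query("4.3.1", db)
        ids = {r.id for r in hits}
        assert {"RX_PAL", "RX_SAL"} <= ids

    def test_xref_resolution(self, db):
        hits = resolve_id_query("MNXR-CHS", db)
        assert [r.id for r in hits] == ["RX_CHS"]

    def test_missing_xref_raises_not_found(self, db):
        with pytest.raises(NotFoundError):
            resolve_id_query("RXN-0000", db)

    def test_missing_ec_lists_nearest_prefixes(self, db):
        with pytest.raises(NotFoundError, match="EC prefixes present"):
            resolve_id_query("9.9.9.9", db)
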