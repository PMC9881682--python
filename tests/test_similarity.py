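"""Fingerprints, Tanimoto, and the aggregate reaction similarity score."""

import itertools
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator

from enzselect import (
    Fingerprint,
    Molecule,
    fingerprint_molecule,
    parse_reaction_smiles,
    reaction_similarity,
    side_similarity,
    tanimoto,
)
from enzselect.errors import ValidationError
from enzselect.reactions import ReactionSide
from enzselect.similarity import greedy_assignment


def fp(bits, nbits=1024):
    return Fingerprint(frozenset(bits), nbits=nbits)


class TestTanimoto:
    def test_hand_counted_overlap(self):
        assert tanimoto(fp({1, 2, 3}), fp({2, 3, 4})) == 0.5

    def test_self_similarity(self):
        f = fingerprint_molecule(Molecule("CCO"))
        assert tanimoto(f, f) == 1.0

    def test_symmetry_on_random_bit_vectors(self):
        rng = random.Random(42)
        for _ in range(100):
            a = fp(rng.sample(range(1024), rng.randint(1, 40)))
            b = fp(rng.sample(range(1024), rng.randint(1, 40)))
            assert tanimoto(a, b) == tanimoto(b, a)
            assert 0.0 <= tanimoto(a, b) <= 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            tanimoto(fp({1}, nbits=1024), fp({1}, nbits=2048))

    @settings(max_examples=100, derandomize=True)
    @given(
        a=st.sets(st.integers(0, 1023), min_size=1, max_size=64),
        b=st.sets(st.integers(0, 1023), min_size=1, max_size=64),
    )
    def test_symmetry_bounds_and_identity_property(self, a, b):
        t = tanimoto(fp(a), fp(b))
        assert t == tanimoto(fp(b), fp(a))
        assert 0.0 <= t <= 1.0
        assert tanimoto(fp(a), fp(a)) == 1.0
        assert (t == 1.0) == (a == b)


class TestFingerprint:
    def test_canonicalization_invariance(self):
        from enzselect.reactions import canonical_smiles

        a = fingerprint_molecule(Molecule(canonical_smiles("CCO")))
        b = fingerprint_molecule(Molecule(canonical_smiles("OCC")))
        assert a == b

    def test_matches_reference_morgan_implementation(self):
        """Dual route: our Tanimoto on our bit sets must equal RDKit's
        DataStructs Tanimoto on RDKit's own Morgan bit vectors."""
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=1024)
        pairs = [("CCO", "c1ccccc1"), ("CC(=O)O", "CCC(=O)O"), ("CCO", "CCO")]
        for sa, sb in pairs:
            ref = DataStructs.TanimotoSimilarity(
                gen.GetFingerprint(Chem.MolFromSmiles(sa)),
                gen.GetFingerprint(Chem.MolFromSmiles(sb)),
            )
            ours = tanimoto(
                fingerprint_molecule(Molecule(sa)), fingerprint_molecule(Molecule(sb))
            )
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_dissimilar_molecules_score_low(self):
        val = tanimoto(
            fingerprint_molecule(Molecule("CCO")),
            fingerprint_molecule(Molecule("c1ccccc1")),
        )
        assert val < 0.2

    def test_stereo_ignored(self):
        a = fingerprint_molecule(Molecule("C[C@H](O)C(=O)O"))
        b = fingerprint_molecule(Molecule("C[C@@H](O)C(=O)O"))
        assert a == b


def brute_force_assignment(matrix):
    """Exhaustive optimal one-to-one assignment score over all permutations."""
    n, m = len(matrix), len(matrix[0])
    if n <= m:
        return max(
            sum(matrix[i][p[i]] for i in range(n))
            for p in itertools.permutations(range(m), n)
        )
    return max(
        sum(matrix[p[j]][j] for j in range(m))
        for p in itertools.permutations(range(n), m)
    )


class TestGreedyAssignment:
    def test_never_exceeds_exhaustive_on_random_matrices(self):
        rng = random.Random(7)
        for _ in range(200):
            n, m = rng.randint(1, 4), rng.randint(1, 4)
            matrix = [[rng.random() for _ in range(m)] for _ in range(n)]
            greedy = sum(v for _, _, v in greedy_assignment(matrix))
            assert greedy <= brute_force_assignment(matrix) + 1e-12

    def test_equals_exhaustive_on_diagonal_dominant_matrices(self):
        rng = random.Random(9)
        for _ in range(50):
            n = rng.randint(2, 4)
            matrix = [
                [1.0 if i == j else rng.uniform(0.0, 0.4) for j in range(n)]
                for i in range(n)
            ]
            greedy = sum(v for _, _, v in greedy_assignment(matrix))
            assert greedy == pytest.approx(brute_force_assignment(matrix))

    def test_equals_exhaustive_on_fixture_reaction_pairs(self, db):
        """On real fingerprint matrices (<= 4 compounds per side) greedy
        matches the exhaustive optimum in at least 90% of pairs and never
        exceeds it."""
        sides = []
        for rid in sorted(db.reactions):
            r = db.reactions[rid]
            for side in (r.substrates, r.products):
                if side.total_count <= 4:
                    sides.append(side)
        rng = random.Random(3)
        pairs = [(rng.choice(sides), rng.choice(sides)) for _ in range(150)]
        equal = 0
        for qa, da in pairs:
            qm = [fingerprint_molecule(x) for x in qa.expanded()]
            dm = [fingerprint_molecule(x) for x in da.expanded()]
            matrix = [[tanimoto(a, b) for b in dm] for a in qm]
            greedy = sum(v for _, _, v in greedy_assignment(matrix))
            optimal = brute_force_assignment(matrix)
            assert greedy <= optimal + 1e-12
            equal += abs(greedy - optimal) < 1e-12
        assert equal / len(pairs) >= 0.9

    def test_tie_break_is_lowest_index_pair(self):
        matrix = [[1.0, 1.0], [1.0, 1.0]]
        assert greedy_assignment(matrix) == [(0, 0, 1.0), (1, 1, 1.0)]


def side(*smiles):
    return ReactionSide.from_molecules([Molecule(s) for s in smiles])


class TestSideSimilarity:
    def test_identical_sides(self):
        s = side("CCO", "CC(=O)O")
        assert side_similarity(s, s) == 1.0

    def test_unmatched_compound_penalty(self):
        a, b = "CCO", "c1ccc(O)cc1"
        assert side_similarity(side(a), side(a, b)) == pytest.approx(
            (1.0 + 0.0) / 2
        )

    def test_adding_unmatched_compound_never_increases(self):
        base = side("CC(=O)O", "CCO")
        q = side("CC(=O)O")
        extras = ["c1ccccc1", "NCC(=O)O", "OCC(O)CO", "CC(=O)C(=O)O"]
        prev = side_similarity(q, base)
        grown = ["CC(=O)O", "CCO"]
        for e in extras:
            grown.append(e)
            cur = side_similarity(q, side(*grown))
            assert cur <= prev + 1e-12
            prev = cur

    def test_currency_mask_removes_cofactors(self):
        from enzselect.reactions import canonical_smiles

        mask = frozenset({canonical_smiles("O")})
        q = side("CCO")
        d = side("CCO", "O")
        assert side_similarity(q, d) == 0.5
        assert side_similarity(q, d, mask=mask) == 1.0

    def test_mask_not_applied_when_it_would_empty_a_side(self):
        from enzselect.reactions import canonical_smiles

        mask = frozenset({canonical_smiles("O")})
        q = side("O")
        d = side("O")
        assert side_similarity(q, d, mask=mask) == 1.0


class TestReactionSimilarity:
    def test_self_similarity_forward(self):
        r = parse_reaction_smiles("CCO.O>>CC=O.N")
        sim = reaction_similarity(r, r)
        assert sim.score == 1.0
        assert sim.matched_direction == "forward"

    def test_reversed_query_matches_in_reverse(self):
        q = parse_reaction_smiles("CC=O>>CCO")
        d = parse_reaction_smiles("CCO>>CC=O")
        sim = reaction_similarity(q, d, mode="both")
        assert sim.score == 1.0
        assert sim.matched_direction == "reverse"

    def test_preferred_only_scores_cross_sides(self):
        from dataclasses import replace

        q = parse_reaction_smiles("CC=O>>CCO")
        d = replace(parse_reaction_smiles("CCO>>CC=O"), preferred_direction="forward")
        sim = reaction_similarity(q, d, mode="preferred_only")
        # forward-only comparison crosses substrate/product identities
        expected = (
            side_similarity(q.substrates, d.substrates)
            + side_similarity(q.products, d.products)
        ) / 2
        assert sim.score == pytest.approx(expected)
        assert sim.score < 1.0
        assert sim.matched_direction == "forward"

    def test_preferred_only_falls_back_to_both_when_unknown(self):
        q = parse_reaction_smiles("CC=O>>CCO")
        d = parse_reaction_smiles("CCO>>CC=O")  # preferred_direction unknown
        sim = reaction_similarity(q, d, mode="preferred_only")
        assert sim.score == 1.0

    def test_self_similarity_on_all_fixture_reactions(self, db):
        for rid in sorted(db.reactions):
            r = db.reactions[rid]
            sim = reaction_similarity(r, r)
            assert sim.score == 1.0
            assert sim.matched_direction == "forward"

    def test_query_reversal_immaterial_in_both_mode(self, db):
        q = parse_reaction_smiles("N[C@@H](Cc1ccccc1)C(=O)O>>OC(=O)/C=C/c1ccccc1.N")
        for rid in sorted(db.reactions)[:15]:
            d = db.reactions[rid]
            assert reaction_similarity(q, d).score == pytest.approx(
                reaction_similarity(q.reversed(), d).score
            )

    def test_per_pair_values_bounded(self, db):
        q = parse_reaction_smiles("CCO>>CC=O")
        for rid in sorted(db.reactions)[:10]:
            sim = reaction_similarity(q, db.reactions[rid])
            assert 0.0 <= sim.score <= 1.0
            for _, _, t in sim.per_pair:
                assert 0.0 <= t <= 1.0
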