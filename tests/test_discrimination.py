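"""Species diagnosability: monophyly, haplotype sharing, the failure cascade."""

import numpy as np
import pytest

from barcodeaudit.discrimination import (
    Condition,
    classify_species,
    condition_counts,
    haplotype_sharing,
    is_monophyletic,
    success_rate,
)
from barcodeaudit.distance import DistanceMatrix, distance_matrix
from barcodeaudit.errors import ValidationError
from barcodeaudit.tree import build_nj

from conftest import make_dataset, mutate, random_sequence


def dm(ids, d):
    d = np.asarray(d, dtype=float)
    return DistanceMatrix(ids=tuple(ids), d=d, comparable_sites=np.full(d.shape, 658))


FOUR_TAXON = dm(
    "ABCD",
    [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]],
)  # NJ topology AB|CD


class TestMonophyly:
    def test_separable_subset_is_monophyletic(self):
        t = build_nj(FOUR_TAXON)
        assert is_monophyletic(t, {"A", "B"})
        assert is_monophyletic(t, {"C", "D"})

    def test_interleaved_subset_is_not(self):
        t = build_nj(FOUR_TAXON)
        assert not is_monophyletic(t, {"A", "C"})
        assert is_monophyletic(t, {"A", "B", "C"})  # = complement of leaf D

    def test_singleton_is_monophyletic_by_convention(self):
        t = build_nj(FOUR_TAXON)
        assert is_monophyletic(t, {"A"})

    def test_unknown_leaf_is_error(self):
        t = build_nj(FOUR_TAXON)
        with pytest.raises(ValidationError):
            is_monophyletic(t, {"Z"})

    def test_agrees_with_bipartition_enumeration(self, rng):
        """Brute-force oracle: enumerate every edge's bipartition on random
        trees (n <= 50) and compare for random subsets."""
        from conftest import random_additive_tree, tree_splits

        for trial in range(8):
            n = int(rng.integers(5, 51))
            ids, D, true_splits = random_additive_tree(rng, n)
            t = build_nj(dm(ids, D))
            # oracle: subset separable iff it or its complement is a split side
            all_sides = set()
            full = frozenset(ids)
            for side in tree_splits(t):
                all_sides.add(side)
                all_sides.add(full - side)
            for _ in range(30):
                k = int(rng.integers(1, n))
                subset = frozenset(rng.choice(ids, size=k, replace=False))
                assert is_monophyletic(t, subset) == (subset in all_sides)


class TestHaplotypeSharing:
    def test_conspecific_identity_not_reported(self):
        seq = "A" * 500
        d = make_dataset([("S1", "G", "a", seq), ("S2", "G", "a", seq)])
        assert haplotype_sharing(d) == []

    def test_cross_species_identity_reported_once(self):
        seq = "ACGT" * 125  # 500 bp
        d = make_dataset(
            [("S1", "G", "a", seq), ("S2", "G", "b", seq), ("S3", "G", "b", mutate(np.random.default_rng(0), seq, 2))]
        )
        pairs = haplotype_sharing(d)
        assert len(pairs) == 1
        p = pairs[0]
        assert {p.specimen_a, p.specimen_b} == {"S1", "S2"}
        assert {p.species_a, p.species_b} == {"G a", "G b"}

    def test_short_fragment_below_floor_excluded(self):
        # identical over 238 comparable sites only: below the 400-site floor
        frag = "A" * 238 + "N" * 420
        full = "A" * 658
        d = make_dataset([("S1", "G", "a", frag), ("S2", "G", "b", full)])
        assert haplotype_sharing(d, min_comparable=400) == []
        assert len(haplotype_sharing(d, min_comparable=200)) == 1

    def test_ambiguity_tolerant_identity(self):
        # one N must not break a true match
        a = "ACGT" * 125
        b = a[:100] + "N" + a[101:]
        d = make_dataset([("S1", "G", "a", a), ("S2", "G", "b", b)])
        assert len(haplotype_sharing(d)) == 1


def community(rng):
    """Hand-built community with known conditions.

    Genus G: species a (monophyletic, distinct), b nested inside c
    (c paraphyletic), e sharing a haplotype with f, singleton g.
    """
    L = 658
    root = random_sequence(rng, L)
    anc_a = mutate(rng, root, 30)
    anc_c = mutate(rng, root, 35, 10)
    anc_b = mutate(rng, anc_c, 8)       # b radiates inside c's cluster
    anc_e = mutate(rng, root, 20, 20)
    anc_f = mutate(rng, anc_e, 25)
    shared = mutate(rng, anc_e, 1)
    rows = [
        ("A1", "G", "a", mutate(rng, anc_a, 1)),
        ("A2", "G", "a", mutate(rng, anc_a, 2)),
        ("C1", "G", "c", mutate(rng, anc_c, 1)),
        ("C2", "G", "c", mutate(rng, anc_c, 16, 4)),  # beyond b's node
        ("B1", "G", "b", mutate(rng, anc_b, 1)),
        ("B2", "G", "b", mutate(rng, anc_b, 2)),
        ("E1", "G", "e", shared),
        ("E2", "G", "e", mutate(rng, anc_e, 2)),
        ("F1", "G", "f", shared),
        ("F2", "G", "f", mutate(rng, anc_f, 1)),
        ("S1", "G", "g", mutate(rng, root, 40, 15)),
    ]
    return make_dataset(rows)


class TestClassification:
    def test_hand_built_community_conditions(self, rng):
        d = community(rng)
        t = build_nj(distance_matrix(d))
        got = {a.species: a for a in classify_species(t, d)}
        assert got["G a"].condition is Condition.DISTINCT
        assert got["G g"].condition is Condition.SINGLETON_DISTINCT
        assert got["G b"].condition is Condition.DISTINCT
        assert got["G c"].condition is Condition.PARAPHYLETIC
        assert got["G c"].congeners_involved == ("G b",)
        assert got["G e"].condition is Condition.IDENTICAL_SHARED
        assert got["G f"].condition is Condition.IDENTICAL_SHARED

    def test_sharing_is_symmetric(self, rng):
        d = community(rng)
        t = build_nj(distance_matrix(d))
        got = {a.species: a for a in classify_species(t, d)}
        assert "G f" in got["G e"].shares_haplotype_with
        assert "G e" in got["G f"].shares_haplotype_with

    def test_every_species_gets_exactly_one_condition(self, rng):
        d = community(rng)
        t = build_nj(distance_matrix(d))
        assessments = classify_species(t, d)
        assert len(assessments) == len(d.species_members())
        counts = condition_counts(assessments)
        assert sum(counts.values()) == len(assessments)

    def test_polyphyletic_with_two_congeners(self, rng):
        # species w interdigitated with two congeners: its MRCA spans both
        L = 658
        root = random_sequence(rng, L)
        anc_w = mutate(rng, root, 30)
        anc_x = mutate(rng, anc_w, 10)   # x nests in one part of w
        anc_y = mutate(rng, anc_w, 22, 6)  # y nests in another part
        rows = [
            ("W1", "G", "w", mutate(rng, anc_w, 1)),
            ("W2", "G", "w", mutate(rng, anc_x, 9, 3)),
            ("W3", "G", "w", mutate(rng, anc_y, 8, 3)),
            ("X1", "G", "x", mutate(rng, anc_x, 1)),
            ("X2", "G", "x", mutate(rng, anc_x, 2)),
            ("Y1", "G", "y", mutate(rng, anc_y, 1)),
            ("Y2", "G", "y", mutate(rng, anc_y, 2)),
        ]
        d = make_dataset(rows)
        t = build_nj(distance_matrix(d))
        got = {a.species: a for a in classify_species(t, d)}
        assert got["G w"].condition is Condition.POLYPHYLETIC
        assert set(got["G w"].congeners_involved) == {"G x", "G y"}

    def test_tree_dataset_mismatch_rejected(self, rng):
        d = community(rng)
        t = build_nj(distance_matrix(d))
        d2 = make_dataset([("Z1", "G", "z", "A" * 658), ("Z2", "G", "z", "C" * 658)])
        with pytest.raises(ValidationError):
            classify_species(t, d2)


class TestSuccessRate:
    def test_all_distinct(self, rng):
        d = community(rng)
        t = build_nj(distance_matrix(d))
        assessments = [a for a in classify_species(t, d) if a.success]
        n_ok, n_tot, prop = success_rate(assessments)
        assert prop == 1.0

    def test_empty_is_error(self):
        with pytest.raises(ValidationError):
            success_rate([])

    def test_proportion_arithmetic(self, rng):
        d = community(rng)
        t = build_nj(distance_matrix(d))
        n_ok, n_tot, prop = success_rate(classify_species(t, d))
        assert n_tot == 6
        assert prop == pytest.approx(n_ok / n_tot)
        # community has 3 failures: c (paraphyletic), e and f (shared)
        assert n_ok == 3
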