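"""Divergence partitioning, deep-split clustering, histograms."""

import numpy as np
import pytest

from barcodeaudit.distance import DistanceMatrix, distance_matrix
from barcodeaudit.divergence import (
    divergence_summary,
    flag_deep_splits,
    histogram,
    split_clusters,
)
from barcodeaudit.errors import ValidationError

from conftest import make_dataset, mutate, random_sequence


def dm(ids, d_pct):
    """Distance matrix from a percent-valued array."""
    d = np.asarray(d_pct, dtype=float) / 100.0
    return DistanceMatrix(ids=tuple(ids), d=d, comparable_sites=np.full(d.shape, 658))


class TestHistogram:
    def test_empty_input_gives_zero_counts(self):
        edges, counts = histogram([], bin_width=1.0, n_bins=3)
        assert counts.sum() == 0 and len(counts) == 3

    def test_left_closed_right_open(self):
        edges, counts = histogram([0.0, 0.5, 1.0], bin_width=1.0)
        assert list(counts) == [2, 1]
        assert list(edges) == [0.0, 1.0, 2.0]

    def test_negative_value_rejected(self):
        with pytest.raises(ValidationError):
            histogram([-0.1])

    def test_counts_match_brute_force_binning(self, rng):
        values = rng.uniform(0, 12, size=400)
        w = 0.5
        edges, counts = histogram(values, bin_width=w)
        brute = [sum(1 for v in values if e <= v < e + w) for e in edges[:-1]]
        assert list(counts) == brute
        assert counts.sum() == len(values)


class TestSummary:
    def test_two_conspecific_specimens(self):
        m = dm(["S1", "S2"], [[0, 1.0], [1.0, 0]])
        d = make_dataset([("S1", "G", "a", "ACGT"), ("S2", "G", "a", "ACGT")])
        s = divergence_summary(m, d)
        assert s.n_intra_pairs == 1
        assert s.mean_intra_pct == pytest.approx(1.0)
        assert s.n_congeneric_pairs == 0

    def test_pair_counting_within_genus(self):
        # genus with species a (2 specimens) and b (1): 2 congeneric, 1 intra
        m = dm(["S1", "S2", "S3"], [[0, 1, 8], [1, 0, 9], [8, 9, 0]])
        d = make_dataset(
            [("S1", "G", "a", "ACGT"), ("S2", "G", "a", "ACGT"), ("S3", "G", "b", "ACGT")]
        )
        s = divergence_summary(m, d)
        assert s.n_intra_pairs == 1
        assert s.n_congeneric_pairs == 2
        assert s.mean_congeneric_pct == pytest.approx(8.5)

    def test_cross_genus_pairs_excluded_but_conserved(self, rng):
        rows = []
        root = random_sequence(rng, 200)
        for g in "GH":
            base = mutate(rng, root, 12, 4)
            for sp in "ab":
                anc = mutate(rng, base, 6)
                for k in range(3):
                    rows.append((f"{g}{sp}{k}", g, sp, mutate(rng, anc, 1)))
        d = make_dataset(rows)
        m = distance_matrix(d)
        s = divergence_summary(m, d)
        n = len(d)
        assert s.n_intra_pairs + s.n_congeneric_pairs + s.n_other_pairs == n * (n - 1) // 2
        # 2 genera x (3+3 specimens): cross-genus = 36 pairs
        assert s.n_other_pairs == 36

    def test_histogram_counts_sum_to_comparisons(self, rng):
        rows = []
        base = random_sequence(rng, 300)
        for sp in "abc":
            anc = mutate(rng, base, 10)
            for k in range(4):
                rows.append((f"{sp}{k}", "G", sp, mutate(rng, anc, 2)))
        d = make_dataset(rows)
        s = divergence_summary(distance_matrix(d), d)
        assert s.intra_counts.sum() == s.n_intra_pairs
        assert s.congeneric_counts.sum() == s.n_congeneric_pairs

    def test_per_species_only_multispecimen(self):
        m = dm(["S1", "S2", "S3"], [[0, 1, 8], [1, 0, 9], [8, 9, 0]])
        d = make_dataset(
            [("S1", "G", "a", "ACGT"), ("S2", "G", "a", "ACGT"), ("S3", "G", "b", "ACGT")]
        )
        s = divergence_summary(m, d)
        assert list(s.per_species["species"]) == ["G a"]
        assert list(s.per_species["n"]) == [2]


class TestSplitClusters:
    def test_all_close_single_cluster(self):
        m = dm("ABC", [[0, 0.5, 0.5], [0.5, 0, 0.5], [0.5, 0.5, 0]])
        assert split_clusters(m, ["A", "B", "C"]) == [["A", "B", "C"]]

    def test_two_groups_split_with_sizes(self):
        # the "1/20"-style pattern, scaled down: 1 vs 3 at 4% separation
        ids = ["X", "A1", "A2", "A3"]
        d = [[0, 4, 4, 4], [4, 0, 1, 1], [4, 1, 0, 1], [4, 1, 1, 0]]
        clusters = split_clusters(dm(ids, d), ids)
        assert sorted(len(c) for c in clusters) == [1, 3]

    def test_single_linkage_chains(self):
        # a-b = 2.9, b-c = 2.9, a-c = 5: chained into one cluster
        m = dm("abc", [[0, 2.9, 5], [2.9, 0, 2.9], [5, 2.9, 0]])
        assert len(split_clusters(m, ["a", "b", "c"])) == 1

    def test_equals_connected_components_oracle(self, rng):
        """Brute-force union-find on the threshold graph, n <= 100."""
        for _ in range(10):
            n = int(rng.integers(5, 101))
            base = rng.uniform(0, 0.08, size=(n, n))
            D = (base + base.T) / 2
            np.fill_diagonal(D, 0)
            ids = [f"S{i}" for i in range(n)]
            m = DistanceMatrix(ids=tuple(ids), d=D, comparable_sites=np.full((n, n), 658))
            got = {frozenset(c) for c in split_clusters(m, ids, threshold_pct=3.0)}
            # oracle: naive union-find
            parent = list(range(n))

            def find(x):
                while parent[x] != x:
                    parent[x] = parent[parent[x]]
                    x = parent[x]
                return x

            for i in range(n):
                for j in range(i + 1, n):
                    if D[i, j] <= 0.03:
                        parent[find(i)] = find(j)
            comp = {}
            for i in range(n):
                comp.setdefault(find(i), set()).add(ids[i])
            assert got == {frozenset(c) for c in comp.values()}


class TestDeepSplits:
    def make_community(self):
        ids = ["A1", "A2", "B1", "B2", "B3", "C1"]
        # species a: max intra 2.9% (not flagged); species b: two clusters
        d = [
            [0, 2.9, 9, 9, 9, 12],
            [2.9, 0, 9, 9, 9, 12],
            [9, 9, 0, 1, 4.5, 12],
            [9, 9, 1, 0, 4.5, 12],
            [9, 9, 4.5, 4.5, 0, 12],
            [12, 12, 12, 12, 12, 0],
        ]
        data = make_dataset(
            [
                ("A1", "G", "a", "ACGT"), ("A2", "G", "a", "ACGT"),
                ("B1", "G", "b", "ACGT"), ("B2", "G", "b", "ACGT"), ("B3", "G", "b", "ACGT"),
                ("C1", "G", "c", "ACGT"),
            ]
        )
        return dm(ids, d), data

    def test_boundary_strictly_greater(self):
        m, d = self.make_community()
        reports = {r.species: r for r in flag_deep_splits(m, d, threshold_pct=3.0)}
        assert not reports["G a"].flagged          # max 2.9% <= 3%
        assert reports["G b"].flagged              # 4.5% split
        assert reports["G b"].cluster_sizes == (2, 1)
        assert reports["G b"].lineage_string == "2/1"

    def test_singletons_excluded(self):
        m, d = self.make_community()
        assert "G c" not in {r.species for r in flag_deep_splits(m, d)}

    def test_three_cluster_pattern(self, rng):
        # clusters sized 2/4/3 at mutual >= 4%: flagged with three clusters
        sizes = [2, 4, 3]
        ids, rows_d = [], []
        n = sum(sizes)
        D = np.full((n, n), 5.0)
        start = 0
        for ci, sz in enumerate(sizes):
            for k in range(sz):
                ids.append(f"C{ci}_{k}")
            D[start:start + sz, start:start + sz] = 0.8
            start += sz
        np.fill_diagonal(D, 0)
        data = make_dataset([(i, "G", "s", "ACGT") for i in ids])
        reports = flag_deep_splits(dm(ids, D), data)
        assert reports[0].flagged
        assert sorted(reports[0].cluster_sizes) == [2, 3, 4]

    def test_mean_is_over_all_pairs(self):
        m, d = self.make_community()
        reports = {r.species: r for r in flag_deep_splits(m, d)}
        assert reports["G b"].mean_intra_pct == pytest.approx((1 + 4.5 + 4.5) / 3)
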