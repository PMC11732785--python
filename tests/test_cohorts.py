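import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from webprint import (
    DistanceMatrix,
    Partition,
    WebMetadata,
    between_group_dispersion,
    decade_summary,
    ecosystem_table,
    mds_embed,
    partition_from_metadata,
    publication_effect,
    publication_weighted_mean,
    size_confound,
    threshold_shares,
    within_group_dispersion,
)


def dm(ids, triples):
    """DistanceMatrix from (a, b, d) triples."""
    n = len(ids)
    values = np.zeros((n, n))
    idx = {w: i for i, w in enumerate(ids)}
    for a, b, d in triples:
        values[idx[a], idx[b]] = values[idx[b], idx[a]] = d
    return DistanceMatrix(web_ids=list(ids), values=values)


@pytest.fixture
def abc():
    return dm("ABC", [("A", "B", 1.0), ("A", "C", 2.0), ("B", "C", 3.0)])


class TestWithinGroup:
    def test_mean_and_median(self, abc):
        assert within_group_dispersion(abc, {"A", "B", "C"}, "mean").value == 2.0
        assert within_group_dispersion(abc, {"A", "B", "C"}, "median").value == 2.0

    def test_pair_group_both_statistics(self, abc):
        for stat in ("mean", "median"):
            s = within_group_dispersion(abc, {"A", "B"}, stat)
            assert s.value == 1.0 and s.n_pairs == 1

    def test_identical_webs_zero(self):
        D = dm("AB", [("A", "B", 0.0)])
        assert within_group_dispersion(D, {"A", "B"}).value == 0.0

    def test_single_web_rejected(self, abc):
        with pytest.raises(ValueError, match="insufficient webs"):
            within_group_dispersion(abc, {"A"})

    def test_permutation_invariant(self, abc):
        a = within_group_dispersion(abc, ["C", "A", "B"]).value
        b = within_group_dispersion(abc, ["A", "B", "C"]).value
        assert a == b


class TestBetweenGroup:
    def test_singletons(self, abc):
        assert between_group_dispersion(abc, {"A"}, {"B"}).value == 1.0

    def test_one_to_many(self, abc):
        s = between_group_dispersion(abc, {"A"}, {"B", "C"})
        assert s.value == pytest.approx(1.5)
        assert s.n_pairs == 2

    def test_overlap_rejected(self, abc):
        with pytest.raises(ValueError, match="overlap"):
            between_group_dispersion(abc, {"A", "B"}, {"B", "C"})

    def test_empty_rejected(self, abc):
        with pytest.raises(ValueError, match="nonempty"):
            between_group_dispersion(abc, set(), {"B"})


class TestPublicationWeightedMean:
    def test_closed_form(self):
        assert publication_weighted_mean([(1.0, 2), (2.0, 4)]) == pytest.approx(5 / 3)

    def test_single_publication_identity(self):
        assert publication_weighted_mean([(1.51, 5)]) == 1.51

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            publication_weighted_mean([])

    def test_singleton_publication_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            publication_weighted_mean([(1.0, 1)])

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.lists(st.tuples(st.floats(0, 15), st.integers(2, 40)),
                    min_size=1, max_size=10))
    def test_bounded_by_min_and_max(self, per_pub):
        w = publication_weighted_mean(per_pub)
        values = [v for v, _ in per_pub]
        assert min(values) - 1e-9 <= w <= max(values) + 1e-9


def toy_meta():
    return [
        WebMetadata("A", "P1", 1989, "aquatic", "lake"),
        WebMetadata("B", "P1", 1989, "aquatic", "lake"),
        WebMetadata("C", "P2", 1990, "terrestrial"),
        WebMetadata("D", "P2", 1990, "terrestrial"),
        WebMetadata("E", "P3", 1990, "aquatic_and_terrestrial"),
        WebMetadata("F", "P4", 1991, "aquatic", "marine"),
    ]


def toy_D(within=1.0, across=3.0):
    ids = list("ABCDEF")
    triples = []
    pubs = {"A": "P1", "B": "P1", "C": "P2", "D": "P2", "E": "P3", "F": "P4"}
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            triples.append((a, b, within if pubs[a] == pubs[b] else across))
    return dm(ids, triples)


class TestEcosystemTable:
    def test_all_cells_present(self):
        table = ecosystem_table(toy_D(), toy_meta())
        pairs = set(zip(table["group1"], table["group2"]))
        classes = ["aquatic", "aquatic_and_terrestrial", "terrestrial"]
        for i, a in enumerate(classes):
            for b in classes[i:]:
                assert (a, b) in pairs

    def test_insufficient_within_cell_flagged_not_zero(self):
        table = ecosystem_table(toy_D(), toy_meta())
        row = table[(table.group1 == "aquatic_and_terrestrial")
                    & (table.group2 == "aquatic_and_terrestrial")].iloc[0]
        assert np.isnan(row["value"]) and row["note"] == "insufficient webs"

    def test_drop_publication_switch(self):
        full = ecosystem_table(toy_D(), toy_meta())
        dropped = ecosystem_table(toy_D(), toy_meta(), drop_publication="P2")
        t_row = dropped[(dropped.group1 == "terrestrial") & (dropped.group2 == "terrestrial")]
        assert t_row.iloc[0]["n_webs"] == 0
        assert full[(full.group1 == "terrestrial")
                    & (full.group2 == "terrestrial")].iloc[0]["n_webs"] == 2


class TestPublicationEffect:
    def test_toy_ratio(self):
        part = Partition({"A": "P1", "B": "P1", "C": "P2", "D": "P2",
                          "E": "P3", "F": "P4"})
        eff = publication_effect(toy_D(), part)
        assert eff["within"] == 1.0 and eff["between"] == 3.0
        assert eff["ratio"] == 3.0

    def test_partition_from_metadata_decade(self):
        part = partition_from_metadata(toy_meta(), "decade")
        assert part.labels["A"] == "1980" and part.labels["C"] == "1990"


class TestDecadeSummary:
    def test_floor_rule_splits_1989_and_1990(self):
        table = decade_summary(toy_D(), toy_meta())
        assert set(table["decade"]) == {1980, 1990}

    def test_single_multiweb_publication_equals_within_dispersion(self):
        meta = toy_meta()
        D = toy_D()
        table = decade_summary(D, meta)
        row = table[(table.decade == 1980) & (table.grouping == "multi_webs_per_publication")]
        expected = within_group_dispersion(D, {"A", "B"}).value
        assert row.iloc[0]["value"] == pytest.approx(expected)


class TestThresholdShares:
    def test_constructed_toy(self):
        table = threshold_shares(toy_D(within=1.0, across=3.0), toy_meta(), [2.0])
        row = table.iloc[0]
        assert row["share_same_publication"] == 1.0
        assert row["share_other_pairs"] == 0.0
        assert row["frac_below_from_same_publication"] == 1.0

    def test_all_zero_distances(self):
        D = toy_D(within=0.0, across=0.0)
        row = threshold_shares(D, toy_meta(), [2.5]).iloc[0]
        assert row["share_same_publication"] == 1.0
        assert row["share_one_web_per_publication"] == 1.0
        assert row["share_other_pairs"] == 1.0

    def test_cutoff_below_minimum(self):
        row = threshold_shares(toy_D(within=1.0, across=3.0), toy_meta(), [0.5]).iloc[0]
        assert row["share_same_publication"] == 0.0
        assert row["share_other_pairs"] == 0.0

    def test_nonpositive_cutoff_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            threshold_shares(toy_D(), toy_meta(), [0.0])


class TestMDS:
    def test_equilateral_triangle(self, ):
        D = dm("ABC", [("A", "B", 1.0), ("A", "C", 1.0), ("B", "C", 1.0)])
        coords, _ = mds_embed(D, dims=2)
        pts = coords.to_numpy()
        for i in range(3):
            for j in range(i + 1, 3):
                assert np.linalg.norm(pts[i] - pts[j]) == pytest.approx(1.0, abs=1e-8)

    def test_euclidean_matrix_reproduced_in_full_dimension(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(6, 3))
        from scipy.spatial.distance import pdist, squareform
        D = DistanceMatrix(web_ids=[f"w{i}" for i in range(6)],
                           values=squareform(pdist(X)))
        coords, stress = mds_embed(D, dims=5)
        emb = squareform(pdist(coords.to_numpy()))
        assert np.allclose(emb, D.values, atol=1e-8)
        assert stress == pytest.approx(0.0, abs=1e-8)

    def test_two_webs(self):
        D = dm("AB", [("A", "B", 2.5)])
        coords, _ = mds_embed(D, dims=1)
        assert abs(coords.iloc[0, 0] - coords.iloc[1, 0]) == pytest.approx(2.5)

    def test_dims_too_large(self, abc):
        with pytest.raises(ValueError, match="dims"):
            mds_embed(abc, dims=3)


class TestSizeConfound:
    @staticmethod
    def random_case(n_groups, seed, size_spread=True):
        rng = np.random.default_rng(seed)
        ids, labels, sizes = [], {}, {}
        for g in range(n_groups):
            for k in range(2):
                wid = f"g{g:02d}w{k}"
                ids.append(wid)
                labels[wid] = f"g{g:02d}"
                sizes[wid] = int(rng.integers(10, 100)) if size_spread else 50
        n = len(ids)
        upper = rng.uniform(0.5, 4.0, size=(n, n))
        values = np.triu(upper, 1)
        values = values + values.T
        return DistanceMatrix(ids, values), sizes, Partition(labels)

    def test_independent_structure_gives_small_rho(self):
        D, sizes, part = self.random_case(30, seed=42)
        table = size_confound(D, sizes, part)
        group_rows = table[table.level == "group"]
        assert (group_rows["rho"].abs() < 0.2).all()

    def test_constant_sizes_flagged_not_zero(self):
        D, sizes, part = self.random_case(5, seed=1, size_spread=False)
        table = size_confound(D, sizes, part)
        row = table[table.predictor == "group_sd_size"].iloc[0]
        assert np.isnan(row["rho"]) and row["note"] == "constant input"

    def test_insufficient_groups_rejected(self):
        D, sizes, part = self.random_case(2, seed=3)
        with pytest.raises(ValueError, match="3 groups"):
            size_confound(D, sizes, part)
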