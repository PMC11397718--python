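"""Feature standardization, agglomeration (vs a brute-force oracle),
two-level cutting and group summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest

from pollenstats import (
    build_feature_matrix,
    cut_two_level,
    group_summaries,
    hierarchical_cluster,
    to_newick,
)
from pollenstats.cluster import DEFAULT_FEATURES

from conftest import table_from_values


def naive_agglomeration(X: np.ndarray, method: str):
    """O(n^3) Lance-Williams agglomeration on Euclidean distances.

    Independent oracle: returns the merge sequence as a list of
    (frozenset of leaf indices, height).
    """
    n = len(X)
    d = {frozenset((i, j)): float(np.linalg.norm(X[i] - X[j]))
         for i, j in itertools.combinations(range(n), 2)}
    sizes = {i: 1 for i in range(n)}
    members = {i: frozenset([i]) for i in range(n)}
    active = set(range(n))
    merges = []
    nxt = n
    while len(active) > 1:
        i, j = min(itertools.combinations(sorted(active), 2),
                   key=lambda p: d[frozenset(p)])
        dij = d[frozenset((i, j))]
        merges.append((members[i] | members[j], dij))
        k = nxt
        nxt += 1
        for m in active - {i, j}:
            dim, djm = d[frozenset((i, m))], d[frozenset((j, m))]
            if method == "complete":
                dk = max(dim, djm)
            elif method == "average":
                dk = (sizes[i] * dim + sizes[j] * djm) / (sizes[i] + sizes[j])
            elif method == "ward":
                si, sj, sm = sizes[i], sizes[j], sizes[m]
                dk = np.sqrt(((si + sm) * dim ** 2 + (sj + sm) * djm ** 2
                              - sm * dij ** 2) / (si + sj + sm))
            else:
                raise ValueError(method)
            d[frozenset((k, m))] = float(dk)
        sizes[k] = sizes[i] + sizes[j]
        members[k] = members[i] | members[j]
        active -= {i, j}
        active.add(k)
    return merges


def merge_sequence(dendro):
    """The scipy linkage as (frozenset of leaves, height) per merge."""
    Z = dendro.linkage_matrix
    n = dendro.n_leaves
    members = {i: frozenset([i]) for i in range(n)}
    out = []
    for r, (a, b, h, _) in enumerate(Z):
        merged = members[int(a)] | members[int(b)]
        members[n + r] = merged
        out.append((merged, float(h)))
    return out


def feature_frame(X: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(X, index=[f"t{i}" for i in range(len(X))],
                        columns=[f"f{j}" for j in range(X.shape[1])])


class TestFeatureMatrix:
    def test_standardization_identity(self, small_study):
        Z = build_feature_matrix(small_study.table)
        assert np.all(np.abs(Z.mean(axis=0)) < 1e-10)
        assert np.allclose(Z.std(axis=0, ddof=0), 1.0)
        assert list(Z.columns) == list(DEFAULT_FEATURES)

    def test_taxa_missing_a_feature_are_excluded(self):
        values = {
            "a": {"P": [40, 41], "E": [22, 23], "Eprime": [19, 19],
                  "RW": [0.2, 0.2], "FW": [0.1, 0.12], "PD": [2, 3]},
            "b": {"P": [30, 31], "E": [21, 22], "Eprime": [18, 18],
                  "RW": [0.15, 0.16], "FW": [0.2, 0.21], "PD": [5, 6]},
            "c": {"P": [35, 36], "E": [24, 25], "Eprime": [20, 20],
                  "RW": [0.22, 0.23], "FW": [0.05, 0.06]},  # no PD
        }
        Z = build_feature_matrix(table_from_values(values))
        assert "c" not in Z.index and Z.attrs["excluded_taxa"] == ["c"]

    def test_constant_feature_raises_with_name(self, small_study):
        table = small_study.table
        df = table.data.copy()
        df.loc[df["trait"] == "RW", "value"] = 0.2
        from pollenstats import TraitTable
        flat = TraitTable(df, expected_replicates=table.expected_replicates)
        with pytest.raises(ValueError, match="RW"):
            build_feature_matrix(flat)

    def test_duplicate_taxa_get_identical_features(self):
        values = {"a": {"P": [40, 41], "E": [22, 23], "Eprime": [19, 19],
                        "RW": [0.2, 0.21], "FW": [0.1, 0.12], "PD": [2, 3]}}
        values["a_copy"] = values["a"]
        values["b"] = {"P": [30, 31], "E": [26, 27], "Eprime": [21, 21],
                       "RW": [0.15, 0.16], "FW": [0.2, 0.21], "PD": [5, 6]}
        Z = build_feature_matrix(table_from_values(values))
        assert np.allclose(Z.loc["a"], Z.loc["a_copy"], atol=1e-12)


class TestAgglomerationOracle:
    def test_two_taxa_single_merge_at_pairwise_distance(self):
        X = np.array([[0.0, 0.0], [3.0, 4.0]])
        dendro = hierarchical_cluster(feature_frame(X))
        [(merged, h)] = merge_sequence(dendro)
        assert merged == frozenset({0, 1}) and h == pytest.approx(5.0)

    @pytest.mark.parametrize("method", ["ward", "average", "complete"])
    def test_small_instances_match_bruteforce(self, method):
        rng = np.random.default_rng(7)
        for _ in range(10):
            n = int(rng.integers(3, 9))
            X = rng.normal(size=(n, 3))
            dendro = hierarchical_cluster(feature_frame(X), linkage=method)
            got = merge_sequence(dendro)
            expected = naive_agglomeration(X, method)
            for (ma, ha), (mb, hb) in zip(got, expected):
                assert ma == mb
                assert ha == pytest.approx(hb, abs=1e-8)

    def test_nan_features_rejected(self):
        X = np.array([[0.0, np.nan], [1.0, 2.0]])
        with pytest.raises(ValueError):
            hierarchical_cluster(feature_frame(X))


class TestTwoLevelCut:
    @staticmethod
    def blobs(sizes, spread=0.05, seed=0):
        rng = np.random.default_rng(seed)
        rows, names = [], []
        for b, size in enumerate(sizes):
            centre = np.array([10.0 * b, -5.0 * b, 3.0 * b])
            for i in range(size):
                rows.append(centre + rng.normal(0.0, spread, 3))
                names.append(f"b{b}_{i}")
        return pd.DataFrame(rows, index=names,
                            columns=["f0", "f1", "f2"])

    def test_largest_group_gets_last_letter_and_subsplit(self):
        F = self.blobs([7, 6, 6, 30])
        result = cut_two_level(hierarchical_cluster(F), k_top=4, k_sub=3)
        sizes = pd.Series(result.group_of).value_counts()
        assert sizes["D"] == 30 and result.largest_group == "D"
        assert set(result.subgroup_of.values()) == {"D1", "D2", "D3"}
        assert all(result.group_of[t] == "D" for t in result.subgroup_of)
        assert sorted(sizes.index) == ["A", "B", "C", "D"]

    def test_two_blobs_first_cut_separates(self):
        F = self.blobs([5, 5])
        result = cut_two_level(hierarchical_cluster(F), k_top=2, k_sub=2)
        groups = {t: g for t, g in result.group_of.items()}
        assert len({groups[t] for t in F.index if t.startswith("b0")}) == 1
        assert groups["b0_0"] != groups["b1_0"]

    def test_every_taxon_its_own_group_boundary(self):
        F = self.blobs([2, 2])
        result = cut_two_level(hierarchical_cluster(F), k_top=4, k_sub=1)
        assert len(set(result.group_of.values())) == 4

    def test_k_exceeding_taxa_raises(self):
        F = self.blobs([2, 2])
        with pytest.raises(ValueError):
            cut_two_level(hierarchical_cluster(F), k_top=5)

    def test_relabelling_taxa_does_not_change_partition(self):
        F = self.blobs([4, 5, 8])
        res1 = cut_two_level(hierarchical_cluster(F), k_top=3, k_sub=2)
        renamed = F.rename(index={t: f"x_{t}" for t in F.index})
        res2 = cut_two_level(hierarchical_cluster(renamed), k_top=3, k_sub=2)
        for t in F.index:
            assert res1.group_of[t] == res2.group_of[f"x_{t}"]

    def test_heights_nondecreasing(self, small_study):
        Z = build_feature_matrix(small_study.table)
        dendro = hierarchical_cluster(Z)
        heights = dendro.linkage_matrix[:, 2]
        assert (np.diff(heights) >= -1e-12).all()


class TestGroupSummaries:
    def test_null_groups_share_letters(self):
        # all taxa from one distribution: expect shared letters mostly
        shared = 0
        runs = 20
        for i in range(runs):
            rng = np.random.default_rng(i)
            values = {
                f"t{j}": {"P": 40 + rng.normal(0, 2, 3),
                          "E": 24 + rng.normal(0, 1, 3),
                          "Eprime": 20 + rng.normal(0, 1, 3),
                          "RW": 0.2 + 0.01 * np.abs(rng.normal(0, 1, 3)),
                          "FW": 0.1 + 0.01 * np.abs(rng.normal(0, 1, 3)),
                          "PD": 3 + np.abs(rng.normal(0, 1, 3))}
                for j in range(12)
            }
            table = table_from_values(values)
            result = cut_two_level(
                hierarchical_cluster(build_feature_matrix(table)),
                k_top=3, k_sub=2)
            summ = group_summaries(table, result)
            p_rows = summ[(summ["level"] == "group") & (summ["trait"] == "P")]
            letters = list(p_rows["letter"])
            if any(set(a) & set(b) for a, b in
                   itertools.combinations(letters, 2)):
                shared += 1
        assert shared >= 0.9 * runs

    def test_shifted_group_gets_distinct_letter(self):
        rng = np.random.default_rng(3)
        values = {}
        for j in range(12):
            shift = 25.0 if j < 4 else 0.0  # one block +many sd in P
            values[f"t{j}"] = {
                "P": 40 + shift + rng.normal(0, 1, 4),
                "E": 24 + 0.05 * rng.normal(0, 1, 4),
                "Eprime": 20 + 0.05 * rng.normal(0, 1, 4),
                "RW": 0.2 + 0.001 * np.abs(rng.normal(0, 1, 4)),
                "FW": 0.1 + 0.001 * np.abs(rng.normal(0, 1, 4)),
                "PD": 3 + 0.05 * np.abs(rng.normal(0, 1, 4))}
        table = table_from_values(values)
        # cluster on the shifted axis (z-scoring would otherwise give
        # the five noise features equal weight to the one signal)
        result = cut_two_level(
            hierarchical_cluster(build_feature_matrix(
                table, features=("P", "E"))), k_top=2, k_sub=2)
        summ = group_summaries(table, result)
        p_rows = summ[(summ["level"] == "group")
                      & (summ["trait"] == "P")].set_index("label")
        hi = p_rows["mean"].idxmax()
        lo = p_rows["mean"].idxmin()
        assert not set(p_rows.loc[hi, "letter"]) & set(p_rows.loc[lo, "letter"])

    def test_singleton_group_reports_missing_sd(self):
        F = TestTwoLevelCut.blobs([1, 4])
        values = {
            t: {"P": [40 + F.loc[t, "f0"]] * 2, "E": [24, 24],
                "Eprime": [20, 20], "RW": [0.2, 0.2], "FW": [0.1, 0.1],
                "PD": [3, 3]}
            for t in F.index
        }
        table = table_from_values(values)
        result = cut_two_level(hierarchical_cluster(build_feature_matrix(
            table, features=("P",))), k_top=2, k_sub=2)
        summ = group_summaries(table, result)
        singleton = summ[(summ["level"] == "group") & (summ["n"] == 1)]
        assert len(singleton) and singleton["sd"].isna().all()


def test_newick_export_contains_all_leaves(small_study):
    dendro = hierarchical_cluster(build_feature_matrix(small_study.table))
    nwk = to_newick(dendro)
    assert nwk.endswith(";")
    for taxon in dendro.labels:
        assert taxon.replace(" ", "_") in nwk
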