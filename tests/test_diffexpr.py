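"""Count filtering, size factors, NB Wald DE, patterns, clustering."""

import numpy as np
import pandas as pd
import pytest

from nmdkit import diffexpr, synthetic
from nmdkit.diffexpr import CountMatrix


def _matrix(data, genotypes=None, cell_types=None):
    counts = pd.DataFrame(data).T  # dict of sample -> list
    counts.columns = [f"g{i}" for i in range(counts.shape[1])]
    counts = counts.T
    samples = pd.DataFrame(
        {
            "genotype": genotypes or ["control"] * counts.shape[1],
            "cell_type": cell_types or ["rs"] * counts.shape[1],
        },
        index=counts.columns,
    )
    return CountMatrix(counts, samples)


class TestFilterLowCounts:
    def test_boundary_inclusive(self):
        m = _matrix({f"s{i}": v for i, v in enumerate(
            zip((10, 10, 10, 0, 0, 0), (9, 100, 100, 0, 0, 0)))})
        kept = diffexpr.filter_low_counts(m, 10, 3)
        assert list(kept.counts.index) == ["g0"]

    def test_zero_min_count_is_identity(self):
        m = _matrix({"a": [0, 5], "b": [0, 7], "c": [1, 2]})
        kept = diffexpr.filter_low_counts(m, 0, 3)
        assert kept.counts.equals(m.counts)

    def test_min_samples_exceeding_samples_rejected(self):
        m = _matrix({"a": [1], "b": [2]})
        with pytest.raises(ValueError):
            diffexpr.filter_low_counts(m, 10, 3)


class TestSizeFactors:
    def test_scale_equivariance(self):
        m = _matrix({"a": [10, 50, 3], "b": [20, 100, 6]})
        sf = diffexpr.size_factors(m)
        assert sf["b"] / sf["a"] == pytest.approx(2.0)

    def test_identical_samples_equal_factors(self):
        m = _matrix({"a": [7, 3, 11], "b": [7, 3, 11], "c": [7, 3, 11]})
        assert diffexpr.size_factors(m).nunique() == 1

    def test_hand_computed_medians_of_ratios(self):
        # g0=(4,9): gm 6; g1=(1,4): gm 2; g2=(9,16): gm 12
        # ratios a: (2/3, 1/2, 3/4) -> median 2/3; b: (3/2, 2, 4/3) -> 3/2
        m = _matrix({"a": [4, 1, 9], "b": [9, 4, 16]})
        sf = diffexpr.size_factors(m)
        assert sf["a"] == pytest.approx(2 / 3)
        assert sf["b"] == pytest.approx(3 / 2)

    def test_no_all_positive_feature_is_an_error(self):
        m = _matrix({"a": [0, 5], "b": [3, 0]})
        with pytest.raises(ValueError, match="filter"):
            diffexpr.size_factors(m)


def _de_table(rows):
    return pd.DataFrame(
        rows, columns=["feature_id", "log2fc", "p", "padj"]
    )


class TestClassifyDe:
    @pytest.mark.parametrize(
        "lfc,padj,expected",
        [
            (1.5, 0.05, "up"),       # both boundaries inclusive
            (-1.5, 0.05, "down"),
            (1.49, 0.01, "non_de"),
            (-2.0, 0.2, "non_de"),
            (0.0, 1.0, "non_de"),
        ],
    )
    def test_thresholds(self, lfc, padj, expected):
        t = diffexpr.classify_de(_de_table([("g", lfc, 0.001, padj)]))
        assert t.de_class.iloc[0] == expected

    def test_idempotent(self):
        t = _de_table([("a", 2.0, 0.001, 0.01), ("b", 0.2, 0.5, 0.6)])
        once = diffexpr.classify_de(t)
        twice = diffexpr.classify_de(once)
        assert once.equals(twice)

    def test_threshold_is_a_parameter(self):
        t = diffexpr.classify_de(
            _de_table([("g", 1.0, 0.001, 0.01)]), lfc_threshold=1.0
        )
        assert t.de_class.iloc[0] == "up"


class TestNbWaldTest:
    def _simulate(self, **kw):
        cfg = synthetic.SimConfig(n_pirnas=0, **kw)
        truth = synthetic.generate_de_truth(cfg)
        return truth, synthetic.generate_counts(truth, cfg)

    def test_all_zero_feature_p_one_lfc_zero(self):
        truth, m = self._simulate(seed=5, n_genes=50)
        m.counts.iloc[0] = 0
        tab = diffexpr.nb_wald_test(m, cell_type="rs").set_index("feature_id")
        row = tab.loc[m.counts.index[0]]
        assert row.p == 1.0 and row.log2fc == 0.0

    def test_null_false_positive_rate_near_nominal(self):
        truth, m = self._simulate(seed=7, n_genes=600, frac_de_up=0, frac_de_down=0)
        tab = diffexpr.nb_wald_test(m, cell_type="rs")
        assert 0.01 <= (tab.p <= 0.05).mean() <= 0.1

    def test_planted_lfc_recovered(self):
        truth, m = self._simulate(
            seed=19, n_genes=2000, frac_de_up=0.1, frac_de_down=0.1,
            planted_lfc=2.0, long_utr_up_bias=1.0, nb_mean_range=(50.0, 500.0),
        )
        tab = diffexpr.classify_de(diffexpr.nb_wald_test(m, cell_type="rs"))
        up = [g for g, v in truth.genes.items() if v["rs"]["de_class"] == "up"]
        sub = tab.set_index("feature_id").loc[up]
        assert abs(sub.log2fc.median() - 2.0) <= 0.25
        assert ((sub.padj <= 0.05) & (sub.log2fc > 0)).mean() >= 0.8

    def test_deterministic(self):
        _, m = self._simulate(seed=3, n_genes=40)
        a = diffexpr.nb_wald_test(m, cell_type="spc")
        b = diffexpr.nb_wald_test(m, cell_type="spc")
        assert a.equals(b)

    def test_padj_at_least_p(self):
        _, m = self._simulate(seed=3, n_genes=80)
        tab = diffexpr.nb_wald_test(m, cell_type="rs")
        assert (tab.padj >= tab.p - 1e-15).all()


class TestPartitionPatterns:
    def test_exhaustive_class_pairs(self):
        classes = ["up", "down", "non_de"]
        rows_spc, rows_rs, expected = [], [], {}
        mapping = {
            ("down", "non_de"): "P1", ("down", "down"): "P2",
            ("non_de", "down"): "P3", ("up", "non_de"): "P4",
            ("up", "up"): "P5", ("non_de", "up"): "P6",
            ("up", "down"): "discordant", ("down", "up"): "discordant",
            ("non_de", "non_de"): "unassigned",
        }
        i = 0
        for s in classes:
            for r in classes:
                gid = f"g{i}"
                rows_spc.append({"feature_id": gid, "de_class": s})
                rows_rs.append({"feature_id": gid, "de_class": r})
                expected[gid] = mapping[(s, r)]
                i += 1
        out = diffexpr.partition_patterns(
            pd.DataFrame(rows_spc), pd.DataFrame(rows_rs)
        )
        assert dict(zip(out.feature_id, out.pattern)) == expected

    def test_mismatched_universe_rejected(self):
        spc = pd.DataFrame([{"feature_id": "a", "de_class": "up"}])
        rs = pd.DataFrame([{"feature_id": "b", "de_class": "up"}])
        with pytest.raises(ValueError):
            diffexpr.partition_patterns(spc, rs)


class TestTransitionGroups:
    def test_three_fates_plus_missing(self):
        cko = pd.DataFrame(
            [
                {"feature_id": "a", "de_class": "down"},
                {"feature_id": "b", "de_class": "non_de"},
                {"feature_id": "c", "de_class": "up"},
            ]
        )
        out = diffexpr.transition_groups({"a", "b", "c", "d"}, cko)
        assert dict(zip(out.feature_id, out.group)) == {
            "a": "1", "b": "2", "c": "3", "d": "unassigned"
        }

    def test_empty_input(self):
        out = diffexpr.transition_groups(set(), pd.DataFrame(
            columns=["feature_id", "de_class"]))
        assert len(out) == 0


class TestClusterProfiles:
    def _two_pattern_data(self, rng, n_per=15):
        groups = ["a", "a", "b", "b", "c", "c"]
        samples = [f"s{i}" for i in range(6)]
        base_a = np.array([10, 10, 100, 100, 10, 10])
        base_b = np.array([100, 100, 10, 10, 100, 100])
        rows = []
        for i in range(2 * n_per):
            base = base_a if i < n_per else base_b
            rows.append(base + rng.normal(0, 1, size=6))
        norm = pd.DataFrame(rows, index=[f"g{i}" for i in range(2 * n_per)],
                            columns=samples)
        return norm, pd.Series(groups, index=samples)

    def test_planted_clusters_recovered_at_k2(self):
        rng = np.random.default_rng(8)
        norm, labels = self._two_pattern_data(rng)
        profiles, link = diffexpr.cluster_profiles(norm, labels)
        cut = diffexpr.cut_clusters(link, profiles.index, k=2)
        first, second = set(cut.iloc[:15]), set(cut.iloc[15:])
        assert first.isdisjoint(second) and len(first) == len(second) == 1

    def test_single_gene_trivial_tree(self):
        norm = pd.DataFrame([[1.0, 2.0]], index=["g0"], columns=["s0", "s1"])
        labels = pd.Series(["a", "b"], index=["s0", "s1"])
        profiles, link = diffexpr.cluster_profiles(norm, labels)
        assert link.shape == (0, 4)
        assert diffexpr.cut_clusters(link, profiles.index, k=2).tolist() == [1]
        assert diffexpr.dendrogram_newick(link, profiles.index) == "g0;"

    def test_gene_order_does_not_change_partition(self):
        rng = np.random.default_rng(9)
        norm, labels = self._two_pattern_data(rng)
        profiles, link = diffexpr.cluster_profiles(norm, labels)
        cut = diffexpr.cut_clusters(link, profiles.index, k=2)
        perm = norm.sample(frac=1.0, random_state=4)
        profiles_p, link_p = diffexpr.cluster_profiles(perm, labels)
        cut_p = diffexpr.cut_clusters(link_p, profiles_p.index, k=2)
        joined = pd.concat([cut, cut_p.rename("perm")], axis=1)
        # same partition up to label swap
        table = joined.groupby(["cluster", "perm"]).size().unstack(fill_value=0)
        assert (table > 0).sum().sum() == 2

    def test_newick_has_all_leaves(self):
        rng = np.random.default_rng(10)
        norm, labels = self._two_pattern_data(rng, n_per=3)
        profiles, link = diffexpr.cluster_profiles(norm, labels)
        nwk = diffexpr.dendrogram_newick(link, profiles.index)
        assert nwk.endswith(";") and all(g in nwk for g in profiles.index)
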