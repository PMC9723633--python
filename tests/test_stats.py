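"""Enrichment statistics: exact Fisher, BH, Kruskal-Wallis/Dunn wiring."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from nmdkit import stats
from nmdkit.stats import TwoByTwo


class TestFisherExact:
    def test_no_association_two_sided_p_is_one(self):
        assert stats.fisher_exact(TwoByTwo(5, 5, 5, 5), "two_sided").p == 1.0

    def test_published_overlap_table(self):
        # 259 shared of 997 vs 4812 upregulated, background 23 024 genes
        res = stats.fisher_exact(TwoByTwo(259, 738, 4553, 17474), "greater")
        assert res.p == pytest.approx(4.9e-05, rel=0.02)
        two = stats.fisher_exact(TwoByTwo(259, 738, 4553, 17474), "two_sided")
        assert two.p > res.p

    def test_two_sided_equals_explicit_enumeration(self):
        # all tables with margins of (1,9 / 11,3): a ranges over 0..10
        a, b, c, d = 1, 9, 11, 3
        n, r, col = a + b + c + d, a + b, a + c
        pmf = {
            k: math.comb(r, k) * math.comb(n - r, col - k) / math.comb(n, col)
            for k in range(max(0, r + col - n), min(r, col) + 1)
        }
        expected = sum(v for v in pmf.values() if v <= pmf[a] * (1 + 1e-12))
        res = stats.fisher_exact(TwoByTwo(a, b, c, d), "two_sided")
        assert res.p == pytest.approx(expected, abs=1e-12)

    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 15, size=4)
            t = TwoByTwo(int(a), int(b), int(c), int(d))
            if t.n == 0:
                continue
            m = [[a, b], [c, d]]
            assert stats.fisher_exact(t, "greater").p == pytest.approx(
                sps.fisher_exact(m, "greater")[1], abs=1e-12
            )
            assert stats.fisher_exact(t, "less").p == pytest.approx(
                sps.fisher_exact(m, "less")[1], abs=1e-12
            )
            assert stats.fisher_exact(t, "two_sided").p == pytest.approx(
                sps.fisher_exact(m, "two-sided")[1], abs=1e-9
            )

    def test_one_sided_overlap_at_observed_table(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            t = TwoByTwo(*(int(x) for x in rng.integers(0, 30, size=4)))
            if t.n == 0:
                continue
            total = (
                stats.fisher_exact(t, "greater").p + stats.fisher_exact(t, "less").p
            )
            assert total >= 1.0 - 1e-12

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            TwoByTwo(-1, 2, 3, 4)


class TestOverlapEnrichment:
    def test_disjoint_sets_not_enriched(self):
        bg = set(range(100))
        res = stats.overlap_enrichment(set(range(10)), set(range(50, 60)), bg)
        assert res.table.a == 0 and res.p > 0.5

    def test_subset_gives_maximal_overlap(self):
        bg = set(range(100))
        s1 = set(range(10))
        res = stats.overlap_enrichment(s1, set(range(20)), bg)
        assert res.table.a == 10
        assert res.extra["frac_of_set1"] == 1.0

    def test_planted_twofold_enrichment_detected(self):
        rng = np.random.default_rng(41)
        bg = list(range(5000))
        s2 = set(rng.choice(bg, size=1000, replace=False).tolist())
        # members of s2 are twice as likely to join s1
        weights = np.array([2.0 if g in s2 else 1.0 for g in bg])
        probs = weights / weights.sum()
        s1 = set(rng.choice(bg, size=800, replace=False, p=probs).tolist())
        res = stats.overlap_enrichment(s1, s2, set(bg))
        assert res.p < 1e-3

    def test_set_outside_background_rejected(self):
        with pytest.raises(ValueError):
            stats.overlap_enrichment({1}, {2}, {2, 3})


class TestBhAdjust:
    def test_hand_computed_stepup(self):
        got = stats.bh_adjust([0.01, 0.02, 0.03, 0.5])
        assert np.allclose(got, [0.04, 0.04, 0.04, 0.5])

    def test_single_p_unchanged(self):
        assert stats.bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_equal_ps_stay_equal_and_monotone(self):
        got = stats.bh_adjust([0.2, 0.2, 0.2])
        assert np.allclose(got, 0.2)
        ps = np.array([0.9, 0.001, 0.3, 0.04, 0.04])
        adj = stats.bh_adjust(ps)
        order = np.argsort(ps)
        assert np.all(np.diff(adj[order]) >= -1e-12)
        assert np.all(adj <= 1) and np.all(adj >= ps)


def _frames(values_by_class):
    de_rows, ann_rows = [], []
    i = 0
    for cls, values in values_by_class.items():
        for v in values:
            de_rows.append(
                {"feature_id": f"f{i}", "log2fc": v, "de_class": "up" if v > 0 else "down"}
            )
            ann_rows.append({"feature_id": f"f{i}", "utr3_class": cls})
            i += 1
    return pd.DataFrame(de_rows), pd.DataFrame(ann_rows)


class TestLfcByUtr3Class:
    def test_identical_groups_h_zero_p_one(self):
        vals = [1.6, 2.0, -1.8, 2.4, -2.2] * 4
        de, ann = _frames({"short": vals, "medium": vals, "long": vals})
        res = stats.lfc_by_utr3_class(de, ann)
        assert res["kw_h"] == 0.0 and res["kw_p"] == 1.0

    def test_planted_ordering_recovered(self):
        rng = np.random.default_rng(77)
        de, ann = _frames(
            {
                "short": rng.normal(-1.9, 0.2, 300).tolist(),
                "medium": rng.normal(0.3, 1.8, 300).tolist(),
                "long": rng.normal(1.9, 0.2, 300).tolist(),
            }
        )
        res = stats.lfc_by_utr3_class(de, ann, de_only=False)
        m = res["medians"]
        assert m["long"] > m["medium"] > m["short"]
        assert res["kw_p"] < 0.01
        dunn = res["dunn"]
        assert (dunn.p_adj >= dunn.p - 1e-15).all()

    def test_two_groups_consistent_with_rank_sum(self):
        rng = np.random.default_rng(78)
        x, y = rng.normal(0, 1, 40), rng.normal(0.8, 1, 40)
        de, ann = _frames({"short": x.tolist(), "long": y.tolist()})
        res = stats.lfc_by_utr3_class(de, ann, de_only=False)
        h_from_z = sps.ranksums(x, y)[0] ** 2
        # with two groups KW's H equals the squared rank-sum z (no ties)
        assert res["kw_h"] == pytest.approx(h_from_z, rel=1e-9)

    def test_single_class_rejected(self):
        de, ann = _frames({"short": [1.6, -1.7, 2.0]})
        with pytest.raises(ValueError):
            stats.lfc_by_utr3_class(de, ann)


class TestMedianUtr3ByClass:
    def _frames(self, lens_by_class):
        de_rows, ann_rows = [], []
        i = 0
        for cls, lens in lens_by_class.items():
            for ln in lens:
                de_rows.append({"feature_id": f"f{i}", "log2fc": 0.0, "de_class": cls})
                ann_rows.append({"feature_id": f"f{i}", "utr3_len": ln})
                i += 1
        return pd.DataFrame(de_rows), pd.DataFrame(ann_rows)

    def test_identical_distributions_p_near_one(self):
        lens = list(range(100, 400, 10))
        de, ann = self._frames({"up": lens, "down": lens})
        res = stats.median_utr3_by_class(de, ann)
        assert res["pairwise"].p.iloc[0] == pytest.approx(1.0)

    def test_planted_median_shift_detected(self):
        rng = np.random.default_rng(12)
        de, ann = self._frames(
            {
                "up": (3 * rng.lognormal(6, 0.4, 200)).tolist(),
                "down": rng.lognormal(6, 0.4, 200).tolist(),
            }
        )
        res = stats.median_utr3_by_class(de, ann)
        assert res["medians"]["up"] > 2 * res["medians"]["down"]
        assert res["pairwise"].p.iloc[0] < 1e-6

    def test_empty_class_excluded(self):
        de, ann = self._frames({"up": [100, 200, 300], "down": [150, 250, 350]})
        res = stats.median_utr3_by_class(de, ann)
        assert res["excluded"] == ["non_de"]
        assert set(res["medians"]) == {"up", "down"}


class TestFeatureProportions:
    def _inputs(self, up_rate=0.0, down_rate=0.0, n=60):
        rng = np.random.default_rng(31)
        de_rows, feat_rows = [], []
        for i in range(n):
            cls = ("up", "down", "non_de")[i % 3]
            rate = {"up": up_rate, "down": down_rate, "non_de": 0.0}[cls]
            de_rows.append({"feature_id": f"f{i}", "de_class": cls})
            feat_rows.append(
                {"feature_id": f"f{i}", "long_utr3": bool(rng.random() < rate)}
            )
        return pd.DataFrame(de_rows), pd.DataFrame(feat_rows)

    def test_absent_feature_zero_proportions(self):
        props, tests = stats.feature_proportions(*self._inputs())
        assert (props.proportion == 0).all()
        assert len(tests) == 3  # three class pairs

    def test_planted_bias_detected(self):
        rng = np.random.default_rng(55)
        n = 2000
        de = pd.DataFrame(
            {"feature_id": [f"f{i}" for i in range(n)],
             "de_class": ["up" if i < n // 2 else "down" for i in range(n)]}
        )
        feats = pd.DataFrame(
            {"feature_id": de.feature_id,
             "long_utr3": [bool(rng.random() < (0.4 if c == "up" else 0.2))
                            for c in de.de_class]}
        )
        props, tests = stats.feature_proportions(de, feats)
        by_class = props.set_index("de_class").proportion
        assert by_class["up"] > by_class["down"]
        updown = tests[(tests.class1 == "up") & (tests.class2 == "down")]
        assert updown.p.iloc[0] < 0.01

    def test_single_class_no_pairwise_tests(self):
        de = pd.DataFrame({"feature_id": ["a", "b"], "de_class": ["up", "up"]})
        feats = pd.DataFrame({"feature_id": ["a", "b"], "long_utr3": [True, False]})
        props, tests = stats.feature_proportions(de, feats)
        assert len(props) == 1 and len(tests) == 0
        assert props.proportion.iloc[0] == 0.5
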