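"""Gene-set enrichment and group-comparison statistics.

The 2x2 enrichment test is Fisher's exact test computed by exact integer
hypergeometric enumeration (no normal or chi-square approximation): with
both margins fixed, the count in cell *a* follows a hypergeometric law, and
one-sided p-values are tail sums of its pmf while the two-sided p-value
sums the probability of every table whose pmf does not exceed the observed
one (the conventional exact definition, as in R's ``fisher.test``).

Group comparisons of log2 fold changes across 3'UTR-length classes use the
Kruskal-Wallis H test with tie correction and Dunn's rank-based post hoc z
tests, Bonferroni-adjusted by default.  Pairwise length-distribution
comparisons use the Wilcoxon rank-sum test.  All counts entering each test
are carried on the result objects for auditability.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class TwoByTwo:
    """Counts a = in both sets, b = set1 only, c = set2 only, d = neither."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("2x2 table cells must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class EnrichmentResult:
    table: TwoByTwo
    odds_ratio: float
    p: float
    alternative: str
    method: str
    extra: dict | None = None


@lru_cache(maxsize=200_000)
def _hypergeom_weights(n: int, r: int, c: int) -> tuple[int, tuple[int, ...], int]:
    """Exact pmf numerators for cell *a* given table margins.

    Returns (a_min, numerators over the support a_min..a_max, total).  The
    pmf of a is numerator[a - a_min] / total, all exact integers.
    """
    a_min = max(0, r + c - n)
    a_max = min(r, c)
    nums = tuple(
        math.comb(r, a) * math.comb(n - r, c - a) for a in range(a_min, a_max + 1)
    )
    return a_min, nums, math.comb(n, c)


def fisher_exact(table: TwoByTwo, alternative: str = "greater") -> EnrichmentResult:
    """Fisher's exact test on a 2x2 table by integer enumeration.

    ``alternative``: 'greater' tests enrichment of cell a, 'less'
    depletion, 'two_sided' sums all tables with pmf <= the observed pmf
    (exact integer comparison, so no floating-point tie ambiguity).
    """
    if alternative not in ("greater", "less", "two_sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    a, b, c, d = table.a, table.b, table.c, table.d
    a_min, nums, total = _hypergeom_weights(table.n, a + b, a + c)
    idx = a - a_min
    obs = nums[idx]
    if alternative == "greater":
        num = sum(nums[idx:])
    elif alternative == "less":
        num = sum(nums[: idx + 1])
    else:
        num = sum(w for w in nums if w <= obs)
    p = min(1.0, num / total)
    odds = math.inf if b * c == 0 and a * d > 0 else (
        a * d / (b * c) if b * c else math.nan
    )
    return EnrichmentResult(
        table=table,
        odds_ratio=odds,
        p=p,
        alternative=alternative,
        method="fisher_exact_enumeration",
    )


def overlap_enrichment(set1, set2, background) -> EnrichmentResult:
    """Enrichment of the overlap between two gene sets over a background.

    Both sets must be subsets of the background.  Reports the one-sided
    (greater) result, with the two-sided p and the overlap fractions
    |set1 ∩ set2| / |set1| and / |set2| in ``extra``.
    """
    set1, set2, background = set(set1), set(set2), set(background)
    if not set1 <= background or not set2 <= background:
        raise ValueError("gene sets must be subsets of the background")
    a = len(set1 & set2)
    b = len(set1) - a
    c = len(set2) - a
    d = len(background) - a - b - c
    table = TwoByTwo(a, b, c, d)
    res = fisher_exact(table, "greater")
    extra = {
        "p_two_sided": fisher_exact(table, "two_sided").p,
        "p_less": fisher_exact(table, "less").p,
        "frac_of_set1": a / len(set1) if set1 else math.nan,
        "frac_of_set2": a / len(set2) if set2 else math.nan,
    }
    return EnrichmentResult(
        table=table,
        odds_ratio=res.odds_ratio,
        p=res.p,
        alternative="greater",
        method=res.method,
        extra=extra,
    )


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals
    return multipletests(pvals, method="fdr_bh")[1]


def feature_proportions(
    de: pd.DataFrame, features: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-DE-class feature proportions with pairwise Fisher tests.

    ``de`` needs columns feature_id, de_class; ``features`` needs
    feature_id plus boolean feature columns (e.g. has_dej, has_uorf,
    long_utr3, targeted_seed_plus_8 ...).  Returns (proportions table,
    pairwise Fisher table).  Classes with no members are omitted.
    """
    merged = de.merge(features, on="feature_id", how="inner")
    feat_cols = [
        c for c in features.columns if c != "feature_id" and merged[c].dtype == bool
    ]
    prop_rows, test_rows = [], []
    classes = [c for c in ("up", "down", "non_de") if (merged.de_class == c).any()]
    for feat in feat_cols:
        counts = {
            cls: (
                int(merged.loc[merged.de_class == cls, feat].sum()),
                int((merged.de_class == cls).sum()),
            )
            for cls in classes
        }
        for cls, (k, n) in counts.items():
            prop_rows.append(
                {
                    "feature": feat,
                    "de_class": cls,
                    "n_with_feature": k,
                    "n_total": n,
                    "proportion": k / n if n else math.nan,
                }
            )
        if len(classes) >= 2:
            for c1, c2 in itertools.combinations(classes, 2):
                k1, n1 = counts[c1]
                k2, n2 = counts[c2]
                res = fisher_exact(
                    TwoByTwo(k1, n1 - k1, k2, n2 - k2), "two_sided"
                )
                test_rows.append(
                    {
                        "feature": feat,
                        "class1": c1,
                        "class2": c2,
                        "a": k1,
                        "b": n1 - k1,
                        "c": k2,
                        "d": n2 - k2,
                        "odds_ratio": res.odds_ratio,
                        "p": res.p,
                    }
                )
    return pd.DataFrame(prop_rows), pd.DataFrame(test_rows)


def dunn_posthoc(
    groups: dict[str, np.ndarray], adjust: str = "bonferroni"
) -> pd.DataFrame:
    """Dunn's post hoc pairwise z tests on joint ranks, tie-corrected.

    Standard large-sample form: for groups i, j with mean joint ranks
    Rbar_i, Rbar_j out of N observations,
    z = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j)),
    with tie term T = sum(t^3 - t) / (12 (N - 1)).
    """
    names = list(groups)
    values = np.concatenate([np.asarray(groups[g], dtype=float) for g in names])
    sizes = {g: len(groups[g]) for g in names}
    n_total = len(values)
    ranks = sps.rankdata(values)
    mean_ranks, start = {}, 0
    for g in names:
        mean_ranks[g] = ranks[start : start + sizes[g]].mean()
        start += sizes[g]
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12 * (n_total - 1))
    rows = []
    for g1, g2 in itertools.combinations(names, 2):
        se = math.sqrt(
            (n_total * (n_total + 1) / 12 - tie_term)
            * (1 / sizes[g1] + 1 / sizes[g2])
        )
        z = (mean_ranks[g1] - mean_ranks[g2]) / se if se > 0 else 0.0
        p = 2 * sps.norm.sf(abs(z))
        rows.append({"group1": g1, "group2": g2, "z": z, "p": p})
    out = pd.DataFrame(rows)
    if adjust == "bonferroni":
        out["p_adj"] = np.minimum(out["p"] * len(out), 1.0)
    elif adjust == "bh":
        out["p_adj"] = bh_adjust(out["p"].to_numpy())
    elif adjust == "none":
        out["p_adj"] = out["p"]
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return out


def lfc_by_utr3_class(
    de: pd.DataFrame,
    ann: pd.DataFrame,
    de_only: bool = True,
    adjust: str = "bonferroni",
) -> dict:
    """log2FC distributions across 3'UTR-length classes.

    ``de`` needs feature_id, log2fc, de_class; ``ann`` needs feature_id,
    utr3_class.  With ``de_only`` the comparison is restricted to
    significantly DE features (class up or down), as when asking whether
    longer-3'UTR transcripts shift toward upregulation.  Returns per-group
    medians and sizes, the Kruskal-Wallis H and p, and the Dunn table.
    """
    merged = de.merge(ann, on="feature_id", how="inner")
    if de_only:
        merged = merged[merged.de_class.isin(["up", "down"])]
    groups = {
        cls: sub.log2fc.to_numpy()
        for cls, sub in merged.groupby("utr3_class")
        if len(sub)
    }
    if len(groups) < 2:
        raise ValueError("need >= 2 non-empty 3'UTR classes")
    medians = {g: float(np.median(v)) for g, v in groups.items()}
    sizes = {g: int(len(v)) for g, v in groups.items()}
    arrays = list(groups.values())
    if all(np.array_equal(arrays[0], arr) for arr in arrays[1:]):
        h, p = 0.0, 1.0  # identical groups: no evidence of separation
    else:
        h, p = sps.kruskal(*arrays)
    return {
        "medians": medians,
        "sizes": sizes,
        "kw_h": float(h),
        "kw_p": float(p),
        "dunn": dunn_posthoc(groups, adjust=adjust),
    }


def median_utr3_by_class(de: pd.DataFrame, ann: pd.DataFrame) -> dict:
    """3'UTR length distributions across DE classes (up / non_de / down).

    Pairwise comparisons use the two-sided Wilcoxon rank-sum test. Empty
    classes are excluded and listed under ``excluded``.
    """
    merged = de.merge(ann, on="feature_id", how="inner")
    groups = {
        cls: merged.loc[merged.de_class == cls, "utr3_len"].to_numpy(dtype=float)
        for cls in ("up", "non_de", "down")
    }
    excluded = [g for g, v in groups.items() if len(v) == 0]
    groups = {g: v for g, v in groups.items() if len(v)}
    rows = []
    for g1, g2 in itertools.combinations(groups, 2):
        if np.array_equal(np.sort(groups[g1]), np.sort(groups[g2])):
            stat, p = 0.0, 1.0
        else:
            stat, p = sps.ranksums(groups[g1], groups[g2])
        rows.append({"group1": g1, "group2": g2, "statistic": stat, "p": p})
    return {
        "medians": {g: float(np.median(v)) for g, v in groups.items()},
        "sizes": {g: int(len(v)) for g, v in groups.items()},
        "pairwise": pd.DataFrame(rows),
        "excluded": excluded,
    }
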