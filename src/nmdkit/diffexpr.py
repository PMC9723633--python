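"""Count filtering, differential-expression calling and pattern partitioning.

The DE engine is a deliberately lightweight, fully deterministic
negative-binomial stage: median-of-ratios size factors, per-feature
method-of-moments dispersion pooled across the two genotype groups, a Wald
test on the log2 fold change with a small-sample t reference
(df = n1 + n2 - 2), and Benjamini-Hochberg adjustment.  It trades the
dispersion shrinkage of full-featured engines for transparency; externally
produced DE tables (feature_id, log2fc, p, padj) can be dropped in at any
downstream step via :func:`read_de_table`.

Downstream partitions:

* six expression patterns over two cell types — P1/P2/P3 down in
  spermatocytes only / both / round spermatids only, P4/P5/P6 the same for
  up; genes significant in opposite directions are reported as discordant,
  not forced into a pattern;
* three transition groups for genes normally downregulated across the
  meiotic-to-postmeiotic transition — still down (1), unchanged (2), or
  up (3) in the knockout;
* hierarchical clustering (complete linkage, Euclidean) of per-group
  z-scaled mean expression profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy

from .stats import bh_adjust

GENOTYPES = ("control", "cko")
LFC_THRESHOLD = 1.5
ALPHA = 0.05
GENE_COUNT_FILTER = (10, 3)
TRANSCRIPT_COUNT_FILTER = (20, 3)


@dataclass(frozen=True)
class CountMatrix:
    """Integer counts (features x samples) with per-sample metadata.

    ``samples`` is indexed by sample id with columns ``genotype``
    (control / cko) and ``cell_type`` (e.g. spc / rs / cb).
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)[:5]}")
        for col in ("genotype", "cell_type"):
            if col not in self.samples.columns:
                raise ValueError(f"sample metadata lacks column {col!r}")

    def subset(self, cell_type: str) -> "CountMatrix":
        keep = self.samples.index[self.samples.cell_type == cell_type]
        keep = [s for s in self.counts.columns if s in set(keep)]
        return CountMatrix(self.counts[keep], self.samples.loc[keep])


def filter_low_counts(
    m: CountMatrix, min_count: int = 10, min_samples: int = 3
) -> CountMatrix:
    """Keep features with >= ``min_count`` reads in >= ``min_samples`` samples.

    Both bounds inclusive.  Defaults are the gene-level filter; use
    (20, 3) for transcript-level tables.
    """
    if min_samples > m.counts.shape[1]:
        raise ValueError(
            f"min_samples={min_samples} exceeds the {m.counts.shape[1]} samples"
        )
    keep = (m.counts >= min_count).sum(axis=1) >= min_samples
    return CountMatrix(m.counts.loc[keep], m.samples)


def size_factors(m: CountMatrix) -> pd.Series:
    """Median-of-ratios normalization factors (DESeq-style).

    Over the features positive in every sample, each sample's factor is
    the median ratio of its counts to the feature-wise geometric mean.
    """
    counts = m.counts.to_numpy(dtype=float)
    all_pos = (counts > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError(
            "no feature has positive counts in every sample; filter first"
        )
    logs = np.log(counts[all_pos])
    log_gm = logs.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logs - log_gm, axis=0))
    return pd.Series(factors, index=m.counts.columns, name="size_factor")


def _mom_dispersion(norm: np.ndarray, groups: list[np.ndarray]) -> np.ndarray:
    """Per-feature NB dispersion, method of moments pooled across groups.

    alpha_g = (s^2_g - xbar_g) / xbar_g^2 per group; pooled by residual
    degrees of freedom and floored at zero (Poisson).
    """
    num = np.zeros(norm.shape[0])
    dof = 0
    for idx in groups:
        sub = norm[:, idx]
        mean = sub.mean(axis=1)
        var = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            alpha = np.where(mean > 0, (var - mean) / np.maximum(mean, 1e-12) ** 2, 0.0)
        num += alpha * (sub.shape[1] - 1)
        dof += sub.shape[1] - 1
    return np.maximum(num / dof, 0.0)


def nb_wald_test(
    m: CountMatrix,
    cell_type: str | None = None,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-feature Wald test of cko vs control on NB means.

    Returns a DE table (feature_id, base_mean, log2fc, se, p, padj) with
    one row per feature; de_class is added by :func:`classify_de`.
    Features with zero counts in both groups get p = 1, log2fc = 0.
    """
    if cell_type is not None:
        m = m.subset(cell_type)
    geno = m.samples.loc[m.counts.columns, "genotype"].to_numpy()
    idx_ctrl = np.flatnonzero(geno == "control")
    idx_cko = np.flatnonzero(geno == "cko")
    if len(idx_ctrl) < 2 or len(idx_cko) < 2:
        raise ValueError("need >= 2 replicates per genotype")
    sf = size_factors(m).to_numpy()
    norm = m.counts.to_numpy(dtype=float) / sf
    mu_c = norm[:, idx_ctrl].mean(axis=1)
    mu_k = norm[:, idx_cko].mean(axis=1)
    alpha = _mom_dispersion(norm, [idx_ctrl, idx_cko])
    lfc = np.log2((mu_k + pseudocount) / (mu_c + pseudocount))
    ln2sq = np.log(2.0) ** 2
    var = (1 / (mu_c + pseudocount) + alpha) / (len(idx_ctrl) * ln2sq) + (
        1 / (mu_k + pseudocount) + alpha
    ) / (len(idx_cko) * ln2sq)
    se = np.sqrt(var)
    df = len(idx_ctrl) + len(idx_cko) - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, lfc / se, 0.0)
    p = 2 * sps.t.sf(np.abs(z), df)
    dead = (mu_c == 0) & (mu_k == 0)
    lfc[dead] = 0.0
    p[dead] = 1.0
    out = pd.DataFrame(
        {
            "feature_id": m.counts.index,
            "base_mean": norm.mean(axis=1),
            "log2fc": lfc,
            "se": se,
            "p": p,
            "padj": bh_adjust(p),
        }
    )
    return out


def classify_de(
    table: pd.DataFrame, lfc_threshold: float = LFC_THRESHOLD, alpha: float = ALPHA
) -> pd.DataFrame:
    """Assign de_class from thresholds, boundaries inclusive.

    up: log2fc >= lfc_threshold and padj <= alpha; down symmetric;
    everything else non_de.  Idempotent.
    """
    out = table.copy()
    sig = out.padj <= alpha
    out["de_class"] = np.select(
        [sig & (out.log2fc >= lfc_threshold), sig & (out.log2fc <= -lfc_threshold)],
        ["up", "down"],
        default="non_de",
    )
    return out


def read_de_table(path) -> pd.DataFrame:
    """Load an externally produced DE table (TSV).

    Required columns: feature_id, log2fc, p, padj — e.g. an export from a
    full-featured DE engine — so downstream classification and
    partitioning run unchanged on it.
    """
    table = pd.read_csv(path, sep="\t")
    required = {"feature_id", "log2fc", "p", "padj"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"DE table lacks columns: {sorted(missing)}")
    return table


_PATTERNS = {
    ("down", "non_de"): "P1",
    ("down", "down"): "P2",
    ("non_de", "down"): "P3",
    ("up", "non_de"): "P4",
    ("up", "up"): "P5",
    ("non_de", "up"): "P6",
    ("up", "down"): "discordant",
    ("down", "up"): "discordant",
    ("non_de", "non_de"): "unassigned",
}


def partition_patterns(spc: pd.DataFrame, rs: pd.DataFrame) -> pd.DataFrame:
    """Six expression patterns across spermatocytes and round spermatids.

    Input tables are classified DE tables sharing a gene universe.  P1-P3
    collect downregulation (spc only / both / rs only), P4-P6 upregulation
    likewise; opposite-direction genes land in the discordant bucket.
    """
    merged = spc[["feature_id", "de_class"]].merge(
        rs[["feature_id", "de_class"]],
        on="feature_id",
        how="outer",
        suffixes=("_spc", "_rs"),
    )
    if merged[["de_class_spc", "de_class_rs"]].isna().any().any():
        raise ValueError("spc and rs tables must share the same gene universe")
    merged["pattern"] = [
        _PATTERNS[(s, r)]
        for s, r in zip(merged.de_class_spc, merged.de_class_rs)
    ]
    return merged[["feature_id", "pattern"]]


def transition_groups(
    ctrl_down_genes, cko_rs_vs_spc: pd.DataFrame
) -> pd.DataFrame:
    """Fate in the knockout of genes normally down after meiosis.

    For genes downregulated in control round spermatids vs spermatocytes:
    group 1 = still down in the knockout comparison, group 2 = unchanged,
    group 3 = upregulated.  Genes absent from the knockout table are
    marked unassigned.
    """
    classes = dict(
        zip(cko_rs_vs_spc.feature_id, cko_rs_vs_spc.de_class)
    )
    mapping = {"down": "1", "non_de": "2", "up": "3"}
    rows = [
        {"feature_id": g, "group": mapping.get(classes.get(g), "unassigned")}
        for g in sorted(ctrl_down_genes)
    ]
    return pd.DataFrame(rows, columns=["feature_id", "group"])


def cluster_profiles(
    normalized: pd.DataFrame,
    group_of_sample: pd.Series,
    method: str = "complete",
    metric: str = "euclidean",
):
    """Hierarchically cluster per-gene group-mean profiles.

    Normalized counts are averaged within each sample group, z-scaled per
    gene (constant genes map to all-zero profiles), and clustered
    agglomeratively.  Returns (profiles, linkage matrix); cut with
    :func:`cut_clusters`.
    """
    groups = group_of_sample.loc[normalized.columns]
    profiles = normalized.T.groupby(groups).mean().T
    vals = profiles.to_numpy(dtype=float)
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=0, keepdims=True)
    scaled = np.where(sd > 0, (vals - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    profiles = pd.DataFrame(scaled, index=profiles.index, columns=profiles.columns)
    if len(profiles) == 1:
        return profiles, np.empty((0, 4))
    link = hierarchy.linkage(scaled, method=method, metric=metric)
    return profiles, link


def cut_clusters(link: np.ndarray, index, k: int) -> pd.Series:
    """Flat k-cluster assignment from a linkage matrix."""
    if len(index) == 1:
        return pd.Series([1], index=index, name="cluster")
    labels = hierarchy.fcluster(link, t=k, criterion="maxclust")
    return pd.Series(labels, index=index, name="cluster")


def dendrogram_newick(link: np.ndarray, labels) -> str:
    """Serialize a linkage matrix as a Newick string with branch lengths."""
    labels = list(labels)
    if len(labels) == 1:
        return f"{labels[0]};"
    tree = hierarchy.to_tree(link)

    def walk(node, parent_dist):
        length = parent_dist - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return f"({walk(tree.left, tree.dist)},{walk(tree.right, tree.dist)});"
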