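"""Differential expression: cluster-specific DEGs and recurrent pairwise DE.

Two procedures operate on log-space matrices:

* ``specific_degs`` — for a focal cluster, run a two-sided Wilcoxon
  rank-sum test per gene against every other cluster, Bonferroni-adjust
  within each comparison, keep genes significantly up (adjusted p < 0.05
  and log2 fold change > 0.5) in *every* pairwise comparison.
* ``recurrent_pairwise_de`` — for a focal sample, run Welch t-tests per
  gene against each other sample separately and keep genes with
  log2FC >= 1 and unadjusted p < 0.05 in *all* comparisons.

Fold changes are differences of group means in log2((TPM/10)+1) space.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import ExpressionMatrix

#: Largest group size for which the exact rank-sum null distribution is
#: computed when the data are tie-free.
EXACT_MAX_N = 25


def _ranksum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Uses the exact permutation distribution when both groups are small
    and the pooled values are tie-free, otherwise the normal
    approximation with tie and continuity corrections.
    """
    # ties within a group leave the rank-sum statistic unchanged; only
    # values shared across the groups make the tie-free exact null invalid
    cross_ties = bool(set(a.tolist()) & set(b.tolist()))
    if not cross_ties and max(len(a), len(b)) <= EXACT_MAX_N:
        method = "exact"
    else:
        method = "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def bonferroni(p: np.ndarray) -> np.ndarray:
    """Bonferroni adjustment: min(1, p * n_tested)."""
    p = np.asarray(p, dtype=np.float64)
    return np.minimum(1.0, p * p.size)


def pairwise_de_wilcoxon(
    m: ExpressionMatrix,
    group_a: list[str],
    group_b: list[str],
    lfc_min: float = 0.5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene rank-sum DE between two cell groups.

    Returns one row per gene with the log2 fold change (mean of A minus
    mean of B in log space), the raw two-sided p, the Bonferroni-adjusted
    p (denominator = number of genes in the matrix), the direction, and
    the ``significant_up`` flag: adjusted p < alpha AND log2FC strictly
    above ``lfc_min``.
    """
    if m.space not in ("log", "centered"):
        raise ValueError("differential expression expects a log-space matrix")
    if len(group_a) < 3 or len(group_b) < 3:
        raise ValueError("each group needs at least 3 cells")
    A = m.values[m.cell_index(group_a)]
    B = m.values[m.cell_index(group_b)]
    lfc = A.mean(axis=0) - B.mean(axis=0)
    raw_p = np.array([_ranksum_p(A[:, j], B[:, j]) for j in range(m.n_genes)])
    adj_p = bonferroni(raw_p)
    return pd.DataFrame(
        {
            "gene_id": m.gene_ids,
            "log2_fold_change": lfc,
            "raw_p": raw_p,
            "adjusted_p": adj_p,
            "direction": np.where(lfc >= 0, "up", "down"),
            "significant_up": (adj_p < alpha) & (lfc > lfc_min),
        }
    )


def specific_degs(
    m: ExpressionMatrix,
    cluster_labels: dict[str, str] | pd.Series,
    focal_cluster: str,
    lfc_min: float = 0.5,
    alpha: float = 0.05,
) -> list[str]:
    """Genes upregulated in the focal cluster versus every other cluster.

    The specific DEG set is the intersection of the upregulated DEG
    lists from all pairwise comparisons involving the focal cluster.
    """
    labels = pd.Series(cluster_labels)
    clusters = sorted(labels.unique())
    if focal_cluster not in clusters:
        raise ValueError(f"unknown focal cluster {focal_cluster!r}")
    if len(clusters) < 2:
        raise ValueError("need at least 2 clusters")
    focal_cells = list(labels.index[labels == focal_cluster])
    specific: set[str] | None = None
    for other in clusters:
        if other == focal_cluster:
            continue
        other_cells = list(labels.index[labels == other])
        table = pairwise_de_wilcoxon(m, focal_cells, other_cells, lfc_min, alpha)
        up = set(table.loc[table["significant_up"], "gene_id"])
        specific = up if specific is None else specific & up
    assert specific is not None
    return sorted(specific)


def recurrent_pairwise_de(
    m: ExpressionMatrix,
    sample_labels: dict[str, str] | pd.Series,
    focal_sample: str,
    lfc_min: float = 1.0,
    alpha: float = 0.05,
) -> list[str]:
    """Genes recurrently overexpressed in the focal sample.

    For each other sample, a per-gene two-sided Welch t-test and log2FC
    (focal minus other) are computed; a gene is returned iff it has
    log2FC >= lfc_min and unadjusted p < alpha against every other
    sample.
    """
    if m.space not in ("log", "centered"):
        raise ValueError("differential expression expects a log-space matrix")
    labels = pd.Series(sample_labels)
    samples = sorted(labels.unique())
    if focal_sample not in samples:
        raise ValueError(f"unknown focal sample {focal_sample!r}")
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    F = m.values[m.cell_index(list(labels.index[labels == focal_sample]))]
    keep = np.ones(m.n_genes, dtype=bool)
    for other in samples:
        if other == focal_sample:
            continue
        O = m.values[m.cell_index(list(labels.index[labels == other]))]
        lfc = F.mean(axis=0) - O.mean(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = stats.ttest_ind(F, O, axis=0, equal_var=False).pvalue
        p = np.where(np.isnan(p), 1.0, p)
        keep &= (lfc >= lfc_min) & (p < alpha)
    return sorted(np.asarray(m.gene_ids)[keep])
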