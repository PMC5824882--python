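"""Bulk subset discovery: across-gate ANOVA, FDR control, specificity
scaling, PCA and correlation-based hierarchical clustering, and the
collapse of seven gates into three major subsets.

All statistics operate on donor-residualized log2 expression. The 7-gate
one-way ANOVA flags genes varying across sorted populations; the
Benjamini-Hochberg step-up converts p-values to q-values; a
specificity-scaled PCA and average-linkage clustering of pairwise Pearson
correlations reveal that the gates form three transcriptional subsets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy
import scipy.spatial.distance
import scipy.stats

from .datatypes import SUBSET_LABELS, gate_to_subset
from .preprocess import ResidualMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterResult",
    "anova_across_gates",
    "bh_fdr",
    "intersect_platforms",
    "specificity_scale",
    "pca",
    "correlation_cluster",
    "collapse_gates",
]


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, clipped to [0, 1].

    Order-preserving: a smaller p never receives a larger q. NaN input is
    a hard error (a missing p-value has no defensible adjustment).
    """
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any():
        raise ValueError("p_values contain NaN")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p_values must lie in [0, 1]")
    q = scipy.stats.false_discovery_control(p, method="bh")
    return np.clip(q, 0.0, 1.0)


def anova_across_gates(
    r: ResidualMatrix, meta: pd.DataFrame, donor_df: int | None = None
) -> pd.DataFrame:
    """One-way F test of each gene across gate groups.

    Gates with fewer than two samples are excluded with a warning; fewer
    than two usable gates is a hard error. Genes with no variance at all
    are reported with F = 0, p = 1 so the gene universe stays stable for
    the FDR step.

    Because the input is donor-residualized, d - 1 degrees of freedom
    (d donors) are already spent; the within-group df is n - k - (d - 1)
    so that null p-values stay calibrated. Pass ``donor_df`` to override
    the inferred count (0 disables the adjustment, e.g. for values that
    were never residualized).

    Returns a DataFrame with columns ``gene_id, statistic, p_value,
    q_value, contrast``.
    """
    gate = meta.set_index("sample_id")["gate"].loc[r.sample_ids]
    groups: list[np.ndarray] = []
    used_gates = []
    for g, block in gate.groupby(gate, sort=True):
        cols = [r.sample_ids.index(s) for s in block.index]
        if len(cols) < 2:
            logger.warning("gate %r has <2 samples; excluded from ANOVA", g)
            continue
        used_gates.append(g)
        groups.append(r.values[:, cols])
    if len(groups) < 2:
        raise ValueError("fewer than 2 gates with >=2 samples; cannot run ANOVA")

    k = len(groups)
    ns = np.array([g.shape[1] for g in groups])
    n = int(ns.sum())
    if donor_df is None:
        donor_df = max(0, r.donor_map.nunique() - 1)
    df_within = n - k - donor_df
    if df_within < 1:
        logger.warning(
            "donor adjustment would leave %d within-group df; disabling it",
            df_within,
        )
        donor_df = 0
        df_within = n - k
    all_values = np.hstack(groups)
    grand = all_values.mean(axis=1)
    group_means = np.column_stack([g.mean(axis=1) for g in groups])
    ss_between = ((group_means - grand[:, None]) ** 2 * ns).sum(axis=1)
    ss_within = np.zeros_like(ss_between)
    for j, g in enumerate(groups):
        ss_within += ((g - group_means[:, [j]]) ** 2).sum(axis=1)

    msb = ss_between / (k - 1)
    msw = ss_within / df_within
    total = ss_between + ss_within
    # Degenerate genes: no variance anywhere -> F = 0, p = 1 by convention;
    # perfect separation (zero within, positive between) -> p = 0.
    eps = 1e-12 * np.maximum(total, 1.0)
    degenerate = total <= eps
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat = msb / msw
    p = np.empty_like(f_stat)
    ok = ~degenerate & (msw > 0)
    p[ok] = scipy.stats.f.sf(f_stat[ok], k - 1, df_within)
    sep = ~degenerate & (msw <= 0)
    f_stat[sep] = np.inf
    p[sep] = 0.0
    f_stat[degenerate] = 0.0
    p[degenerate] = 1.0

    return pd.DataFrame(
        {
            "gene_id": r.gene_ids,
            "statistic": f_stat,
            "p_value": p,
            "q_value": bh_fdr(p),
            "contrast": f"{len(used_gates)}-gate ANOVA",
        }
    )


def intersect_platforms(
    a: pd.DataFrame, b: pd.DataFrame, threshold: float
) -> set[str]:
    """Genes measured on both platforms and significant (q < threshold) in both."""
    a_idx = a.set_index("gene_id")
    b_idx = b.set_index("gene_id")
    shared = a_idx.index.intersection(b_idx.index)
    if len(shared) == 0:
        raise ValueError("the two platforms share no measured genes")
    sig_a = set(a_idx.loc[shared][a_idx.loc[shared, "q_value"] < threshold].index)
    sig_b = set(b_idx.loc[shared][b_idx.loc[shared, "q_value"] < threshold].index)
    return sig_a & sig_b


def specificity_scale(values: np.ndarray, sample_ids: Sequence[str] | None = None) -> np.ndarray:
    """Scale each sample column, then each gene row (z-scores, ddof=1).

    The two-step scaling turns expression into a per-gene specificity
    profile across samples. A zero-variance sample is a hard error (it
    carries no information and breaks the first step); gene rows that
    become constant after step 1 are set to zero with a warning.
    """
    x = np.asarray(values, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("specificity_scale needs >=2 genes and >=2 samples")
    col_sd = x.std(axis=0, ddof=1)
    if (col_sd == 0).any():
        j = int(np.nonzero(col_sd == 0)[0][0])
        name = sample_ids[j] if sample_ids is not None else f"column {j}"
        raise ValueError(f"zero-variance sample: {name}")
    x = (x - x.mean(axis=0)) / col_sd
    row_sd = x.std(axis=1, ddof=1)
    zero = row_sd == 0
    if zero.any():
        logger.warning(
            "%d gene rows constant after sample scaling; set to zero",
            int(zero.sum()),
        )
    out = np.zeros_like(x)
    nz = ~zero
    out[nz] = (x[nz] - x[nz].mean(axis=1, keepdims=True)) / row_sd[nz, None]
    return out


def pca(
    x: np.ndarray, n_components: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PCA of a samples x features matrix with centered, unit-variance features.

    Returns ``(scores, loadings, variance_explained)`` where scores is
    samples x k, loadings features x k, and variance_explained the
    fraction of total variance per component (nonincreasing). Each
    component's sign is fixed so its largest-magnitude loading is
    positive.
    """
    x = np.asarray(x, dtype=np.float64)
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if n_components > min(x.shape):
        raise ValueError(
            f"n_components={n_components} exceeds min(samples, features)="
            f"{min(x.shape)}"
        )
    sd = x.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise ValueError(
            f"feature {int(np.nonzero(sd == 0)[0][0])} has zero variance; "
            "drop constant features before PCA"
        )
    z = (x - x.mean(axis=0)) / sd
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    var = s**2
    var_explained = var / var.sum()
    scores = u[:, :n_components] * s[:n_components]
    loadings = vt[:n_components].T
    for j in range(n_components):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] = -loadings[:, j]
            scores[:, j] = -scores[:, j]
    return scores, loadings, var_explained[:n_components]


@dataclass
class ClusterResult:
    """Agglomerative clustering of items on 1 - Pearson distance.

    ``linkage`` is a SciPy linkage matrix over the items in ``item_ids``
    order (items are sorted lexicographically before clustering so the
    result is independent of input order).
    """

    item_ids: list[str]
    linkage: np.ndarray
    distance_name: str
    linkage_method: str

    def labels(self, k: int) -> pd.Series:
        """Cut the tree into exactly ``k`` nonempty clusters (1-based labels)."""
        if k < 1 or k > len(self.item_ids):
            raise ValueError(f"k must lie in [1, {len(self.item_ids)}]")
        flat = scipy.cluster.hierarchy.cut_tree(self.linkage, n_clusters=k).ravel()
        return pd.Series(flat + 1, index=self.item_ids, name="cluster")


def correlation_cluster(
    values: np.ndarray,
    item_ids: Sequence[str],
    linkage_method: str = "average",
) -> ClusterResult:
    """Hierarchical clustering of items (rows) on 1 - Pearson correlation.

    Items are ordered lexicographically by id before clustering so ties
    in merge heights resolve deterministically regardless of input order.
    An item with zero variance over the feature set has no defined
    correlation and is a hard error.
    """
    x = np.asarray(values, dtype=np.float64)
    item_ids = [str(i) for i in item_ids]
    if x.shape[0] != len(item_ids):
        raise ValueError("values rows must match item_ids")
    if len(item_ids) < 2:
        raise ValueError("need at least 2 items to cluster")
    order = np.argsort(np.asarray(item_ids, dtype=object))
    x = x[order]
    ids_sorted = [item_ids[i] for i in order]
    sd = x.std(axis=1)
    if (sd == 0).any():
        bad = ids_sorted[int(np.nonzero(sd == 0)[0][0])]
        raise ValueError(f"item {bad!r} has zero variance over the gene subset")
    r = np.corrcoef(x)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)  # symmetrize away rounding
    condensed = scipy.spatial.distance.squareform(d, checks=False)
    z = scipy.cluster.hierarchy.linkage(condensed, method=linkage_method)
    return ClusterResult(ids_sorted, z, "1 - Pearson", linkage_method)


def collapse_gates(
    meta: pd.DataFrame,
    cluster: ClusterResult | None = None,
    rule: str = "marker",
) -> tuple[pd.Series, dict]:
    """Map each sample to one of the three major subsets.

    ``marker`` (default) ignores CDH11 and splits on CD34/THY1 status.
    ``data_driven`` cuts the provided cluster tree at k = 3 and names each
    cluster by the majority marker-rule subset of its members (ties break
    toward the fixed subset order and are flagged). The report carries the
    disagreement rate between the two rules.
    """
    if rule not in ("marker", "data_driven"):
        raise ValueError("rule must be 'marker' or 'data_driven'")
    gates = meta.set_index("sample_id")["gate"]
    marker_map = gates.map(gate_to_subset).rename("subset")
    if rule == "marker":
        return marker_map, {"rule": "marker", "disagreement_rate": 0.0}
    if cluster is None:
        raise ValueError("data_driven rule requires a ClusterResult")
    labels = cluster.labels(3)
    assigned = pd.Series(index=labels.index, dtype=object, name="subset")
    ties: list[int] = []
    for c in sorted(labels.unique()):
        members = labels.index[labels == c]
        counts = marker_map.loc[members].value_counts()
        top = counts[counts == counts.max()].index
        if len(top) > 1:
            ties.append(int(c))
            winner = min(top, key=SUBSET_LABELS.index)
        else:
            winner = top[0]
        assigned.loc[members] = winner
    disagree = float((assigned.loc[marker_map.index] != marker_map).mean())
    report = {
        "rule": "data_driven",
        "disagreement_rate": disagree,
        "tied_clusters": ties,
    }
    return assigned, report
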