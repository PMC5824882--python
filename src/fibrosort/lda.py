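"""Bulk-trained linear discriminant classification of single cells.

Gene selection is two-staged: genes with significant (default 5% FDR)
differential expression between any pair of the three bulk subsets, then
restricted to genes with single-cell mean log2 expression above the
log2(10 TPM) floor. An equal-covariance Gaussian (LDA) model is fitted on
the bulk profiles and each cell receives a posterior probability over the
three subsets.

With far more genes than bulk samples the pooled covariance is singular,
so it is regularized by convex shrinkage toward its diagonal plus a small
ridge:  S_reg = (1 - s) * S + s * diag(S) + eps * I. At s = 1 this is
diagonal ("naive Gaussian") LDA, the robust high-dimensional default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats

from .datatypes import SUBSET_LABELS, ExpressionMatrix
from .discovery import bh_fdr
from .preprocess import ResidualMatrix

__all__ = [
    "LdaModel",
    "pairwise_subset_de",
    "select_lda_genes",
    "fit_lda",
    "classify_cells",
    "classification_summary",
]


def pairwise_subset_de(r: ResidualMatrix, subset_map: pd.Series) -> pd.DataFrame:
    """Two-sample pooled-variance t tests between every pair of subsets.

    Per gene and pair: pooled-variance t on residualized values, two-sided
    p, and BH q-values computed within each contrast. Every subset needs
    at least two samples.
    """
    subset_map = subset_map.loc[r.sample_ids]
    col = {s: i for i, s in enumerate(r.sample_ids)}
    groups: dict[str, np.ndarray] = {}
    for subset in SUBSET_LABELS:
        members = subset_map.index[subset_map == subset]
        if len(members) < 2:
            raise ValueError(
                f"subset {subset!r} has {len(members)} samples; need >= 2"
            )
        groups[subset] = r.values[:, [col[s] for s in members]]

    frames = []
    for i in range(3):
        for j in range(i + 1, 3):
            s1, s2 = SUBSET_LABELS[i], SUBSET_LABELS[j]
            x, y = groups[s1], groups[s2]
            n1, n2 = x.shape[1], y.shape[1]
            m1, m2 = x.mean(axis=1), y.mean(axis=1)
            ss = ((x - m1[:, None]) ** 2).sum(axis=1) + (
                (y - m2[:, None]) ** 2
            ).sum(axis=1)
            df = n1 + n2 - 2
            pooled_var = ss / df
            se = np.sqrt(pooled_var * (1.0 / n1 + 1.0 / n2))
            with np.errstate(divide="ignore", invalid="ignore"):
                t = (m1 - m2) / se
            with np.errstate(invalid="ignore"):
                p = np.where(
                    se > 0,
                    2.0 * scipy.stats.t.sf(np.abs(np.where(se > 0, t, 0.0)), df),
                    np.where(m1 == m2, 1.0, 0.0),
                )
                t = np.where(
                    se > 0, t, np.where(m1 == m2, 0.0, np.inf * np.sign(m1 - m2))
                )
            frames.append(
                pd.DataFrame(
                    {
                        "gene_id": r.gene_ids,
                        "statistic": t,
                        "p_value": p,
                        "q_value": bh_fdr(p),
                        "contrast": f"{s1}_vs_{s2}",
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def select_lda_genes(
    pairwise_de: pd.DataFrame,
    sc: ExpressionMatrix,
    fdr: float = 0.05,
    expr_floor_log2: float = np.log2(10.0),
) -> list[str]:
    """Two-stage classifier gene selection.

    Stage 1: union over the three pairwise contrasts of genes with
    q < ``fdr``. Stage 2: keep genes whose mean log2 expression across
    the (already cell-filtered) single cells strictly exceeds
    ``expr_floor_log2``. Returned in deterministic gene-id order; an
    empty result is a hard error.
    """
    stage1 = set(pairwise_de.loc[pairwise_de["q_value"] < fdr, "gene_id"])
    sc_means = pd.Series(sc.values.mean(axis=1), index=sc.gene_ids)
    selected = sorted(
        g for g in stage1 if g in sc_means.index and sc_means[g] > expr_floor_log2
    )
    if not selected:
        raise ValueError(
            "no genes survive the two-stage selection; relax fdr or the "
            "expression floor"
        )
    return selected


@dataclass
class LdaModel:
    """Equal-covariance Gaussian classifier over the three subsets.

    ``class_means`` is 3 x |genes| in fixed subset order; ``pooled_cov``
    is the shrunk pooled within-class covariance; ``priors`` are the
    training class frequencies.
    """

    genes: list[str]
    class_means: np.ndarray
    pooled_cov: np.ndarray
    priors: np.ndarray
    shrinkage: float
    trained_on: list[str]

    def __post_init__(self) -> None:
        assert abs(self.priors.sum() - 1.0) < 1e-12


def fit_lda(
    bulk: np.ndarray,
    labels: pd.Series,
    genes: list[str],
    gene_ids: list[str],
    sample_ids: list[str],
    shrinkage: float = 0.5,
) -> LdaModel:
    """Fit LDA on bulk profiles restricted to ``genes``.

    ``bulk`` is genes x samples over ``gene_ids``/``sample_ids``; class
    means are per-class sample means, the pooled within-class covariance
    uses denominator (n - k), and the regularized covariance is
    ``(1 - s) S + s diag(S) + eps I`` with ``eps = 1e-8 tr(S)/p``.
    """
    if not (0.0 <= shrinkage <= 1.0):
        raise ValueError("shrinkage must lie in [0, 1]")
    row = {g: i for i, g in enumerate(gene_ids)}
    missing = [g for g in genes if g not in row]
    if missing:
        raise KeyError(f"genes absent from bulk matrix: {missing[:5]}")
    x = bulk[[row[g] for g in genes], :].T  # samples x genes
    labels = labels.loc[sample_ids]
    classes = [c for c in SUBSET_LABELS if (labels == c).any()]
    if len(classes) < 2:
        raise ValueError("need at least 2 classes present in the training labels")
    p = len(genes)
    n = x.shape[0]
    k = len(classes)
    means = np.zeros((3, p))
    scatter = np.zeros((p, p))
    counts = np.zeros(3)
    for ci, c in enumerate(SUBSET_LABELS):
        mask = (labels == c).to_numpy()
        counts[ci] = mask.sum()
        if counts[ci] == 0:
            continue
        xc = x[mask]
        means[ci] = xc.mean(axis=0)
        centered = xc - means[ci]
        scatter += centered.T @ centered
    s = scatter / (n - k)
    eps = 1e-8 * np.trace(s) / p if np.trace(s) > 0 else 1e-8
    s_reg = (1.0 - shrinkage) * s + shrinkage * np.diag(np.diag(s))
    s_reg[np.diag_indices(p)] += eps
    s_reg = (s_reg + s_reg.T) / 2.0
    try:
        scipy.linalg.cho_factor(s_reg)
    except scipy.linalg.LinAlgError as exc:
        raise ValueError(
            "regularized pooled covariance is numerically singular; "
            "increase shrinkage (shrinkage=1 gives diagonal LDA)"
        ) from exc
    priors = counts / counts.sum()
    return LdaModel(
        genes=list(genes),
        class_means=means,
        pooled_cov=s_reg,
        priors=priors,
        shrinkage=shrinkage,
        trained_on=list(sample_ids),
    )


def classify_cells(model: LdaModel, sc: ExpressionMatrix) -> pd.DataFrame:
    """Posterior subset probabilities for every cell.

    Discriminant scores delta_c = x' S^-1 mu_c - mu_c' S^-1 mu_c / 2 +
    log pi_c, softmaxed stably into posteriors; prediction is the argmax
    with ties broken toward the fixed subset order. Returns a DataFrame
    with columns ``cell_id, predicted, p_<subset>`` (three posterior
    columns) and ``max_posterior``.
    """
    row = {g: i for i, g in enumerate(sc.gene_ids)}
    missing = [g for g in model.genes if g not in row]
    if missing:
        raise KeyError(
            f"single-cell matrix lacks {len(missing)} model genes, e.g. "
            f"{missing[:5]}"
        )
    x = sc.values[[row[g] for g in model.genes], :]  # p x cells
    if not np.isfinite(x).all():
        bad = int(np.argwhere(~np.isfinite(x).all(axis=0)).ravel()[0])
        raise ValueError(f"non-finite expression in cell {sc.sample_ids[bad]!r}")
    cho = scipy.linalg.cho_factor(model.pooled_cov)
    # alpha: p x 3 with columns S^-1 mu_c; only classes with prior > 0 score
    alpha = scipy.linalg.cho_solve(cho, model.class_means.T)
    const = -0.5 * np.einsum("cp,pc->c", model.class_means, alpha)
    with np.errstate(divide="ignore"):
        log_prior = np.where(model.priors > 0, np.log(model.priors), -np.inf)
    scores = x.T @ alpha + const + log_prior  # cells x 3
    shifted = scores - scores.max(axis=1, keepdims=True)
    expd = np.exp(shifted)
    posteriors = expd / expd.sum(axis=1, keepdims=True)
    predicted = [SUBSET_LABELS[i] for i in posteriors.argmax(axis=1)]
    out = pd.DataFrame(
        {
            "cell_id": sc.sample_ids,
            "predicted": predicted,
            **{
                f"p_{s}": posteriors[:, i] for i, s in enumerate(SUBSET_LABELS)
            },
        }
    )
    out["max_posterior"] = posteriors.max(axis=1)
    return out


def classification_summary(
    cls: pd.DataFrame, gate_subset_labels: pd.Series
) -> dict:
    """Cross-modal agreement summary.

    Reports the median maximal posterior, per-subset counts by gate and
    by classification, the RMSE between the two 3-vectors of subset
    proportions, and the overall per-cell agreement fraction.
    """
    gate = gate_subset_labels.loc[cls["cell_id"]].to_numpy()
    pred = cls["predicted"].to_numpy()
    n = len(pred)
    p_gate = np.array([(gate == s).mean() for s in SUBSET_LABELS])
    p_pred = np.array([(pred == s).mean() for s in SUBSET_LABELS])
    rmse = float(np.sqrt(((p_gate - p_pred) ** 2).mean()))
    return {
        "n_cells": n,
        "median_max_posterior": float(cls["max_posterior"].median()),
        "counts_by_gate": {s: int((gate == s).sum()) for s in SUBSET_LABELS},
        "counts_by_classification": {
            s: int((pred == s).sum()) for s in SUBSET_LABELS
        },
        "proportion_rmse": rmse,
        "agreement_fraction": float((gate == pred).mean()),
    }
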