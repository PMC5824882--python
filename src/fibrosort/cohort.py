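"""Disease-group comparison of per-donor subset proportions.

Each donor contributes a 3-vector of subset proportions (from flow
cytometry or classified cells). Per subset, RA and OA donors are compared
with Wilcoxon's rank-sum test against a Bonferroni threshold of 0.05/3,
and the disease association is summarized as an odds ratio from a
logistic regression of disease status on the proportion (per
10-percentage-point unit by default, a definition of this package since
a proportion has no intrinsic odds). Correlations with inflammation
covariates use Spearman's rank correlation or an OLS slope.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .datatypes import SUBSET_LABELS

logger = logging.getLogger(__name__)

__all__ = [
    "GroupComparison",
    "proportions_from_labels",
    "wilcoxon_rank_sum",
    "proportion_odds_ratio",
    "bonferroni_threshold",
    "covariate_association",
    "compare_groups",
]


def proportions_from_labels(
    labels: pd.Series, meta: pd.DataFrame, min_cells: int = 20
) -> pd.DataFrame:
    """Per-donor subset proportions from per-cell subset labels.

    Donors with zero cells are excluded with a warning; donors with fewer
    than ``min_cells`` cells are retained but flagged (their proportions
    are noisy).
    """
    donor = meta.set_index("sample_id")["donor_id"].loc[labels.index]
    disease = meta.set_index("sample_id")["disease"].loc[labels.index]
    rows = []
    for d in pd.unique(donor):
        mask = donor == d
        cells = labels[mask]
        if len(cells) == 0:
            logger.warning("donor %r has no cells; excluded", d)
            continue
        props = [float((cells == s).mean()) for s in SUBSET_LABELS]
        rows.append(
            [d, disease[mask].iloc[0], *props, len(cells), len(cells) < min_cells]
        )
    return pd.DataFrame(
        rows,
        columns=["donor_id", "disease", *SUBSET_LABELS, "n_cells", "low_count"],
    )


def wilcoxon_rank_sum(
    x: np.ndarray, y: np.ndarray, mode: str = "auto"
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (W, p).

    W is the rank sum of ``x`` (midranks for ties). ``mode='exact'``
    enumerates the permutation distribution when the combined sample has
    at most 20 observations and no ties, otherwise (and for
    ``mode='approx'``) a normal approximation with tie and continuity
    corrections is used. Completely constant data yields p = 1 with a
    warning.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size < 1 or y.size < 1:
        raise ValueError("both samples must be nonempty")
    if mode not in ("auto", "exact", "approx"):
        raise ValueError("mode must be 'auto', 'exact' or 'approx'")
    combined = np.concatenate([x, y])
    ranks = scipy.stats.rankdata(combined)
    w = float(ranks[: x.size].sum())
    if np.ptp(combined) == 0:
        warnings.warn("all values identical across both groups; p = 1")
        return w, 1.0
    has_ties = len(np.unique(combined)) < combined.size
    use_exact = (
        mode in ("auto", "exact") and (x.size + y.size) <= 20 and not has_ties
    )
    method = "exact" if use_exact else "asymptotic"
    res = scipy.stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return w, float(res.pvalue)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test significance threshold alpha / m."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def _logistic_newton(
    x: np.ndarray, y: np.ndarray, max_iter: int = 100, tol: float = 1e-10
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Newton-Raphson fit of logit(P(y=1)) = b0 + b1 x.

    Returns (coefficients, standard errors, converged).
    """
    design = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    converged = False
    for _ in range(max_iter):
        eta = design @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        wt = mu * (1.0 - mu)
        grad = design.T @ (y - mu)
        hess = (design * wt[:, None]).T @ design
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.abs(step).max() < tol:
            converged = True
            break
    eta = design @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    wt = mu * (1.0 - mu)
    hess = (design * wt[:, None]).T @ design
    try:
        cov = np.linalg.inv(hess)
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        se = np.full(2, np.inf)
    return beta, se, converged


def proportion_odds_ratio(
    pt: pd.DataFrame, subset: str, unit: float = 0.10
) -> dict:
    """Odds ratio for RA per ``unit`` increase in a subset's proportion.

    Logistic regression of disease (RA = 1) on proportion / unit, fitted
    by Newton-Raphson, with a Wald 95% CI. Perfect separation (every RA
    proportion above every OA proportion, or vice versa) is reported as an
    infinite/zero OR with a flag rather than failing silently.
    """
    if unit <= 0:
        raise ValueError("unit must be > 0")
    if subset not in pt.columns:
        raise KeyError(f"subset column {subset!r} absent from proportion table")
    y = (pt["disease"] == "RA").to_numpy(dtype=np.float64)
    if y.all() or not y.any():
        raise ValueError("both disease groups must be present")
    x = pt[subset].to_numpy(dtype=np.float64) / unit
    x_ra, x_oa = x[y == 1], x[y == 0]
    separated = x_ra.min() > x_oa.max() or x_ra.max() < x_oa.min()
    if separated:
        direction = 1.0 if x_ra.min() > x_oa.max() else -1.0
        return {
            "subset": subset,
            "odds_ratio": float("inf") if direction > 0 else 0.0,
            "ci_low": float("nan"),
            "ci_high": float("nan"),
            "unit": unit,
            "separated": True,
            "converged": False,
        }
    beta, se, converged = _logistic_newton(x, y)
    z = scipy.stats.norm.ppf(0.975)
    return {
        "subset": subset,
        "odds_ratio": float(np.exp(beta[1])),
        "ci_low": float(np.exp(beta[1] - z * se[1])),
        "ci_high": float(np.exp(beta[1] + z * se[1])),
        "log_or_se": float(se[1]),
        "unit": unit,
        "separated": False,
        "converged": bool(converged),
    }


@dataclass
class GroupComparison:
    """RA vs OA comparison of one subset's per-donor proportions."""

    subset: str
    median_ra: float
    median_oa: float
    w_statistic: float
    p_value: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    alpha_adjusted: float
    separated: bool = False

    def to_dict(self) -> dict:
        return {
            "subset": self.subset,
            "median_ra": self.median_ra,
            "median_oa": self.median_oa,
            "w_statistic": self.w_statistic,
            "p_value": self.p_value,
            "odds_ratio": self.odds_ratio,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "alpha_adjusted": self.alpha_adjusted,
            "significant": self.p_value < self.alpha_adjusted,
            "separated": self.separated,
        }


def compare_groups(
    pt: pd.DataFrame, alpha: float = 0.05, m: int = 3, unit: float = 0.10
) -> list[GroupComparison]:
    """Wilcoxon + odds-ratio comparison for each of the three subsets."""
    thr = bonferroni_threshold(alpha, m)
    out = []
    for subset in SUBSET_LABELS:
        ra = pt.loc[pt["disease"] == "RA", subset].to_numpy()
        oa = pt.loc[pt["disease"] == "OA", subset].to_numpy()
        w, p = wilcoxon_rank_sum(ra, oa)
        orr = proportion_odds_ratio(pt, subset, unit)
        out.append(
            GroupComparison(
                subset=subset,
                median_ra=float(np.median(ra)),
                median_oa=float(np.median(oa)),
                w_statistic=w,
                p_value=p,
                odds_ratio=orr["odds_ratio"],
                ci_low=orr["ci_low"],
                ci_high=orr["ci_high"],
                alpha_adjusted=thr,
                separated=orr["separated"],
            )
        )
    return out


def covariate_association(
    proportion: np.ndarray, covariate: np.ndarray, method: str = "spearman"
) -> dict:
    """Association of a subset proportion with a per-donor covariate.

    ``spearman``: midrank Spearman rho with the t approximation p-value.
    ``linear``: OLS slope, its standard error and a two-sided t-test p.
    """
    x = np.asarray(proportion, dtype=np.float64)
    y = np.asarray(covariate, dtype=np.float64)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in proportion or covariate")
    if method == "spearman":
        rho, p = scipy.stats.spearmanr(x, y)
        return {"method": "spearman", "rho": float(rho), "p_value": float(p)}
    if method == "linear":
        res = scipy.stats.linregress(x, y)
        return {
            "method": "linear",
            "slope": float(res.slope),
            "intercept": float(res.intercept),
            "stderr": float(res.stderr),
            "p_value": float(res.pvalue),
        }
    raise ValueError("method must be 'spearman' or 'linear'")
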