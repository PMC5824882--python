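"""Cell filtering and donor-effect residualization.

Donor-to-donor shifts dominate sorted-population transcriptomes, so every
gene is modelled as a linear combination of donor indicator effects fitted
by ordinary least squares; the residuals — equivalently, each value minus
its donor's per-gene mean — feed all downstream discovery steps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ResidualMatrix",
    "filter_cells_by_genes_detected",
    "residualize_donor",
    "marker_panel_report",
]


@dataclass
class ResidualMatrix:
    """Per-gene OLS residuals after removing donor effects.

    Within every donor, residual means are zero per gene (to numerical
    precision). ``donor_map`` records the sample -> donor assignment the
    residuals were computed under.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    donor_map: pd.Series

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


def filter_cells_by_genes_detected(
    m: ExpressionMatrix, meta: pd.DataFrame, min_genes: int
) -> tuple[ExpressionMatrix, pd.DataFrame, dict]:
    """Drop cells with fewer than ``min_genes`` detected genes.

    Returns the filtered matrix and metadata plus a report with the
    discarded count and fraction. Discarding every cell is a hard error.
    """
    if min_genes < 0:
        raise ValueError("min_genes must be >= 0")
    if "genes_detected" not in meta.columns:
        raise ValueError("metadata lacks the genes_detected column")
    meta = meta.set_index("sample_id", drop=False).loc[m.sample_ids]
    keep_mask = meta["genes_detected"].to_numpy() >= min_genes
    kept = [s for s, k in zip(m.sample_ids, keep_mask) if k]
    n_discarded = int((~keep_mask).sum())
    if not kept:
        raise ValueError(
            f"all {len(m.sample_ids)} cells fall below min_genes={min_genes}"
        )
    report = {
        "n_input": len(m.sample_ids),
        "n_retained": len(kept),
        "n_discarded": n_discarded,
        "fraction_discarded": n_discarded / len(m.sample_ids),
        "min_genes": int(min_genes),
    }
    return m.subset_samples(kept), meta.loc[kept].reset_index(drop=True), report


def residualize_donor(
    m: ExpressionMatrix | ResidualMatrix, meta: pd.DataFrame
) -> ResidualMatrix:
    """OLS residuals of each gene on donor indicators.

    With a saturated donor-indicator design the fit is each donor's mean,
    so residuals are donor-mean-centered values. Donors with a single
    sample contribute all-zero residuals (warned, not an error). Applying
    the operation twice is a no-op.
    """
    donor_map = (
        meta.set_index("sample_id")["donor_id"].astype(str).loc[m.sample_ids]
    )
    values = np.array(m.values, dtype=np.float64, copy=True)
    codes, donors = pd.factorize(donor_map.to_numpy())
    counts = np.bincount(codes)
    for d, c in zip(donors, counts):
        if c == 1:
            logger.warning(
                "donor %r has a single sample; its residuals are all zero", d
            )
    # per-gene donor means via one matmul: sums[g, d] / counts[d]
    indicator = np.zeros((len(codes), len(donors)))
    indicator[np.arange(len(codes)), codes] = 1.0
    donor_means = (values @ indicator) / counts
    values -= donor_means[:, codes]
    return ResidualMatrix(
        list(m.gene_ids), list(m.sample_ids), values, donor_map
    )


def marker_panel_report(
    m: ExpressionMatrix, panels: Mapping[str, Sequence[str]]
) -> pd.DataFrame:
    """Mean expression per sample for each named marker panel.

    Used to confirm lineage identity (e.g. fibroblast vs endothelial vs
    hematopoietic panels). Panels with no genes in the matrix yield an
    all-missing column rather than an error.
    """
    idx = {g: i for i, g in enumerate(m.gene_ids)}
    out = {}
    for name, genes in panels.items():
        rows = [idx[g] for g in genes if g in idx]
        if not rows:
            logger.warning("panel %r matched no genes in the matrix", name)
            out[name] = np.full(len(m.sample_ids), np.nan)
        else:
            out[name] = m.values[rows].mean(axis=0)
    return pd.DataFrame(out, index=m.sample_ids)
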