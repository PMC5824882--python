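"""Core domain types shared across the pipeline.

The analysis revolves around three objects:

* an :class:`ExpressionMatrix` — genes x samples abundances on a declared
  scale (linear TPM or log2);
* a sample metadata table (a validated :class:`pandas.DataFrame`) carrying
  donor, disease, modality and the flow-cytometry gate of each sample or
  cell;
* the three-level subset vocabulary into which the seven surface-marker
  gates collapse (CD34-THY1-, CD34-THY1+, CD34+).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SUBSET_LABELS",
    "DEFAULT_GATES",
    "DISEASES",
    "MODALITIES",
    "ExpressionMatrix",
    "RunConfig",
    "gate_to_subset",
    "to_log2",
]

#: Fixed order of the three major fibroblast subsets. Ties anywhere in the
#: pipeline (argmax of posteriors, majority votes) break toward the earlier
#: label in this tuple.
SUBSET_LABELS: tuple[str, str, str] = (
    "CD34neg_THY1neg",
    "CD34neg_THY1pos",
    "CD34pos",
)

#: Default 7-gate sorting vocabulary: four CD34- combinations of THY1/CDH11
#: and three CD34+ combinations. Any 7-label scheme can be substituted as
#: long as labels encode CD34/THY1 status the same way.
DEFAULT_GATES: tuple[str, ...] = (
    "CD34neg_THY1neg_CDH11neg",
    "CD34neg_THY1neg_CDH11pos",
    "CD34neg_THY1pos_CDH11neg",
    "CD34neg_THY1pos_CDH11pos",
    "CD34pos_THY1neg_CDH11neg",
    "CD34pos_THY1neg_CDH11pos",
    "CD34pos_THY1pos_CDH11pos",
)

DISEASES = ("RA", "OA")
MODALITIES = ("bulk", "single_cell")

#: Required columns of every sample metadata table.
META_COLUMNS = ("sample_id", "donor_id", "disease", "modality", "gate")


def gate_to_subset(gate: str) -> str:
    """Collapse a surface-marker gate label into its major subset.

    The marker rule ignores CDH11: every CD34+ gate maps to ``CD34pos``,
    CD34- gates split on THY1 status.
    """
    if gate.startswith("CD34pos"):
        return "CD34pos"
    if gate.startswith("CD34neg"):
        return "CD34neg_THY1pos" if "THY1pos" in gate else "CD34neg_THY1neg"
    raise ValueError(
        f"gate label {gate!r} does not encode CD34 status; expected a label "
        "starting with 'CD34pos' or 'CD34neg'"
    )


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with a declared scale.

    Parameters
    ----------
    gene_ids, sample_ids
        Unique, ordered identifiers for rows and columns.
    values
        Real matrix of shape ``(len(gene_ids), len(sample_ids))``.
    scale
        ``"tpm"`` (linear, nonnegative) or ``"log2"``.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    scale: str

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=np.float64)
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if self.scale not in ("tpm", "log2"):
            raise ValueError(f"unknown scale {self.scale!r}; use 'tpm' or 'log2'")
        if self.values.ndim != 2 or self.values.shape != (
            len(self.gene_ids),
            len(self.sample_ids),
        ):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.isfinite(self.values).all():
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                "non-finite expression value at gene "
                f"{self.gene_ids[bad[0]]!r}, sample {self.sample_ids[bad[1]]!r}"
            )
        if self.scale == "tpm" and (self.values < 0).any():
            bad = np.argwhere(self.values < 0)[0]
            raise ValueError(
                "negative value on the TPM scale at gene "
                f"{self.gene_ids[bad[0]]!r}, sample {self.sample_ids[bad[1]]!r}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.gene_ids, columns=self.sample_ids
        )

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        """Row-subset preserving the requested gene order."""
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in idx]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing[:5]}")
        rows = [idx[g] for g in genes]
        return ExpressionMatrix(
            list(genes), list(self.sample_ids), self.values[rows], self.scale
        )

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in samples if s not in idx]
        if missing:
            raise KeyError(f"samples absent from matrix: {missing[:5]}")
        cols = [idx[s] for s in samples]
        return ExpressionMatrix(
            list(self.gene_ids), list(samples), self.values[:, cols], self.scale
        )


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {what} identifier: {x!r}")
        seen.add(x)


def to_log2(m: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2-transform a TPM matrix: ``log2(tpm + pseudocount)``.

    ``pseudocount`` must be positive; 0 is allowed only when every value is
    strictly positive. Transforming an already log2 matrix is an error.
    """
    if m.scale == "log2":
        raise ValueError("matrix is already on the log2 scale")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if pseudocount == 0 and (m.values <= 0).any():
        raise ValueError(
            "pseudocount 0 requires strictly positive values everywhere"
        )
    return ExpressionMatrix(
        list(m.gene_ids),
        list(m.sample_ids),
        np.log2(m.values + pseudocount),
        "log2",
    )


@dataclass
class RunConfig:
    """Analysis thresholds, mirroring the published defaults.

    ``fdr_discovery`` gates the across-gate ANOVA (1% FDR);
    ``fdr_pairwise`` gates the pairwise subset contrasts feeding the LDA
    gene list (5% FDR); single cells need at least ``sc_min_genes``
    detected genes; the unbiased single-cell heatmap genes come from the
    top ``topq_mean``/``topq_var`` quantiles of mean and variance; LDA
    genes must exceed ``sc_expr_floor_log2`` (log2 of 10 TPM) in
    single-cell mean expression; group tests use a Bonferroni threshold of
    0.05 / ``bonferroni_m``.
    """

    seed: int = 0
    fdr_discovery: float = 0.01
    fdr_pairwise: float = 0.05
    sc_min_genes: int = 5000
    topq_mean: float = 0.01
    topq_var: float = 0.01
    sc_expr_floor_log2: float = math.log2(10.0)
    n_permutations: int = 9999
    lda_shrinkage: float = 0.5
    bonferroni_m: int = 3
    linkage_method: str = "average"
    collapse_rule: str = "marker"

    def __post_init__(self) -> None:
        for name in ("fdr_discovery", "fdr_pairwise", "topq_mean", "topq_var"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1); got {v}")
        if not (0.0 <= self.lda_shrinkage <= 1.0):
            raise ValueError("lda_shrinkage must lie in [0, 1]")
        if self.sc_min_genes < 0 or self.bonferroni_m < 1:
            raise ValueError("sc_min_genes must be >= 0 and bonferroni_m >= 1")
        if self.n_permutations < 99:
            raise ValueError("n_permutations must be >= 99")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def validate_metadata(
    meta: pd.DataFrame, gate_vocabulary: Sequence[str] = DEFAULT_GATES
) -> pd.DataFrame:
    """Validate a sample metadata table in place and return it.

    Requires the columns ``sample_id, donor_id, disease, modality, gate``;
    rejects duplicate sample ids, unknown disease/modality levels and gate
    labels outside ``gate_vocabulary``.
    """
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata is missing required columns: {missing}")
    dup = meta["sample_id"][meta["sample_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate sample_id in metadata: {dup.iloc[0]!r}")
    bad_disease = set(meta["disease"]) - set(DISEASES)
    if bad_disease:
        raise ValueError(
            f"unknown disease level(s) {sorted(bad_disease)}; allowed: {DISEASES}"
        )
    bad_mod = set(meta["modality"]) - set(MODALITIES)
    if bad_mod:
        raise ValueError(
            f"unknown modality level(s) {sorted(bad_mod)}; allowed: {MODALITIES}"
        )
    vocab = set(gate_vocabulary)
    bad_gate = set(meta["gate"]) - vocab
    if bad_gate:
        raise ValueError(
            f"unknown gate label(s) {sorted(bad_gate)}; allowed vocabulary: "
            f"{sorted(vocab)}"
        )
    if "genes_detected" in meta.columns:
        gd = pd.to_numeric(meta["genes_detected"])
        if (gd < 0).any():
            raise ValueError("genes_detected must be nonnegative")
        meta = meta.assign(genes_detected=gd.astype(int))
    return meta.reset_index(drop=True)
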