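"""Candidate biomarker identification: VIP scores and rank products.

Two complementary views of variable importance are combined.  The VIP
(variable importance in projection) score of a fitted PLS-DA model
apportions the response variance the model explains to the individual
predictors; the scores are scaled so their squares average 1, which makes
"VIP > 1" a natural relevance rule.  The rank product (RP) instead asks
how *consistently* a variable mattered across the resampling: in every
rDCV segment (one outer-fold model of one repetition) variables are ranked
by descending absolute regression coefficient (rank 1 = most
discriminant), and RP is the geometric mean of a variable's ranks over all
segments.  Low RP = persistently near the top.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .cohort import MultiBlockDataset
from .fusion import apply_scaling, fit_scaling
from .plsda import PLSDAModel, fit_plsda
from .validation import RDCVResult

__all__ = [
    "VIPResult",
    "RPResult",
    "vip",
    "rank_product",
    "select_candidates",
    "fit_reference_model",
]


@dataclass
class VIPResult:
    analytes: list[str]
    scores: np.ndarray

    @property
    def selected(self) -> np.ndarray:
        """Boolean mask of the VIP > 1 rule."""
        return self.scores > 1.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"vip": self.scores, "vip_selected": self.selected}, index=self.analytes
        )


@dataclass
class RPResult:
    analytes: list[str]
    rp: np.ndarray
    rank_table: np.ndarray  # (segments, p)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"rp": self.rp}, index=self.analytes)


def vip(model: PLSDAModel, analytes: list[str] | None = None) -> VIPResult:
    """VIP scores of a fitted PLS-DA model.

    ``VIP_j = sqrt( p * sum_a (w_ja / ||w_a||)^2 SSY_a / sum_a SSY_a )``
    with ``SSY_a = q_a^2 t_a' t_a`` the response variance captured by
    component a.  The squared scores sum to p by construction.
    """
    W = model.weights
    p = W.shape[0]
    ssy = model.y_loadings**2 * np.einsum("ia,ia->a", model.scores, model.scores)
    if ssy.sum() <= 0:
        raise ValueError("model explains no response variance")
    w_unit2 = W**2 / np.sum(W**2, axis=0)
    scores = np.sqrt(p * (w_unit2 @ ssy) / ssy.sum())
    if analytes is None:
        analytes = [f"x{j}" for j in range(p)]
    return VIPResult(list(analytes), scores)


def rank_product(result: RDCVResult) -> RPResult:
    """Rank product of absolute regression coefficients across rDCV segments.

    Per segment, rank 1 goes to the largest |coefficient| (average ranks on
    ties); RP is the geometric mean over segments, evaluated as the
    exponential of the mean log rank for numerical safety.  RP lies in
    [1, p].
    """
    coefs = result.segment_coefs
    if coefs.size == 0:
        raise ValueError("rDCV result contains no segments")
    ranks = np.apply_along_axis(rankdata, 1, -coefs)
    rp = np.exp(np.mean(np.log(ranks), axis=0))
    return RPResult(list(result.columns), rp, ranks)


def select_candidates(
    vip_result: VIPResult, rp_result: RPResult, k: int = 7
) -> list[str]:
    """Candidate analytes: the VIP > 1 set, ordered by ascending RP, top k.

    Both full score tables should always be reported alongside the
    selection; this function only applies the combined rule.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if vip_result.analytes != rp_result.analytes:
        raise ValueError("VIP and RP results cover different analyte sets")
    eligible = [
        (rp_result.rp[j], vip_result.analytes[j])
        for j in range(len(vip_result.analytes))
        if vip_result.scores[j] > 1.0
    ]
    eligible.sort()
    return [name for _, name in eligible[:k]]


def fit_reference_model(
    data: MultiBlockDataset, result: RDCVResult, threshold: float = 0.5
) -> PLSDAModel:
    """Fit the VIP-bearing reference model on all samples.

    The LV count is the median of the per-segment counts chosen inside the
    rDCV (halves truncated toward the smaller, more parsimonious model);
    scaling is refit on the full dataset.
    """
    a = max(1, int(np.median(result.chosen_components)))
    scaling = fit_scaling(data)
    fused = apply_scaling(scaling, data)
    a = min(a, data.n_samples - 1, fused.values.shape[1])
    return fit_plsda(fused.values, data.labels, a, threshold=threshold)
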