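"""SIMCA: one-class modeling with a reduced T2/Q acceptance distance.

Where discriminant analysis asks "case or control?", class modeling asks
"does this sample look like the modeled class at all?".  A SIMCA model of
one category is a principal component analysis of that category's samples
alone (after within-class autoscaling).  A sample's relation to the model
is summarized by two statistics: Hotelling's T2, the Mahalanobis distance
from the class center within the PC score space, and Q, the squared
orthogonal residual of the sample from the PC subspace.  Each is divided
by its 95th percentile over the calibration samples (the "reduced"
statistics), making the two comparable, and combined into a single
distance

    d = sqrt( (T2_red)^2 + (Q_red)^2 ),

with a sample accepted by the class when d < 2 (strict).  Sensitivity is
the percentage of in-class samples accepted, specificity the percentage of
out-of-class samples rejected, and efficiency their geometric mean; the
number of principal components is chosen to maximize cross-validated
efficiency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SIMCAModel",
    "SIMCAAssessment",
    "fit_simca",
    "simca_statistics",
    "simca_distance",
    "simca_classify",
    "assess",
    "efficiency_curve",
    "select_npc",
]

# A reduced statistic whose calibration 95th percentile is numerically zero
# (e.g. Q at full PC rank) is identically zero for any representable sample;
# treat it as contributing nothing to the distance.
_EPS = 1e-12


@dataclass
class SIMCAModel:
    """Within-class PCA with calibration 95th percentiles of T2 and Q."""

    means: np.ndarray            # (p,) within-class analyte means
    sds: np.ndarray              # (p,) within-class analyte SDs (ddof=1)
    loadings: np.ndarray         # (p, A) orthonormal PC loadings
    score_var: np.ndarray        # (A,) per-component score variances
    t2_95: float                 # calibration 95th percentile of T2
    q_95: float                  # calibration 95th percentile of Q
    threshold: float = 2.0
    calibration_t2: np.ndarray | None = None
    calibration_q: np.ndarray | None = None

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


@dataclass(frozen=True)
class SIMCAAssessment:
    sensitivity: float   # percent of in-class samples accepted
    specificity: float   # percent of out-of-class samples rejected
    mode: str = "calibration"

    @property
    def efficiency(self) -> float:
        return float(np.sqrt(self.sensitivity * self.specificity))


def _as_table(data) -> np.ndarray:
    X = data.to_numpy(dtype=float) if isinstance(data, pd.DataFrame) else np.asarray(data, dtype=float)
    return np.atleast_2d(X)


def fit_simca(class_data, n_components: int, threshold: float = 2.0) -> SIMCAModel:
    """Fit a one-class PCA model on samples of a single category.

    The class table is autoscaled with its own means/SDs, decomposed by
    SVD, and each calibration sample's T2 (score-space Mahalanobis
    distance, per-component variances with the n-1 denominator) and Q
    (squared reconstruction residual) are computed; their empirical 95th
    percentiles (linear interpolation) are stored for the reduction.
    """
    X = _as_table(class_data)
    n, p = X.shape
    if not (1 <= n_components <= min(n - 1, p)):
        raise ValueError(
            f"n_components must be in [1, min(n-1, p)] = [1, {min(n - 1, p)}]"
        )
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    if np.any(sds <= 0):
        bad = np.flatnonzero(sds <= 0)
        raise ValueError(f"zero within-class variance in column(s) {bad.tolist()}")
    Z = (X - means) / sds
    _, s, Vt = np.linalg.svd(Z, full_matrices=False)
    loadings = Vt[:n_components].T
    scores = Z @ loadings
    score_var = s[:n_components] ** 2 / (n - 1)
    t2 = np.sum(scores**2 / score_var, axis=1)
    resid = Z - scores @ loadings.T
    q = np.sum(resid**2, axis=1)
    return SIMCAModel(
        means=means,
        sds=sds,
        loadings=loadings,
        score_var=score_var,
        t2_95=float(np.percentile(t2, 95)),
        q_95=float(np.percentile(q, 95)),
        threshold=threshold,
        calibration_t2=t2,
        calibration_q=q,
    )


def simca_statistics(model: SIMCAModel, data) -> pd.DataFrame:
    """Per-sample T2_red, Q_red and the combined distance d.

    Out-of-class samples are transformed with the *class* model's scaling —
    the one-class model knows nothing else.
    """
    X = _as_table(data)
    if X.shape[1] != model.means.size:
        raise ValueError(
            f"samples have {X.shape[1]} variables, model expects {model.means.size}"
        )
    Z = (X - model.means) / model.sds
    scores = Z @ model.loadings
    t2 = np.sum(scores**2 / model.score_var, axis=1)
    q = np.sum((Z - scores @ model.loadings.T) ** 2, axis=1)
    t2_red = t2 / model.t2_95 if model.t2_95 > _EPS else np.zeros_like(t2)
    q_red = q / model.q_95 if model.q_95 > _EPS else np.zeros_like(q)
    d = np.hypot(t2_red, q_red)
    return pd.DataFrame({"t2_red": t2_red, "q_red": q_red, "d": d})


def simca_distance(model: SIMCAModel, sample) -> float | np.ndarray:
    """Combined class distance ``sqrt(T2_red^2 + Q_red^2)``.

    A single sample vector yields a scalar; a 2-D table yields one
    distance per row.
    """
    arr = np.asarray(sample, dtype=float)
    d = simca_statistics(model, arr)["d"].to_numpy()
    return float(d[0]) if arr.ndim == 1 else d


def simca_classify(model: SIMCAModel, data) -> np.ndarray:
    """Acceptance flags: True iff d < threshold (strict; default 2)."""
    arr = np.asarray(data, dtype=float)
    acc = simca_statistics(model, arr)["d"].to_numpy() < model.threshold
    return bool(acc[0]) if arr.ndim == 1 else acc


def assess(model: SIMCAModel, in_class_data, out_class_data, mode: str = "calibration") -> SIMCAAssessment:
    """Sensitivity / specificity / efficiency of a class model."""
    inn = _as_table(in_class_data)
    out = _as_table(out_class_data)
    if inn.size == 0 or out.size == 0:
        raise ValueError("assessment requires nonempty in- and out-of-class data")
    sens = 100.0 * np.mean(simca_classify(model, inn))
    spec = 100.0 * np.mean(~simca_classify(model, out))
    return SIMCAAssessment(sensitivity=float(sens), specificity=float(spec), mode=mode)


def _venetian_folds(n: int, k: int) -> np.ndarray:
    return np.arange(n) % k


def efficiency_curve(
    in_class_data, out_class_data, cv_folds: int = 7, a_max: int = 5
) -> pd.DataFrame:
    """Cross-validated sensitivity/specificity/efficiency per PC count.

    Venetian-blinds folds over the in-class samples; per fold the model is
    refit without the held-out class samples, which supply CV sensitivity
    (pooled), while the out-of-class samples are scored against every
    fold's model and their per-fold rejection rates averaged into CV
    specificity.
    """
    inn = _as_table(in_class_data)
    out = _as_table(out_class_data)
    n = inn.shape[0]
    if cv_folds < 2 or cv_folds > n:
        raise ValueError("infeasible fold count for the in-class sample size")
    fold = _venetian_folds(n, cv_folds)
    min_train = min(int(np.sum(fold != g)) for g in range(cv_folds))
    a_cap = min(a_max, min_train - 1, inn.shape[1])
    if a_cap < 1:
        raise ValueError("too few in-class samples per training fold")
    rows = []
    for a in range(1, a_cap + 1):
        accepted = np.empty(n, dtype=bool)
        spec_folds = []
        for g in range(cv_folds):
            te = fold == g
            model = fit_simca(inn[~te], a)
            accepted[te] = simca_classify(model, inn[te])
            spec_folds.append(100.0 * np.mean(~simca_classify(model, out)))
        rows.append(
            {
                "n_components": a,
                "sensitivity": 100.0 * accepted.mean(),
                "specificity": float(np.mean(spec_folds)),
            }
        )
    table = pd.DataFrame(rows)
    table["efficiency"] = np.sqrt(table["sensitivity"] * table["specificity"])
    return table


def select_npc(
    in_class_data, out_class_data, cv_folds: int = 7, a_max: int = 5
) -> int:
    """PC count with the highest cross-validated efficiency (ties: fewer PCs)."""
    table = efficiency_curve(in_class_data, out_class_data, cv_folds, a_max)
    best = int(table.loc[table["efficiency"].idxmax(), "n_components"])
    return best
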