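"""Repeated double cross-validation (rDCV) and permutation testing.

Small case-control panels make single train/test splits meaningless, so
the whole preprocess-and-fit pipeline is validated with two nested
cross-validation loops: the inner loop picks the number of latent
variables (minimum mean inner misclassification count, ties to the
smaller model), the outer loop produces out-of-fold predictions that never
touched model selection, and the whole procedure is repeated (default 30
times) over fresh random splits so results do not hinge on one partition.
Scaling (autoscaling + block normalization) is refit inside every training
fold by default — held-out samples never influence any learned parameter.

Three figures of merit summarize each repetition's pooled out-of-fold
predictions:

* NMC — number of misclassifications;
* AUROC — Mann-Whitney probability that a case's predicted response
  exceeds a control's (ties count one half);
* DQ2 — discriminant Q2: a prediction Q2 in which residuals of
  predictions *beyond* their class label (a case predicted above 1, a
  control below 0) are not penalized.

Their significance is assessed by a permutation test: class labels are
randomized, the full rDCV merit pipeline is re-run per randomization, and
the add-one estimator ``p = (1 + #{null at least as extreme}) / (n_perm + 1)``
is reported per merit (more extreme = smaller NMC, larger AUROC/DQ2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import MultiBlockDataset
from .fusion import DegenerateVariableError, _apply_scaling_arrays, _fit_scaling_arrays
from .plsda import fit_plsda, predict_components, predict_response

__all__ = [
    "RDCVConfig",
    "MeritSet",
    "RDCVResult",
    "PermutationResult",
    "nmc",
    "auroc",
    "dq2",
    "run_rdcv",
    "classification_summary",
    "permutation_test",
]


# ---------------------------------------------------------------------------
# figures of merit

def nmc(labels: Sequence[int], predicted_labels: Sequence[int]) -> int:
    """Number of misclassifications between two equal-length binary vectors."""
    y = np.asarray(labels)
    yhat = np.asarray(predicted_labels)
    if y.shape != yhat.shape:
        raise ValueError("label vectors must have equal length")
    return int(np.sum(y != yhat))


def auroc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Area under the ROC curve, Mann-Whitney pair-counting formulation.

    Fraction of (case, control) pairs in which the case scores strictly
    higher, with ties counted one half.  Computed through tie-averaged
    ranks, which is algebraically the same quantity.
    """
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("labels and scores must have equal length")
    n1 = int(np.sum(y == 1))
    n0 = int(np.sum(y == 0))
    if n1 == 0 or n0 == 0:
        raise ValueError("AUROC requires both classes")
    from scipy.stats import rankdata

    r = rankdata(s)
    u = float(np.sum(r[y == 1])) - n1 * (n1 + 1) / 2.0
    return u / (n1 * n0)


def dq2(labels: Sequence[int], predictions: Sequence[float]) -> float:
    """Discriminant Q2 of continuous predictions of a 0/1 response.

    ``DQ2 = 1 - PRESSD / TSS`` where the per-sample discriminant residual
    is zero whenever the prediction lies beyond its class label (>= 1 for
    a case, <= 0 for a control) and ``label - prediction`` otherwise;
    ``TSS`` is the total sum of squares of the labels about their mean.
    Always at least the raw-residual Q2, never more than 1.
    """
    y = np.asarray(labels, dtype=float)
    yhat = np.asarray(predictions, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("labels and predictions must have equal length")
    if np.unique(y).size < 2:
        raise ValueError("DQ2 requires both classes")
    resid = y - yhat
    resid[(y == 1) & (yhat >= 1)] = 0.0
    resid[(y == 0) & (yhat <= 0)] = 0.0
    tss = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - float(np.sum(resid**2)) / tss


# ---------------------------------------------------------------------------
# configuration and results

@dataclass(frozen=True)
class RDCVConfig:
    repetitions: int = 30
    outer_folds: int = 7
    inner_folds: int = 5
    a_max: int = 10
    seed: int = 0
    stratified: bool = True
    #: refit scaling inside every training fold (default) or, for strict
    #: replication of one-shot preprocessing, scale the full dataset once
    #: before splitting.
    refit_scaling: bool = True
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("fold counts must be >= 2")
        if self.a_max < 1:
            raise ValueError("a_max must be >= 1")


@dataclass(frozen=True)
class MeritSet:
    nmc: int
    auroc: float
    dq2: float


@dataclass
class RDCVResult:
    """Everything the downstream stages need from one rDCV run.

    ``predictions[r]`` holds repetition r's pooled out-of-fold continuous
    predictions in sample order (every sample predicted exactly once per
    repetition).  ``segment_coefs`` stacks the absolute composite
    regression coefficients of every outer-fold model (repetitions x
    outer_folds segments), feeding the rank-product ranking.
    """

    labels: np.ndarray                 # (n,)
    columns: list[str]
    predictions: np.ndarray            # (R, n)
    merits: list[MeritSet]
    percent_correct: pd.DataFrame      # R rows, columns case/control/overall
    chosen_components: np.ndarray      # (R, outer_folds)
    segment_coefs: np.ndarray          # (R * outer_folds, p), absolute values
    config: RDCVConfig = field(repr=False, default=None)

    @property
    def n_segments(self) -> int:
        return self.segment_coefs.shape[0]


@dataclass
class PermutationResult:
    observed: dict[str, float]         # across-repetition mean merit
    null: pd.DataFrame                 # n_perm rows, columns nmc/auroc/dq2
    pvalues: dict[str, float]
    observed_result: RDCVResult = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# splitting

def _fold_assignment(
    labels: np.ndarray, k: int, rng: np.random.Generator, stratified: bool
) -> np.ndarray:
    """Fold id per sample; stratified deals each class round-robin."""
    n = labels.size
    fold = np.empty(n, dtype=int)
    if stratified:
        for cls in np.unique(labels):
            idx = np.flatnonzero(labels == cls)
            rng.shuffle(idx)
            fold[idx] = np.arange(idx.size) % k
    else:
        idx = rng.permutation(n)
        fold[idx] = np.arange(n) % k
    return fold


def _check_feasible(labels: np.ndarray, config: RDCVConfig) -> None:
    n = labels.size
    counts = np.bincount(labels, minlength=2)
    if counts[0] < 2 or counts[1] < 2:
        raise ValueError("each class needs at least 2 samples")
    if config.outer_folds > n:
        raise ValueError("more outer folds than samples")
    if config.stratified and config.outer_folds > max(counts):
        raise ValueError("outer fold count exceeds the larger class size")


# ---------------------------------------------------------------------------
# the rDCV engine

def _inner_select(
    X: np.ndarray,
    y: np.ndarray,
    slices: dict[str, slice],
    columns: list[str],
    config: RDCVConfig,
    rng: np.random.Generator,
    prescaled: bool,
) -> int:
    """Pick the LV count minimizing total inner-CV misclassifications."""
    a_cap = min(config.a_max, X.shape[1])
    err = np.zeros(a_cap)
    fold = _fold_assignment(y, config.inner_folds, rng, config.stratified)
    for g in range(config.inner_folds):
        te = fold == g
        tr = ~te
        if not te.any():
            continue
        ytr = y[tr]
        if np.unique(ytr).size < 2:
            continue
        if prescaled:
            Ztr, Zte = X[tr], X[te]
        else:
            sm = _fit_scaling_arrays(X[tr], columns, slices)
            Ztr = _apply_scaling_arrays(sm, X[tr])
            Zte = _apply_scaling_arrays(sm, X[te])
        a_fit = min(a_cap, tr.sum() - 1)
        model = fit_plsda(Ztr, ytr, a_fit, threshold=config.threshold)
        preds = predict_components(model, Zte)  # (n_te, A_extracted)
        miss = ((preds > config.threshold).astype(int) != y[te][:, None]).sum(axis=0)
        # components beyond those extractable in this fold keep the fullest
        # available prediction
        err[: miss.size] += miss
        if miss.size < a_cap:
            err[miss.size:] += miss[-1]
    return int(np.argmin(err)) + 1  # argmin takes the smallest index on ties


def _rdcv_arrays(
    X: np.ndarray,
    labels: np.ndarray,
    columns: list[str],
    slices: dict[str, slice],
    config: RDCVConfig,
    seed_seq: np.random.SeedSequence,
    repetitions: int,
) -> RDCVResult:
    n, p = X.shape
    _check_feasible(labels, config)
    prescaled = not config.refit_scaling
    if prescaled:
        sm = _fit_scaling_arrays(X, columns, slices)
        X = _apply_scaling_arrays(sm, X)

    K = config.outer_folds
    preds = np.empty((repetitions, n))
    merits: list[MeritSet] = []
    pc = np.empty((repetitions, 3))
    chosen = np.empty((repetitions, K), dtype=int)
    seg_coefs = np.empty((repetitions * K, p))

    is_case = labels == 1
    rep_seqs = seed_seq.spawn(repetitions)
    for r in range(repetitions):
        rng = np.random.default_rng(rep_seqs[r])
        fold = _fold_assignment(labels, K, rng, config.stratified)
        yhat = np.empty(n)
        for f in range(K):
            te = fold == f
            tr = ~te
            ytr = labels[tr]
            if np.unique(ytr).size < 2:
                raise ValueError(
                    f"outer-training set of fold {f} contains a single class"
                )
            try:
                a_star = _inner_select(
                    X[tr], ytr, slices, columns, config, rng, prescaled
                )
                if prescaled:
                    Ztr, Zte = X[tr], X[te]
                else:
                    sm = _fit_scaling_arrays(X[tr], columns, slices)
                    Ztr = _apply_scaling_arrays(sm, X[tr])
                    Zte = _apply_scaling_arrays(sm, X[te])
            except DegenerateVariableError as exc:
                raise DegenerateVariableError(
                    f"repetition {r}, outer fold {f}: {exc}"
                ) from exc
            a_fit = min(a_star, tr.sum() - 1, p)
            model = fit_plsda(Ztr, ytr, a_fit, threshold=config.threshold)
            if te.any():
                yhat[te] = predict_response(model, Zte)
            chosen[r, f] = model.n_components
            seg_coefs[r * K + f] = np.abs(model.coef)
        preds[r] = yhat
        pred_labels = (yhat > config.threshold).astype(int)
        merits.append(
            MeritSet(
                nmc=nmc(labels, pred_labels),
                auroc=auroc(labels, yhat),
                dq2=dq2(labels, yhat),
            )
        )
        pc[r, 0] = 100.0 * np.mean(pred_labels[is_case] == 1)
        pc[r, 1] = 100.0 * np.mean(pred_labels[~is_case] == 0)
        pc[r, 2] = 100.0 * np.mean(pred_labels == labels)

    return RDCVResult(
        labels=labels.copy(),
        columns=list(columns),
        predictions=preds,
        merits=merits,
        percent_correct=pd.DataFrame(pc, columns=["case", "control", "overall"]),
        chosen_components=chosen,
        segment_coefs=seg_coefs,
        config=config,
    )


def run_rdcv(data: MultiBlockDataset, config: RDCVConfig) -> RDCVResult:
    """Run repeated double cross-validation of the fusion + PLS-DA pipeline.

    Deterministic given ``config.seed``: one master seed sequence fans out
    into per-repetition substreams.
    """
    X, columns, slices = data.to_matrix()
    return _rdcv_arrays(
        X, data.labels, columns, slices, config,
        np.random.SeedSequence(config.seed), config.repetitions,
    )


def classification_summary(result: RDCVResult) -> pd.DataFrame:
    """Across-repetition mean and SD (n-1 denominator) of percent correct.

    Rows ``case``, ``control``, ``overall``; per-class percent correct is
    computed per repetition on that repetition's pooled out-of-fold
    predictions, then averaged across repetitions.
    """
    pc = result.percent_correct
    if pc.empty:
        raise ValueError("empty rDCV result")
    mean = pc.mean(axis=0)
    sd = pc.std(axis=0, ddof=1) if len(pc) > 1 else pc.iloc[0] * 0.0
    return pd.DataFrame({"mean": mean, "sd": sd})


def permutation_test(
    data: MultiBlockDataset,
    config: RDCVConfig,
    n_perm: int = 1000,
    perm_repetitions: int = 1,
) -> PermutationResult:
    """Permutation test of the rDCV figures of merit.

    The observed merits are the across-repetition means from an rDCV run at
    ``config``.  Each randomization permutes the class labels and re-runs
    the identical pipeline with ``perm_repetitions`` repetitions (default 1
    for tractability; set it to ``config.repetitions`` to mirror the
    observed pipeline exactly).  P-values use the add-one estimator, so the
    smallest attainable p is ``1 / (n_perm + 1)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if perm_repetitions < 1:
        raise ValueError("perm_repetitions must be >= 1")
    observed_result = run_rdcv(data, config)
    obs = {
        "nmc": float(np.mean([m.nmc for m in observed_result.merits])),
        "auroc": float(np.mean([m.auroc for m in observed_result.merits])),
        "dq2": float(np.mean([m.dq2 for m in observed_result.merits])),
    }
    X, columns, slices = data.to_matrix()
    null = np.empty((n_perm, 3))
    for i in range(n_perm):
        ss = np.random.SeedSequence([config.seed & 0x7FFFFFFF, 0x5EED, i])
        rng = np.random.default_rng(ss)
        perm_labels = rng.permutation(data.labels)
        res = _rdcv_arrays(
            X, perm_labels, columns, slices, config, ss.spawn(1)[0], perm_repetitions
        )
        null[i, 0] = np.mean([m.nmc for m in res.merits])
        null[i, 1] = np.mean([m.auroc for m in res.merits])
        null[i, 2] = np.mean([m.dq2 for m in res.merits])
    null_df = pd.DataFrame(null, columns=["nmc", "auroc", "dq2"])
    pvals = {
        "nmc": float(1.0 + np.sum(null[:, 0] <= obs["nmc"])) / (n_perm + 1),
        "auroc": float(1.0 + np.sum(null[:, 1] >= obs["auroc"])) / (n_perm + 1),
        "dq2": float(1.0 + np.sum(null[:, 2] >= obs["dq2"])) / (n_perm + 1),
    }
    return PermutationResult(
        observed=obs, null=null_df, pvalues=pvals, observed_result=observed_result
    )
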