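"""Low-level (measurement-level) data fusion of multi-platform blocks.

Blocks measured on different platforms live on incommensurate scales, so
before a joint model is fit each variable is autoscaled (centered, divided
by its training standard deviation) and each block is then divided by the
Frobenius norm of its autoscaled training submatrix.  After this every
block contributes unit total variance regardless of how many variables it
holds or what units they carry; the normalized blocks are concatenated
column-wise into one fused matrix.

All scaling statistics are learned from training samples only and applied
unchanged to held-out samples, which keeps cross-validation honest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .cohort import MultiBlockDataset

__all__ = [
    "DegenerateVariableError",
    "ScalingModel",
    "FusedMatrix",
    "fit_scaling",
    "apply_scaling",
    "inverse_scaling",
]


class DegenerateVariableError(ValueError):
    """A variable has zero sample variance in the training set."""


@dataclass
class FusedMatrix:
    """Fused samples x analytes matrix with its column -> block map."""

    values: np.ndarray
    columns: list[str]
    block_of: dict[str, str]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class ScalingModel:
    """Per-analyte means/SDs and per-block Frobenius norms, training-derived."""

    columns: list[str]
    means: np.ndarray
    sds: np.ndarray
    block_slices: dict[str, slice]
    block_norms: dict[str, float]

    @property
    def block_of(self) -> dict[str, str]:
        return {
            self.columns[j]: blk
            for blk, sl in self.block_slices.items()
            for j in range(sl.start, sl.stop)
        }

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "columns": self.columns,
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "blocks": {
                blk: {"start": sl.start, "stop": sl.stop, "norm": self.block_norms[blk]}
                for blk, sl in self.block_slices.items()
            },
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ScalingModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        return cls(
            columns=list(payload["columns"]),
            means=np.asarray(payload["means"], dtype=float),
            sds=np.asarray(payload["sds"], dtype=float),
            block_slices={
                blk: slice(b["start"], b["stop"]) for blk, b in payload["blocks"].items()
            },
            block_norms={blk: float(b["norm"]) for blk, b in payload["blocks"].items()},
        )


def _fit_scaling_arrays(
    X: np.ndarray, columns: list[str], block_slices: dict[str, slice]
) -> ScalingModel:
    n = X.shape[0]
    if n < 2:
        raise ValueError("scaling requires at least 2 training samples")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    bad = np.flatnonzero(sds <= 0)
    if bad.size:
        names = ", ".join(columns[j] for j in bad)
        raise DegenerateVariableError(
            f"zero training variance for analyte(s): {names}"
        )
    Z = (X - means) / sds
    norms = {}
    for blk, sl in block_slices.items():
        norms[blk] = float(np.sqrt(np.sum(Z[:, sl] ** 2)))
    return ScalingModel(list(columns), means, sds, dict(block_slices), norms)


def _apply_scaling_arrays(model: ScalingModel, X: np.ndarray) -> np.ndarray:
    Z = (X - model.means) / model.sds
    for blk, sl in model.block_slices.items():
        Z[:, sl] /= model.block_norms[blk]
    return Z


def fit_scaling(train: MultiBlockDataset) -> ScalingModel:
    """Learn autoscaling and block-norm parameters from training samples.

    SDs use the n-1 denominator.  A zero-variance analyte raises
    :class:`DegenerateVariableError` naming the analyte — silently dropping
    or epsilon-padding it would desynchronize downstream variable rankings.
    """
    X, columns, block_slices = train.to_matrix()
    return _fit_scaling_arrays(X, columns, block_slices)


def apply_scaling(model: ScalingModel, data: MultiBlockDataset) -> FusedMatrix:
    """Transform a dataset with a fitted scaling model and concatenate blocks.

    Each entry becomes ``((x - mean) / sd) / block_norm``; column order is
    the model's fixed block-then-analyte order.  Analyte or block mismatch
    raises ``ValueError``.
    """
    X, columns, block_slices = data.to_matrix()
    if columns != model.columns or {
        b: (s.start, s.stop) for b, s in block_slices.items()
    } != {b: (s.start, s.stop) for b, s in model.block_slices.items()}:
        raise ValueError("dataset schema does not match the fitted scaling model")
    return FusedMatrix(_apply_scaling_arrays(model, X), list(columns), model.block_of)


def inverse_scaling(model: ScalingModel, fused: FusedMatrix | np.ndarray) -> np.ndarray:
    """Map fused values back to the original measurement scale."""
    Z = fused.values if isinstance(fused, FusedMatrix) else np.asarray(fused, dtype=float)
    X = Z.copy()
    for blk, sl in model.block_slices.items():
        X[:, sl] *= model.block_norms[blk]
    return X * model.sds + model.means
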