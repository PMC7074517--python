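"""Synthetic case-control cohort generation for multi-platform biomarker panels.

The analysis pipeline in this package was designed around a small
case-control study (16 Parkinson's disease cases, 12 controls) in which 37
serum analytes were measured on three platforms: a 27-plex bead-based
cytokine/chemokine/growth-factor panel, a 4-analyte automated immunoassay
(CRP, MPO, FGF21, BDNF), and a 6-analyte extracellular-vesicle immunoblot
(tetraspanins CD9/CD63/CD81 and the mitochondrial subunits
ATP5A/NDUFS3/SDHB).  The raw cohort data were never deposited; what is
public are per-arm medians and interquartile ranges for the seven analytes
the discriminant analysis singled out.  This module turns those printed
summaries into a seeded generator: each analyte, in each arm, is drawn from
a log-normal distribution whose median and IQR exactly match the published
(or default) values.  Log-normals are strictly positive and right-skewed,
which is how serum cytokine data actually look, and they admit a closed-form
median/IQR match (see :func:`fit_lognormal`).

Analytes with no published arm difference are given identical parameters in
both arms ("null analytes"); downstream autoscaling removes their arbitrary
location and scale, so any shared default works.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AnalyteSpec",
    "CohortConfig",
    "MultiBlockDataset",
    "BLOCK_NAMES",
    "build_default_panel",
    "fit_lognormal",
    "generate_cohort",
]

# Standard normal 75th-percentile quantile, z_{0.75}.
_Z75 = 0.6744897501960817

BLOCK_NAMES = ("multiplex_panel", "automated_immunoassay", "ev_immunoblot")

# 27-plex bead panel: 16 cytokines, 6 chemokines, 5 growth factors.
_MULTIPLEX = [
    "IFNg", "IL1b", "IL1Ra", "IL2", "IL4", "IL5", "IL6", "IL7", "IL8",
    "IL9", "IL10", "IL12", "IL13", "IL15", "IL17", "TNFa",
    "CCL5", "CCL11", "IP-10", "MCP-1", "MIP-1a", "MIP-1b",
    "FGF-b", "G-CSF", "GM-CSF", "PDGF-BB", "VEGF",
]
_IMMUNOASSAY = ["CRP", "MPO", "FGF21", "BDNF"]
_EV_BLOT = ["CD9", "CD63", "CD81", "ATP5A", "NDUFS3", "SDHB"]

# Published per-arm median (IQR) for the seven discriminant analytes:
# analyte -> (control_median, control_iqr, case_median, case_iqr).
# The NDUFS3 case entry is typeset as "96.8 +/- 128.0" in the source table
# (a mean+/-SD amid median(IQR) rows); it is read here as median 96.8,
# IQR 128.0 for consistency with the rest of the table.
_DISCRIMINANT_PARAMS = {
    "CD9": (1133.4, 2710.4, 82.3, 53.2),
    "NDUFS3": (316.6, 881.8, 96.8, 128.0),
    "CRP": (0.5, 0.7, 1.5, 2.2),
    "FGF21": (325.3, 392.0, 265.5, 151.8),
    "IL9": (115.0, 27.1, 101.8, 3.6),
    "MIP-1b": (158.6, 97.5, 184.6, 23.5),
    "TNFa": (31.2, 27.4, 42.2, 10.2),
}

# Null analytes share an arbitrary location/scale in both arms; autoscaling
# downstream makes the actual numbers immaterial.
_NULL_MEDIAN = 100.0
_NULL_IQR = 50.0

_UNITS = {
    "CRP": "mg/L", "MPO": "ng/mL", "FGF21": "pg/mL", "BDNF": "ng/mL",
    **{a: "a.u." for a in _EV_BLOT},
    **{a: "pg/mL" for a in _MULTIPLEX},
}


@dataclass(frozen=True)
class AnalyteSpec:
    """Per-analyte, per-arm distribution parameters.

    Medians must be strictly positive and IQRs nonnegative; together they
    pin down one log-normal per arm via :func:`fit_lognormal`.
    """

    name: str
    block: str
    units: str
    case_median: float
    case_iqr: float
    control_median: float
    control_iqr: float
    discriminant: bool = False

    def __post_init__(self) -> None:
        if self.block not in BLOCK_NAMES:
            raise ValueError(f"unknown block {self.block!r} for analyte {self.name!r}")
        if self.case_median <= 0 or self.control_median <= 0:
            raise ValueError(f"analyte {self.name!r}: medians must be strictly positive")
        if self.case_iqr < 0 or self.control_iqr < 0:
            raise ValueError(f"analyte {self.name!r}: IQRs must be nonnegative")


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of one synthetic cohort draw."""

    n_case: int = 16
    n_control: int = 12
    seed: int = 0
    panel: Sequence[AnalyteSpec] = field(default_factory=lambda: build_default_panel())
    #: optional analyte -> (case_median, case_iqr) replacement, for
    #: effect-recovery experiments.
    effect_overrides: Mapping[str, tuple[float, float]] | None = None
    #: optional analyte-by-analyte Gaussian-copula correlation matrix
    #: (panel order).  Default None = independent analytes.
    correlation: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_case < 1 or self.n_control < 1:
            raise ValueError("both arms must contain at least one sample")
        if self.n_case + self.n_control < 4:
            raise ValueError("cohort must contain at least 4 samples")
        if not self.panel:
            raise ValueError("panel is empty")
        names = [a.name for a in self.panel]
        if len(set(names)) != len(names):
            raise ValueError("duplicate analyte names in panel")
        if self.correlation is not None:
            R = np.asarray(self.correlation, dtype=float)
            p = len(self.panel)
            if R.shape != (p, p):
                raise ValueError(f"correlation matrix must be {p}x{p}")
            if not np.allclose(R, R.T):
                raise ValueError("correlation matrix must be symmetric")

    def resolved_panel(self) -> list[AnalyteSpec]:
        """Panel with effect overrides applied to the case arm."""
        if not self.effect_overrides:
            return list(self.panel)
        known = {a.name for a in self.panel}
        unknown = set(self.effect_overrides) - known
        if unknown:
            raise ValueError(f"effect_overrides name unknown analytes: {sorted(unknown)}")
        out = []
        for spec in self.panel:
            if spec.name in self.effect_overrides:
                m, i = self.effect_overrides[spec.name]
                spec = replace(spec, case_median=float(m), case_iqr=float(i))
            out.append(spec)
        return out


@dataclass
class MultiBlockDataset:
    """Samples x analytes split into named platform blocks, plus labels.

    ``labels`` is 1 for cases and 0 for controls.  All blocks share the
    same sample order; analyte names are unique across blocks.
    """

    sample_ids: list[str]
    labels: np.ndarray
    blocks: dict[str, pd.DataFrame]
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        n = len(self.sample_ids)
        if self.labels.shape != (n,):
            raise ValueError("labels length must match sample_ids")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be binary 0/1")
        seen: set[str] = set()
        for name, tbl in self.blocks.items():
            if len(tbl) != n:
                raise ValueError(f"block {name!r} has {len(tbl)} rows, expected {n}")
            dup = seen & set(tbl.columns)
            if dup:
                raise ValueError(f"analytes appear in multiple blocks: {sorted(dup)}")
            seen |= set(tbl.columns)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def analytes(self) -> list[str]:
        return [c for tbl in self.blocks.values() for c in tbl.columns]

    def to_matrix(self) -> tuple[np.ndarray, list[str], dict[str, slice]]:
        """Concatenated values plus column names and per-block column slices."""
        mats, cols, slices = [], [], {}
        start = 0
        for name, tbl in self.blocks.items():
            mats.append(tbl.to_numpy(dtype=float))
            cols.extend(tbl.columns)
            slices[name] = slice(start, start + tbl.shape[1])
            start += tbl.shape[1]
        return np.hstack(mats), cols, slices

    def to_frame(self) -> pd.DataFrame:
        """Single samples x analytes table (block column order)."""
        X, cols, _ = self.to_matrix()
        return pd.DataFrame(X, index=self.sample_ids, columns=cols)

    def subset(self, rows: np.ndarray) -> "MultiBlockDataset":
        """Row subset (boolean mask or integer indices), same block layout."""
        idx = np.asarray(rows)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return MultiBlockDataset(
            sample_ids=[self.sample_ids[i] for i in idx],
            labels=self.labels[idx],
            blocks={k: v.iloc[idx] for k, v in self.blocks.items()},
            units=dict(self.units),
        )

    def write(self, data_path: str | Path, sidecar_path: str | Path | None = None) -> None:
        """Write the dataset as a CSV plus a JSON sidecar of block/unit metadata."""
        data_path = Path(data_path)
        if sidecar_path is None:
            sidecar_path = data_path.with_suffix(".schema.json")
        df = self.to_frame()
        out = pd.concat(
            [pd.Series(self.labels, index=df.index, name="label"), df], axis=1
        )
        out.to_csv(data_path, index_label="sample_id")
        schema = {
            col: {"block": blk, "units": self.units.get(col, "")}
            for blk, tbl in self.blocks.items()
            for col in tbl.columns
        }
        Path(sidecar_path).write_text(json.dumps(schema, indent=1))

    @classmethod
    def read(cls, data_path: str | Path, sidecar_path: str | Path | None = None) -> "MultiBlockDataset":
        data_path = Path(data_path)
        if sidecar_path is None:
            sidecar_path = data_path.with_suffix(".schema.json")
        schema = json.loads(Path(sidecar_path).read_text())
        df = pd.read_csv(data_path, index_col="sample_id")
        labels = df.pop("label").to_numpy(dtype=int)
        blocks: dict[str, pd.DataFrame] = {}
        order = [c for c in df.columns]
        block_names = list(dict.fromkeys(schema[c]["block"] for c in order))
        for blk in block_names:
            cols = [c for c in order if schema[c]["block"] == blk]
            blocks[blk] = df[cols]
        return cls(
            sample_ids=[str(s) for s in df.index],
            labels=labels,
            blocks=blocks,
            units={c: schema[c]["units"] for c in order},
        )


def build_default_panel() -> list[AnalyteSpec]:
    """The default 37-analyte, 3-block panel.

    Seven analytes (CD9, NDUFS3, CRP, FGF21, IL9, MIP-1b, TNFa) carry the
    published arm-specific median/IQR and are flagged ``discriminant``; the
    other 30 are null analytes with identical parameters in both arms.
    """
    panel = []
    for block, names in zip(BLOCK_NAMES, (_MULTIPLEX, _IMMUNOASSAY, _EV_BLOT)):
        for name in names:
            if name in _DISCRIMINANT_PARAMS:
                cm, ci, pm, pi = _DISCRIMINANT_PARAMS[name]
                panel.append(AnalyteSpec(name, block, _UNITS[name], pm, pi, cm, ci, True))
            else:
                panel.append(
                    AnalyteSpec(
                        name, block, _UNITS[name],
                        _NULL_MEDIAN, _NULL_IQR, _NULL_MEDIAN, _NULL_IQR, False,
                    )
                )
    return panel


def fit_lognormal(median: float, iqr: float) -> tuple[float, float]:
    """Parameters (mu, sigma) of the log-normal with the given median and IQR.

    For ``X = exp(mu + sigma Z)`` the median is ``exp(mu)`` and the IQR is
    ``2 median sinh(z_0.75 sigma)``, so the match is closed-form::

        mu    = ln(median)
        sigma = asinh(iqr / (2 median)) / z_0.75

    ``iqr = 0`` yields ``sigma = 0``, a point mass at the median.
    """
    if median <= 0:
        raise ValueError(f"median must be strictly positive, got {median}")
    if iqr < 0:
        raise ValueError(f"iqr must be nonnegative, got {iqr}")
    mu = float(np.log(median))
    sigma = float(np.arcsinh(iqr / (2.0 * median)) / _Z75)
    return mu, sigma


def generate_cohort(config: CohortConfig) -> MultiBlockDataset:
    """Draw one seeded cohort.

    Cases are drawn first (labels 1), then controls (labels 0).  Within an
    arm, a standard-normal matrix of shape (n_arm, n_analytes) is drawn in
    one call and mapped column-wise through ``exp(mu + sigma z)``; with a
    Gaussian-copula correlation matrix configured, the normal matrix is
    premultiplied by its Cholesky factor first.  Output is byte-identical
    for identical configs and seeds.
    """
    panel = config.resolved_panel()
    rng = np.random.default_rng(config.seed)
    p = len(panel)
    chol = None
    if config.correlation is not None:
        chol = np.linalg.cholesky(np.asarray(config.correlation, dtype=float))

    def draw(n: int, arm: str) -> np.ndarray:
        Z = rng.standard_normal((n, p))
        if chol is not None:
            Z = Z @ chol.T
        X = np.empty_like(Z)
        for j, spec in enumerate(panel):
            if arm == "case":
                mu, sigma = fit_lognormal(spec.case_median, spec.case_iqr)
            else:
                mu, sigma = fit_lognormal(spec.control_median, spec.control_iqr)
            X[:, j] = np.exp(mu + sigma * Z[:, j])
        return X

    X = np.vstack([draw(config.n_case, "case"), draw(config.n_control, "control")])
    labels = np.concatenate(
        [np.ones(config.n_case, dtype=int), np.zeros(config.n_control, dtype=int)]
    )
    sample_ids = [f"case_{i + 1:03d}" for i in range(config.n_case)] + [
        f"control_{i + 1:03d}" for i in range(config.n_control)
    ]
    blocks: dict[str, pd.DataFrame] = {}
    for blk in BLOCK_NAMES:
        cols = [j for j, a in enumerate(panel) if a.block == blk]
        if cols:
            blocks[blk] = pd.DataFrame(
                X[:, cols], index=sample_ids, columns=[panel[j].name for j in cols]
            )
    return MultiBlockDataset(
        sample_ids=sample_ids,
        labels=labels,
        blocks=blocks,
        units={a.name: a.units for a in panel},
    )
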