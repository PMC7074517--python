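"""End-to-end orchestration: simulate/load -> rDCV -> permutation -> ranking -> SIMCA.

One :class:`RunConfig` (a plain mapping, loadable from YAML/JSON) drives
the whole analysis; a single master seed fans out into the stage
substreams, so one number reproduces the entire run.  The result is a
:class:`RunReport` — a JSON-serializable record of the classification
summary, merit values with permutation p-values, the ranked analyte
table, and the SIMCA assessment — plus CSV side tables when an output
directory is given.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .cohort import CohortConfig, MultiBlockDataset, generate_cohort
from .ranking import fit_reference_model, rank_product, select_candidates, vip
from .simca import assess, efficiency_curve, fit_simca, simca_statistics
from .validation import (
    RDCVConfig,
    classification_summary,
    permutation_test,
    run_rdcv,
)

__all__ = ["RunConfig", "RunReport", "run_all"]

log = logging.getLogger("fusionda")


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration of one end-to-end run."""

    seed: int = 0
    #: path to a dataset CSV (with its ``.schema.json`` sidecar) — if None,
    #: a cohort is simulated from ``cohort``.
    data_path: str | None = None
    n_case: int = 16
    n_control: int = 12
    repetitions: int = 30
    outer_folds: int = 7
    inner_folds: int = 5
    a_max: int = 10
    n_perm: int = 1000
    perm_repetitions: int = 1
    rank_k: int = 7
    simca_block: str | None = None   # None = all analytes; else a block name
    simca_threshold: float = 2.0
    simca_folds: int = 7
    simca_a_max: int = 5
    output_dir: str | None = None

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class RunReport:
    config: dict[str, Any]
    config_digest: str
    version: str
    classification: dict[str, dict[str, float]]
    merits: dict[str, float]
    pvalues: dict[str, float] | None
    ranking: list[dict[str, Any]]
    selected: list[str]
    simca: dict[str, Any]

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


def _load_or_simulate(config: RunConfig) -> MultiBlockDataset:
    if config.data_path is not None:
        return MultiBlockDataset.read(config.data_path)
    cohort = CohortConfig(
        n_case=config.n_case, n_control=config.n_control, seed=config.seed
    )
    return generate_cohort(cohort)


def run_all(config: RunConfig) -> RunReport:
    """Execute every stage and return (and optionally write) the report."""
    t0 = time.perf_counter()
    data = _load_or_simulate(config)
    n = data.n_samples
    p = len(data.analytes)
    log.info("dataset: %d samples, %d analytes, seed=%d", n, p, config.seed)

    rdcv_cfg = RDCVConfig(
        repetitions=config.repetitions,
        outer_folds=config.outer_folds,
        inner_folds=config.inner_folds,
        a_max=config.a_max,
        seed=config.seed,
    )
    if config.n_perm > 0:
        perm = permutation_test(
            data, rdcv_cfg, n_perm=config.n_perm,
            perm_repetitions=config.perm_repetitions,
        )
        result = perm.observed_result
        merits, pvalues = perm.observed, perm.pvalues
    else:
        perm = None
        result = run_rdcv(data, rdcv_cfg)
        merits = {
            "nmc": float(np.mean([m.nmc for m in result.merits])),
            "auroc": float(np.mean([m.auroc for m in result.merits])),
            "dq2": float(np.mean([m.dq2 for m in result.merits])),
        }
        pvalues = None
    summary = classification_summary(result)
    log.info(
        "rDCV: overall %.1f%% +/- %.1f%% (%d repetitions)",
        summary.loc["overall", "mean"], summary.loc["overall", "sd"],
        config.repetitions,
    )

    model = fit_reference_model(data, result)
    vip_res = vip(model, data.analytes)
    rp_res = rank_product(result)
    selected = select_candidates(vip_res, rp_res, k=config.rank_k)
    ranking = vip_res.to_frame().join(rp_res.to_frame())
    ranking["block"] = [
        blk for blk, tbl in data.blocks.items() for _ in tbl.columns
    ]
    ranking["selected"] = [a in selected for a in ranking.index]
    ranking = ranking.sort_values("rp")
    log.info("ranking: %d candidates selected (k=%d)", len(selected), config.rank_k)

    if config.simca_block is not None:
        simca_table = data.blocks[config.simca_block]
    else:
        simca_table = data.to_frame()
    in_class = simca_table.loc[data.labels == 1]
    out_class = simca_table.loc[data.labels == 0]
    curve = efficiency_curve(
        in_class, out_class, cv_folds=config.simca_folds, a_max=config.simca_a_max
    )
    best_row = curve.loc[curve["efficiency"].idxmax()]
    a_pc = int(best_row["n_components"])
    simca_model = fit_simca(in_class, a_pc, threshold=config.simca_threshold)
    cal = assess(simca_model, in_class, out_class, mode="calibration")
    stats_in = simca_statistics(simca_model, in_class)
    stats_out = simca_statistics(simca_model, out_class)
    simca_report = {
        "n_components": a_pc,
        "calibration": {
            "sensitivity": cal.sensitivity,
            "specificity": cal.specificity,
            "efficiency": cal.efficiency,
        },
        "cross_validation": {
            "sensitivity": float(best_row["sensitivity"]),
            "specificity": float(best_row["specificity"]),
            "efficiency": float(best_row["efficiency"]),
        },
    }
    log.info(
        "SIMCA: %d PCs, calibration sens/spec %.1f/%.1f, CV %.1f/%.1f",
        a_pc, cal.sensitivity, cal.specificity,
        best_row["sensitivity"], best_row["specificity"],
    )

    report = RunReport(
        config=asdict(config),
        config_digest=config.digest(),
        version=__version__,
        classification={
            row: {"mean": float(summary.loc[row, "mean"]), "sd": float(summary.loc[row, "sd"])}
            for row in summary.index
        },
        merits=merits,
        pvalues=pvalues,
        ranking=[
            {"analyte": a, **{k: (v.item() if hasattr(v, "item") else v) for k, v in row.items()}}
            for a, row in ranking.iterrows()
        ],
        selected=selected,
        simca=simca_report,
    )

    if config.output_dir is not None:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        report.to_json(outdir / "report.json")
        if config.data_path is None:
            data.write(outdir / "dataset.csv")
        pd.DataFrame(
            [{"nmc": m.nmc, "auroc": m.auroc, "dq2": m.dq2} for m in result.merits]
        ).to_csv(outdir / "merits.csv", index_label="repetition")
        pd.DataFrame(
            result.predictions.T,
            index=data.sample_ids,
            columns=[f"rep_{r}" for r in range(result.predictions.shape[0])],
        ).to_csv(outdir / "predictions.csv", index_label="sample_id")
        ranking.to_csv(outdir / "ranking.csv", index_label="analyte")
        simca_samples = pd.concat([stats_in, stats_out], ignore_index=True)
        simca_samples.insert(0, "sample_id", list(in_class.index) + list(out_class.index))
        simca_samples["accepted"] = simca_samples["d"] < config.simca_threshold
        simca_samples.to_csv(outdir / "simca_samples.csv", index=False)
        if perm is not None:
            perm.null.to_csv(outdir / "permutation_null.csv", index_label="randomization")
    log.info("run complete in %.1f s", time.perf_counter() - t0)
    return report
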