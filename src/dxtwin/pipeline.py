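"""Run configuration and orchestration of the full analysis pipeline.

A run is described by a small YAML/JSON config (cohort context, sample
size, seed, thresholds, reporting mode, stage toggles).  ``run_pipeline``
executes calibrate -> generate -> evaluate -> reports, writing CSV tables
plus a JSON manifest (config hash, seed, package version) so any output
can be regenerated bit-identically in expected mode and seed-identically
in realized mode.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .benefit import BenefitModel, GENOMIC_SETS, testing_window
from .calibration import (
    builtin_targets,
    calibrate_mindact,
    calibrate_tailorx,
    default_params,
)
from .cohorts import CohortConfig, generate_cohort, write_cohort
from .params import DGPParams
from .sensitivity import sensitivity_grid, subsample_ci
from .strategies import (
    Strategy,
    decision_curve,
    outcome_table,
    format_outcome_table,
    reclassification_summary,
    reclassification_table,
    standard_strategies,
)

log = logging.getLogger("dxtwin")

STAGES = ("table1", "windows", "reclassification", "curve", "ci", "sensitivity")

#: Trial sample sizes used for the subsampling uncertainty stage.
TRIAL_SIZES = {"mindact": 6693, "tailorx": 10253}


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    cohort: str = "mindact"
    n_patients: int = 100_000
    seed: int = 0
    thresholds: tuple = (0.05,)
    mode: str = "expected"            # expected | realized
    out_dir: str = "results"
    stages: tuple = STAGES
    params_file: str | None = None    # None -> shipped calibrated parameters
    recalibrate: bool = False
    curve_grid: tuple = (0.005, 0.20, 0.005)   # start, stop, step
    n_subsample: int | None = None    # None -> trial size for the cohort
    n_replicates: int = 1000

    def __post_init__(self):
        if self.cohort not in ("mindact", "tailorx"):
            raise ValueError(f"unknown cohort {self.cohort!r}")
        if self.mode not in ("expected", "realized"):
            raise ValueError(f"unknown mode {self.mode!r}")
        for t in self.thresholds:
            if not (0.0 < t <= 0.20):
                raise ValueError(f"threshold {t} outside (0, 0.20]")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("thresholds", "stages", "curve_grid"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def resolve_params(config: RunConfig) -> DGPParams:
    """Parameter set for a run: file override, recalibration, or shipped."""
    if config.params_file:
        return DGPParams.from_json(config.params_file)
    if config.recalibrate:
        res = calibrate_mindact()
        if config.cohort == "tailorx":
            res = calibrate_tailorx(res.params)
        return res.params
    return default_params(config.cohort)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns {stage: output path}."""
    t_start = time.time()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    params = resolve_params(config)
    model = BenefitModel(params)
    needs_cohort = config.mode == "realized" or not set(config.stages).isdisjoint(
        {"reclassification", "ci"})
    cohort = None
    if needs_cohort:
        cohort = generate_cohort(
            CohortConfig(config.cohort, config.n_patients, config.seed, params),
            model=model)
        log.info("generated cohort n=%d in %.1fs", len(cohort),
                 time.time() - t_start)

    outputs: dict = {}

    def _write(name: str, df: pd.DataFrame) -> None:
        path = out_dir / name
        df.to_csv(path, index=False)
        outputs[name] = str(path)
        log.info("wrote %s (%d rows)", path, len(df))

    for t in config.thresholds:
        tag = f"{int(round(1000 * t))}"
        if "table1" in config.stages:
            tab = outcome_table(model, threshold=t,
                                cohort=cohort if config.mode == "realized" else None,
                                mode=config.mode)
            _write(f"table1_t{tag}_{config.cohort}.csv", tab)
            _write(f"table1_t{tag}_{config.cohort}_rounded.csv",
                   format_outcome_table(tab))
        if "windows" in config.stages:
            rows = []
            for info in GENOMIC_SETS:
                w = testing_window(model, info, t)
                rows.append({"info": info.value, "threshold": t,
                             "lower": w.lower, "upper": w.upper,
                             "fraction_tested": w.fraction_tested})
            _write(f"windows_t{tag}_{config.cohort}.csv", pd.DataFrame(rows))
        if "reclassification" in config.stages:
            rows = []
            strats = standard_strategies(t)
            for key in ("mp", "otbin", "otcont"):
                summ = reclassification_summary(model, strats[key].info, t)
                rec = reclassification_table(model, cohort, strats["clinical"],
                                             strats[key])
                rows.append({"info": strats[key].info.value, "threshold": t,
                             **{f"expected_{k}": v for k, v in summ.items()},
                             "realized_total": rec.total_reclassified,
                             "realized_to_treat": rec.to_treat,
                             "realized_to_no_treat": rec.to_no_treat,
                             "realized_correct": rec.correct,
                             "realized_incorrect": rec.incorrect})
            _write(f"reclassification_t{tag}_{config.cohort}.csv",
                   pd.DataFrame(rows))

    if "curve" in config.stages:
        start, stop, step = config.curve_grid
        grid = np.round(np.arange(start, stop + step / 2, step), 10)
        curve = decision_curve(model, grid,
                               cohort=cohort if config.mode == "realized" else None,
                               mode=config.mode)
        _write(f"decision_curve_{config.cohort}.csv", curve)

    if "ci" in config.stages:
        n_sub = config.n_subsample or TRIAL_SIZES[config.cohort]
        ci = subsample_ci(model, cohort, strategy_pair=("otcont", "mp"),
                          n_sub=n_sub, n_rep=config.n_replicates,
                          seed=config.seed + 2)
        _write(f"subsample_ci_{config.cohort}.csv", ci.to_frame())

    if "sensitivity" in config.stages:
        grid = sensitivity_grid(params, threshold=config.thresholds[0])
        _write(f"sensitivity_{config.cohort}.csv", grid)

    if cohort is not None and config.mode == "realized":
        write_cohort(cohort, out_dir / f"cohort_{config.cohort}.csv")
        outputs["cohort"] = str(out_dir / f"cohort_{config.cohort}.csv")

    manifest = {
        "package": "dxtwin", "version": __version__,
        "config": config.to_dict(), "config_hash": config.hash(),
        "params": params.to_dict(),
        "outputs": sorted(outputs), "runtime_s": round(time.time() - t_start, 2),
    }
    (out_dir / f"manifest_{config.cohort}.json").write_text(
        json.dumps(manifest, indent=2) + "\n")
    outputs["manifest"] = str(out_dir / f"manifest_{config.cohort}.json")
    return outputs


def calibration_report(cohort: str = "mindact") -> pd.DataFrame:
    """Residual table of the shipped parameters against the registry."""
    from .calibration import moment_table

    params = default_params(cohort)
    moments = moment_table(params)
    rows = []
    for t in builtin_targets(cohort).targets:
        fitted = moments[t.name]
        rows.append({"target": t.name, "printed": t.value, "fitted": fitted,
                     "residual": fitted - t.value, "tolerance": t.tol,
                     "within_tol": abs(fitted - t.value) <= t.tol})
    return pd.DataFrame(rows)
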