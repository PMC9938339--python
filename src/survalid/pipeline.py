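"""End-to-end validation runs and Table-1-shaped reports.

`ExternalValidator` executes the full procedure on a cohort: eligibility
filter, complete-case filter, horizon capping, minimum-event check, risk
scoring, discrimination, calibration and censoring-adjusted classification
— with a competing-risks sensitivity variant appended whenever competing
deaths are present (never replacing the main analysis). Every number in the
report is recomputable by calling the module-level operations directly on
the filtered cohort.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict
from sklearn.base import BaseEstimator

from . import __version__
from .calibration import (age_group_calibration, calibration_slope,
                          decile_calibration, mean_calibration)
from .classification import (censoring_adjusted_sn_sp,
                             clinical_threshold_classification,
                             threshold_at_observed_risk, threshold_sweep)
from .cohort import Cohort
from .discrimination import (GROUP_LABELS, harrells_c, harrells_c_competing,
                             km_by_group, risk_groups_by_pi)
from .model import (ModelDefinition, RiskScorer, apply_eligibility,
                    complete_case_filter, load_model_definition)

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "PipelineError",
    "ExternalValidator",
    "check_min_events",
    "run_validation",
    "run_head_to_head",
    "write_report",
]


class PipelineError(RuntimeError):
    """A validation stage failed; the message names the stage."""


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    horizon: float = 10.0
    deciles: int = 10
    age_bands: Optional[tuple[float, ...]] = None  # e.g. (65, 70, 75)
    min_events: int = 100
    allow_few_events: bool = False
    clinical_threshold: bool = False  # classify at the model's clinical threshold too
    sweep_thresholds: Optional[tuple[float, ...]] = None
    seed: int = 0


def check_min_events(cohort: Cohort, minimum: int = 100) -> tuple[bool, int]:
    """Sample-size rule: the validation needs at least ``minimum`` outcome events."""
    n = cohort.n_events(1)
    return n >= minimum, n


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"[{name}] {exc}") from exc
        return wrapper
    return deco


def _round(x: float, nd: int = 6) -> float:
    return float(round(float(x), nd))


class ExternalValidator(BaseEstimator):
    """Fit-shaped runner of a full external validation.

    Parameters
    ----------
    model : ModelDefinition or path to its JSON file.
    config : RunConfig, optional.

    Fitted attributes
    -----------------
    cohort_ : Cohort
        The analysis cohort after eligibility, complete-case filtering and
        horizon capping.
    predictions_ : pandas.DataFrame
        Per-subject PI, CPI, probability and scaled probability.
    report_ : dict
        JSON-serializable Table-1-shaped report.
    """

    def __init__(self, model: Union[ModelDefinition, str, Path], config: Optional[RunConfig] = None):
        self.model = model
        self.config = config

    # -- stages ------------------------------------------------------------
    @_stage("load")
    def _load(self):
        model = self.model if isinstance(self.model, ModelDefinition) else load_model_definition(self.model)
        cfg = self.config or RunConfig()
        return model, cfg

    @_stage("sample-restriction")
    def _restrict(self, cohort: Cohort, model: ModelDefinition, cfg: RunConfig):
        n0 = len(cohort)
        eligible = apply_eligibility(cohort, model)
        complete = complete_case_filter(eligible, model)
        capped = complete.cap_horizon(cfg.horizon)
        return capped, {"n_initial": n0, "n_eligible": len(eligible), "n_complete": len(complete)}

    @_stage("min-events")
    def _min_events(self, cohort: Cohort, cfg: RunConfig):
        ok, n = check_min_events(cohort, cfg.min_events)
        if not ok and not cfg.allow_few_events:
            raise ValueError(
                f"only {n} outcome events; the sample-size rule requires {cfg.min_events} "
                "(set allow_few_events to override)"
            )
        return n

    @_stage("scoring")
    def _score(self, cohort: Cohort, model: ModelDefinition) -> pd.DataFrame:
        return RiskScorer(model).predict_set(cohort.covariates())

    @_stage("discrimination")
    def _discrimination(self, cohort: Cohort, preds: pd.DataFrame, variant: str):
        p = preds["scaled_probability"].to_numpy()
        if variant == "main":
            ev = (cohort.events == 1).astype(int)
            return harrells_c(cohort.times, ev, p)
        return harrells_c_competing(cohort.times, cohort.events, p)

    @_stage("calibration")
    def _calibration(self, cohort: Cohort, preds: pd.DataFrame, cfg: RunConfig, variant: str):
        reference = "cif" if variant == "competing_risk" else "km"
        slope = calibration_slope(cohort.times, cohort.events, preds["cpi"].to_numpy(), variant=variant)
        ratio = mean_calibration(preds["scaled_probability"].to_numpy(), cohort.times,
                                 cohort.events, cfg.horizon, reference)
        deciles = decile_calibration(preds["scaled_probability"].to_numpy(), cohort.times,
                                     cohort.events, cfg.deciles, cfg.horizon, reference)
        return slope, ratio, deciles

    @_stage("classification")
    def _classification(self, cohort: Cohort, preds: pd.DataFrame, cfg: RunConfig, variant: str):
        cutoff = threshold_at_observed_risk(cohort.times, cohort.events, cfg.horizon, variant)
        result = censoring_adjusted_sn_sp(cohort.times, cohort.events,
                                          preds["scaled_probability"].to_numpy(), cutoff,
                                          cfg.horizon, variant, threshold_source="observed_risk")
        return cutoff, result

    # -- public API --------------------------------------------------------
    def fit(self, cohort: Cohort):
        model, cfg = self._load()
        cohort, counts = self._restrict(cohort, model, cfg)
        n_events = self._min_events(cohort, cfg)
        preds = self._score(cohort, model)

        counts.update(
            n_analysis=len(cohort),
            events=n_events,
            competing_events=cohort.n_events(2),
        )
        has_competing = counts["competing_events"] > 0
        variants = ("main", "competing_risk") if has_competing else ("main",)

        variant_blocks = {}
        for variant in variants:
            disc = self._discrimination(cohort, preds, variant)
            slope, ratio, deciles = self._calibration(cohort, preds, cfg, variant)
            cutoff, cls = self._classification(cohort, preds, cfg, variant)
            variant_blocks[variant] = {
                "harrells_c": {
                    "estimate": _round(disc.c_index),
                    "se": _round(disc.se),
                    "ci95": [_round(disc.ci95[0]), _round(disc.ci95[1])],
                    "n_pairs": disc.n_pairs,
                },
                "calibration_slope": {
                    "estimate": _round(slope.slope),
                    "se": _round(slope.se),
                    "ci95": [_round(slope.ci95[0]), _round(slope.ci95[1])],
                    "p_vs_1": _round(slope.p_vs_1, 8),
                },
                "mean_calibration": _round(ratio),
                "cutoff_high_risk_pct": _round(100 * cutoff, 4),
                "observed_risk_pct": _round(100 * cutoff, 4),
                "sensitivity_pct": _round(100 * cls.sensitivity, 4),
                "specificity_pct": _round(100 * cls.specificity, 4),
                "ppv_pct": _round(100 * cls.ppv, 4),
                "npv_pct": _round(100 * cls.npv, 4),
                "decile_table": _table_records(deciles),
            }

        groups = risk_groups_by_pi(preds["pi"].to_numpy())
        curves = km_by_group(cohort.times, cohort.events, groups)
        group_block = {
            "cut_points": [_round(c) for c in groups.cut_points],
            "sizes": {g: int((groups.labels == g).sum()) for g in GROUP_LABELS},
            "ten_year_risk": {g: _round(c.risk_at(cfg.horizon)) for g, c in curves.items()},
        }

        report = {
            "model": model.name,
            "outcome": model.outcome_label,
            "horizon": cfg.horizon,
            "outcome_fraction": model.outcome_fraction,
            "sample": counts,
            "variants": variant_blocks,
            "risk_groups": group_block,
        }

        if cfg.clinical_threshold and model.clinical_threshold is not None:
            cls = censoring_adjusted_sn_sp(cohort.times, cohort.events,
                                           preds["probability"].to_numpy(),
                                           model.clinical_threshold, cfg.horizon,
                                           "main", threshold_source="clinical")
            report["clinical_threshold"] = {
                "threshold_pct": _round(100 * model.clinical_threshold, 4),
                "applies_to": "unscaled_composite_probability",
                "sensitivity_pct": _round(100 * cls.sensitivity, 4),
                "specificity_pct": _round(100 * cls.specificity, 4),
                "ppv_pct": _round(100 * cls.ppv, 4),
                "npv_pct": _round(100 * cls.npv, 4),
            }

        if cfg.age_bands:
            table = age_group_calibration(cohort.ages, preds["scaled_probability"].to_numpy(),
                                          cohort.times, cohort.events, cfg.age_bands, cfg.horizon)
            report["age_groups"] = _table_records(table)

        if cfg.sweep_thresholds:
            sweep = threshold_sweep(preds["scaled_probability"].to_numpy(), cohort.times,
                                    cohort.events, sorted(cfg.sweep_thresholds), cfg.horizon)
            report["threshold_sweep"] = _table_records(sweep)

        self.model_definition_ = model
        self.run_config_ = cfg
        self.cohort_ = cohort
        self.predictions_ = preds
        self.risk_groups_ = groups
        self.group_curves_ = curves
        self.report_ = report
        return self


def _table_records(df: pd.DataFrame) -> list[dict]:
    records = []
    for rec in df.to_dict(orient="records"):
        records.append({k: (_round(v) if isinstance(v, float) else v) for k, v in rec.items()})
    return records


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(65536), b""):
            h.update(block)
    return h.hexdigest()


def _provenance(inputs: dict[str, str], cfg: RunConfig) -> dict:
    return {
        "software": f"survalid {__version__}",
        "input_sha256": {k: _sha256(v) for k, v in inputs.items()},
        "config": json.loads(cfg.model_dump_json()),
    }


def write_report(report: dict, path) -> None:
    """Deterministic JSON serialization (sorted keys, fixed indentation)."""
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_validation(cohort_path, model_path, config: Optional[RunConfig] = None,
                   out_dir=None) -> dict:
    """Validate one model against one cohort file; optionally write outputs.

    Outputs (when ``out_dir`` is given): ``report.json`` plus tidy CSV
    sub-tables for deciles and per-risk-group survival curves. All outputs
    are byte-identical across re-runs with identical inputs.
    """
    cfg = config or RunConfig()
    cohort = Cohort.from_csv(cohort_path).cap_horizon(cfg.horizon)
    validator = ExternalValidator(model=str(model_path), config=cfg).fit(cohort)
    report = validator.report_
    report["provenance"] = _provenance({"cohort": str(cohort_path), "model": str(model_path)}, cfg)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_report(report, out / "report.json")
        for variant, block in report["variants"].items():
            pd.DataFrame(block["decile_table"]).to_csv(out / f"deciles_{variant}.csv", index=False)
        frames = []
        for g, curve in validator.group_curves_.items():
            f = curve.to_frame()
            f.insert(0, "group", g)
            frames.append(f)
        pd.concat(frames).to_csv(out / "risk_group_curves.csv", index=False)
        if "age_groups" in report:
            pd.DataFrame(report["age_groups"]).to_csv(out / "age_groups.csv", index=False)
        logger.info("report written to %s", out / "report.json")
    return report


def run_head_to_head(cohort_path, model_paths: Sequence, config: Optional[RunConfig] = None,
                     out_dir=None, n_agreement_bins: int = 10) -> dict:
    """Compare >= 2 models head-to-head on a single common sub-sample.

    Eligibility is the union of all models' exclusion predicates and the
    complete-case rule covers every model's predictors, so each model is
    scored on exactly the same subjects. The agreement table bins subjects
    by deciles of the across-model mean scaled prediction and reports each
    model's mean prediction per bin.
    """
    if len(model_paths) < 2:
        raise PipelineError("[head-to-head] need at least 2 models")
    cfg = config or RunConfig()
    models = [load_model_definition(p) for p in model_paths]
    names = [m.name for m in models]
    if len(set(names)) != len(names):
        names = [f"{m.name}#{i}" for i, m in enumerate(models)]

    cohort = Cohort.from_csv(cohort_path).cap_horizon(cfg.horizon)
    common = cohort
    for m in models:
        common = apply_eligibility(common, m)
        common = complete_case_filter(common, m)
    if len(common) == 0:
        raise PipelineError("[head-to-head] common sub-sample is empty")

    reports = {}
    pred_cols = {}
    for name, m in zip(names, models):
        v = ExternalValidator(model=m, config=cfg).fit(common)
        reports[name] = v.report_
        pred_cols[name] = v.predictions_["scaled_probability"].to_numpy()

    pred_df = pd.DataFrame(pred_cols)
    mean_pred = pred_df.mean(axis=1).to_numpy()
    order = np.argsort(mean_pred, kind="stable")
    agreement = []
    for b, idx in enumerate(np.array_split(order, n_agreement_bins), start=1):
        row = {"bin": b, "n": len(idx), "mean_of_means": _round(float(mean_pred[idx].mean()))}
        for name in names:
            row[name] = _round(float(pred_cols[name][idx].mean()))
        agreement.append(row)

    bundle = {
        "models": names,
        "common_sample_size": len(common),
        "events": common.n_events(1),
        "competing_events": common.n_events(2),
        "reports": reports,
        "agreement_table": agreement,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        bundle["provenance"] = _provenance(
            {"cohort": str(cohort_path), **{n: str(p) for n, p in zip(names, model_paths)}}, cfg
        )
        write_report(bundle, out / "head_to_head.json")
        pd.DataFrame(agreement).to_csv(out / "agreement_table.csv", index=False)
        scatter = pred_df.copy()
        scatter.insert(0, "id", common.ids)
        scatter.to_csv(out / "prediction_scatter.csv", index=False)
    return bundle
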