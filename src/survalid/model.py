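"""Declarative proportional-hazards risk-model engine.

A risk model is described entirely by data: an ordered list of predictors
(each a covariate, a transform and a coefficient), per-predictor centring
means on the transformed scale, a published baseline survivor function at
the prediction horizon, and an outcome fraction that rescales a composite
predicted probability to the outcome of interest. The engine turns such a
definition plus subject covariates into 10-year predicted probabilities:

    PI  = sum_j beta_j * t_j(x_j)          (prognostic index)
    CPI = PI - sum_j beta_j * m_j          (centred prognostic index)
    P   = 1 - S0(h)^exp(CPI)               (predicted probability at horizon h)
    P*  = P * outcome_fraction             (outcome-scale probability)

Eligibility predicates and the complete-case rule are part of the model
definition so a validation run reproduces the development paper's sample
restrictions.
"""

from __future__ import annotations

import json
import logging
import warnings
from typing import Any, Literal, Optional, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator, model_validator
from sklearn.base import BaseEstimator

from .cohort import Cohort

logger = logging.getLogger(__name__)

# exp(CPI) beyond this implies a scoring bug upstream; probability saturates
_EXP_OVERFLOW = 700.0


class TransformSpec(BaseModel):
    """How a raw covariate value maps onto the model's predictor scale.

    ``identity`` uses the raw value; ``log`` its natural logarithm;
    ``indicator`` is 1 when the value equals ``value`` (or is truthy when no
    value is given); ``one_hot`` is the indicator of a categorical level;
    ``product`` multiplies the transformed value with a second transformed
    covariate (interaction terms such as age x smoking).
    """

    model_config = ConfigDict(extra="forbid")

    type: Literal["identity", "log", "indicator", "one_hot", "product"] = "identity"
    value: Optional[Union[str, int, float, bool]] = None  # indicator / one_hot level
    with_covariate: Optional[str] = None  # product only
    with_transform: Optional["TransformSpec"] = None  # product only

    @model_validator(mode="after")
    def _check_product(self) -> "TransformSpec":
        if self.type == "product" and self.with_covariate is None:
            raise ValueError("product transform requires 'with_covariate'")
        return self


class Predictor(BaseModel):
    model_config = ConfigDict(extra="forbid")

    name: str
    covariate: str
    transform: TransformSpec = Field(default_factory=TransformSpec)
    coefficient: float

    def referenced_covariates(self) -> list[str]:
        refs = [self.covariate]
        if self.transform.type == "product":
            refs.append(self.transform.with_covariate)
        return refs


class EligibilityPredicate(BaseModel):
    """An exclusion rule: subjects for whom it evaluates true are dropped."""

    model_config = ConfigDict(extra="forbid")

    name: str
    covariate: str
    op: Literal["truthy", "eq", "ne", "gt", "ge", "lt", "le"] = "truthy"
    value: Optional[Union[str, int, float, bool]] = None


class ModelDefinition(BaseModel):
    model_config = ConfigDict(extra="forbid")

    name: str
    outcome_label: str
    horizon: float = 10.0
    predictors: list[Predictor]
    centring_means: dict[str, float]
    baseline_survival: float
    outcome_fraction: float = 1.0
    eligibility: list[EligibilityPredicate] = Field(default_factory=list)
    clinical_threshold: Optional[float] = None  # on the UNSCALED composite scale

    @field_validator("horizon")
    @classmethod
    def _horizon_positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("horizon must be > 0")
        return v

    @field_validator("baseline_survival")
    @classmethod
    def _s0_range(cls, v: float) -> float:
        if not (0 < v <= 1):
            raise ValueError(f"baseline_survival must lie in (0, 1]; got {v}")
        return v

    @field_validator("outcome_fraction")
    @classmethod
    def _fraction_range(cls, v: float) -> float:
        if not (0 < v <= 1):
            raise ValueError(f"outcome_fraction must lie in (0, 1]; got {v}")
        return v

    @model_validator(mode="after")
    def _aligned(self) -> "ModelDefinition":
        names = [p.name for p in self.predictors]
        if len(set(names)) != len(names):
            raise ValueError("duplicate predictor names")
        missing = [n for n in names if n not in self.centring_means]
        if missing:
            raise ValueError(f"centring_means missing entries for predictors: {missing}")
        return self

    def referenced_covariates(self) -> list[str]:
        seen: list[str] = []
        for p in self.predictors:
            for c in p.referenced_covariates():
                if c not in seen:
                    seen.append(c)
        return seen

    def centring_offset(self) -> float:
        """sum_j beta_j * m_j on the transformed scale."""
        return float(sum(p.coefficient * self.centring_means[p.name] for p in self.predictors))


class ModelLoadError(ValueError):
    """A model-definition file failed schema or range validation."""


class MissingPredictorError(KeyError):
    """A subject lacks a covariate required by the model (complete-case rule)."""


def load_model_definition(path) -> ModelDefinition:
    """Load and validate a JSON model definition."""
    with open(path) as fh:
        raw = json.load(fh)
    try:
        return ModelDefinition.model_validate(raw)
    except ValidationError as exc:
        first = exc.errors()[0]
        loc = ".".join(str(p) for p in first["loc"]) or "<root>"
        raise ModelLoadError(f"invalid model definition {path!s}: field '{loc}': {first['msg']}") from exc


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def _apply_transform(spec: TransformSpec, values: np.ndarray, covariate: str, row_values=None) -> np.ndarray:
    t = spec.type
    if t == "identity":
        return values.astype(float)
    if t == "log":
        with np.errstate(divide="raise", invalid="raise"):
            try:
                return np.log(values.astype(float))
            except FloatingPointError as exc:
                raise ValueError(f"log transform of non-positive value for covariate '{covariate}'") from exc
    if t in ("indicator", "one_hot"):
        if spec.value is None:
            return (values.astype(float) != 0).astype(float)
        return (values == spec.value).astype(float)
    raise AssertionError(f"unhandled transform {t}")  # pragma: no cover


def transformed_design(model: ModelDefinition, covariates: pd.DataFrame) -> pd.DataFrame:
    """Per-subject transformed predictor values t_j(x_j), one column per predictor.

    Raises
    ------
    MissingPredictorError
        If a referenced covariate column is absent. NaN values propagate and
        are handled by the complete-case filter, never imputed.
    """
    cols = {}
    for p in model.predictors:
        for c in p.referenced_covariates():
            if c not in covariates.columns:
                raise MissingPredictorError(
                    f"model '{model.name}' requires covariate '{c}' (predictor '{p.name}') "
                    "which is absent from the cohort"
                )
        base = _apply_transform(p.transform if p.transform.type != "product" else TransformSpec(),
                                covariates[p.covariate].to_numpy(), p.covariate)
        if p.transform.type == "product":
            inner = p.transform.with_transform or TransformSpec()
            other = _apply_transform(inner, covariates[p.transform.with_covariate].to_numpy(),
                                     p.transform.with_covariate)
            base = base * other
        cols[p.name] = base
    return pd.DataFrame(cols, index=covariates.index)


def compute_prognostic_index(model: ModelDefinition, covariates) -> np.ndarray:
    """Linear predictor PI = sum_j beta_j t_j(x_j) per subject.

    ``covariates`` may be a DataFrame or a single mapping for one subject.
    """
    single = isinstance(covariates, dict)
    if single:
        covariates = pd.DataFrame([covariates])
    design = transformed_design(model, covariates)
    beta = np.array([p.coefficient for p in model.predictors])
    pi = design.to_numpy(dtype=float) @ beta
    return float(pi[0]) if single else pi


def centre_prognostic_index(model: ModelDefinition, pi):
    """CPI = PI - sum_j beta_j m_j."""
    return pi - model.centring_offset()


def predict_event_probability(model: ModelDefinition, cpi):
    """P = 1 - S0(h)^exp(CPI), in [0, 1)."""
    cpi = np.asarray(cpi, dtype=float)
    if np.any(cpi > _EXP_OVERFLOW):
        warnings.warn(
            "extreme centred prognostic index (exp overflow); probability saturated toward 1 — "
            "check predictor scaling",
            RuntimeWarning,
        )
    s0 = model.baseline_survival
    with np.errstate(over="ignore", under="ignore"):
        p = 1.0 - np.power(s0, np.exp(np.clip(cpi, -_EXP_OVERFLOW, _EXP_OVERFLOW)))
    p = np.clip(p, 0.0, 1.0 if s0 == 0 else np.nextafter(1.0, 0.0))
    if s0 == 1.0:
        p = np.zeros_like(p)
    return float(p) if p.ndim == 0 else p


def scale_to_outcome(model: ModelDefinition, p):
    """Rescale a composite predicted probability to the outcome of interest."""
    return np.asarray(p, dtype=float) * model.outcome_fraction if np.ndim(p) else float(p) * model.outcome_fraction


class RiskScorer(BaseEstimator):
    """Predict-shaped wrapper turning covariates into horizon probabilities.

    Parameters
    ----------
    model : ModelDefinition or path
        Declarative model definition (or path to its JSON file).

    Notes
    -----
    ``predict`` returns the outcome-scale (scaled) probability; use
    ``predict_set`` for the full per-subject table (PI, CPI, unscaled and
    scaled probability).
    """

    def __init__(self, model: Union[ModelDefinition, str]):
        self.model = model

    @property
    def definition_(self) -> ModelDefinition:
        if isinstance(self.model, ModelDefinition):
            return self.model
        return load_model_definition(self.model)

    def predict_set(self, X: pd.DataFrame) -> pd.DataFrame:
        """Per-subject PI, CPI, probability and scaled probability."""
        model = self.definition_
        pi = compute_prognostic_index(model, X)
        cpi = centre_prognostic_index(model, pi)
        prob = predict_event_probability(model, cpi)
        return pd.DataFrame(
            {
                "pi": pi,
                "cpi": cpi,
                "probability": prob,
                "scaled_probability": prob * model.outcome_fraction,
            },
            index=X.index,
        )

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.predict_set(X)["scaled_probability"].to_numpy()


# ---------------------------------------------------------------------------
# sample restriction
# ---------------------------------------------------------------------------

_OPS = {
    "eq": lambda a, b: a == b,
    "ne": lambda a, b: a != b,
    "gt": lambda a, b: a > b,
    "ge": lambda a, b: a >= b,
    "lt": lambda a, b: a < b,
    "le": lambda a, b: a <= b,
}


def eligibility_mask(cohort: Cohort, predicates: list[EligibilityPredicate]) -> np.ndarray:
    """Boolean mask of subjects failing *no* exclusion predicate."""
    cov = cohort.covariates()
    keep = np.ones(len(cohort), dtype=bool)
    for pred in predicates:
        if pred.covariate not in cov.columns:
            raise ValueError(
                f"eligibility predicate '{pred.name}' references absent covariate '{pred.covariate}'"
            )
        col = cov[pred.covariate]
        if pred.op == "truthy":
            excluded = (col.fillna(0) != 0).to_numpy()
        else:
            excluded = _OPS[pred.op](col, pred.value).fillna(False).to_numpy()
        logger.info("eligibility '%s': %d subjects excluded", pred.name, int(excluded.sum()))
        keep &= ~excluded
    return keep


def apply_eligibility(cohort: Cohort, model: ModelDefinition) -> Cohort:
    """Drop subjects matching any of the model's exclusion predicates."""
    return cohort.subset(eligibility_mask(cohort, model.eligibility))


def complete_case_filter(cohort: Cohort, model: ModelDefinition, warn_above: float = 0.15) -> Cohort:
    """Drop subjects missing any covariate the model references.

    Logs per-covariate missingness; warns when more than ``warn_above`` of
    subjects are dropped (typical validation samples lose well under that).
    """
    refs = model.referenced_covariates()
    cov = cohort.covariates()
    absent = [c for c in refs if c not in cov.columns]
    if absent:
        raise MissingPredictorError(
            f"model '{model.name}' references covariates absent from the cohort: {absent}"
        )
    missing = cov[refs].isna()
    for c in refs:
        n_miss = int(missing[c].sum())
        if n_miss:
            logger.info("complete-case: covariate '%s' missing for %d subjects", c, n_miss)
    drop = missing.any(axis=1).to_numpy()
    frac = drop.mean() if len(cohort) else 0.0
    logger.info("complete-case: dropping %d/%d subjects (%.1f%%)", int(drop.sum()), len(cohort), 100 * frac)
    if frac > warn_above:
        warnings.warn(
            f"complete-case filter removed {100 * frac:.1f}% of subjects "
            f"(> {100 * warn_above:.0f}%); check data quality",
            UserWarning,
        )
    return cohort.subset(~drop)
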