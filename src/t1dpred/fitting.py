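"""Survival model fitting and horizon-specific absolute risk prediction.

Models are fitted on a temporal training split (participants entering on or
before a cutoff date) and evaluated exclusively on the later-entry validation
split.  Two approaches are supported: Cox proportional hazards (partial
likelihood with Efron tie handling, Breslow-type baseline cumulative hazard)
and random survival forests with log-rank splitting.  Each candidate model
either yields a :class:`FittedModel` or a logged :class:`FitFailure` — a
singular fit never aborts a run over the whole model space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import date
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from sksurv.ensemble import RandomSurvivalForest
from sksurv.util import Surv

from .cohort import Cohort
from .features import AB_COMBINATION_LEVELS
from .model_space import ModelSpec


class ExtrapolationError(ValueError):
    """Requested horizon lies beyond the fitted baseline hazard's support."""


@dataclass(frozen=True)
class SplitRule:
    """Temporal train/validation split by study entry date."""

    cutoff_date: date = date(2013, 1, 31)


def temporal_split(data, rule: SplitRule = SplitRule()):
    """Partition a cohort or feature frame by entry date.

    Entries on or before ``rule.cutoff_date`` form the training half, later
    entries the validation half.  The split is disjoint and exhaustive; a
    one-sided split warns but does not raise.
    """
    if isinstance(data, Cohort):
        train = [p for p in data if p.entry_date <= rule.cutoff_date]
        valid = [p for p in data if p.entry_date > rule.cutoff_date]
        if len(data) > 0 and (not train or not valid):
            warnings.warn("temporal split left one side empty", stacklevel=2)
        return (
            Cohort(train, provenance=data.provenance),
            Cohort(valid, provenance=data.provenance),
        )
    df = data
    dates = pd.to_datetime(df["entry_date"])
    mask = dates <= pd.Timestamp(rule.cutoff_date)
    if len(df) > 0 and (mask.all() or (~mask).all()):
        warnings.warn("temporal split left one side empty", stacklevel=2)
    return df[mask], df[~mask]


def design_matrix(features: pd.DataFrame, variables: Sequence[str]) -> pd.DataFrame:
    """Numeric design matrix for a variable subset.

    The categorical autoantibody-combination factor is expanded into
    indicator columns against a fixed reference level so column sets are
    stable across splits.
    """
    cols = []
    for v in variables:
        if v == "ab_combination":
            ref, *rest = AB_COMBINATION_LEVELS
            for level in rest:
                col = (features["ab_combination"] == level).astype(float)
                col.name = f"ab_combination[{level}]"
                cols.append(col)
        else:
            cols.append(features[v].astype(float))
    return pd.concat(cols, axis=1)


@dataclass
class FitFailure:
    spec: ModelSpec
    reason: str


@dataclass
class FittedModel:
    """A fitted survival model plus everything needed to predict risk.

    For Cox models, ``baseline_times``/``baseline_cumhaz`` hold the
    cumulative hazard of a reference subject at the training covariate means,
    and the absolute risk of a subject ``x`` by horizon ``t`` is
    ``1 - exp(-H0(t) * exp(beta . (x - mean)))``.  Random survival forests
    keep the fitted ensemble as an opaque handle.
    """

    spec: ModelSpec
    approach: str
    columns: list[str]
    training_n: int
    max_time: float
    coefficients: dict[str, float] | None = None
    covariate_means: dict[str, float] | None = None
    baseline_times: np.ndarray | None = None
    baseline_cumhaz: np.ndarray | None = None
    handle: object = field(default=None, repr=False)

    def to_record(self) -> dict:
        """JSON-serialisable summary (coefficients and baseline hazard knots)."""
        rec = {
            "model_id": self.spec.model_id,
            "approach": self.approach,
            "stage": self.spec.stage,
            "training_n": self.training_n,
            "max_time": self.max_time,
        }
        if self.coefficients is not None:
            rec["coefficients"] = self.coefficients
            rec["covariate_means"] = self.covariate_means
            rec["baseline_times"] = [float(t) for t in self.baseline_times]
            rec["baseline_cumhaz"] = [float(h) for h in self.baseline_cumhaz]
        return rec


def _survival_frame(features: pd.DataFrame, variables: Sequence[str]) -> pd.DataFrame:
    X = design_matrix(features, variables)
    X = X.assign(
        followup_time=features["followup_time"].astype(float),
        event=features["event"].astype(int),
    )
    return X


def fit_cox(
    train: pd.DataFrame, spec: ModelSpec, penalizer: float = 0.0
) -> FittedModel | FitFailure:
    """Cox proportional-hazards fit for one model specification.

    ``train`` is a feature frame with ``followup_time`` and ``event``
    columns.  Degenerate inputs (no events, constant covariates) and
    non-convergence produce a :class:`FitFailure` record instead of raising.
    """
    df = _survival_frame(train, spec.variables)
    if df["event"].sum() < 1:
        return FitFailure(spec, "no events in training data")
    covs = [c for c in df.columns if c not in ("followup_time", "event")]
    for c in covs:
        if np.isclose(df[c].std(ddof=0), 0.0):
            return FitFailure(spec, f"constant covariate {c!r}")
    cph = CoxPHFitter(penalizer=penalizer)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="followup_time", event_col="event")
    except (ConvergenceError, ValueError, np.linalg.LinAlgError) as exc:
        return FitFailure(spec, f"convergence failure: {exc}")
    if not np.all(np.isfinite(cph.params_.to_numpy())):
        return FitFailure(spec, "non-finite coefficients")

    means = df[covs].mean()
    ref = pd.DataFrame([means])
    H0 = cph.predict_cumulative_hazard(ref)  # reference subject at the means
    times = H0.index.to_numpy(dtype=float)
    cumhaz = H0.iloc[:, 0].to_numpy(dtype=float)
    return FittedModel(
        spec=spec,
        approach="cox",
        columns=covs,
        training_n=len(df),
        max_time=float(df["followup_time"].max()),
        coefficients={c: float(cph.params_[c]) for c in covs},
        covariate_means={c: float(means[c]) for c in covs},
        baseline_times=times,
        baseline_cumhaz=cumhaz,
        handle=cph,
    )


@dataclass(frozen=True)
class RSFParams:
    """Random-survival-forest hyperparameters (package defaults; the method's
    originators give none for this setting)."""

    n_estimators: int = 200
    min_samples_leaf: int = 15
    max_features: str | int | float | None = "sqrt"
    max_depth: int | None = None
    bootstrap: bool = True
    seed: int = 0


def fit_rsf(
    train: pd.DataFrame, spec: ModelSpec, params: RSFParams = RSFParams()
) -> FittedModel | FitFailure:
    """Random survival forest (log-rank splitting) for one specification."""
    df = _survival_frame(train, spec.variables)
    if df["event"].sum() < 1:
        return FitFailure(spec, "no events in training data")
    covs = [c for c in df.columns if c not in ("followup_time", "event")]
    y = Surv.from_arrays(df["event"].astype(bool), df["followup_time"])
    rsf = RandomSurvivalForest(
        n_estimators=params.n_estimators,
        min_samples_leaf=params.min_samples_leaf,
        max_features=params.max_features,
        max_depth=params.max_depth,
        bootstrap=params.bootstrap,
        random_state=params.seed,
        n_jobs=1,
    )
    try:
        rsf.fit(df[covs].to_numpy(), y)
    except ValueError as exc:
        return FitFailure(spec, f"rsf failure: {exc}")
    return FittedModel(
        spec=spec,
        approach="rsf",
        columns=covs,
        training_n=len(df),
        max_time=float(df["followup_time"].max()),
        handle=rsf,
    )


def _step_interp(t: float, times: np.ndarray, values: np.ndarray) -> float:
    """Right-continuous step-function lookup with value 0 before the first knot."""
    idx = np.searchsorted(times, t, side="right") - 1
    return float(values[idx]) if idx >= 0 else 0.0


def predict_risk(
    fitted: FittedModel, features: pd.DataFrame, horizon: float
) -> np.ndarray:
    """Absolute risk of progression by ``horizon`` years for each subject.

    Cox: ``1 - exp(-H0(t) exp(beta . (x - mean)))``; RSF: ensemble-averaged
    cumulative incidence.  ``horizon`` beyond the fitted support raises
    :class:`ExtrapolationError`; ``horizon == 0`` returns zeros.
    """
    if horizon < 0:
        raise ValueError("horizon must be non-negative")
    n = len(features)
    if horizon == 0:
        return np.zeros(n)
    if horizon > fitted.max_time:
        raise ExtrapolationError(
            f"horizon {horizon} beyond fitted support {fitted.max_time:.3f}"
        )
    X = design_matrix(features, fitted.spec.variables)
    X = X[fitted.columns]
    if fitted.approach == "cox":
        beta = np.array([fitted.coefficients[c] for c in fitted.columns])
        means = np.array([fitted.covariate_means[c] for c in fitted.columns])
        lp = (X.to_numpy(dtype=float) - means) @ beta
        h0 = _step_interp(horizon, fitted.baseline_times, fitted.baseline_cumhaz)
        return 1.0 - np.exp(-h0 * np.exp(lp))
    rsf: RandomSurvivalForest = fitted.handle
    surv = rsf.predict_survival_function(X.to_numpy(dtype=float), return_array=True)
    times = rsf.unique_times_
    idx = np.searchsorted(times, horizon, side="right") - 1
    if idx < 0:
        return np.zeros(n)
    return 1.0 - surv[:, idx]
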