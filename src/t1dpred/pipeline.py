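"""End-to-end orchestration: cohort -> features -> model space -> fits ->
metrics -> costs -> Pareto front, with every intermediate persisted.

A single call reproduces the whole analysis on synthetic data: generate (or
load) a cohort, apply eligibility filters, compute features and stages, split
temporally, fit every enumerated predictor combination per preclinical
stage, evaluate censoring-adjusted discrimination and calibration on the
validation half only, attach cost and participant time to every model, and
identify the non-dominated trade-offs.  Per-model failures are isolated and
logged; they never abort the run.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict, replace
from datetime import date
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .cohort import Cohort, GeneratorConfig, generate_cohort, summarize_cohort
from .economics import load_cost_table, load_rate_card, model_cost_time
from .features import (
    apply_eligibility_filters,
    feature_matrix,
    load_lms_tables,
    load_score_registry,
)
from .fitting import (
    ExtrapolationError,
    FitFailure,
    RSFParams,
    SplitRule,
    fit_cox,
    fit_rsf,
    predict_risk,
    temporal_split,
)
from .metrics import (
    DegenerateInputError,
    MetricResult,
    censoring_weights,
    td_auc_ci,
    td_brier,
)
from .model_space import ModelSpec, default_catalog, enumerate_models, space_to_dataframe
from .pareto import GroupThresholds, ObjectiveVector, group_front, pareto_front

STAGES = ("single_ab", "stage1", "stage2")


@dataclass(frozen=True)
class PipelineConfig:
    """Full-run configuration.

    ``catalog_variables`` restricts the default variable catalogue;
    ``max_models`` truncates the (deterministically ordered) enumerated
    space.  ``stagewise_objectives`` selects 8 objectives (cost, time, three
    stage-wise AUCs, three stage-wise Briers) versus 4 (cost, time, mean
    AUC, mean Brier).
    """

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    catalog_variables: tuple[str, ...] | None = None
    max_models: int | None = None
    approach: str = "cox"
    horizons: tuple[float, ...] = (2.0, 3.0, 5.0)
    primary_horizon: float = 3.0
    cutoff_date: date = date(2013, 1, 31)
    stagewise_objectives: bool = True
    rsf_params: RSFParams = field(default_factory=RSFParams)
    out_dir: str | None = None

    @staticmethod
    def smoke(seed: int = 0, out_dir: str | None = None) -> "PipelineConfig":
        """Small deterministic end-to-end configuration (n=300, 20 models)."""
        return PipelineConfig(
            generator=GeneratorConfig(n_participants=300, seed=seed),
            catalog_variables=(
                "auc_glucose",
                "gender",
                "grs2",
                "hba1c",
                "ia2a_flag",
                "index60",
            ),
            max_models=20,
            out_dir=out_dir,
        )


@dataclass
class RunResult:
    config: PipelineConfig
    cohort: Cohort
    summary: dict
    space: list[tuple[str, ...]]
    metrics: pd.DataFrame
    costs: pd.DataFrame
    objectives: pd.DataFrame
    front: list[str]
    records: dict
    groups: pd.DataFrame
    failures: list[dict]
    manifest: dict


def _restricted_catalog(config: PipelineConfig):
    catalog = default_catalog()
    if config.catalog_variables is None:
        return catalog
    wanted = set(config.catalog_variables)
    unknown = wanted - set(catalog.names())
    if unknown:
        raise ValueError(f"unknown catalogue variables {sorted(unknown)}")
    from .model_space import VariableCatalog

    kept = tuple(v for v in catalog.variables if v.name in wanted)
    # degrade singleton exclusion groups to unconstrained variables
    counts: dict[str, int] = {}
    for v in kept:
        if v.exclusion_group:
            counts[v.exclusion_group] = counts.get(v.exclusion_group, 0) + 1
    kept = tuple(
        replace(v, exclusion_group=None)
        if v.exclusion_group and counts[v.exclusion_group] < 2
        else v
        for v in kept
    )
    return VariableCatalog(kept)


def evaluate_model(
    fitted, validation: pd.DataFrame, horizons: Sequence[float], stage: str | None
) -> list[MetricResult]:
    """Validation-split AUC/Brier of one fitted model at each horizon.

    Undefined metrics (no cases/controls, horizon beyond support) are
    recorded as NaN rather than raised.
    """
    times = validation["followup_time"].to_numpy(dtype=float)
    events = validation["event"].to_numpy(dtype=bool)
    out = []
    for h in horizons:
        try:
            w = censoring_weights(times, events, h)
            preds = predict_risk(fitted, validation, h)
            auc, ci = td_auc_ci(preds, times, events, h, w)
            brier = td_brier(np.clip(preds, 0, 1), times, events, h, w)
            n_eff = int(np.sum(w > 0))
        except (DegenerateInputError, ExtrapolationError):
            auc, ci, brier, n_eff = float("nan"), (float("nan"), float("nan")), float("nan"), 0
        out.append(
            MetricResult(
                model_id=fitted.spec.model_id,
                stage=stage,
                horizon=h,
                auc=auc,
                auc_ci=ci,
                brier=brier,
                n_effective=n_eff,
            )
        )
    return out


def run_pipeline(config: PipelineConfig = PipelineConfig()) -> RunResult:
    timings: dict[str, float] = {}
    failures: list[dict] = []
    t0 = time.perf_counter()

    cohort = generate_cohort(config.generator)
    eligible, exclusions = apply_eligibility_filters(cohort)
    summary = summarize_cohort(eligible)
    registry = load_score_registry()
    lms = load_lms_tables()
    features = feature_matrix(eligible, registry, lms)
    timings["cohort_s"] = time.perf_counter() - t0

    t1 = time.perf_counter()
    catalog = _restricted_catalog(config)
    space = enumerate_models(catalog)
    if config.max_models is not None:
        space = space[: config.max_models]
    timings["space_s"] = time.perf_counter() - t1

    rule = SplitRule(config.cutoff_date)
    fit_fn = fit_cox if config.approach == "cox" else (
        lambda df, spec: fit_rsf(df, spec, config.rsf_params)
    )

    t2 = time.perf_counter()
    metric_rows = []
    fit_records = []
    for stage in STAGES:
        stage_df = features[features["stage"] == stage]
        train, valid = temporal_split(stage_df, rule)
        for varset in space:
            spec = ModelSpec(variables=varset, approach=config.approach, stage=stage)
            if len(train) == 0 or len(valid) == 0:
                failures.append(
                    {"model_id": spec.model_id, "stage": stage, "reason": "empty split"}
                )
                continue
            fitted = fit_fn(train, spec)
            if isinstance(fitted, FitFailure):
                failures.append(
                    {"model_id": spec.model_id, "stage": stage, "reason": fitted.reason}
                )
                continue
            fit_records.append(fitted.to_record())
            for r in evaluate_model(fitted, valid, config.horizons, stage):
                metric_rows.append(
                    {
                        "model_id": r.model_id,
                        "stage": r.stage,
                        "horizon": r.horizon,
                        "auc": r.auc,
                        "ci_lo": r.auc_ci[0],
                        "ci_hi": r.auc_ci[1],
                        "brier": r.brier,
                        "n_effective": r.n_effective,
                    }
                )
    metrics = pd.DataFrame(
        metric_rows,
        columns=["model_id", "stage", "horizon", "auc", "ci_lo", "ci_hi", "brier", "n_effective"],
    )
    timings["fit_eval_s"] = time.perf_counter() - t2

    t3 = time.perf_counter()
    cost_table = load_cost_table()
    rates = load_rate_card()
    cost_rows = []
    for varset in space:
        mc = model_cost_time(varset, cost_table, rates)
        cost_rows.append(
            {
                "model_id": mc.model_id,
                "cost_usd": round(mc.total_usd, 1),
                "participant_min": mc.participant_min,
            }
        )
    costs = pd.DataFrame(cost_rows, columns=["model_id", "cost_usd", "participant_min"])
    timings["costs_s"] = time.perf_counter() - t3

    t4 = time.perf_counter()
    ph = config.primary_horizon
    at_h = metrics[metrics["horizon"] == ph]
    # stages where the primary-horizon metrics are globally undefined drop
    # out of the objective vector rather than emptying it
    usable_stages = [
        s for s in STAGES if np.isfinite(at_h[at_h["stage"] == s]["auc"]).any()
    ]
    obj_rows = []
    for varset in space:
        mid = "+".join(sorted(varset))
        row = dict(costs[costs["model_id"] == mid].iloc[0])
        ok = True
        for s in usable_stages:
            sel = at_h[(at_h["stage"] == s) & (at_h["model_id"] == mid)]
            if sel.empty or not np.isfinite(sel["auc"].iloc[0]) or not np.isfinite(
                sel["brier"].iloc[0]
            ):
                ok = False
                break
            row[f"auc_{s}"] = float(sel["auc"].iloc[0])
            row[f"brier_{s}"] = float(sel["brier"].iloc[0])
        if ok and usable_stages:
            obj_rows.append(row)
        elif not ok:
            failures.append(
                {"model_id": mid, "stage": "all", "reason": "incomplete objective vector"}
            )
    objectives = pd.DataFrame(obj_rows)

    front: list[str] = []
    records: dict = {}
    groups = pd.DataFrame(columns=["model_id", "cost_usd", "participant_min", "performance", "group"])
    if not objectives.empty:
        auc_cols = [f"auc_{s}" for s in usable_stages]
        brier_cols = [f"brier_{s}" for s in usable_stages]
        if config.stagewise_objectives:
            names = ["cost_usd", "participant_min"] + auc_cols + brier_cols
            directions = ["min", "min"] + ["max"] * len(auc_cols) + ["min"] * len(brier_cols)
        else:
            objectives["mean_auc"] = objectives[auc_cols].mean(axis=1)
            objectives["mean_brier"] = objectives[brier_cols].mean(axis=1)
            names = ["cost_usd", "participant_min", "mean_auc", "mean_brier"]
            directions = ["min", "min", "max", "min"]
        vectors = [
            ObjectiveVector(r["model_id"], tuple(float(r[c]) for c in names))
            for _, r in objectives.iterrows()
        ]
        front, records = pareto_front(vectors, directions)
        perf = objectives[auc_cols].mean(axis=1)
        fm = objectives.loc[objectives["model_id"].isin(front), ["model_id", "cost_usd", "participant_min"]].copy()
        fm["performance"] = perf[objectives["model_id"].isin(front)]
        groups = group_front(fm.reset_index(drop=True))
    timings["pareto_s"] = time.perf_counter() - t4
    timings["total_s"] = time.perf_counter() - t0

    manifest = {
        "package_version": __version__,
        "seed": config.generator.seed,
        "n_participants": config.generator.n_participants,
        "n_eligible": len(eligible),
        "n_excluded": len(exclusions),
        "n_models": len(space),
        "approach": config.approach,
        "horizons": list(config.horizons),
        "primary_horizon": ph,
        "cutoff_date": config.cutoff_date.isoformat(),
        "usable_stages": usable_stages,
        "n_failures": len(failures),
        "front_size": len(front),
        "complete": True,
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "library_versions": _library_versions(),
    }

    result = RunResult(
        config=config,
        cohort=eligible,
        summary=summary,
        space=space,
        metrics=metrics,
        costs=costs,
        objectives=objectives,
        front=front,
        records=records,
        groups=groups,
        failures=failures,
        manifest=manifest,
    )
    if config.out_dir is not None:
        _persist(result, exclusions, fit_records, Path(config.out_dir))
    return result


def _library_versions() -> dict[str, str]:
    import lifelines
    import sksurv

    return {
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "lifelines": lifelines.__version__,
        "scikit-survival": sksurv.__version__,
    }


def _persist(result: RunResult, exclusions: pd.DataFrame, fit_records, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    result.cohort.to_csv(out / "cohort.csv")
    exclusions.to_csv(out / "exclusions.csv", index=False)
    space_to_dataframe(result.space).to_csv(out / "space.csv", index=False)
    result.metrics.to_csv(out / "metrics.csv", index=False)
    result.costs.to_csv(out / "costs.csv", index=False)
    result.objectives.to_csv(out / "objectives.csv", index=False)
    pd.DataFrame(
        [
            {
                "model_id": m,
                "on_front": rec.on_front,
                "dominated_by": ";".join(rec.dominated_by),
            }
            for m, rec in result.records.items()
        ]
    ).to_csv(out / "front.csv", index=False)
    result.groups.to_csv(out / "front_groups.csv", index=False)
    with open(out / "fits.json", "w") as fh:
        json.dump(fit_records, fh, indent=1)
    with open(out / "failures.json", "w") as fh:
        json.dump(result.failures, fh, indent=1)
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=1)
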