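"""Censoring-adjusted evaluation of horizon-specific risk predictions.

Implements the cumulative/dynamic time-dependent ROC AUC and time-dependent
Brier score under inverse-probability-of-censoring weighting (IPCW), a
paired test for the difference of two IPCW AUCs via their iid
influence-function representation, permutation variable importance, and the
"similar performance" selection rule (|dAUC| < 0.03 and p > 0.05 versus the
best model).

Case/control definition at horizon t is cumulative/dynamic: cases are
subjects with an observed event at or before t; controls are subjects still
event-free beyond t.  Subjects censored at or before t without an event
carry zero weight.  Event weights use the left limit G(T-) of the
Kaplan-Meier censoring-survival estimate; control weights use G(t).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from sksurv.nonparametric import kaplan_meier_estimator

DEFAULT_HORIZONS = (2.0, 3.0, 5.0, 7.0, 10.0)


class DegenerateInputError(ValueError):
    """The metric is undefined on this input (e.g. no cases or no controls)."""


@dataclass(frozen=True)
class MetricResult:
    model_id: str
    stage: str | None
    horizon: float
    auc: float
    auc_ci: tuple[float, float]
    brier: float
    n_effective: int


@dataclass(frozen=True)
class ComparisonResult:
    model_a: str
    model_b: str
    horizon: float
    auc_difference: float
    p_value: float


# ---------------------------------------------------------------------------
# IPCW weights


def _censoring_survival(times: np.ndarray, events: np.ndarray):
    """Kaplan-Meier estimate of the censoring distribution G(t) = P(C > t)."""
    cens = ~events.astype(bool)
    if not cens.any():
        return np.array([0.0]), np.array([1.0])  # no censoring: G == 1
    grid, gvals = kaplan_meier_estimator(cens, times)
    return np.asarray(grid, dtype=float), np.asarray(gvals, dtype=float)


def _G(at: np.ndarray, grid: np.ndarray, gvals: np.ndarray, left: bool = False) -> np.ndarray:
    """Right-continuous G evaluated at ``at`` (or its left limit G(t-))."""
    side = "left" if left else "right"
    idx = np.searchsorted(grid, at, side=side) - 1
    out = np.where(idx >= 0, gvals[np.clip(idx, 0, len(gvals) - 1)], 1.0)
    return np.asarray(out, dtype=float)


def censoring_weights(
    times: Sequence[float],
    events: Sequence[bool],
    horizon: float,
    max_weight: float | None = None,
) -> np.ndarray:
    """Per-subject IPCW weights at ``horizon``.

    Subjects with an observed event at or before the horizon get
    ``1/G(T-)``; subjects at risk beyond the horizon get ``1/G(horizon)``;
    subjects censored at or before the horizon without an event get 0.
    Weights are finite by construction (the last at-risk subject defines the
    KM support).  By default no truncation is applied; a warning is issued if
    the largest weight exceeds 50, and ``max_weight`` clips if given.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if np.any(t <= 0):
        raise ValueError("times must be positive")
    if t.size and np.all(~e) and np.all(t <= horizon):
        raise DegenerateInputError("all subjects censored before the horizon")
    grid, gvals = _censoring_survival(t, e)

    w = np.zeros_like(t)
    case = e & (t <= horizon)
    atrisk = t > horizon
    g_case = _G(t[case], grid, gvals, left=True)
    g_at = _G(np.full(atrisk.sum(), horizon), grid, gvals, left=False)
    with np.errstate(divide="ignore"):
        w[case] = np.where(g_case > 0, 1.0 / g_case, 0.0)
        w[atrisk] = np.where(g_at > 0, 1.0 / g_at, 0.0)
    if w.size and np.nanmax(w) > 50 and max_weight is None:
        import warnings

        warnings.warn(
            f"largest IPCW weight {np.nanmax(w):.1f} > 50; "
            "consider truncation via max_weight",
            stacklevel=2,
        )
    if max_weight is not None:
        w = np.minimum(w, max_weight)
    return w


# ---------------------------------------------------------------------------
# time-dependent ROC AUC


def _case_control(times, events, horizon):
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    return e & (t <= horizon), t > horizon


def _weighted_concordance(pred_case, w_case, pred_ctrl, w_ctrl) -> float:
    """Weighted P(case score > control score), ties counted one half."""
    order = np.argsort(pred_ctrl, kind="mergesort")
    pc = np.asarray(pred_ctrl)[order]
    wc = np.asarray(w_ctrl)[order]
    cum = np.concatenate([[0.0], np.cumsum(wc)])
    lo = np.searchsorted(pc, pred_case, side="left")
    hi = np.searchsorted(pc, pred_case, side="right")
    below = cum[lo]
    tied = cum[hi] - cum[lo]
    num = float(np.sum(np.asarray(w_case) * (below + 0.5 * tied)))
    den = float(np.sum(w_case) * np.sum(w_ctrl))
    return num / den


def td_auc(
    predictions: Sequence[float],
    times: Sequence[float],
    events: Sequence[bool],
    horizon: float,
    weights: np.ndarray | None = None,
) -> float:
    """Cumulative/dynamic IPCW time-dependent ROC AUC at ``horizon``.

    The weighted proportion of concordant (case, control) prediction pairs;
    1 is perfect discrimination, 0.5 is none.  Raises
    :class:`DegenerateInputError` when there is no case or no control.
    """
    p = np.asarray(predictions, dtype=float)
    if weights is None:
        weights = censoring_weights(times, events, horizon)
    case, ctrl = _case_control(times, events, horizon)
    if not case.any() or not ctrl.any():
        raise DegenerateInputError("need at least one case and one control")
    return _weighted_concordance(p[case], weights[case], p[ctrl], weights[ctrl])


def _auc_influence(p, times, events, horizon, weights) -> tuple[float, np.ndarray]:
    """IPCW AUC and its per-subject iid influence-function values.

    First-order representation treating the censoring-KM weights as known;
    reduces to the two-sample (DeLong-type) decomposition when there is no
    censoring.
    """
    p = np.asarray(p, dtype=float)
    n = p.size
    case, ctrl = _case_control(times, events, horizon)
    if not case.any() or not ctrl.any():
        raise DegenerateInputError("need at least one case and one control")
    w = weights
    s1 = np.sum(w[case]) / n
    s0 = np.sum(w[ctrl]) / n
    auc = _weighted_concordance(p[case], w[case], p[ctrl], w[ctrl])

    # mean concordance of each case against controls and vice versa
    order = np.argsort(p[ctrl], kind="mergesort")
    pc, wc = p[ctrl][order], w[ctrl][order]
    cum = np.concatenate([[0.0], np.cumsum(wc)])
    lo = np.searchsorted(pc, p[case], side="left")
    hi = np.searchsorted(pc, p[case], side="right")
    conc_case = (cum[lo] + 0.5 * (cum[hi] - cum[lo])) / n  # (1/n) sum_j w_j c_ij

    order1 = np.argsort(p[case], kind="mergesort")
    p1, w1 = p[case][order1], w[case][order1]
    cum1 = np.concatenate([[0.0], np.cumsum(w1)])
    lo1 = np.searchsorted(p1, p[ctrl], side="left")
    hi1 = np.searchsorted(p1, p[ctrl], side="right")
    above = cum1[-1] - cum1[np.searchsorted(p1, p[ctrl], side="right")]
    tied1 = cum1[hi1] - cum1[lo1]
    conc_ctrl = (above + 0.5 * tied1) / n

    phi = np.zeros(n)
    phi[case] = (w[case] * conc_case - auc * w[case] * s0) / (s1 * s0)
    phi[ctrl] = (w[ctrl] * conc_ctrl - auc * w[ctrl] * s1) / (s1 * s0)
    return auc, phi


def td_auc_ci(
    predictions, times, events, horizon, weights=None, alpha: float = 0.05
) -> tuple[float, tuple[float, float]]:
    """AUC with a logit-transformed influence-function confidence interval."""
    if weights is None:
        weights = censoring_weights(times, events, horizon)
    auc, phi = _auc_influence(predictions, times, events, horizon, weights)
    n = phi.size
    se = float(np.sqrt(np.sum(phi**2)) / n)
    z = stats.norm.ppf(1 - alpha / 2)
    if se == 0 or auc in (0.0, 1.0):
        return auc, (auc, auc)
    logit = np.log(auc / (1 - auc))
    se_logit = se / (auc * (1 - auc))
    lo = 1 / (1 + np.exp(-(logit - z * se_logit)))
    hi = 1 / (1 + np.exp(-(logit + z * se_logit)))
    return auc, (float(lo), float(hi))


# ---------------------------------------------------------------------------
# time-dependent Brier score


def td_brier(
    predictions: Sequence[float],
    times: Sequence[float],
    events: Sequence[bool],
    horizon: float,
    weights: np.ndarray | None = None,
) -> float:
    """IPCW time-dependent Brier score at ``horizon``.

    Weighted mean squared difference between the predicted horizon risk and
    the observed event status; 0 is perfect agreement.
    """
    p = np.asarray(predictions, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("predictions must be probabilities in [0, 1]")
    if weights is None:
        weights = censoring_weights(times, events, horizon)
    case, ctrl = _case_control(times, events, horizon)
    if not case.any() and not ctrl.any():
        raise DegenerateInputError("no observable status at the horizon")
    n = p.size
    contrib = np.zeros(n)
    contrib[case] = weights[case] * (1.0 - p[case]) ** 2
    contrib[ctrl] = weights[ctrl] * (0.0 - p[ctrl]) ** 2
    return float(np.sum(contrib) / n)


# ---------------------------------------------------------------------------
# paired AUC comparison


def compare_auc(
    predictions_a: Sequence[float],
    predictions_b: Sequence[float],
    times: Sequence[float],
    events: Sequence[bool],
    horizon: float,
    model_a: str = "A",
    model_b: str = "B",
) -> ComparisonResult:
    """Two-sided test for a difference of paired IPCW AUCs.

    The variance of the difference comes from the per-subject influence
    functions of the two estimators on the same subjects; identical
    predictions give difference 0 and p = 1 by construction.
    """
    pa = np.asarray(predictions_a, dtype=float)
    pb = np.asarray(predictions_b, dtype=float)
    if pa.shape != pb.shape:
        raise ValueError("both models must score the same subjects")
    w = censoring_weights(times, events, horizon)
    auc_a, phi_a = _auc_influence(pa, times, events, horizon, w)
    auc_b, phi_b = _auc_influence(pb, times, events, horizon, w)
    diff = auc_a - auc_b
    n = phi_a.size
    se = float(np.sqrt(np.sum((phi_a - phi_b) ** 2)) / n)
    if se == 0:
        p = 1.0 if diff == 0 else 0.0
    else:
        p = float(2 * stats.norm.sf(abs(diff) / se))
    return ComparisonResult(model_a, model_b, horizon, float(diff), p)


# ---------------------------------------------------------------------------
# permutation variable importance


def variable_importance(
    fitted,
    features,
    horizon: float,
    n_repeats: int = 10,
    seed: int = 0,
) -> dict[str, float]:
    """Permutation importance on validation data.

    For each model variable, the drop in time-dependent AUC after permuting
    that variable's values across validation subjects, averaged over
    ``n_repeats`` seeded permutations.  Uninformative variables score near 0.
    """
    from .fitting import predict_risk  # deferred to avoid an import cycle

    if len(features) < 2:
        raise DegenerateInputError("importance undefined for < 2 subjects")
    times = features["followup_time"].to_numpy(dtype=float)
    events = features["event"].to_numpy(dtype=bool)
    w = censoring_weights(times, events, horizon)
    base = td_auc(predict_risk(fitted, features, horizon), times, events, horizon, w)
    rng = np.random.default_rng(seed)
    out: dict[str, float] = {}
    for var in fitted.spec.variables:
        drops = []
        for _ in range(n_repeats):
            shuffled = features.copy()
            shuffled[var] = rng.permutation(shuffled[var].to_numpy())
            perm_auc = td_auc(
                predict_risk(fitted, shuffled, horizon), times, events, horizon, w
            )
            drops.append(base - perm_auc)
        out[var] = float(np.mean(drops))
    return out


# ---------------------------------------------------------------------------
# similar-performance selection


def similar_performance_set(
    aucs: Mapping[str, float],
    comparisons: Mapping[str, float],
    best_model: str,
    auc_margin: float = 0.03,
    p_threshold: float = 0.05,
) -> set[str]:
    """Models statistically indistinguishable from the best one.

    A model is "similar" when |AUC - AUC_best| < ``auc_margin`` AND its
    pairwise p-value against the best model exceeds ``p_threshold``; both
    conditions are required.  The best model is not a member of its own set.
    ``comparisons`` maps model id to the p-value versus the best model.
    """
    best_auc = aucs[best_model]
    out = set()
    for model, auc in aucs.items():
        if model == best_model:
            continue
        p = comparisons.get(model)
        if p is None:
            continue
        if abs(auc - best_auc) < auc_margin and p > p_threshold:
            out.add(model)
    return out
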