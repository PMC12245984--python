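"""Multi-objective non-dominated selection over the model landscape.

Each model carries an objective vector — financial cost and participant time
(minimised) and stage-wise 3-year discrimination/calibration (AUC maximised,
Brier minimised).  A model dominates another when it is at least as good on
every objective and strictly better on at least one; the Pareto front is the
set of non-dominated models.  Identical vectors do not dominate each other,
so duplicates are both retained on the front.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ObjectiveVector:
    model_id: str
    values: tuple[float, ...]


@dataclass
class ParetoRecord:
    model_id: str
    dominated_by: list[str]
    group: str | None = None

    @property
    def on_front(self) -> bool:
        return not self.dominated_by


def _signed(values: np.ndarray, directions: Sequence[str]) -> np.ndarray:
    """Orient every objective so that smaller is better."""
    if values.shape[1] != len(directions):
        raise ValueError("objective dimension mismatch")
    signs = []
    for d in directions:
        if d == "min":
            signs.append(1.0)
        elif d == "max":
            signs.append(-1.0)
        else:
            raise ValueError(f"direction must be 'min' or 'max', got {d!r}")
    return values * np.asarray(signs)


def pareto_front(
    vectors: Sequence[ObjectiveVector], directions: Sequence[str]
) -> tuple[list[str], dict[str, ParetoRecord]]:
    """Non-dominated set plus per-model dominance records.

    Returns the front (model ids, input order) and a mapping from model id to
    its :class:`ParetoRecord` listing every model that dominates it.  The
    result is independent of input order and invariant to positive rescaling
    of any single objective.
    """
    if not vectors:
        raise ValueError("need at least one objective vector")
    ids = [v.model_id for v in vectors]
    raw = np.array([v.values for v in vectors], dtype=float)
    if not np.all(np.isfinite(raw)):
        raise ValueError("objective vectors must be finite")
    vals = _signed(raw, directions)

    records: dict[str, ParetoRecord] = {}
    n = len(vectors)
    for i in range(n):
        leq = np.all(vals <= vals[i], axis=1)
        lt = np.any(vals < vals[i], axis=1)
        dominators = np.flatnonzero(leq & lt)
        records[ids[i]] = ParetoRecord(
            model_id=ids[i],
            dominated_by=sorted(ids[j] for j in dominators if j != i),
        )
    front = [m for m in ids if records[m].on_front]
    return front, records


@dataclass(frozen=True)
class GroupThresholds:
    """Thresholds for splitting the front into interpretable groups.

    Group 1 ("high_perf_high_cost"): performance within ``high_perf_margin``
    of the best model's, with cost above ``high_cost_usd`` and participant
    time above ``high_time_min``.  Group 2 ("balanced"): within
    ``balanced_margin`` of best with lower cost and/or time.  Group 3
    ("no_ogtt"): cost below ``no_ogtt_cost_usd`` and time below
    ``no_ogtt_time_min`` (no OGTT needed).
    """

    high_perf_margin: float = 0.05
    high_cost_usd: float = 135.0
    high_time_min: float = 100.0
    balanced_margin: float = 0.10
    no_ogtt_cost_usd: float = 100.0
    no_ogtt_time_min: float = 20.0


def group_front(
    front_metrics: pd.DataFrame,
    thresholds: GroupThresholds = GroupThresholds(),
) -> pd.DataFrame:
    """Assign each front model to a trade-off group.

    ``front_metrics`` needs columns ``model_id``, ``cost_usd``,
    ``participant_min`` and ``performance`` (larger better; typically the
    mean 3-year AUC across stages).  Returns the frame with a ``group``
    column in {high_perf_high_cost, balanced, no_ogtt, None}.
    """
    df = front_metrics.copy()
    if df.empty:
        df["group"] = pd.Series(dtype=object)
        return df
    best = df["performance"].max()
    rel_gap = (best - df["performance"]) / best if best > 0 else best - df["performance"]

    def classify(row, gap):
        if gap <= thresholds.high_perf_margin and (
            row["cost_usd"] > thresholds.high_cost_usd
            and row["participant_min"] > thresholds.high_time_min
        ):
            return "high_perf_high_cost"
        if (
            row["cost_usd"] < thresholds.no_ogtt_cost_usd
            and row["participant_min"] < thresholds.no_ogtt_time_min
        ):
            return "no_ogtt"
        if gap <= thresholds.balanced_margin:
            return "balanced"
        return None

    df["group"] = [classify(r, g) for (_, r), g in zip(df.iterrows(), rel_gap)]
    return df
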