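"""Financial cost and participant-time accounting for predictor acquisition.

Each predictor variable has a cost decomposition: assay reimbursement (HCPCS
bundle), physician minutes, assistant minutes, and participant minutes valued
as lost wages.  Procedure-bound variables (OGTT-derived measures) carry the
sampling duration plus a fixed 45-minute preparation/discharge overhead; a
simple blood draw takes 10 minutes.  When several variables are measured at
the same visit the participant commits only the time of the longest
procedure, and clinician time is shared within each procedure group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml


class CostConfigurationError(ValueError):
    """Unknown procedure label or missing cost-table entry."""


#: OGTT sampling durations (minutes); participant time adds PROCEDURE_OVERHEAD_MIN
OGTT_DURATIONS = {"ogtt_120": 120, "ogtt_90": 90, "ogtt_60": 60, "ogtt_30": 30}
PROCEDURE_OVERHEAD_MIN = 45
BLOOD_DRAW_MIN = 10


def procedure_time(procedure: str) -> float:
    """Participant minutes for one procedure label.

    OGTT procedures cost their sampling duration plus 45 min of preparation
    and discharge (a 120-min OGTT therefore takes 165 min); a simple blood
    draw takes 10 min; ``none`` takes 0.
    """
    if procedure in OGTT_DURATIONS:
        return float(OGTT_DURATIONS[procedure] + PROCEDURE_OVERHEAD_MIN)
    if procedure == "blood_draw":
        return float(BLOOD_DRAW_MIN)
    if procedure == "none":
        return 0.0
    raise CostConfigurationError(f"unknown procedure {procedure!r}")


@dataclass(frozen=True)
class RateCard:
    """Per-minute unit prices (USD) for clinician and participant time."""

    physician_rate: float = 2.48
    assistant_rate: float = 0.46
    participant_wage: float = 0.26
    reference_year: int = 2024

    def __post_init__(self):
        if min(self.physician_rate, self.assistant_rate, self.participant_wage) < 0:
            raise ValueError("rates must be non-negative")


@dataclass(frozen=True)
class CostEntry:
    """Cost decomposition for acquiring one predictor variable."""

    variable: str
    physician_min: float
    assistant_min: float
    assay_usd: float
    hcpcs: str = ""
    procedure: str = "none"

    def __post_init__(self):
        if self.physician_min < 0 or self.assistant_min < 0:
            raise ValueError("minutes must be non-negative")
        if self.assay_usd < 0:
            raise ValueError("assay cost must be non-negative")
        procedure_time(self.procedure)  # validates the label

    @property
    def participant_min(self) -> float:
        return procedure_time(self.procedure)


@dataclass(frozen=True)
class ModelCost:
    """Aggregated cost/time of one predictor combination."""

    model_id: str
    total_usd: float
    participant_min: float
    breakdown: Mapping[str, float] = field(default_factory=dict)


def load_rate_card(path=None) -> RateCard:
    if path is None:
        with resources.files("t1dpred.data").joinpath("rate_card.yaml").open() as fh:
            raw = yaml.safe_load(fh)
    else:
        with open(str(path)) as fh:
            raw = yaml.safe_load(fh)
    return RateCard(**raw)


def load_cost_table(path=None) -> dict[str, CostEntry]:
    """Cost table keyed by variable name; packaged default transcribes the
    published per-variable cost table (2024 USD)."""
    if path is None:
        with resources.files("t1dpred.data").joinpath("cost_table.csv").open() as fh:
            df = pd.read_csv(fh)
    else:
        df = pd.read_csv(str(path))
    table = {}
    for _, r in df.iterrows():
        table[str(r["variable"])] = CostEntry(
            variable=str(r["variable"]),
            physician_min=float(r["physician_min"]),
            assistant_min=float(r["assistant_min"]),
            assay_usd=float(r["assay_usd"]),
            hcpcs="" if pd.isna(r.get("hcpcs")) else str(r["hcpcs"]),
            procedure=str(r["procedure"]),
        )
    return table


def variable_cost(entry: CostEntry, rates: RateCard) -> float:
    """Total acquisition cost of one variable measured on its own."""
    return (
        entry.assay_usd
        + entry.physician_min * rates.physician_rate
        + entry.assistant_min * rates.assistant_rate
        + entry.participant_min * rates.participant_wage
    )


def model_cost_time(
    variables: Sequence[str],
    cost_table: Mapping[str, CostEntry],
    rates: RateCard,
    sharing: str = "max_within_group",
    model_id: str | None = None,
) -> ModelCost:
    """Cost and participant time of a predictor combination.

    Assay costs always sum over variables.  Participant time is the maximum
    over the procedure groups invoked, never the sum: every variable is
    collected within a single screening visit, so the participant commits
    only the longest procedure's time.  Under the default
    ``max_within_group`` policy, physician and assistant minutes are shared
    (max) among variables in the same procedure group and summed across
    groups; ``sum`` charges every variable's clinician time separately.
    """
    if not variables:
        raise ValueError("model must contain at least one variable")
    if sharing not in ("max_within_group", "sum"):
        raise CostConfigurationError(f"unknown sharing policy {sharing!r}")
    entries = []
    for v in variables:
        if v not in cost_table:
            raise CostConfigurationError(f"no cost entry for variable {v!r}")
        entries.append(cost_table[v])

    assay = sum(e.assay_usd for e in entries)
    times = [e.participant_min for e in entries]
    participant_min = max(times) if times else 0.0

    if sharing == "sum":
        physician = sum(e.physician_min for e in entries)
        assistant = sum(e.assistant_min for e in entries)
    else:
        physician = assistant = 0.0
        for proc in sorted({e.procedure for e in entries}):
            group = [e for e in entries if e.procedure == proc]
            physician += max(e.physician_min for e in group)
            assistant += max(e.assistant_min for e in group)

    total = (
        assay
        + physician * rates.physician_rate
        + assistant * rates.assistant_rate
        + participant_min * rates.participant_wage
    )
    return ModelCost(
        model_id=model_id or "+".join(sorted(variables)),
        total_usd=total,
        participant_min=participant_min,
        breakdown={
            "assay_usd": assay,
            "physician_min": physician,
            "assistant_min": assistant,
            "participant_min": participant_min,
        },
    )


def cost_table_report(
    cost_table: Mapping[str, CostEntry], rates: RateCard
) -> pd.DataFrame:
    """Per-variable totals and participant time (currency to 1 decimal)."""
    rows = []
    for name in sorted(cost_table):
        e = cost_table[name]
        rows.append(
            {
                "variable": name,
                "physician_min": e.physician_min,
                "assistant_min": e.assistant_min,
                "hcpcs": e.hcpcs,
                "participant_min": e.participant_min,
                "total_usd": round(variable_cost(e, rates), 1),
            }
        )
    return pd.DataFrame(rows)
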