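"""Financial cost and participant time of candidate screening panels.

Each predictor carries assay reimbursement, clinician minutes and a
procedure; within one visit the participant commits only the longest
procedure's time (an OGTT plus a blood draw is still one OGTT visit).
"""

from t1dpred import (
    cost_table_report,
    load_cost_table,
    load_rate_card,
    model_cost_time,
)

table = load_cost_table()
rates = load_rate_card()

print("per-variable acquisition cost (USD) and participant minutes:")
report = cost_table_report(table, rates)
cols = ["variable", "participant_min", "total_usd"]
print(report[report["variable"].isin(
    ["auc_glucose", "auc_cpeptide", "index60", "cpeptide30", "hba1c", "grs2", "age"]
)][cols].to_string(index=False))

print("\nthree candidate panels:")
for name, panel in [
    ("full 2-h OGTT model", ["auc_glucose", "auc_cpeptide", "hba1c", "age"]),
    ("1-h Index60 panel", ["index60", "hba1c", "age", "gender", "ia2a_flag"]),
    ("bloods-only panel", ["hba1c", "grs2", "ia2a_flag", "age"]),
]:
    mc = model_cost_time(panel, table, rates)
    print(f"  {name:22s} ${mc.total_usd:6.1f}  {mc.participant_min:5.0f} min")

print("\nShortening the OGTT from 120 to 60 minutes saves an hour of")
print("participant time per visit; dropping it entirely leaves a 10-minute")
print("blood draw — the trade-off the Pareto comparison quantifies.")
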