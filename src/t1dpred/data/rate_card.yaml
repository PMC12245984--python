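# Unit prices for clinician and participant time, 2024 US dollars per minute.
#
# Calibrated once so that the per-variable totals computed by
# economics.cost_table_report reproduce the published per-variable cost
# table exactly under the linear costing model
#   total = assay + physician_min * physician_rate
#         + assistant_min * assistant_rate + participant_min * participant_wage.
# The implied hourly rates (physician ~$149/h, medical assistant ~$28/h,
# participant lost wages ~$16/h) are of the magnitude of US Medicare
# reimbursement and Bureau of Labor Statistics wage data.
physician_rate: 2.48
assistant_rate: 0.46
participant_wage: 0.26
reference_year: 2024
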