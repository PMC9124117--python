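"""Clean a cohort, impute missing values and derive the five-year label.

Cleaning drops identifier and post-operative columns (the model predicts
before the operation); temporal-neighbour imputation fills each missing
covariate with the mean of its nearest observed neighbours in transplant-
date order; the censoring step turns the three date columns into a binary
survive / not-survive label at the 1826-day horizon.
"""

from graftsurv import preprocessing as pp
from graftsurv.synthetic import CohortSpec, generate_cohort

table, _ = generate_cohort(CohortSpec(n_patients=500, seed=7))
print(f"raw columns:       {len(table.frame.columns)}")

run_log: list[str] = []
table = pp.clean_table(table, run_log)
table = pp.drop_sparse_rows(table, run_log=run_log)
n_missing = int(table.frame[table.columns_by_tag("preop")].isna().sum().sum())
table = pp.impute_table(table, run_log)
table = pp.attach_labels(table, horizon_days=1826)

print(f"after cleaning:    {len(table.frame.columns)} columns "
      f"({len(table.columns_by_tag('preop'))} pre-op + outcome)")
print(f"imputed cells:     {n_missing}")
print(f"run-log entries:   {len(run_log)} (column drops, row drops, imputations)")
print(f"label prevalence:  {table.frame[table.outcome_column].mean():.3f} "
      "(class 1 = graft functioning: survived or censored)")

# the censoring arithmetic on a single record
rec = {
    "transplant_date": "2000-01-01",
    "dialysis_start_date": "2001-01-01",
    "last_followup_date": None,
}
out = pp.derive_graft_outcome(rec)
print(f"example record:    graft_time={out.graft_time_days}d "
      f"status={out.status} label={out.label}")
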