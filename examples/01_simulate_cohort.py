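"""Generate a synthetic longitudinal allo-HCT cohort and look at its shape.

The generator emulates a transcriptional fingerprint assay study: weekly
blood sampling from engraftment to day 100, biweekly after, one
pre-transplant sample, GVHD episodes for a subset of patients, infection
windows, relapse flags, batch structure and detection censoring.
"""

from tfaflow import SimConfig, simulate_cohort, sampling_schedule

schedule = sampling_schedule(engraftment_day=21, followup_days=215)
print(f"collection days ({len(schedule)} per patient): {schedule}")

cohort = simulate_cohort(SimConfig(seed=7))
print(f"\nCt table: {cohort.ct.shape[0]} samples x "
      f"{len(cohort.assay_columns)} assays (264 targets + 8 housekeeping)")
print(f"patients: {cohort.annotations.patient_id.nunique()} "
      f"({len(cohort.truth['gvhd_patients'])} develop GVHD)")
print("\nGVHD episodes:")
print(cohort.episodes.to_string(index=False))

n_missing = cohort.ct[cohort.assay_columns].isna().sum().sum()
print(f"\nmissing Ct entries (MCAR + detection censoring): {n_missing}")
# Each row of the episodes table is one clinically graded GVHD episode;
# ACTIVE-phase samples are the ones collected inside [onset, resolution].
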