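"""Run the complete study analysis on a synthetic cohort.

Per subject: productive filtering, donor-reactive classification,
downsampling-normalized abundance, diversity, divergence, and networks;
then cohort-level paired/unpaired t-tests and ANOVA.  Writes all tables,
plots, and a metrics JSON to an output directory.
"""

from allotrace import CohortConfig, StudyConfig, generate_cohort, run_study, write_report
from allotrace.pipeline import comparisons_frame

cohort = generate_cohort(
    CohortConfig(
        n_subjects=6,
        clonotypes_per_compartment=800,
        tissue_clonotypes=500,
        depth_blood=15_000,
        depth_tissue=6_000,
        seed=11,
    )
)
report = run_study(cohort, StudyConfig(n_reps=50, seed=11))
write_report(report, "scratch/example_report")

frame = comparisons_frame(report)
print(f"analyzed {report.n_subjects_analyzed} subjects; key comparisons:")
cols = ["statistic_name", "test", "mean_a", "mean_b", "estimate", "p_value"]
show = frame[
    frame["statistic_name"].isin(
        ["cum_dr_frequency_CD4", "delta_cum_dr_frequency_CD4", "modularity_dr_vs_pretx_CD4"]
    )
]
print(show[cols].to_string(index=False))
print("full report written to scratch/example_report/")
# cum_dr_frequency_CD4: paired t, post- vs pre-transplant donor-reactive cell %
#   (the planted 2.4x gain makes this strongly significant);
# delta_...: rejectors vs controls on the change (no group difference planted);
# modularity_dr_vs_pretx: donor-reactive networks cluster more than bulk blood.
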