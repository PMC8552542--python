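"""Generate a small synthetic transplant cohort and write it to disk.

Each subject gets paired pre-/post-transplant CD4 and CD8 blood repertoires,
an MLR-stimulated pre-transplant pair per compartment, and — for rejectors —
a bulk graft-tissue repertoire.  A truth table records which clonotypes were
planted as donor-reactive.
"""

from allotrace import CohortConfig, generate_cohort

config = CohortConfig(
    n_subjects=4,
    clonotypes_per_compartment=1000,
    depth_blood=20_000,
    depth_tissue=8_000,
    tissue_clonotypes=700,
    seed=7,
)
cohort = generate_cohort(config, out_dir="scratch/example_cohort")

print(f"subjects: {len(cohort.subjects)}")
for subject_id, subj in cohort.subjects.items():
    n_dr = sum(len(k) for k in subj.truth.dr_keys.values())
    print(
        f"  {subject_id}: {'rejector' if subj.rejector else 'control '}"
        f"  samples={len(subj.samples)}  planted donor-reactive clonotypes={n_dr}"
    )
print("files written to scratch/example_cohort (manifest.csv + samples/*.tsv)")
# Each sample TSV is a clonotype table (CDR3 nt/aa, V/D/J, count, frequency);
# the truth table lists the planted donor-reactive clonotype keys per subject.
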