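# allotrace

Tracking donor-reactive T-cell clones in blood and kidney allografts from
TCRβ repertoire sequencing.

After kidney transplantation, recipient T-cells recognizing donor antigens
can expand in the circulation and infiltrate the graft, driving T-cell-
mediated rejection.  Because each T-cell clone carries a unique CDR3β
sequence, the donor-reactive repertoire can be defined *functionally* before
transplantation — by sequencing recipient cells that proliferate in a mixed
lymphocyte reaction (MLR) against donor cells — and then tracked in any
later blood or biopsy sample.  `allotrace` implements this complete
downstream analysis for researchers working with clonotype tables from
standard V(D)J consensus-assembly pipelines:

* **Donor-reactive classification** — a clonotype is donor-reactive when its
  frequency in the MLR-stimulated sample satisfies
  `f_stim / max(f_unstim, 1/N_unstim) ≥ 5`
  against the unstimulated pre-transplant sample (the floor handles clones
  undetected at baseline).
* **Depth normalization** — statistics are means over 1,000 random
  downsamplings (multivariate hypergeometric) to the lowest read count among
  the compared samples.
* **Diversity** — Shannon entropy *H*; clonality `C = 1 − H_obs/ln S`;
  `R20` = fraction of top clones jointly holding 20% of the repertoire;
  power-law slope of the bulk clone-size spectrum by log–log OLS after
  splitting off the high-frequency component.
* **Repertoire divergence** — Jensen–Shannon divergence in bits,
  `JSD(p,q) = H₂((p+q)/2) − (H₂(p)+H₂(q))/2 ∈ [0,1]`,
  over each pair's top-1,000 clones, and over V–J gene usage.
* **CDR3 similarity networks** — undirected graphs over unique productive
  CDR3β amino-acid sequences (top 10,000 clonotypes), linked when the inner
  segments (first and last 3 residues trimmed) are at Levenshtein distance 1;
  modularity, edge density, degree and betweenness centrality.
* **Synthetic cohort generator** — power-law repertoires with planted
  donor-reactive clone families, MLR enrichment, post-transplant expansion
  and graft infiltrates, plus a truth table, so the whole pipeline can be
  validated end-to-end with known ground truth.
* **Study pipeline** — orchestration across a cohort with paired/unpaired
  t-tests and ANOVA, tables, plots, and a reproducible seed.

## Worked example

```python
from allotrace import CohortConfig, StudyConfig, generate_cohort, run_study
from allotrace.pipeline import comparisons_frame

cohort = generate_cohort(CohortConfig(n_subjects=6, clonotypes_per_compartment=800,
                                      tissue_clonotypes=500, depth_blood=15_000,
                                      depth_tissue=6_000, seed=11))
report = run_study(cohort, StudyConfig(n_reps=50, seed=11))
print(comparisons_frame(report)[["statistic_name", "test", "mean_a", "mean_b", "p_value"]])
```

Running `python examples/06_full_study.py` (which adds `write_report`) prints:

```
            statistic_name       test   mean_a   mean_b  estimate  p_value
      cum_dr_frequency_CD4   PAIRED_T 2.069526 0.572231  1.497295 0.000320
delta_cum_dr_frequency_CD4 UNPAIRED_T 1.586787 1.407804  0.178983 0.654973
modularity_dr_vs_pretx_CD4   PAIRED_T 0.635185 0.442130  0.193056 0.000021
```

Reading these numbers: the donor-reactive CD4 cell fraction rises from
0.57% of cells pre-transplant to 2.07% at biopsy (paired t, p < 0.001),
recovering the simulated 2.4-fold expansion; the *change* does not differ
between rejectors and controls (p = 0.65), matching the planted null; and
donor-reactive similarity networks are more modular than bulk pre-transplant
networks (p < 0.001) because donor-reactive clones arise in families of
near-identical CDR3s.  The other `examples/` scripts each demonstrate one
capability (simulation, classification, diversity, divergence, networks)
with a line on how to read the output.

A thin CLI wraps the same functions:

```bash
allotrace simulate --out cohort_dir --seed 1
allotrace run --manifest cohort_dir/manifest.csv --out report_dir
allotrace network --sample cohort_dir/samples/S01_TISSUE_BULK_UNSTIMULATED.tsv --out net_dir
```

## Input formats

One TSV per sample with columns for count, CDR3 nucleotide and amino-acid
sequence, and V/D/J gene labels (`cloneCount`, `nSeqCDR3`, `aaSeqCDR3`,
`bestVGene`, ... — synonyms configurable via `allotrace.io.DEFAULT_COLUMNS`),
plus a CSV manifest mapping each file to subject, timepoint
(`PRE_TX`/`POST_TX`/`TISSUE`), compartment (`CD4`/`CD8`/`BULK`), condition
(`UNSTIMULATED`/`MLR_STIMULATED`) and rejection group.  Frequencies are
always recomputed from counts.  See `docs/methods.md` for the statistical
model, parameter defaults, and known limitations.
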