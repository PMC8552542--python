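# Methods

This note documents the statistical model behind `allotrace`, the defaults
and why they were chosen, what the synthetic cohort generator does and does
not emulate, and the numerical conventions used throughout.

## Data model

A clonotype is identified by the triple (CDR3 nucleotide sequence, V gene,
J gene).  Clone tracking across samples of a subject operates on the
nucleotide sequence; the V/J labels guard against convergent nucleotide
rearrangements from different gene segments.  The D gene is excluded from
identity because it is frequently undetermined in short-read assemblies.
Frequencies are always recomputed from counts after any read, merge, or
filter; frequency columns in input files are treated as advisory.

Non-productive clonotypes — CDR3 amino-acid sequences containing a stop
(`*`) or frameshift (`_`) marker — are removed before any sequence-level
analysis, with renormalization.

Clonotypes observed in both the CD4- and CD8-sorted unstimulated samples of
a subject are resolved by a doubling rule: the clone is assigned to the
subset in which its maximum frequency across timepoints is at least twice
that in the other; otherwise it is dropped.  `≥ 2×` (an exact tie counts as
doubling) makes the rule deterministic.  The rule uses the unstimulated
sorted samples only; MLR samples inherit the assignment.

## Donor-reactive classification

Given a subject's MLR-stimulated and unstimulated pre-transplant samples of
the same compartment, the fold change of every clone present in the
stimulated sample is

    FC = f_stim / max(f_unstim, 1/N_unstim)

with `N_unstim` the unstimulated sample's total reads.  Clones with
`FC ≥ 5` form the donor-reactive set.  The pseudo-frequency floor
`1/N_unstim` is the limit of detection and makes the rule well defined for
clones undetected at baseline; it is configurable, as is a minimum
stimulated count (default 1).  Fold changes use normalized frequencies so
unequal sequencing depths cannot bias classification.  Donor-reactive sets
are compartment-specific; bulk tissue samples are queried against the union
of the subject's CD4 and CD8 sets.

Operating characteristics: a point-estimate fold-change threshold is noisy
for clones whose expected read count is O(10).  Under the generator's
default conditions (5,000 clonotypes per compartment at depth 10⁵, so most
background clones expect ~10 reads) roughly 5 background clones per
compartment drift across the 5-fold threshold per draw, which puts the
rule's precision near 0.90 at a planted 1% donor-reactive fraction, while
sensitivity at 20-fold enrichment is ~1.0.  This is a property of the
classification rule at these read depths, not of its implementation.

## Depth normalization

Comparisons across samples are made at a common depth: the minimum total
reads among the compared samples (per subject and compartment; tissue
samples join the minimum for tissue comparisons).  Reads are drawn without
replacement — a multivariate hypergeometric draw over the clonotype counts —
and each statistic is reported as mean ± SD over `n_reps = 1000` independent
replicates (configurable).  Clones absent from a replicate contribute zero
to that replicate's clonotype counts.  Per-replicate seeds derive
deterministically from the root seed (`seed + replicate_index`), so
replicate 0 reproduces a single `downsample` call with the root seed.

## Diversity statistics

* Shannon entropy `H = −Σ f ln f` (nats).
* Clonality `C = 1 − H/ln S` over the `S` observed unique clonotypes; `C = 1`
  for a single-clonotype sample (the limit of the formula; `ln 1 = 0` would
  give 0/0).  Natural logs; the base cancels in the ratio.
* `R20`: clones are ranked by descending frequency, ties broken by clonotype
  key; `R20 = k/S` with `k` the smallest number of top clones whose
  cumulative frequency reaches 0.20.  Any alternative tie rule changes
  `R20` by at most (tied-group size)/S, which the test suite asserts.
* Power-law slope: "expanded" clones default to frequency ≥ 10⁻³; the
  repertoire is split at the second-smallest distinct expanded frequency
  (with fewer than two expanded clones everything is bulk); the clone-size
  spectrum of the bulk (x = raw integer count, y = fraction of distinct
  clonotypes at that count, unbinned) is fitted by unweighted OLS of log y
  on log x.  The cutoff actually used is reported for auditability.  The
  fit requires ≥ 3 distinct clone sizes and reports NaN in the summary
  tables otherwise.

## Repertoire divergence

The Jensen–Shannon divergence is computed in log base 2,
`JSD = H₂(m) − (H₂(p)+H₂(q))/2` with `m = (p+q)/2` and `0·log 0 := 0`, which
bounds it by [0, 1] (natural-log JSD is bounded by ln 2 instead).  Clone
distributions are truncated to each repertoire's top 1,000 clones *before*
forming union-support distributions and renormalizing; clone keys are
nucleotide-level by default (amino-acid option available).  V–J usage
divergence applies the same JSD to frequencies aggregated by (V, J) pair.
For blood↔tissue comparisons, sorted CD4/CD8 blood samples are pooled into
a bulk repertoire to match the unsorted tissue.

## Similarity networks

Nodes are unique productive CDR3β amino-acid sequences among the top 10,000
clonotypes (nucleotide-convergent clones merged, frequencies summed;
boundary ties broken lexicographically).  The first and last three residues
are trimmed and two nodes are linked iff their inner segments are at
Levenshtein distance exactly 1; sequences shorter than 7 aa have no inner
segment and are excluded (counted).  Identical inner segments (flank-only
differences) are *not* linked by default.  For unit distance the edge set
is computed exactly by deletion-variant hashing (O(n·L) expected) and is
verified against a brute-force O(n²) dynamic-programming oracle in the test
suite; other thresholds use banded pairwise alignment via edlib.

Communities come from deterministic greedy (Clauset–Newman–Moore)
modularity maximization so modularity values are reproducible run to run;
`Q = Σ_c (e_c/m − (d_c/2m)²)`.  Edge density is `|E| / (n(n−1)/2)`.
Betweenness centrality is reported in unnormalized shortest-path-count form
and used for ranking only (ties broken by degree, then sequence).  A graph
with no edges reports modularity 0 and betweenness 0.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes and
serves as the acceptance oracle for every stage.  Per subject and
compartment:

* Base clone weights are drawn from a discrete power law (Zipf, exponent
  2.5 by default) over 5,000 clonotypes.
* A 1% donor-reactive fraction is planted as clone *families* — groups of 3
  CDR3s at inner-segment Levenshtein distance 1 sharing a V gene — which is
  what gives donor-reactive networks their modular structure.  Family CDR3s
  are built as single inner substitutions of a family head; all sequences
  start with C, end with F, and carry consistent reverse-translated
  nucleotide sequences with random synonymous codons.  Donor-reactive
  clones draw their weights from outside the top-1% order statistics: the
  expansion signal of interest is carried by low/mid-frequency clones, and
  central network nodes are expected to be low-frequency.
* Samples are emitted as multinomial draws from the true frequencies
  (sequencing an effectively infinite cell pool): an unstimulated and an
  MLR-stimulated pre-transplant pair, a post-transplant sample, and — for
  rejectors — a bulk tissue sample.  Per-sample depth varies uniformly by
  ±25% around the nominal depth (10⁵ blood, 2·10⁴ tissue) to exercise the
  downsampling normalization.
* MLR stimulation multiplies donor-reactive weights by 20 and renormalizes.
  Post-transplant, donor-reactive weights are multiplied by 2.4; one quarter
  of donor-reactive clones are additionally suppressed below 1/depth in the
  unstimulated pre-transplant sample (true frequency 0.1/depth) so they are
  undetectable at baseline, yet respond in the MLR at their unsuppressed
  weight — the floor rule is what classifies them.
* Rejector tissue holds the subject's pooled donor-reactive clones at 3.5%
  cumulative frequency over a background that is 40% shared with blood and
  60% tissue-unique, producing the elevated blood↔tissue divergence.
* V/J labels are drawn from per-subject Dirichlet usage vectors, giving each
  subject a distinct V–J landscape.

Default effect sizes (20× MLR enrichment, 2.4× post-transplant gain, 1%
donor-reactive clonotypes, 3.5% tissue cumulative frequency, 12 subjects
with 6 rejectors) are the cohort conditions used throughout the tests.

What the generator does **not** emulate: V(D)J recombination statistics,
thymic selection or HLA restriction; sort impurity; and — importantly — the
depletion of non-responding clones in the MLR well.  Real MLR samples are
FACS-sorted proliferating cells and contain far fewer unique clonotypes
than unstimulated blood, whereas the simulated MLR keeps the whole
background at reduced relative weight.  Passing tests therefore demonstrate
correct recovery of planted enrichment/divergence/cluster structure under
idealized sampling, not performance on real sorted-well data, where
classification is easier (background carryover is strongly depleted) but
clonotype richness and sequencing artifacts are harsher.

## Cohort statistics

Pre- vs. post-transplant comparisons use two-sided paired t-tests;
rejector-vs-control comparisons of changes (including ΔR20 and Δclonality,
post − pre) use the two-sided two-sample Student's t-test (Welch available
but off by default); edge density across the pre-/post-/donor-reactive
repertoire classes uses one-way ANOVA; donor-reactive vs. bulk network
modularity uses paired t-tests.  95% confidence intervals accompany mean
differences.  p-values are not adjusted for multiple testing (exploratory
analysis); the significance threshold is 0.05.  The helpers are verified
against independent reference implementations to 10⁻⁸ on fixed vectors.

## Reproducibility and problem sizes

Every stochastic step takes a seed; a pipeline run is a pure function of
(manifest, config, seed), and cohort generation with a fixed config is
byte-identical across runs.  The test suite exercises the full-scale
conditions where a single subject suffices (e.g. classifier recovery at
depth 10⁵) and uses reduced cohorts (600 clonotypes per compartment, depth
1.5·10⁴, 10 downsampling replicates) for the repeated-cohort experiments —
type-I calibration over 100 null cohorts and power over 50 seeded cohorts —
keeping the planted effect sizes identical to the full-scale defaults.

## Known limitations

* TCRβ only; no α chain pairing.
* The fold-change rule has no uncertainty model; its precision degrades for
  clones near the detection limit (see operating characteristics above).
* Betweenness on very large, dense networks is O(n·m) and is the slow path;
  the pipeline computes it only where node centrality is reported.
* Greedy modularity maximization is deterministic but not optimal; absolute
  modularity values depend on the community algorithm (Louvain with a fixed
  seed is available as an alternative through networkx).
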