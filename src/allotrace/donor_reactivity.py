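"""Definition and tracking of the donor-reactive TCR repertoire.

Donor reactivity is defined functionally: recipient T-cells proliferating in
a mixed lymphocyte reaction (MLR) against irradiated donor cells.  A
clonotype is classified donor-reactive when its frequency in the
MLR-stimulated sample is at least ``fc_threshold`` (default 5) times its
frequency in the unstimulated pre-transplant sample.  Clones undetected in
the unstimulated sample receive the pseudo-frequency 1/total_reads (the
limit of detection), which makes the fold-change rule well-defined for
de-novo detected clones.

Abundance of the donor-reactive set in any other sample (blood or graft) is
then quantified on downsampled replicates at a common depth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import _check_depth, _downsample_counts, replicate_seed
from .types import (
    ClonotypeKey,
    Compartment,
    Condition,
    RepertoireSample,
    SampleMeta,
    Timepoint,
)


@dataclass
class DonorReactiveSet:
    """Clonotype keys classified donor-reactive, with their fold changes."""

    subject_id: str
    compartment: Compartment
    entries: dict[ClonotypeKey, float] = field(default_factory=dict)
    fc_threshold: float = 5.0
    pseudo_frequency: float = float("nan")  # floor used for undetected clones

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, key: ClonotypeKey) -> bool:
        return key in self.entries

    @classmethod
    def union(cls, sets: Sequence["DonorReactiveSet"]) -> "DonorReactiveSet":
        """Pool compartment-specific sets, e.g. CD4 ∪ CD8 for bulk tissue queries."""
        if not sets:
            raise ValueError("no donor-reactive sets to pool")
        entries: dict[ClonotypeKey, float] = {}
        for s in sets:
            for key, fc in s.entries.items():
                entries[key] = max(fc, entries.get(key, 0.0))
        return cls(
            subject_id=sets[0].subject_id,
            compartment=Compartment.BULK,
            entries=entries,
            fc_threshold=min(s.fc_threshold for s in sets),
            pseudo_frequency=float("nan"),
        )

    def to_frame(self) -> pd.DataFrame:
        keys = sorted(self.entries)
        return pd.DataFrame(
            {
                "cdr3_nt": [k.cdr3_nt for k in keys],
                "v_gene": [k.v_gene for k in keys],
                "j_gene": [k.j_gene for k in keys],
                "fold_change": [self.entries[k] for k in keys],
            }
        )


@dataclass
class DonorReactiveAbundance:
    """Downsampling-normalized abundance of a donor-reactive set in one sample."""

    sample_ref: SampleMeta
    depth: int
    n_reps: int
    n_dr_clonotypes: float  # mean over replicates
    pct_dr_clonotypes: float  # % of unique clonotypes per replicate
    cum_dr_frequency: float  # % of all cells per replicate
    sd_n_dr_clonotypes: float = 0.0
    sd_pct_dr_clonotypes: float = 0.0
    sd_cum_dr_frequency: float = 0.0


def classify_donor_reactive(
    stimulated: RepertoireSample,
    unstimulated_pre: RepertoireSample,
    fc_threshold: float = 5.0,
    min_stim_count: int = 1,
    pseudo_frequency: float | None = None,
) -> DonorReactiveSet:
    """Classify donor-reactive clonotypes from a paired MLR / unstimulated sample.

    For each clone of the stimulated sample, fold change =
    freq_stim / max(freq_unstim, floor) with floor = 1/total_reads of the
    unstimulated sample (overridable via ``pseudo_frequency``).  Clones with
    fold change ≥ ``fc_threshold`` and stimulated count ≥ ``min_stim_count``
    are returned; fold changes use normalized frequencies so unequal depths
    do not bias classification.
    """
    if stimulated.meta.compartment is not unstimulated_pre.meta.compartment:
        raise ValueError(
            "compartment mismatch between stimulated "
            f"({stimulated.meta.compartment.value}) and unstimulated "
            f"({unstimulated_pre.meta.compartment.value}) samples"
        )
    if stimulated.meta.subject_id != unstimulated_pre.meta.subject_id:
        raise ValueError("stimulated and unstimulated samples are from different subjects")
    if stimulated.meta.condition is not Condition.MLR_STIMULATED:
        raise ValueError("stimulated sample is not MLR_STIMULATED")
    if unstimulated_pre.meta.timepoint is not Timepoint.PRE_TX:
        raise ValueError("unstimulated reference sample is not PRE_TX")
    if not stimulated.clonotypes:
        raise ValueError("stimulated sample is empty")

    floor = (
        1.0 / unstimulated_pre.total_reads
        if pseudo_frequency is None
        else pseudo_frequency
    )
    unstim_freq = unstimulated_pre.freq_by_key()
    entries: dict[ClonotypeKey, float] = {}
    for clone in stimulated.clonotypes:
        if clone.count < min_stim_count:
            continue
        fc = clone.frequency / max(unstim_freq.get(clone.key, 0.0), floor)
        if fc >= fc_threshold:
            entries[clone.key] = fc
    return DonorReactiveSet(
        subject_id=stimulated.meta.subject_id,
        compartment=stimulated.meta.compartment,
        entries=entries,
        fc_threshold=fc_threshold,
        pseudo_frequency=floor,
    )


def donor_reactive_abundance(
    sample: RepertoireSample,
    dr: DonorReactiveSet | Iterable[ClonotypeKey],
    depth: int,
    n_reps: int = 1000,
    seed: int = 0,
) -> DonorReactiveAbundance:
    """Downsampled abundance of the donor-reactive set in ``sample``.

    Per replicate the detected donor-reactive clonotype count, its percentage
    of the replicate's unique clonotypes, and the summed donor-reactive
    frequency (%) are computed; means and SDs over replicates are reported.
    """
    _check_depth(depth, sample.total_reads)
    dr_keys = set(dr.entries) if isinstance(dr, DonorReactiveSet) else set(dr)
    mask = np.array([c.key in dr_keys for c in sample.clonotypes], dtype=bool)
    counts = sample.counts
    stats = np.empty((n_reps, 3), dtype=float)
    for i in range(n_reps):
        rng = np.random.default_rng(replicate_seed(seed, i))
        rep = _downsample_counts(counts, depth, rng)
        detected = rep > 0
        n_unique = int(detected.sum())
        n_dr = int((detected & mask).sum())
        stats[i, 0] = n_dr
        stats[i, 1] = 100.0 * n_dr / n_unique if n_unique else 0.0
        stats[i, 2] = 100.0 * rep[mask].sum() / depth
    mean = stats.mean(axis=0)
    sd = stats.std(axis=0, ddof=0)
    return DonorReactiveAbundance(
        sample_ref=sample.meta,
        depth=depth,
        n_reps=n_reps,
        n_dr_clonotypes=float(mean[0]),
        pct_dr_clonotypes=float(mean[1]),
        cum_dr_frequency=float(mean[2]),
        sd_n_dr_clonotypes=float(sd[0]),
        sd_pct_dr_clonotypes=float(sd[1]),
        sd_cum_dr_frequency=float(sd[2]),
    )


def abundance_table(
    samples: Sequence[RepertoireSample],
    dr_sets: Mapping[tuple[str, Compartment], DonorReactiveSet],
    n_reps: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Long-format donor-reactive abundance across a cohort.

    One row per subject × timepoint × compartment.  Unstimulated blood samples
    are queried against their compartment's donor-reactive set; bulk tissue
    samples against the union of the subject's CD4 and CD8 sets.  The common
    downsampling depth per subject × compartment is the minimum total reads
    among that subject's compared samples (tissue included for tissue rows).
    """
    rows = []
    by_subject: dict[str, list[RepertoireSample]] = {}
    for s in samples:
        if s.meta.condition is Condition.UNSTIMULATED:
            by_subject.setdefault(s.meta.subject_id, []).append(s)

    for subject_id in sorted(by_subject):
        subj_samples = by_subject[subject_id]
        timepoints = {s.meta.timepoint for s in subj_samples}
        if Timepoint.PRE_TX not in timepoints:
            warnings.warn(
                f"subject {subject_id} lacks a PRE_TX sample; skipped", stacklevel=2
            )
            continue
        blood_min = min(
            s.total_reads for s in subj_samples if s.meta.timepoint is not Timepoint.TISSUE
        )
        for sample in sorted(subj_samples, key=lambda s: s.meta.label):
            comp = sample.meta.compartment
            if comp is Compartment.BULK:
                subject_sets = [
                    dr_sets[(subject_id, c)]
                    for c in (Compartment.CD4, Compartment.CD8)
                    if (subject_id, c) in dr_sets
                ]
                if not subject_sets:
                    continue
                dr = DonorReactiveSet.union(subject_sets)
                depth = min(blood_min, sample.total_reads)
            else:
                if (subject_id, comp) not in dr_sets:
                    continue
                dr = dr_sets[(subject_id, comp)]
                depth = min(
                    s.total_reads
                    for s in subj_samples
                    if s.meta.compartment is comp
                    and s.meta.timepoint is not Timepoint.TISSUE
                )
            ab = donor_reactive_abundance(sample, dr, depth, n_reps=n_reps, seed=seed)
            rows.append(
                {
                    "subject_id": subject_id,
                    "timepoint": sample.meta.timepoint.value,
                    "compartment": comp.value,
                    "rejection_group": sample.meta.rejection_group.value,
                    "depth": depth,
                    "n_dr_clonotypes": ab.n_dr_clonotypes,
                    "pct_dr_clonotypes": ab.pct_dr_clonotypes,
                    "cum_dr_frequency": ab.cum_dr_frequency,
                    "sd_n_dr_clonotypes": ab.sd_n_dr_clonotypes,
                    "sd_pct_dr_clonotypes": ab.sd_pct_dr_clonotypes,
                    "sd_cum_dr_frequency": ab.sd_cum_dr_frequency,
                }
            )
    return pd.DataFrame(rows)
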