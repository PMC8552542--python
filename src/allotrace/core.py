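"""Core repertoire operations: productive filtering, CD4/CD8 disambiguation,
and depth normalization by random downsampling.

Downsampling removes sequencing-depth bias before repertoire statistics are
compared: reads are subsampled *without replacement* to a common depth
(multivariate hypergeometric draw over the clonotype counts), and statistics
are averaged over many independent replicates.
"""

from __future__ import annotations

import copy
from typing import Callable, Iterable, Sequence

import numpy as np

from .types import (
    Clonotype,
    ClonotypeKey,
    Compartment,
    Phenotype,
    PhenotypeAssignment,
    RepertoireSample,
    SampleMeta,
)


def filter_productive(sample: RepertoireSample) -> RepertoireSample:
    """Remove non-productive clonotypes (CDR3 aa containing '*' or '_').

    Frequencies are renormalized over the surviving clones.  Raises if no
    productive clone remains.
    """
    kept = [copy.copy(c) for c in sample.clonotypes if c.productive]
    if not kept:
        raise ValueError(
            f"all {sample.n_clonotypes} clonotypes of {sample.meta.label} are non-productive"
        )
    return RepertoireSample.from_counts(sample.meta, kept)


def _max_freq_by_key(samples: Iterable[RepertoireSample]) -> dict[ClonotypeKey, float]:
    out: dict[ClonotypeKey, float] = {}
    for sample in samples:
        for clone in sample.clonotypes:
            key = clone.key
            if clone.frequency > out.get(key, 0.0):
                out[key] = clone.frequency
    return out


def assign_phenotypes(
    cd4_samples: Sequence[RepertoireSample],
    cd8_samples: Sequence[RepertoireSample],
    ratio: float = 2.0,
) -> list[PhenotypeAssignment]:
    """Resolve the phenotype of every clonotype key seen in the sorted subsets.

    Keys found in both the CD4- and CD8-sorted samples are assigned to the
    subset in which their maximum frequency across timepoints is at least
    ``ratio`` times (default: doubles) the other; otherwise they are DROPPED.
    Keys seen in only one subset keep that subset unconditionally.
    """
    cd4_max = _max_freq_by_key(cd4_samples)
    cd8_max = _max_freq_by_key(cd8_samples)
    assignments: list[PhenotypeAssignment] = []
    for key in sorted(set(cd4_max) | set(cd8_max)):
        f4 = cd4_max.get(key, 0.0)
        f8 = cd8_max.get(key, 0.0)
        if key not in cd8_max:
            assigned = Phenotype.CD4
        elif key not in cd4_max:
            assigned = Phenotype.CD8
        elif f4 >= ratio * f8:
            assigned = Phenotype.CD4
        elif f8 >= ratio * f4:
            assigned = Phenotype.CD8
        else:
            assigned = Phenotype.DROPPED
        assignments.append(
            PhenotypeAssignment(key=key, assigned=assigned, max_freq_cd4=f4, max_freq_cd8=f8)
        )
    return assignments


def _check_depth(depth: int, total_reads: int) -> None:
    if depth <= 0:
        raise ValueError(f"downsampling depth must be positive, got {depth}")
    if depth > total_reads:
        raise ValueError(
            f"downsampling depth {depth} exceeds sample total reads {total_reads}"
        )


def _downsample_counts(
    counts: np.ndarray, depth: int, rng: np.random.Generator, replace: bool = False
) -> np.ndarray:
    if replace:
        return rng.multinomial(depth, counts / counts.sum())
    return rng.multivariate_hypergeometric(counts, depth)


def downsample(
    sample: RepertoireSample,
    depth: int,
    seed: int,
    replace: bool = False,
) -> RepertoireSample:
    """Draw ``depth`` reads without replacement from the sample's counts.

    Clonotypes drawn zero times are removed and frequencies renormalized.
    The draw is reproducible given ``seed``.  ``replace=True`` switches to a
    with-replacement (multinomial) draw.
    """
    _check_depth(depth, sample.total_reads)
    rng = np.random.default_rng(seed)
    new_counts = _downsample_counts(sample.counts, depth, rng, replace=replace)
    clones = []
    for clone, n in zip(sample.clonotypes, new_counts):
        if n > 0:
            c = copy.copy(clone)
            c.count = int(n)
            clones.append(c)
    return RepertoireSample.from_counts(sample.meta, clones)


def replicate_seed(seed: int, replicate: int) -> int:
    """Deterministic per-replicate seed; replicate 0 reuses the root seed."""
    return seed + replicate


def downsampled_mean_statistic(
    sample: RepertoireSample,
    depth: int,
    statistic: Callable[[RepertoireSample], float],
    n_reps: int = 1000,
    seed: int = 0,
    replace: bool = False,
) -> tuple[float, float]:
    """Mean and SD of ``statistic`` over ``n_reps`` downsampled replicates."""
    _check_depth(depth, sample.total_reads)
    values = np.empty(n_reps, dtype=float)
    for i in range(n_reps):
        rep = downsample(sample, depth, seed=replicate_seed(seed, i), replace=replace)
        values[i] = statistic(rep)
    return float(values.mean()), float(values.std(ddof=0))


def merge_samples(
    samples: Sequence[RepertoireSample],
    meta: SampleMeta | None = None,
) -> RepertoireSample:
    """Pool several samples (e.g. sorted CD4 + CD8) into one bulk repertoire.

    Counts of shared keys are summed; frequencies recomputed.  ``meta``
    defaults to the first sample's metadata with compartment BULK.
    """
    if not samples:
        raise ValueError("no samples to merge")
    if meta is None:
        meta = samples[0].meta.replace(compartment=Compartment.BULK)
    pooled: dict[ClonotypeKey, Clonotype] = {}
    for sample in samples:
        for clone in sample.clonotypes:
            key = clone.key
            if key in pooled:
                pooled[key].count += clone.count
            else:
                pooled[key] = copy.copy(clone)
    return RepertoireSample.from_counts(meta, pooled.values())
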