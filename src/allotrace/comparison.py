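"""Pairwise repertoire similarity.

The Jensen–Shannon divergence (JSD) in log base 2 is bounded by [0, 1]:
0 for identical clone distributions, 1 for fully disjoint ones.  Repertoire
pairs are compared on their top-N most frequent clonotypes (default 1,000)
over the union key space; V–J usage is compared the same way over (V, J)
gene combinations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Mapping, Sequence

import numpy as np
import pandas as pd

from .donor_reactivity import DonorReactiveSet
from .types import Clonotype, ClonotypeKey, RepertoireSample, SampleMeta, VJUsage

FREQ_TOL = 1e-9


@dataclass
class OverlapReport:
    """Similarity summary of one sample pair."""

    pair: tuple[SampleMeta, SampleMeta]
    shared_clonotypes: int
    jsd_clones: float
    jsd_vj: float = float("nan")
    top_clone_table: pd.DataFrame | None = None


@dataclass
class TissueTracking:
    """Blood↔graft comparison for one subject: top graft clones traced to blood."""

    subject_id: str
    top_clones: pd.DataFrame
    jsd: dict[str, float] = field(default_factory=dict)  # pre_tissue, post_tissue, pre_post


def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def jsd(
    p: Mapping[Hashable, float] | np.ndarray,
    q: Mapping[Hashable, float] | np.ndarray,
) -> float:
    """Jensen–Shannon divergence in bits: H₂(m) − (H₂(p)+H₂(q))/2, m=(p+q)/2.

    ``p`` and ``q`` may be mappings (aligned over the union of their keys,
    missing keys = 0) or equal-length arrays.  Each must sum to 1 ± 1e-9.
    """
    if isinstance(p, Mapping) or isinstance(q, Mapping):
        keys = sorted(set(p) | set(q), key=repr)
        pv = np.array([p.get(k, 0.0) for k in keys], dtype=float)
        qv = np.array([q.get(k, 0.0) for k in keys], dtype=float)
    else:
        pv = np.asarray(p, dtype=float)
        qv = np.asarray(q, dtype=float)
        if pv.shape != qv.shape:
            raise ValueError("array distributions must share a common support")
    for name, v in (("p", pv), ("q", qv)):
        if (v < 0).any():
            raise ValueError(f"distribution {name} has negative entries")
        if abs(v.sum() - 1.0) > FREQ_TOL:
            raise ValueError(f"distribution {name} sums to {v.sum():.12f}, expected 1")
    m = 0.5 * (pv + qv)
    value = _entropy_bits(m) - 0.5 * (_entropy_bits(pv) + _entropy_bits(qv))
    return float(min(1.0, max(0.0, value)))


def _top_clones(
    sample: RepertoireSample, top_n: int, level: str
) -> dict[Hashable, float]:
    clones: Sequence[Clonotype] = sorted(
        sample.clonotypes, key=lambda c: (-c.frequency, c.key)
    )[:top_n]
    out: dict[Hashable, float] = {}
    for c in clones:
        key: Hashable = c.cdr3_aa if level == "aa" else c.key
        out[key] = out.get(key, 0.0) + c.frequency
    total = sum(out.values())
    return {k: v / total for k, v in out.items()}


def clone_jsd(
    a: RepertoireSample,
    b: RepertoireSample,
    top_n: int = 1000,
    level: str = "nt",
) -> float:
    """JSD of the two samples' top-``top_n`` clone distributions.

    Truncation happens per repertoire before forming union-support
    distributions; samples smaller than ``top_n`` use all their clones.
    ``level`` selects nucleotide-level keys (default) or amino-acid sequences.
    """
    return jsd(_top_clones(a, top_n, level), _top_clones(b, top_n, level))


def vj_usage(sample: RepertoireSample) -> VJUsage:
    """Aggregate clone frequencies by (V gene, J gene) combination."""
    matrix: dict[tuple[str, str], float] = {}
    for c in sample.clonotypes:
        pair = (c.v_gene, c.j_gene)
        matrix[pair] = matrix.get(pair, 0.0) + c.frequency
    usage = VJUsage(sample_ref=sample.meta, matrix=matrix)
    usage.validate()
    return usage


def vj_jsd(a: RepertoireSample | VJUsage, b: RepertoireSample | VJUsage) -> float:
    """JSD of V–J usage distributions over the union of (V, J) combinations."""
    ua = a if isinstance(a, VJUsage) else vj_usage(a)
    ub = b if isinstance(b, VJUsage) else vj_usage(b)
    return jsd(ua.matrix, ub.matrix)


def overlap_report(
    a: RepertoireSample,
    b: RepertoireSample,
    top_n: int = 1000,
    level: str = "nt",
) -> OverlapReport:
    shared = len(set(a.keys) & set(b.keys))
    return OverlapReport(
        pair=(a.meta, b.meta),
        shared_clonotypes=shared,
        jsd_clones=clone_jsd(a, b, top_n=top_n, level=level),
        jsd_vj=vj_jsd(a, b),
    )


def tissue_tracking_table(
    tissue: RepertoireSample,
    blood_pre: RepertoireSample,
    blood_post: RepertoireSample,
    dr: DonorReactiveSet | None = None,
    top_n: int = 20,
    top_n_jsd: int = 1000,
) -> TissueTracking:
    """Trace the top graft-infiltrating clones back to the circulation.

    Returns the ``top_n`` tissue clones ranked by tissue frequency with their
    frequencies in the pre- and post-transplant blood (0 if absent) and their
    donor-reactive flag, plus clone JSDs of the three sample pairs.
    """
    pre_freq = blood_pre.freq_by_key()
    post_freq = blood_post.freq_by_key()
    dr_keys: set[ClonotypeKey] = set(dr.entries) if dr is not None else set()
    ranked = sorted(tissue.clonotypes, key=lambda c: (-c.frequency, c.key))[:top_n]
    table = pd.DataFrame(
        {
            "rank": np.arange(1, len(ranked) + 1),
            "cdr3_nt": [c.cdr3_nt for c in ranked],
            "cdr3_aa": [c.cdr3_aa for c in ranked],
            "v_gene": [c.v_gene for c in ranked],
            "j_gene": [c.j_gene for c in ranked],
            "tissue_freq": [c.frequency for c in ranked],
            "pre_freq": [pre_freq.get(c.key, 0.0) for c in ranked],
            "post_freq": [post_freq.get(c.key, 0.0) for c in ranked],
            "donor_reactive": [c.key in dr_keys for c in ranked],
        }
    )
    jsds = {
        "pre_tissue": clone_jsd(blood_pre, tissue, top_n=top_n_jsd),
        "post_tissue": clone_jsd(blood_post, tissue, top_n=top_n_jsd),
        "pre_post": clone_jsd(blood_pre, blood_post, top_n=top_n_jsd),
    }
    return TissueTracking(subject_id=tissue.meta.subject_id, top_clones=table, jsd=jsds)
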