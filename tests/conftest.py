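"""Shared fixtures and toy-sample builders."""

from __future__ import annotations

import itertools

import pytest

from allotrace.types import (
    Clonotype,
    Compartment,
    Condition,
    RepertoireSample,
    SampleMeta,
    Timepoint,
)

# enough distinct codons to give every toy clone a unique nucleotide key
_NT_COUNTER = itertools.count()


def make_meta(
    subject: str = "S1",
    timepoint: Timepoint = Timepoint.PRE_TX,
    compartment: Compartment = Compartment.CD4,
    condition: Condition = Condition.UNSTIMULATED,
    **kwargs,
) -> SampleMeta:
    return SampleMeta(
        subject_id=subject,
        timepoint=timepoint,
        compartment=compartment,
        condition=condition,
        **kwargs,
    )


def make_sample(
    counts,
    meta: SampleMeta | None = None,
    aa_seqs=None,
    nt_seqs=None,
    v_genes=None,
    j_genes=None,
) -> RepertoireSample:
    """Toy repertoire from a count vector; sequences default to unique stand-ins."""
    meta = meta or make_meta()
    n = len(counts)
    letters = "ACDEFGHIKL"
    aa_seqs = aa_seqs or [
        "CASS" + "".join(letters[int(d)] for d in f"{i:04d}") + "QYF" for i in range(n)
    ]
    nt_seqs = nt_seqs or [
        "TGT" + "".join("ACGT"[(i >> (2 * k)) & 3] for k in range(9)) for i in range(n)
    ]
    v_genes = v_genes or ["TRBV1"] * n
    j_genes = j_genes or ["TRBJ1"] * n
    clones = [
        Clonotype(
            cdr3_nt=nt_seqs[i],
            cdr3_aa=aa_seqs[i],
            v_gene=v_genes[i],
            j_gene=j_genes[i],
            count=int(counts[i]),
            frequency=0.0,
        )
        for i in range(n)
    ]
    return RepertoireSample.from_counts(meta, clones)


@pytest.fixture
def two_clone_sample() -> RepertoireSample:
    return make_sample([9000, 1000])


@pytest.fixture
def uniform_sample() -> RepertoireSample:
    return make_sample([10] * 10)
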