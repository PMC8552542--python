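"""Domain types for TCRβ clonotype repertoires.

A *clonotype* is a unique rearranged TCRβ chain, identified here by its CDR3
nucleotide sequence together with the V and J gene labels (the nucleotide
sequence alone can be produced by convergent rearrangements using different
gene segments).  A *repertoire sample* is one sequenced library: all
clonotypes observed in a sorted T-cell compartment of one subject at one
timepoint, under one culture condition.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple

import numpy as np

FREQ_TOL = 1e-9

# CDR3 amino-acid markers for out-of-frame / truncated junctions
STOP_MARKER = "*"
FRAMESHIFT_MARKER = "_"


class Timepoint(str, enum.Enum):
    PRE_TX = "PRE_TX"
    POST_TX = "POST_TX"
    TISSUE = "TISSUE"


class Compartment(str, enum.Enum):
    CD4 = "CD4"
    CD8 = "CD8"
    BULK = "BULK"


class Condition(str, enum.Enum):
    UNSTIMULATED = "UNSTIMULATED"
    MLR_STIMULATED = "MLR_STIMULATED"


class RejectionGroup(str, enum.Enum):
    REJECTOR = "REJECTOR"
    CONTROL = "CONTROL"
    UNKNOWN = "UNKNOWN"


class Phenotype(str, enum.Enum):
    """Resolved T-cell phenotype of a clonotype observed in both sorted subsets."""

    CD4 = "CD4"
    CD8 = "CD8"
    DROPPED = "DROPPED"


class ClonotypeKey(NamedTuple):
    """Identity of a clonotype within and across samples of one subject."""

    cdr3_nt: str
    v_gene: str
    j_gene: str


@dataclass(slots=True)
class Clonotype:
    """One TCRβ clone: junction sequences, gene segments, abundance."""

    cdr3_nt: str
    cdr3_aa: str
    v_gene: str
    j_gene: str
    count: int
    frequency: float
    d_gene: str = ""

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError(f"negative clonotype count: {self.count}")
        if self.frequency < 0:
            raise ValueError(f"negative clonotype frequency: {self.frequency}")

    @property
    def key(self) -> ClonotypeKey:
        return ClonotypeKey(self.cdr3_nt, self.v_gene, self.j_gene)

    @property
    def productive(self) -> bool:
        return (
            STOP_MARKER not in self.cdr3_aa and FRAMESHIFT_MARKER not in self.cdr3_aa
        )


@dataclass(frozen=True)
class SampleMeta:
    subject_id: str
    timepoint: Timepoint
    compartment: Compartment
    condition: Condition = Condition.UNSTIMULATED
    rejection_group: RejectionGroup = RejectionGroup.UNKNOWN
    day_post_tx: int | None = None

    def __post_init__(self) -> None:
        # graft biopsies cannot be FACS-sorted; only bulk tissue repertoires exist
        if (
            self.timepoint is Timepoint.TISSUE
            and self.compartment is not Compartment.BULK
        ):
            raise ValueError("TISSUE samples must have compartment BULK")

    @property
    def label(self) -> str:
        parts = [
            self.subject_id,
            self.timepoint.value,
            self.compartment.value,
            self.condition.value,
        ]
        return "_".join(parts)

    def replace(self, **kwargs) -> "SampleMeta":
        return replace(self, **kwargs)


@dataclass
class RepertoireSample:
    """A sequenced repertoire: metadata plus clonotypes with normalized frequencies.

    Frequencies are always recomputed from counts (``from_counts``); any stated
    frequency column in an input file is advisory only.
    """

    meta: SampleMeta
    clonotypes: list[Clonotype]
    total_reads: int

    @classmethod
    def from_counts(
        cls, meta: SampleMeta, clonotypes: Iterable[Clonotype]
    ) -> "RepertoireSample":
        """Build a sample, dropping zero-count clones and renormalizing."""
        clones = [c for c in clonotypes if c.count > 0]
        if not clones:
            raise ValueError(f"empty repertoire for sample {meta.label}")
        total = sum(c.count for c in clones)
        for c in clones:
            c.frequency = c.count / total
        sample = cls(meta=meta, clonotypes=clones, total_reads=total)
        sample.validate()
        return sample

    def validate(self) -> None:
        if not self.clonotypes:
            raise ValueError("sample has no clonotypes")
        if self.total_reads != sum(c.count for c in self.clonotypes):
            raise ValueError("total_reads does not equal the sum of counts")
        keys = [c.key for c in self.clonotypes]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate clonotype keys within sample")
        if abs(sum(c.frequency for c in self.clonotypes) - 1.0) > FREQ_TOL:
            raise ValueError("frequencies do not sum to 1")

    @property
    def n_clonotypes(self) -> int:
        return len(self.clonotypes)

    @property
    def counts(self) -> np.ndarray:
        return np.array([c.count for c in self.clonotypes], dtype=np.int64)

    @property
    def frequencies(self) -> np.ndarray:
        return np.array([c.frequency for c in self.clonotypes], dtype=float)

    @property
    def keys(self) -> list[ClonotypeKey]:
        return [c.key for c in self.clonotypes]

    def freq_by_key(self) -> dict[ClonotypeKey, float]:
        return {c.key: c.frequency for c in self.clonotypes}

    def count_by_key(self) -> dict[ClonotypeKey, int]:
        return {c.key: c.count for c in self.clonotypes}


@dataclass(slots=True)
class PhenotypeAssignment:
    """Outcome of the CD4/CD8 doubling rule for one clonotype key."""

    key: ClonotypeKey
    assigned: Phenotype
    max_freq_cd4: float
    max_freq_cd8: float


@dataclass
class DiversityReport:
    """Diversity statistics of one repertoire sample.

    ``shannon_H`` is in nats; ``clonality`` = 1 − H_obs/H_max with
    H_max = ln(number of unique clonotypes).  ``powerlaw_slope`` is the signed
    log–log OLS slope of the bulk clone-size spectrum (NaN when the spectrum
    is degenerate).
    """

    sample_ref: SampleMeta
    n_clonotypes: int
    shannon_H: float
    clonality: float
    r20: float
    powerlaw_slope: float = float("nan")
    powerlaw_r2: float = float("nan")
    cutoff_frequency: float = float("nan")

    @property
    def powerlaw_abs_slope(self) -> float:
        return abs(self.powerlaw_slope)


@dataclass
class VJUsage:
    """Aggregate clone frequency per (V gene, J gene) combination."""

    sample_ref: SampleMeta
    matrix: dict[tuple[str, str], float] = field(default_factory=dict)

    def validate(self) -> None:
        if abs(sum(self.matrix.values()) - 1.0) > FREQ_TOL:
            raise ValueError("V–J usage entries do not sum to 1")
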