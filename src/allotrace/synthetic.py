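"""Synthetic transplant-cohort generator with a known truth table.

Emulates the statistical structure the downstream analysis assumes, so every
analysis stage can be validated against planted ground truth:

* power-law clone-size distributions (Zipf weights, exponent ``powerlaw_alpha``);
* a small donor-reactive subset (``dr_fraction`` of clonotypes) drawn as
  *clone families* — groups of CDR3s at inner-segment Levenshtein distance 1
  sharing a V gene — which gives donor-reactive similarity networks their
  high-modularity cluster structure;
* MLR stimulation enriching donor-reactive clones ``mlr_enrichment``-fold;
* post-transplant expansion of donor-reactive clones (``posttx_dr_gain``),
  part of them (``novel_dr_fraction``) below the detection limit 1/depth in
  the unstimulated pre-transplant sample;
* for rejectors, a bulk graft-tissue repertoire enriched in donor-reactive
  clones (cumulative frequency ``tissue_dr_cum_freq``) with a partially
  distinct background, elevating blood↔tissue divergence.

Reads are emitted by multinomial draws at the configured depths (sequencing
from an effectively infinite cell pool); depth normalization within the
analysis pipeline remains hypergeometric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import write_clonotype_table
from .types import (
    Clonotype,
    ClonotypeKey,
    Compartment,
    Condition,
    RejectionGroup,
    RepertoireSample,
    SampleMeta,
    Timepoint,
)

AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: standard genetic code, amino acid -> codons (stop codons unused)
CODONS: dict[str, tuple[str, ...]] = {
    "A": ("GCT", "GCC", "GCA", "GCG"),
    "C": ("TGT", "TGC"),
    "D": ("GAT", "GAC"),
    "E": ("GAA", "GAG"),
    "F": ("TTT", "TTC"),
    "G": ("GGT", "GGC", "GGA", "GGG"),
    "H": ("CAT", "CAC"),
    "I": ("ATT", "ATC", "ATA"),
    "K": ("AAA", "AAG"),
    "L": ("TTA", "TTG", "CTT", "CTC", "CTA", "CTG"),
    "M": ("ATG",),
    "N": ("AAT", "AAC"),
    "P": ("CCT", "CCC", "CCA", "CCG"),
    "Q": ("CAA", "CAG"),
    "R": ("CGT", "CGC", "CGA", "CGG", "AGA", "AGG"),
    "S": ("TCT", "TCC", "TCA", "TCG", "AGT", "AGC"),
    "T": ("ACT", "ACC", "ACA", "ACG"),
    "V": ("GTT", "GTC", "GTA", "GTG"),
    "W": ("TGG",),
    "Y": ("TAT", "TAC"),
}


@dataclass
class CohortConfig:
    """Study conditions of the synthetic cohort.

    Defaults mirror the analyzed study design: 12 subjects (6 rejectors /
    6 controls), a 1% donor-reactive clonotype fraction, 20-fold MLR
    enrichment, a 2.4-fold post-transplant gain of donor-reactive abundance,
    and a graft infiltrate holding 3.5% cumulative donor-reactive frequency.
    """

    n_subjects: int = 12
    n_rejectors: int | None = None  # default: half the cohort
    clonotypes_per_compartment: int = 5000
    powerlaw_alpha: float = 2.5
    dr_fraction: float = 0.01
    mlr_enrichment: float = 20.0
    posttx_dr_gain: float = 2.4
    novel_dr_fraction: float = 0.25
    tissue_dr_cum_freq: float = 0.035
    tissue_clonotypes: int = 3000
    tissue_shared_background: float = 0.4  # fraction of tissue background shared with blood
    depth_blood: int = 100_000
    depth_tissue: int = 20_000
    depth_jitter: float = 0.25  # relative spread of per-sample sequencing depth
    cdr3_length_mean: float = 14.5
    cdr3_length_sd: float = 1.5
    family_size: int = 3
    n_v_genes: int = 30
    n_j_genes: int = 13
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rejectors is None:
            self.n_rejectors = self.n_subjects // 2
        for name in ("dr_fraction", "novel_dr_fraction", "tissue_dr_cum_freq"):
            value = getattr(self, name)
            if not 0 <= value < 1:
                raise ValueError(f"{name} must lie in [0, 1), got {value}")
        if self.mlr_enrichment < 1:
            raise ValueError("mlr_enrichment must be >= 1")
        if self.n_rejectors > self.n_subjects:
            raise ValueError("n_rejectors exceeds n_subjects")
        n_dr = round(self.dr_fraction * self.clonotypes_per_compartment)
        if n_dr >= self.clonotypes_per_compartment:
            raise ValueError("dr_fraction leaves no background clonotypes")
        if self.tissue_clonotypes <= 2 * n_dr:
            raise ValueError(
                "tissue_clonotypes must exceed the pooled donor-reactive clone count"
            )
        if self.cdr3_length_mean < 8:
            raise ValueError("cdr3_length_mean must be at least 8 aa")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        import yaml

        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


@dataclass
class SubjectTruth:
    """Ground truth for one subject: donor-reactive keys and true frequencies."""

    subject_id: str
    dr_keys: dict[Compartment, set[ClonotypeKey]] = field(default_factory=dict)
    true_frequencies: dict[str, dict[ClonotypeKey, float]] = field(default_factory=dict)

    def dr_union(self) -> set[ClonotypeKey]:
        out: set[ClonotypeKey] = set()
        for keys in self.dr_keys.values():
            out |= keys
        return out


@dataclass
class SyntheticSubject:
    subject_id: str
    rejector: bool
    samples: list[RepertoireSample]
    truth: SubjectTruth


@dataclass
class SyntheticCohort:
    config: CohortConfig
    subjects: dict[str, SyntheticSubject]

    def all_samples(self) -> list[RepertoireSample]:
        return [s for subj in self.subjects.values() for s in subj.samples]

    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for subj in self.subjects.values():
            for comp, keys in subj.truth.dr_keys.items():
                for key in sorted(keys):
                    rows.append(
                        {
                            "subject_id": subj.subject_id,
                            "compartment": comp.value,
                            "cdr3_nt": key.cdr3_nt,
                            "v_gene": key.v_gene,
                            "j_gene": key.j_gene,
                        }
                    )
        return pd.DataFrame(rows)


def generate_cdr3(
    rng: np.random.Generator,
    length_mean: float = 14.5,
    length_sd: float = 1.5,
    family_seed: str | None = None,
    trim: int = 3,
) -> tuple[str, str]:
    """One CDR3 (nucleotide, amino-acid) pair.

    Sequences start with 'C' and end with 'F'.  With ``family_seed`` given, a
    variant at inner-segment Levenshtein distance exactly 1 (one inner
    substitution) is returned.  The nucleotide sequence is a consistent
    reverse-translation with codons drawn at random.
    """
    if family_seed is not None:
        aa_list = list(family_seed)
        pos = int(rng.integers(trim, len(aa_list) - trim))
        old = aa_list[pos]
        choices = [a for a in AA20 if a != old]
        aa_list[pos] = choices[int(rng.integers(0, len(choices)))]
        aa = "".join(aa_list)
    else:
        length = max(8, int(round(rng.normal(length_mean, length_sd))))
        inner_idx = rng.integers(0, len(AA20), size=length - 2)
        aa = "C" + "".join(AA20[i] for i in inner_idx) + "F"
    codon_draw = rng.integers(0, 1 << 30, size=len(aa))
    nt = "".join(CODONS[a][int(r) % len(CODONS[a])] for a, r in zip(aa, codon_draw))
    return nt, aa


def _translate(nt: str) -> str:
    inverse = {codon: aa for aa, codons in CODONS.items() for codon in codons}
    return "".join(inverse[nt[i : i + 3]] for i in range(0, len(nt), 3))


@dataclass(slots=True)
class _CloneTemplate:
    cdr3_nt: str
    cdr3_aa: str
    v_gene: str
    j_gene: str

    @property
    def key(self) -> ClonotypeKey:
        return ClonotypeKey(self.cdr3_nt, self.v_gene, self.j_gene)


def _emit_sample(
    meta: SampleMeta,
    templates: list[_CloneTemplate],
    true_freq: np.ndarray,
    depth: int,
    rng: np.random.Generator,
    truth: SubjectTruth,
) -> RepertoireSample:
    counts = rng.multinomial(depth, true_freq)
    clones = [
        Clonotype(
            cdr3_nt=t.cdr3_nt,
            cdr3_aa=t.cdr3_aa,
            v_gene=t.v_gene,
            j_gene=t.j_gene,
            count=int(n),
            frequency=0.0,
        )
        for t, n in zip(templates, counts)
        if n > 0
    ]
    sample = RepertoireSample.from_counts(meta, clones)
    truth.true_frequencies[meta.label] = {
        t.key: float(f) for t, f in zip(templates, true_freq)
    }
    return sample


def _compartment_clones(
    config: CohortConfig,
    rng: np.random.Generator,
    v_labels: list[str],
    j_labels: list[str],
    v_probs: np.ndarray,
    j_probs: np.ndarray,
    used_aa: set[str],
) -> tuple[list[_CloneTemplate], np.ndarray, np.ndarray]:
    """Clone templates, base power-law weights, and the donor-reactive mask."""
    s_total = config.clonotypes_per_compartment
    n_dr = max(1, round(config.dr_fraction * s_total))
    n_background = s_total - n_dr

    def fresh_cdr3(family_seed: str | None = None) -> tuple[str, str]:
        for _ in range(1000):
            nt, aa = generate_cdr3(
                rng,
                config.cdr3_length_mean,
                config.cdr3_length_sd,
                family_seed=family_seed,
            )
            if aa not in used_aa:
                used_aa.add(aa)
                return nt, aa
        raise RuntimeError("could not draw a fresh CDR3 sequence")

    n_families = math.ceil(n_dr / config.family_size)
    bg_v = rng.choice(len(v_labels), size=n_background, p=v_probs)
    bg_j = rng.choice(len(j_labels), size=n_background, p=j_probs)
    fam_v = rng.choice(len(v_labels), size=n_families, p=v_probs)
    dr_j = rng.choice(len(j_labels), size=n_dr, p=j_probs)

    templates: list[_CloneTemplate] = []
    for vi, ji in zip(bg_v, bg_j):
        nt, aa = fresh_cdr3()
        templates.append(_CloneTemplate(nt, aa, v_labels[vi], j_labels[ji]))

    # donor-reactive clone families: members at inner distance 1, shared V gene
    dr_templates: list[_CloneTemplate] = []
    for fam in range(n_families):
        family_v = v_labels[fam_v[fam]]
        seed_nt, seed_aa = fresh_cdr3()
        dr_templates.append(
            _CloneTemplate(seed_nt, seed_aa, family_v, j_labels[dr_j[len(dr_templates)]])
        )
        for _ in range(config.family_size - 1):
            if len(dr_templates) >= n_dr:
                break
            nt, aa = fresh_cdr3(family_seed=seed_aa)
            dr_templates.append(
                _CloneTemplate(nt, aa, family_v, j_labels[dr_j[len(dr_templates)]])
            )
    dr_templates = dr_templates[:n_dr]
    templates.extend(dr_templates)

    # power-law clone sizes; donor-reactive clones avoid the top-1% order
    # statistics (expansion is carried by low/mid-frequency clones)
    weights = rng.zipf(config.powerlaw_alpha, size=s_total).astype(float)
    order = np.argsort(-weights)
    n_top = max(1, s_total // 100)
    top = weights[order[:n_top]]
    rest = weights[order[n_top:]]
    rng.shuffle(rest)
    dr_weights = rest[:n_dr]
    bg_weights = np.concatenate([top, rest[n_dr:]])
    rng.shuffle(bg_weights)
    base_weights = np.concatenate([bg_weights, dr_weights])

    dr_mask = np.zeros(s_total, dtype=bool)
    dr_mask[n_background:] = True
    return templates, base_weights, dr_mask


def _jittered_depth(depth: int, jitter: float, rng: np.random.Generator) -> int:
    """Per-sample sequencing depth: uniform spread around the nominal depth."""
    if jitter <= 0:
        return depth
    return max(1, int(round(depth * (1.0 + rng.uniform(-jitter, jitter)))))


def generate_subject(
    config: CohortConfig,
    subject_id: str,
    rejector: bool,
    rng: np.random.Generator,
) -> SyntheticSubject:
    """All samples of one subject plus their truth-table rows."""
    v_labels = [f"TRBV{i}" for i in range(1, config.n_v_genes + 1)]
    j_labels = [f"TRBJ{i}" for i in range(1, config.n_j_genes + 1)]
    v_probs = rng.dirichlet(np.ones(config.n_v_genes))
    j_probs = rng.dirichlet(np.ones(config.n_j_genes))
    day_post_tx = int(rng.integers(6, 252))

    group = RejectionGroup.REJECTOR if rejector else RejectionGroup.CONTROL
    truth = SubjectTruth(subject_id=subject_id)
    samples: list[RepertoireSample] = []
    used_aa: set[str] = set()
    blood_background: list[tuple[_CloneTemplate, float]] = []
    dr_pool: list[tuple[_CloneTemplate, float]] = []

    for comp in (Compartment.CD4, Compartment.CD8):
        templates, base_w, dr_mask = _compartment_clones(
            config, rng, v_labels, j_labels, v_probs, j_probs, used_aa
        )
        truth.dr_keys[comp] = {t.key for t, m in zip(templates, dr_mask) if m}
        blood_background.extend(
            (t, w) for t, w, m in zip(templates, base_w, dr_mask) if not m
        )
        dr_pool.extend((t, w) for t, w, m in zip(templates, base_w, dr_mask) if m)

        dr_idx = np.flatnonzero(dr_mask)
        n_novel = round(config.novel_dr_fraction * dr_idx.size)
        novel_idx = rng.choice(dr_idx, size=n_novel, replace=False) if n_novel else []

        # pre-transplant: novel donor-reactive clones sit below 1/depth
        pre_w = base_w.copy()
        pre_w[novel_idx] = 0.1 / config.depth_blood * base_w.sum()
        stim_w = base_w.copy()
        stim_w[dr_idx] *= config.mlr_enrichment
        post_w = base_w.copy()
        post_w[dr_idx] *= config.posttx_dr_gain

        def meta(timepoint: Timepoint, condition: Condition) -> SampleMeta:
            return SampleMeta(
                subject_id=subject_id,
                timepoint=timepoint,
                compartment=comp,
                condition=condition,
                rejection_group=group,
                day_post_tx=day_post_tx if timepoint is not Timepoint.PRE_TX else None,
            )

        for tp, cond, w in (
            (Timepoint.PRE_TX, Condition.UNSTIMULATED, pre_w),
            (Timepoint.PRE_TX, Condition.MLR_STIMULATED, stim_w),
            (Timepoint.POST_TX, Condition.UNSTIMULATED, post_w),
        ):
            depth = _jittered_depth(config.depth_blood, config.depth_jitter, rng)
            samples.append(
                _emit_sample(meta(tp, cond), templates, w / w.sum(), depth, rng, truth)
            )

    if rejector:
        samples.append(
            _tissue_sample(
                config, subject_id, group, day_post_tx, blood_background, dr_pool,
                used_aa, v_labels, j_labels, v_probs, j_probs, rng, truth,
            )
        )
    return SyntheticSubject(
        subject_id=subject_id, rejector=rejector, samples=samples, truth=truth
    )


def _tissue_sample(
    config: CohortConfig,
    subject_id: str,
    group: RejectionGroup,
    day_post_tx: int,
    blood_background: list[tuple[_CloneTemplate, float]],
    dr_pool: list[tuple[_CloneTemplate, float]],
    used_aa: set[str],
    v_labels: list[str],
    j_labels: list[str],
    v_probs: np.ndarray,
    j_probs: np.ndarray,
    rng: np.random.Generator,
    truth: SubjectTruth,
) -> RepertoireSample:
    """Bulk graft infiltrate: all donor-reactive clones at ``tissue_dr_cum_freq``
    cumulative frequency over a background partly shared with blood, partly
    tissue-unique (driving the elevated blood↔tissue divergence)."""
    n_dr = len(dr_pool)
    n_bg = config.tissue_clonotypes - n_dr
    n_shared = round(config.tissue_shared_background * n_bg)
    n_unique = n_bg - n_shared

    shared_pick = rng.choice(len(blood_background), size=n_shared, replace=False)
    shared = [blood_background[i] for i in shared_pick]
    unique: list[tuple[_CloneTemplate, float]] = []
    unique_w = rng.zipf(config.powerlaw_alpha, size=n_unique).astype(float)
    uniq_v = rng.choice(len(v_labels), size=n_unique, p=v_probs)
    uniq_j = rng.choice(len(j_labels), size=n_unique, p=j_probs)
    for w, vi, ji in zip(unique_w, uniq_v, uniq_j):
        for _ in range(1000):
            nt, aa = generate_cdr3(rng, config.cdr3_length_mean, config.cdr3_length_sd)
            if aa not in used_aa:
                used_aa.add(aa)
                break
        unique.append((_CloneTemplate(nt, aa, v_labels[vi], j_labels[ji]), float(w)))

    templates = [t for t, _ in dr_pool] + [t for t, _ in shared] + [t for t, _ in unique]
    dr_w = np.array([w for _, w in dr_pool])
    bg_w = np.array([w for _, w in shared] + [w for _, w in unique])
    freq = np.concatenate(
        [
            dr_w / dr_w.sum() * config.tissue_dr_cum_freq,
            bg_w / bg_w.sum() * (1.0 - config.tissue_dr_cum_freq),
        ]
    )
    meta = SampleMeta(
        subject_id=subject_id,
        timepoint=Timepoint.TISSUE,
        compartment=Compartment.BULK,
        condition=Condition.UNSTIMULATED,
        rejection_group=group,
        day_post_tx=day_post_tx,
    )
    depth = _jittered_depth(config.depth_tissue, config.depth_jitter, rng)
    return _emit_sample(meta, templates, freq, depth, rng, truth)


def generate_cohort(
    config: CohortConfig, out_dir: str | Path | None = None
) -> SyntheticCohort:
    """Generate the full cohort; optionally write TSVs, manifest, and truth tables.

    Fully reproducible from (config, seed): the same configuration produces
    byte-identical outputs.
    """
    seed_seq = np.random.SeedSequence(config.seed)
    children = seed_seq.spawn(config.n_subjects)
    subjects: dict[str, SyntheticSubject] = {}
    for i in range(config.n_subjects):
        subject_id = f"S{i + 1:02d}"
        rejector = i < config.n_rejectors
        rng = np.random.default_rng(children[i])
        subjects[subject_id] = generate_subject(config, subject_id, rejector, rng)
    cohort = SyntheticCohort(config=config, subjects=subjects)
    if out_dir is not None:
        write_cohort(cohort, out_dir)
    return cohort


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> Path:
    """Write canonical sample TSVs, the manifest CSV, and the truth table."""
    out_dir = Path(out_dir)
    sample_dir = out_dir / "samples"
    sample_dir.mkdir(parents=True, exist_ok=True)
    manifest_rows = []
    for subj in cohort.subjects.values():
        for sample in subj.samples:
            path = sample_dir / f"{sample.meta.label}.tsv"
            if path.exists():
                raise FileExistsError(f"output collision: {path}")
            write_clonotype_table(sample, path)
            manifest_rows.append(
                {
                    "path": str(path.relative_to(out_dir)),
                    "subject_id": sample.meta.subject_id,
                    "timepoint": sample.meta.timepoint.value,
                    "compartment": sample.meta.compartment.value,
                    "condition": sample.meta.condition.value,
                    "rejection_group": sample.meta.rejection_group.value,
                    "day_post_tx": sample.meta.day_post_tx,
                }
            )
    pd.DataFrame(manifest_rows).to_csv(out_dir / "manifest.csv", index=False)
    cohort.truth_frame().to_csv(out_dir / "truth_donor_reactive.tsv", sep="\t", index=False)
    return out_dir / "manifest.csv"
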