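"""End-to-end study replication on a cohort of clonotype samples.

Per subject: productive filtering → CD4/CD8 disambiguation → donor-reactive
classification from the pre-transplant MLR pair → downsampling-normalized
abundance in blood and graft → diversity statistics → repertoire divergence
→ CDR3 similarity networks.  Cohort level: paired t-tests pre vs. post,
unpaired (Student's) t-tests rejectors vs. controls on post−pre changes
(including ΔR20 and Δclonality), ANOVA on network edge density across
repertoire classes, and paired t-tests on donor-reactive vs. bulk
modularity.  Tests are two-sided; p-values are not adjusted for multiple
testing (the analysis is exploratory); 95% CIs accompany mean differences.
"""

from __future__ import annotations

import enum
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .comparison import TissueTracking, clone_jsd, tissue_tracking_table, vj_jsd
from .core import assign_phenotypes, filter_productive, merge_samples
from .diversity import diversity_report
from .donor_reactivity import DonorReactiveSet, abundance_table, classify_donor_reactive
from .io import load_samples
from .network import (
    DRNetworkSummary,
    analyze_sample,
    donor_reactive_network_summary,
    donor_reactive_sequences,
)
from .types import (
    Compartment,
    Condition,
    Phenotype,
    RejectionGroup,
    RepertoireSample,
    Timepoint,
)

logger = logging.getLogger("allotrace")

ALL_STAGES = frozenset({"abundance", "diversity", "jsd", "network", "tissue", "stats"})


class TestKind(str, enum.Enum):
    PAIRED_T = "PAIRED_T"
    UNPAIRED_T = "UNPAIRED_T"
    ANOVA = "ANOVA"


@dataclass
class StudyConfig:
    """Every analysis threshold in one place."""

    fc_threshold: float = 5.0
    top_n_jsd: int = 1000
    top_n_network: int = 10000
    levenshtein_threshold: int = 1
    trim: int = 3
    n_reps: int = 1000
    expanded_threshold: float = 1e-3
    alpha: float = 0.05
    welch: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        import yaml

        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.md5(payload).hexdigest()[:12]


@dataclass
class GroupComparison:
    """One statistical test with its effect estimate and 95% CI."""

    statistic_name: str
    group_a: str
    group_b: str
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    test: TestKind
    estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    n_a: int = 0
    n_b: int = 0
    delta_r20: float | None = None
    delta_clonality: float | None = None


@dataclass
class StudyReport:
    seed: int
    config_hash: str
    n_subjects_analyzed: int
    abundance: pd.DataFrame = field(default_factory=pd.DataFrame)
    diversity: pd.DataFrame = field(default_factory=pd.DataFrame)
    jsd: pd.DataFrame = field(default_factory=pd.DataFrame)
    network_metrics: pd.DataFrame = field(default_factory=pd.DataFrame)
    tissue_tracking: dict[str, TissueTracking] = field(default_factory=dict)
    dr_network: dict[str, DRNetworkSummary] = field(default_factory=dict)
    comparisons: list[GroupComparison] = field(default_factory=list)
    failures: list[str] = field(default_factory=list)


def paired_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, float, float]:
    """Two-sided paired t-test: (mean difference a−b, ci_low, ci_high, p)."""
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    n = d.size
    mean = d.mean()
    se = d.std(ddof=1) / np.sqrt(n)
    if se == 0:
        p = 1.0 if mean == 0 else 0.0
        return float(mean), float(mean), float(mean), p
    t = mean / se
    p = 2 * sps.t.sf(abs(t), n - 1)
    crit = sps.t.ppf(0.975, n - 1)
    return float(mean), float(mean - crit * se), float(mean + crit * se), float(p)


def unpaired_t(
    a: Sequence[float], b: Sequence[float], welch: bool = False
) -> tuple[float, float, float, float]:
    """Two-sided two-sample t-test (Student's by default, Welch optional)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    va, vb = a.var(ddof=1), b.var(ddof=1)
    mean = a.mean() - b.mean()
    if welch:
        se = np.sqrt(va / na + vb / nb)
        df = (va / na + vb / nb) ** 2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
        )
    else:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se = np.sqrt(sp2 * (1 / na + 1 / nb))
        df = na + nb - 2
    if se == 0:
        p = 1.0 if mean == 0 else 0.0
        return float(mean), float(mean), float(mean), p
    t = mean / se
    p = 2 * sps.t.sf(abs(t), df)
    crit = sps.t.ppf(0.975, df)
    return float(mean), float(mean - crit * se), float(mean + crit * se), float(p)


def anova(groups: Sequence[Sequence[float]]) -> float:
    """One-way ANOVA p-value across the groups."""
    return float(sps.f_oneway(*[np.asarray(g, dtype=float) for g in groups]).pvalue)


@dataclass
class _Subject:
    subject_id: str
    rejection_group: RejectionGroup
    blood: dict[tuple[Timepoint, Compartment, Condition], RepertoireSample]
    tissue: RepertoireSample | None
    dr_sets: dict[Compartment, DonorReactiveSet] = field(default_factory=dict)

    def dr_union(self) -> DonorReactiveSet:
        return DonorReactiveSet.union(list(self.dr_sets.values()))


def _apply_phenotypes(
    samples: list[RepertoireSample],
) -> list[RepertoireSample]:
    """Resolve clonotypes observed in both sorted subsets.

    The doubling rule is applied to the unstimulated CD4/CD8 samples only;
    MLR samples inherit the assignment.  Keys assigned to the other subset
    (or dropped) are removed from each compartment's samples.
    """
    cd4_unstim = [
        s
        for s in samples
        if s.meta.compartment is Compartment.CD4
        and s.meta.condition is Condition.UNSTIMULATED
    ]
    cd8_unstim = [
        s
        for s in samples
        if s.meta.compartment is Compartment.CD8
        and s.meta.condition is Condition.UNSTIMULATED
    ]
    shared = {c.key for s in cd4_unstim for c in s.clonotypes} & {
        c.key for s in cd8_unstim for c in s.clonotypes
    }
    if not shared:
        return samples
    verdict = {
        a.key: a.assigned
        for a in assign_phenotypes(cd4_unstim, cd8_unstim)
        if a.key in shared
    }
    out = []
    for sample in samples:
        comp = sample.meta.compartment
        if comp is Compartment.BULK:
            out.append(sample)
            continue
        allowed = Phenotype.CD4 if comp is Compartment.CD4 else Phenotype.CD8
        kept = [
            c
            for c in sample.clonotypes
            if c.key not in verdict or verdict[c.key] is allowed
        ]
        out.append(RepertoireSample.from_counts(sample.meta, kept))
    return out


def _group_subjects(samples: Iterable[RepertoireSample]) -> dict[str, list[RepertoireSample]]:
    by_subject: dict[str, list[RepertoireSample]] = {}
    for s in samples:
        by_subject.setdefault(s.meta.subject_id, []).append(s)
    return by_subject


def _prepare_subject(
    subject_id: str, samples: list[RepertoireSample], config: StudyConfig
) -> _Subject:
    samples = [filter_productive(s) for s in samples]
    samples = _apply_phenotypes(samples)
    blood: dict[tuple[Timepoint, Compartment, Condition], RepertoireSample] = {}
    tissue = None
    group = RejectionGroup.UNKNOWN
    for s in samples:
        if s.meta.rejection_group is not RejectionGroup.UNKNOWN:
            group = s.meta.rejection_group
        if s.meta.timepoint is Timepoint.TISSUE:
            tissue = s
        else:
            blood[(s.meta.timepoint, s.meta.compartment, s.meta.condition)] = s
    subject = _Subject(subject_id, group, blood, tissue)
    for comp in (Compartment.CD4, Compartment.CD8):
        stim = blood.get((Timepoint.PRE_TX, comp, Condition.MLR_STIMULATED))
        unstim = blood.get((Timepoint.PRE_TX, comp, Condition.UNSTIMULATED))
        if stim is None or unstim is None:
            raise ValueError(
                f"subject {subject_id} lacks the pre-transplant MLR pair for {comp.value}"
            )
        subject.dr_sets[comp] = classify_donor_reactive(
            stim, unstim, fc_threshold=config.fc_threshold
        )
    return subject


def run_study(
    data: "SyntheticCohortLike | Sequence[RepertoireSample] | str | Path",
    config: StudyConfig | None = None,
    stages: Iterable[str] | None = None,
) -> StudyReport:
    """Run the complete analysis over a cohort.

    ``data`` may be a synthetic cohort object, a sequence of samples, or a
    manifest CSV path.  ``stages`` restricts the analysis (any subset of
    {'abundance','diversity','jsd','network','tissue','stats'}); statistics
    are computed from whichever upstream stages ran.  Per-subject failures
    are logged and skipped; the run fails if fewer than two subjects
    complete.  The run is a pure function of (data, config): reruns with the
    same seed are identical.
    """
    config = config or StudyConfig()
    stages = ALL_STAGES if stages is None else frozenset(stages)
    unknown = stages - ALL_STAGES
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")

    if isinstance(data, (str, Path)):
        samples = load_samples(data)
    elif hasattr(data, "all_samples"):
        samples = data.all_samples()
    else:
        samples = list(data)

    subjects: dict[str, _Subject] = {}
    failures: list[str] = []
    for subject_id, subj_samples in sorted(_group_subjects(samples).items()):
        try:
            subjects[subject_id] = _prepare_subject(subject_id, subj_samples, config)
        except (ValueError, KeyError) as exc:
            logger.warning("subject %s skipped: %s", subject_id, exc)
            failures.append(f"{subject_id}: {exc}")
    if len(subjects) < 2:
        raise RuntimeError(
            f"only {len(subjects)} subject(s) completed preprocessing; need at least 2"
        )

    report = StudyReport(
        seed=config.seed,
        config_hash=config.hash(),
        n_subjects_analyzed=len(subjects),
        failures=failures,
    )

    dr_sets = {
        (sid, comp): s for sid, subj in subjects.items() for comp, s in subj.dr_sets.items()
    }
    if "abundance" in stages:
        cohort_samples = [
            s
            for subj in subjects.values()
            for s in list(subj.blood.values()) + ([subj.tissue] if subj.tissue else [])
        ]
        report.abundance = abundance_table(
            cohort_samples, dr_sets, n_reps=config.n_reps, seed=config.seed
        )

    if "diversity" in stages:
        report.diversity = _diversity_table(subjects, config)
    if "jsd" in stages:
        report.jsd = _jsd_table(subjects, config)
    if "network" in stages:
        report.network_metrics = _network_table(subjects, config)
    if "tissue" in stages:
        _tissue_stage(subjects, config, report)
    if "stats" in stages:
        report.comparisons = _comparisons(report, config)
    return report


def _diversity_table(subjects: dict[str, _Subject], config: StudyConfig) -> pd.DataFrame:
    rows = []
    for subj in subjects.values():
        all_samples = list(subj.blood.values()) + (
            [subj.tissue] if subj.tissue is not None else []
        )
        for sample in all_samples:
            rep = diversity_report(sample, expanded_threshold=config.expanded_threshold)
            rows.append(
                {
                    "subject_id": subj.subject_id,
                    "rejection_group": subj.rejection_group.value,
                    "timepoint": sample.meta.timepoint.value,
                    "compartment": sample.meta.compartment.value,
                    "condition": sample.meta.condition.value,
                    "n_clonotypes": rep.n_clonotypes,
                    "shannon_H": rep.shannon_H,
                    "clonality": rep.clonality,
                    "r20": rep.r20,
                    "powerlaw_slope": rep.powerlaw_slope,
                    "powerlaw_abs_slope": rep.powerlaw_abs_slope,
                    "powerlaw_r2": rep.powerlaw_r2,
                    "cutoff_frequency": rep.cutoff_frequency,
                }
            )
    return pd.DataFrame(rows)


def _jsd_table(subjects: dict[str, _Subject], config: StudyConfig) -> pd.DataFrame:
    rows = []
    for subj in subjects.values():
        for comp in (Compartment.CD4, Compartment.CD8):
            pre = subj.blood.get((Timepoint.PRE_TX, comp, Condition.UNSTIMULATED))
            post = subj.blood.get((Timepoint.POST_TX, comp, Condition.UNSTIMULATED))
            if pre is None or post is None:
                continue
            rows.append(
                {
                    "subject_id": subj.subject_id,
                    "compartment": comp.value,
                    "Sample.1": "PreTX",
                    "Sample.2": "PostTX",
                    "JSD": clone_jsd(pre, post, top_n=config.top_n_jsd),
                    "JSD_VJ": vj_jsd(pre, post),
                }
            )
        if subj.tissue is not None:
            pre_bulk, post_bulk = _bulk_blood(subj)
            for name, blood in (("PreTX", pre_bulk), ("PostTX", post_bulk)):
                rows.append(
                    {
                        "subject_id": subj.subject_id,
                        "compartment": "BULK",
                        "Sample.1": name,
                        "Sample.2": "Tissue",
                        "JSD": clone_jsd(blood, subj.tissue, top_n=config.top_n_jsd),
                        "JSD_VJ": vj_jsd(blood, subj.tissue),
                    }
                )
            rows.append(
                {
                    "subject_id": subj.subject_id,
                    "compartment": "BULK",
                    "Sample.1": "PreTX",
                    "Sample.2": "PostTX",
                    "JSD": clone_jsd(pre_bulk, post_bulk, top_n=config.top_n_jsd),
                    "JSD_VJ": vj_jsd(pre_bulk, post_bulk),
                }
            )
    return pd.DataFrame(rows)


def _bulk_blood(subj: _Subject) -> tuple[RepertoireSample, RepertoireSample]:
    def merged(tp: Timepoint) -> RepertoireSample:
        parts = [
            subj.blood[(tp, c, Condition.UNSTIMULATED)]
            for c in (Compartment.CD4, Compartment.CD8)
            if (tp, c, Condition.UNSTIMULATED) in subj.blood
        ]
        return merge_samples(parts)

    return merged(Timepoint.PRE_TX), merged(Timepoint.POST_TX)


_REPERTOIRE_CLASSES = (
    ("PreTX", Timepoint.PRE_TX, Condition.UNSTIMULATED),
    ("PostTX", Timepoint.POST_TX, Condition.UNSTIMULATED),
    ("DonorReactive", Timepoint.PRE_TX, Condition.MLR_STIMULATED),
)


def _network_table(subjects: dict[str, _Subject], config: StudyConfig) -> pd.DataFrame:
    rows = []
    for subj in subjects.values():
        for comp in (Compartment.CD4, Compartment.CD8):
            for label, tp, cond in _REPERTOIRE_CLASSES:
                sample = subj.blood.get((tp, comp, cond))
                if sample is None:
                    continue
                net = analyze_sample(
                    sample,
                    top_n=config.top_n_network,
                    distance_threshold=config.levenshtein_threshold,
                    trim=config.trim,
                    dr=subj.dr_sets.get(comp),
                    betweenness=False,
                )
                rows.append(
                    {
                        "subject_id": subj.subject_id,
                        "rejection_group": subj.rejection_group.value,
                        "compartment": comp.value,
                        "repertoire": label,
                        "n_nodes": net.n_nodes,
                        "n_edges": net.n_edges,
                        "modularity": net.modularity,
                        "edge_density": net.edge_density,
                    }
                )
    return pd.DataFrame(rows)


def _tissue_stage(
    subjects: dict[str, _Subject], config: StudyConfig, report: StudyReport
) -> None:
    for subj in subjects.values():
        if subj.tissue is None:
            continue
        pre_bulk, post_bulk = _bulk_blood(subj)
        dr_union = subj.dr_union()
        report.tissue_tracking[subj.subject_id] = tissue_tracking_table(
            subj.tissue, pre_bulk, post_bulk, dr_union, top_n_jsd=config.top_n_jsd
        )
        net = analyze_sample(
            subj.tissue,
            top_n=config.top_n_network,
            distance_threshold=config.levenshtein_threshold,
            trim=config.trim,
            dr=dr_union,
            betweenness=True,
        )
        report.dr_network[subj.subject_id] = donor_reactive_network_summary(
            net, donor_reactive_sequences(subj.tissue, dr_union)
        )


def _paired_by_subject(
    table: pd.DataFrame, value: str, comp: str, cond: str = "UNSTIMULATED"
) -> tuple[list[float], list[float], list[str]]:
    sel = table[(table["compartment"] == comp)]
    if "condition" in sel.columns:
        sel = sel[sel["condition"] == cond]
    pre = sel[sel["timepoint"] == "PRE_TX"].set_index("subject_id")[value]
    post = sel[sel["timepoint"] == "POST_TX"].set_index("subject_id")[value]
    common = sorted(set(pre.index) & set(post.index))
    return [post[s] for s in common], [pre[s] for s in common], common


def _comparison(
    name: str,
    a: Sequence[float],
    b: Sequence[float],
    group_a: str,
    group_b: str,
    kind: TestKind,
    welch: bool = False,
    **extra,
) -> GroupComparison | None:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if kind is TestKind.PAIRED_T and (a.size < 2 or a.size != b.size):
        return None
    if kind is TestKind.UNPAIRED_T and (a.size < 2 or b.size < 2):
        return None
    if kind is TestKind.PAIRED_T:
        est, lo, hi, p = paired_t(a, b)
    else:
        est, lo, hi, p = unpaired_t(a, b, welch=welch)
    return GroupComparison(
        statistic_name=name,
        group_a=group_a,
        group_b=group_b,
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)) if a.size > 1 else 0.0,
        sd_b=float(b.std(ddof=1)) if b.size > 1 else 0.0,
        test=kind,
        estimate=est,
        ci_low=lo,
        ci_high=hi,
        p_value=p,
        n_a=int(a.size),
        n_b=int(b.size),
        **extra,
    )


def _comparisons(report: StudyReport, config: StudyConfig) -> list[GroupComparison]:
    out: list[GroupComparison] = []
    ab = report.abundance
    abundance_stats = ("n_dr_clonotypes", "pct_dr_clonotypes", "cum_dr_frequency")
    if len(ab):
        for comp in ("CD4", "CD8"):
            for stat in abundance_stats:
                post, pre, _ = _paired_by_subject(ab, stat, comp)
                cmp = _comparison(
                    f"{stat}_{comp}", post, pre, "PostTX", "PreTX", TestKind.PAIRED_T
                )
                if cmp:
                    out.append(cmp)
            # rejector vs control on the post−pre change
            for stat in abundance_stats:
                post, pre, subjects = _paired_by_subject(ab, stat, comp)
                delta = dict(zip(subjects, np.subtract(post, pre)))
                groups = ab.drop_duplicates("subject_id").set_index("subject_id")[
                    "rejection_group"
                ]
                rej = [delta[s] for s in subjects if groups.get(s) == "REJECTOR"]
                ctl = [delta[s] for s in subjects if groups.get(s) == "CONTROL"]
                cmp = _comparison(
                    f"delta_{stat}_{comp}",
                    rej,
                    ctl,
                    "REJECTOR",
                    "CONTROL",
                    TestKind.UNPAIRED_T,
                    welch=config.welch,
                )
                if cmp:
                    out.append(cmp)

    div = report.diversity
    if len(div):
        for comp in ("CD4", "CD8"):
            for stat, delta_field in (("r20", "delta_r20"), ("clonality", "delta_clonality")):
                post, pre, subjects = _paired_by_subject(div, stat, comp)
                if not subjects:
                    continue
                delta = dict(zip(subjects, np.subtract(post, pre)))
                groups = div.drop_duplicates("subject_id").set_index("subject_id")[
                    "rejection_group"
                ]
                rej = [delta[s] for s in subjects if groups.get(s) == "REJECTOR"]
                ctl = [delta[s] for s in subjects if groups.get(s) == "CONTROL"]
                cmp = _comparison(
                    f"delta_{stat}_{comp}",
                    rej,
                    ctl,
                    "REJECTOR",
                    "CONTROL",
                    TestKind.UNPAIRED_T,
                    welch=config.welch,
                    **{delta_field: float(np.mean(list(delta.values())))},
                )
                if cmp:
                    out.append(cmp)

    net = report.network_metrics
    if len(net):
        for comp in ("CD4", "CD8"):
            sel = net[net["compartment"] == comp]
            groups = [
                sel[sel["repertoire"] == label]["edge_density"].to_numpy()
                for label, _, _ in _REPERTOIRE_CLASSES
            ]
            if all(len(g) >= 2 for g in groups):
                p = anova(groups)
                means = [g.mean() for g in groups]
                out.append(
                    GroupComparison(
                        statistic_name=f"edge_density_{comp}",
                        group_a="PreTX/PostTX/DonorReactive",
                        group_b="",
                        mean_a=float(np.mean(means)),
                        mean_b=float("nan"),
                        sd_a=float(np.std(means)),
                        sd_b=float("nan"),
                        test=TestKind.ANOVA,
                        estimate=float("nan"),
                        ci_low=float("nan"),
                        ci_high=float("nan"),
                        p_value=p,
                        n_a=int(sum(len(g) for g in groups)),
                    )
                )
            wide = sel.pivot_table(
                index="subject_id", columns="repertoire", values="modularity"
            )
            for bulk_label in ("PreTX", "PostTX"):
                if {"DonorReactive", bulk_label} <= set(wide.columns):
                    paired = wide[["DonorReactive", bulk_label]].dropna()
                    cmp = _comparison(
                        f"modularity_dr_vs_{bulk_label.lower()}_{comp}",
                        paired["DonorReactive"],
                        paired[bulk_label],
                        "DonorReactive",
                        bulk_label,
                        TestKind.PAIRED_T,
                    )
                    if cmp:
                        out.append(cmp)
    return out


def comparisons_frame(report: StudyReport) -> pd.DataFrame:
    rows = []
    for c in report.comparisons:
        row = asdict(c)
        row["test"] = c.test.value
        rows.append(row)
    return pd.DataFrame(rows)


def write_report(report: StudyReport, out_dir: str | Path) -> Path:
    """Write all tables (TSV), graph metrics (JSON), and summary plots."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, frame in (
        ("abundance", report.abundance),
        ("diversity", report.diversity),
        ("jsd", report.jsd),
        ("network_metrics", report.network_metrics),
        ("comparisons", comparisons_frame(report)),
    ):
        if len(frame):
            frame.to_csv(out_dir / f"{name}.tsv", sep="\t", index=False)
    for subject_id, tracking in report.tissue_tracking.items():
        tracking.top_clones.to_csv(
            out_dir / f"tissue_top_clones_{subject_id}.tsv", sep="\t", index=False
        )
    metrics = {
        "seed": report.seed,
        "config_hash": report.config_hash,
        "n_subjects_analyzed": report.n_subjects_analyzed,
        "failures": report.failures,
        "tissue_jsd": {s: t.jsd for s, t in report.tissue_tracking.items()},
        "dr_network": {s: asdict(d) for s, d in report.dr_network.items()},
        "note": "p-values are not adjusted for multiple testing",
    }
    with open(out_dir / "metrics.json", "w") as fh:
        json.dump(metrics, fh, indent=2, sort_keys=True)
    _plots(report, out_dir)
    return out_dir


def _plots(report: StudyReport, out_dir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    div = report.diversity
    if len(div):
        blood = div[
            (div["condition"] == "UNSTIMULATED") & (div["compartment"] != "BULK")
        ]
        fig, axes = plt.subplots(1, 2, figsize=(9, 4))
        for ax, stat in zip(axes, ("clonality", "r20")):
            data, labels = [], []
            for tp in ("PRE_TX", "POST_TX"):
                for grp in ("REJECTOR", "CONTROL"):
                    vals = blood[
                        (blood["timepoint"] == tp) & (blood["rejection_group"] == grp)
                    ][stat].dropna()
                    if len(vals):
                        data.append(vals)
                        labels.append(f"{tp}\n{grp.lower()}")
            if data:
                ax.boxplot(data, tick_labels=labels)
            ax.set_ylabel(stat)
        fig.tight_layout()
        fig.savefig(out_dir / "diversity_boxplots.png", dpi=120)
        plt.close(fig)

    ab = report.abundance
    if len(ab):
        fig, ax = plt.subplots(figsize=(8, 4))
        order = {"PRE_TX": 0, "POST_TX": 1, "TISSUE": 2}
        colors = {"PRE_TX": "#9ecae1", "POST_TX": "#3182bd", "TISSUE": "#de2d26"}
        subjects = sorted(ab["subject_id"].unique())
        width = 0.25
        for tp, off in order.items():
            sel = ab[ab["timepoint"] == tp].groupby("subject_id")["cum_dr_frequency"].mean()
            xs = [i + (off - 1) * width for i, s in enumerate(subjects) if s in sel.index]
            ys = [sel[s] for s in subjects if s in sel.index]
            ax.bar(xs, ys, width=width, color=colors[tp], label=tp)
        ax.set_xticks(range(len(subjects)))
        ax.set_xticklabels(subjects, rotation=90)
        ax.set_ylabel("donor-reactive cells (%)")
        ax.legend()
        fig.tight_layout()
        fig.savefig(out_dir / "donor_reactive_fractions.png", dpi=120)
        plt.close(fig)

    net = report.network_metrics
    if len(net):
        fig, ax = plt.subplots(figsize=(5, 4))
        palette = {"PreTX": "#9ecae1", "PostTX": "#3182bd", "DonorReactive": "#fdae27"}
        for label, color in palette.items():
            sel = net[net["repertoire"] == label]
            ax.scatter(100 * sel["edge_density"], sel["modularity"], s=18, c=color, label=label)
        ax.set_xlabel("edge density (%)")
        ax.set_ylabel("modularity")
        ax.legend()
        fig.tight_layout()
        fig.savefig(out_dir / "network_scatter.png", dpi=120)
        plt.close(fig)


# type alias for documentation purposes only
SyntheticCohortLike = object
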