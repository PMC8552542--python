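"""Reading and writing clonotype tables and sample manifests.

Input tables are TSV, one file per sample, in the dialect produced by common
V(D)J consensus-assembly tools (columns ``cloneCount``, ``cloneFraction``,
``nSeqCDR3``, ``aaSeqCDR3``, ``bestVGene``/``allVHitsWithScore``, ...).  The
column mapping is configurable.  Output is a canonical TSV with one row per
clonotype key plus count and recomputed frequency.
"""

from __future__ import annotations

import re
from pathlib import Path

import pandas as pd

from .types import (
    Clonotype,
    Compartment,
    Condition,
    RejectionGroup,
    RepertoireSample,
    SampleMeta,
    Timepoint,
)


class ClonotypeTableError(ValueError):
    """Raised when a clonotype table does not match the expected format."""


#: logical field -> accepted header synonyms, in priority order
DEFAULT_COLUMNS: dict[str, tuple[str, ...]] = {
    "count": ("cloneCount", "count", "reads", "cellCount"),
    "frequency": ("cloneFraction", "frequency", "freq", "fraction"),
    "cdr3_nt": ("nSeqCDR3", "cdr3_nt", "nSeqImputedCDR3", "cdr3nt"),
    "cdr3_aa": ("aaSeqCDR3", "cdr3_aa", "aaSeqImputedCDR3", "cdr3aa"),
    "v_gene": ("bestVGene", "allVHitsWithScore", "v_gene", "v"),
    "d_gene": ("bestDGene", "allDHitsWithScore", "d_gene", "d"),
    "j_gene": ("bestJGene", "allJHitsWithScore", "j_gene", "j"),
}

MANDATORY_FIELDS = ("count", "cdr3_nt", "cdr3_aa", "v_gene", "j_gene")

_GENE_SCORE_RE = re.compile(r"[\*\(].*$")


def _clean_gene(label: object) -> str:
    """Strip allele and alignment-score decorations, e.g. 'TRBV7-9*00(123)' -> 'TRBV7-9'."""
    if label is None or (isinstance(label, float) and pd.isna(label)):
        return ""
    text = str(label).split(",")[0].strip()
    return _GENE_SCORE_RE.sub("", text)


def _resolve_columns(
    header: list[str], columns: dict[str, tuple[str, ...]]
) -> dict[str, str]:
    resolved: dict[str, str] = {}
    lower = {h.lower(): h for h in header}
    for field_name, synonyms in columns.items():
        for syn in synonyms:
            if syn.lower() in lower:
                resolved[field_name] = lower[syn.lower()]
                break
    missing = [f for f in MANDATORY_FIELDS if f not in resolved]
    if missing:
        raise ClonotypeTableError(
            f"clonotype table is missing mandatory column(s): {', '.join(missing)} "
            f"(accepted names: {', '.join(columns[missing[0]])})"
        )
    return resolved


def read_clonotype_table(
    path: str | Path,
    meta: SampleMeta,
    columns: dict[str, tuple[str, ...]] | None = None,
) -> RepertoireSample:
    """Read one TSV clonotype table into a :class:`RepertoireSample`.

    Rows with zero count are dropped, duplicate keys (same CDR3 nt + V + J)
    are merged by summing counts, and frequencies are recomputed from counts.
    """
    path = Path(path)
    table = pd.read_csv(path, sep="\t", dtype=str)
    if table.empty:
        raise ClonotypeTableError(f"clonotype table {path} is empty")
    resolved = _resolve_columns(list(table.columns), columns or DEFAULT_COLUMNS)

    out = pd.DataFrame(
        {
            "count": pd.to_numeric(table[resolved["count"]]).astype(int),
            "cdr3_nt": table[resolved["cdr3_nt"]].astype(str),
            "cdr3_aa": table[resolved["cdr3_aa"]].astype(str),
            "v_gene": table[resolved["v_gene"]].map(_clean_gene),
            "j_gene": table[resolved["j_gene"]].map(_clean_gene),
        }
    )
    if "d_gene" in resolved:
        out["d_gene"] = table[resolved["d_gene"]].map(_clean_gene)
    else:
        out["d_gene"] = ""
    out = out[out["count"] > 0]
    if out.empty:
        raise ClonotypeTableError(f"clonotype table {path} has no rows with count > 0")

    merged = (
        out.groupby(["cdr3_nt", "v_gene", "j_gene"], as_index=False, sort=False)
        .agg(
            count=("count", "sum"),
            cdr3_aa=("cdr3_aa", "first"),
            d_gene=("d_gene", "first"),
        )
    )
    clones = [
        Clonotype(
            cdr3_nt=row.cdr3_nt,
            cdr3_aa=row.cdr3_aa,
            v_gene=row.v_gene,
            j_gene=row.j_gene,
            d_gene=row.d_gene,
            count=int(row.count),
            frequency=0.0,
        )
        for row in merged.itertuples(index=False)
    ]
    return RepertoireSample.from_counts(meta, clones)


def write_clonotype_table(sample: RepertoireSample, path: str | Path) -> Path:
    """Write the canonical TSV (key columns + count + frequency)."""
    path = Path(path)
    frame = sample_to_frame(sample)
    frame.to_csv(path, sep="\t", index=False)
    return path


def sample_to_frame(sample: RepertoireSample) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cdr3_nt": [c.cdr3_nt for c in sample.clonotypes],
            "cdr3_aa": [c.cdr3_aa for c in sample.clonotypes],
            "v_gene": [c.v_gene for c in sample.clonotypes],
            "d_gene": [c.d_gene for c in sample.clonotypes],
            "j_gene": [c.j_gene for c in sample.clonotypes],
            "cloneCount": [c.count for c in sample.clonotypes],
            "cloneFraction": [c.frequency for c in sample.clonotypes],
        }
    )


MANIFEST_COLUMNS = (
    "path",
    "subject_id",
    "timepoint",
    "compartment",
    "condition",
    "rejection_group",
    "day_post_tx",
)


def meta_from_record(record: dict) -> SampleMeta:
    day = record.get("day_post_tx")
    if day in (None, "", "NA") or (isinstance(day, float) and pd.isna(day)):
        day = None
    else:
        day = int(day)
    return SampleMeta(
        subject_id=str(record["subject_id"]),
        timepoint=Timepoint(record["timepoint"]),
        compartment=Compartment(record["compartment"]),
        condition=Condition(record.get("condition", "UNSTIMULATED")),
        rejection_group=RejectionGroup(record.get("rejection_group", "UNKNOWN")),
        day_post_tx=day,
    )


def read_manifest(path: str | Path) -> list[tuple[Path, SampleMeta]]:
    """Read a CSV manifest mapping sample files to their metadata."""
    path = Path(path)
    frame = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS[:5] if c not in frame.columns]
    if missing:
        raise ClonotypeTableError(f"manifest missing column(s): {', '.join(missing)}")
    entries = []
    for record in frame.to_dict("records"):
        sample_path = Path(record["path"])
        if not sample_path.is_absolute():
            sample_path = path.parent / sample_path
        entries.append((sample_path, meta_from_record(record)))
    return entries


def load_samples(manifest_path: str | Path) -> list[RepertoireSample]:
    """Load every sample referenced by a manifest CSV."""
    return [
        read_clonotype_table(p, meta) for p, meta in read_manifest(manifest_path)
    ]
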