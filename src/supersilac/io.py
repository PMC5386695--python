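"""Readers and writers for protein-group tables, sample designs and annotations.

The quantification input is a MaxQuant ``proteinGroups.txt``-style
tab-separated table: one row per protein group, per-sample ``Ratio H/L``
columns (heavy spike-in standard over light sample), per-sample
``LFQ intensity`` columns, and the usual decoy/contaminant marker columns.
Missing quantifications are empty cells, ``NaN``, or — for label-free
intensities — ``0``; all of these are represented as *missing*, never as a
numeric zero, so that downstream imputation sees the true detection pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ProteinRecord",
    "SampleDesign",
    "AnnotationMap",
    "Dialect",
    "FormatError",
    "read_protein_groups",
    "write_protein_groups",
    "filter_records",
    "read_design",
    "read_gmt",
    "write_gmt",
]


class FormatError(ValueError):
    """An input table does not conform to the expected dialect."""


@dataclass
class Dialect:
    """Column conventions of the protein-groups table.

    ``ratio_prefixes`` are tried in order; the first prefix for which
    per-sample columns exist wins, so the MaxQuant-normalized ratios are
    preferred over raw ones when both are present.
    """

    id_column: str = "Protein IDs"
    gene_column: str = "Gene names"
    ratio_prefixes: tuple[str, ...] = ("Ratio H/L normalized ", "Ratio H/L ")
    lfq_prefix: str = "LFQ intensity "
    reverse_column: str = "Reverse"
    contaminant_columns: tuple[str, ...] = ("Potential contaminant", "Contaminant")
    site_column: str = "Only identified by site"
    flag_marker: str = "+"
    reverse_prefix: str = "REV__"
    contaminant_prefix: str = "CON__"


@dataclass
class ProteinRecord:
    """One protein group with its per-sample quantifications."""

    protein_ids: list[str]
    gene_name: str = ""
    is_reverse: bool = False
    is_contaminant: bool = False
    only_identified_by_site: bool = False
    ratio_hl: dict[str, float] = field(default_factory=dict)
    lfq_intensity: dict[str, float] = field(default_factory=dict)
    terms: set[str] = field(default_factory=set)

    @property
    def accession(self) -> str:
        """Leading accession, used as the row key throughout the pipeline."""
        return self.protein_ids[0]

    def __post_init__(self) -> None:
        if not self.protein_ids:
            raise ValueError("protein_ids must be non-empty")
        bad = {s: v for s, v in self.ratio_hl.items() if not v > 0}
        if bad:
            raise ValueError(f"ratio_hl must be strictly positive, got {bad}")


class SampleDesign:
    """Mapping sample -> (group, biological replicate, technical replicate).

    Exactly two group levels are required, each with at least two biological
    replicates; (group, bio, tech) triples must be unique.
    """

    REQUIRED = ("sample_id", "group", "biological_replicate", "technical_replicate")

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in frame.columns]
        if missing:
            raise FormatError(f"design is missing required columns: {missing}")
        frame = frame.loc[:, list(self.REQUIRED)].copy()
        frame["biological_replicate"] = frame["biological_replicate"].astype(int)
        frame["technical_replicate"] = frame["technical_replicate"].astype(int)
        if (frame[["biological_replicate", "technical_replicate"]] < 1).any().any():
            raise ValueError("replicate indices must be >= 1")
        if frame["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in design")
        triples = frame[["group", "biological_replicate", "technical_replicate"]]
        if triples.duplicated().any():
            raise ValueError("duplicate (group, biological, technical) triple in design")
        groups = list(dict.fromkeys(frame["group"]))
        if len(groups) != 2:
            raise ValueError(f"design must have exactly 2 groups, found {groups}")
        for g in groups:
            n_bio = frame.loc[frame["group"] == g, "biological_replicate"].nunique()
            if n_bio < 2:
                raise ValueError(f"group {g!r} has {n_bio} biological replicate(s); need >= 2")
        self.frame = frame.reset_index(drop=True)
        self.groups: tuple[str, str] = (groups[0], groups[1])

    @property
    def samples(self) -> list[str]:
        return list(self.frame["sample_id"])

    def group_of(self, sample_id: str) -> str:
        row = self.frame.loc[self.frame["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(sample_id)
        return row["group"].iloc[0]

    def samples_in_group(self, group: str) -> list[str]:
        return list(self.frame.loc[self.frame["group"] == group, "sample_id"])

    def bio_replicates(self) -> dict[tuple[str, int], list[str]]:
        """(group, biological_replicate) -> ordered technical-replicate samples."""
        out: dict[tuple[str, int], list[str]] = {}
        for _, row in self.frame.iterrows():
            out.setdefault((row["group"], row["biological_replicate"]), []).append(row["sample_id"])
        return out

    def n_bio(self, group: str) -> int:
        return self.frame.loc[self.frame["group"] == group, "biological_replicate"].nunique()

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    def __len__(self) -> int:
        return len(self.frame)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        a, b = self.groups
        return (
            f"<SampleDesign {len(self)} samples; {a}: {self.n_bio(a)} bio reps, "
            f"{b}: {self.n_bio(b)} bio reps>"
        )


class AnnotationMap:
    """Annotation terms (GO-style) mapping term -> member protein accessions."""

    def __init__(
        self,
        members: Mapping[str, set[str]],
        names: Mapping[str, str] | None = None,
        namespaces: Mapping[str, str] | None = None,
    ):
        self.members = {t: set(m) for t, m in members.items()}
        for t, m in self.members.items():
            if not m:
                raise ValueError(f"term {t!r} has an empty member set")
        self.names = dict(names or {})
        self.namespaces = dict(namespaces or {})

    def terms(self, namespace: str | None = None) -> list[str]:
        if namespace is None:
            return list(self.members)
        return [t for t in self.members if self.namespaces.get(t) == namespace]

    def terms_of(self, accession: str) -> set[str]:
        return {t for t, m in self.members.items() if accession in m}

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, term: str) -> bool:
        return term in self.members


# ---------------------------------------------------------------------------
# protein-groups table


def _sample_columns(columns: Sequence[str], prefix: str) -> dict[str, str]:
    """Map sample_id -> column name for columns starting with ``prefix``."""
    out: dict[str, str] = {}
    for col in columns:
        if col.startswith(prefix):
            sample = col[len(prefix):]
            if sample in out:
                raise FormatError(f"duplicate sample column for {sample!r} under prefix {prefix!r}")
            out[sample] = col
    return out


def _pick_ratio_columns(columns: Sequence[str], dialect: Dialect) -> dict[str, str]:
    for prefix in dialect.ratio_prefixes:
        cols = _sample_columns(columns, prefix)
        # "Ratio H/L " also matches "Ratio H/L normalized X"; drop those.
        cols = {
            s: c
            for s, c in cols.items()
            if not any(c.startswith(p) for p in dialect.ratio_prefixes if len(p) > len(prefix))
        }
        if cols:
            return cols
    return {}


def _to_float(cell: object) -> float:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return np.nan
    try:
        return float(cell)
    except (TypeError, ValueError):
        return np.nan


def read_protein_groups(path: str | Path, dialect: Dialect | None = None) -> list[ProteinRecord]:
    """Read a protein-groups table into :class:`ProteinRecord` objects.

    Empty or non-numeric quantification cells become missing; label-free
    intensities of 0 are treated as "not detected" (missing), following the
    output convention of the upstream search software where 0 is a
    placeholder for a protein that was not quantified in that run.
    """
    dialect = dialect or Dialect()
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if dialect.id_column not in table.columns:
        raise FormatError(f"no protein-identifier column {dialect.id_column!r} in header")
    ratio_cols = _pick_ratio_columns(table.columns, dialect)
    lfq_cols = _sample_columns(table.columns, dialect.lfq_prefix)
    if not ratio_cols and not lfq_cols:
        raise FormatError(
            "no per-sample quantification columns found "
            f"(looked for prefixes {dialect.ratio_prefixes + (dialect.lfq_prefix,)})"
        )

    contaminant_col = next((c for c in dialect.contaminant_columns if c in table.columns), None)

    records: list[ProteinRecord] = []
    for _, row in table.iterrows():
        ids = [p for p in str(row[dialect.id_column]).split(";") if p]
        if not ids:
            continue
        is_rev = any(p.startswith(dialect.reverse_prefix) for p in ids)
        is_con = any(p.startswith(dialect.contaminant_prefix) for p in ids)
        if dialect.reverse_column in table.columns:
            is_rev = is_rev or row[dialect.reverse_column].strip() == dialect.flag_marker
        if contaminant_col is not None:
            is_con = is_con or row[contaminant_col].strip() == dialect.flag_marker
        by_site = (
            dialect.site_column in table.columns
            and row[dialect.site_column].strip() == dialect.flag_marker
        )
        ratios: dict[str, float] = {}
        for sample, col in ratio_cols.items():
            v = _to_float(row[col])
            if np.isfinite(v) and v > 0:
                ratios[sample] = v
        lfq: dict[str, float] = {}
        for sample, col in lfq_cols.items():
            v = _to_float(row[col])
            if np.isfinite(v) and v > 0:  # 0 intensity == not detected
                lfq[sample] = v
        records.append(
            ProteinRecord(
                protein_ids=ids,
                gene_name=str(row.get(dialect.gene_column, "") or ""),
                is_reverse=is_rev,
                is_contaminant=is_con,
                only_identified_by_site=by_site,
                ratio_hl=ratios,
                lfq_intensity=lfq,
            )
        )
    return records


def write_protein_groups(
    records: Iterable[ProteinRecord],
    path: str | Path,
    samples: Sequence[str],
    dialect: Dialect | None = None,
) -> None:
    """Serialize records back to the tab-separated protein-groups dialect.

    Missing quantifications are written as empty cells (ratios) and ``0``
    (label-free intensities), mirroring the format read by
    :func:`read_protein_groups`, so the two round-trip.
    """
    dialect = dialect or Dialect()
    ratio_prefix = dialect.ratio_prefixes[-1]
    rows = []
    for rec in records:
        row: dict[str, object] = {
            dialect.id_column: ";".join(rec.protein_ids),
            dialect.gene_column: rec.gene_name,
            dialect.reverse_column: dialect.flag_marker if rec.is_reverse else "",
            dialect.contaminant_columns[0]: dialect.flag_marker if rec.is_contaminant else "",
            dialect.site_column: dialect.flag_marker if rec.only_identified_by_site else "",
        }
        for s in samples:
            v = rec.ratio_hl.get(s, np.nan)
            row[ratio_prefix + s] = "" if not np.isfinite(v) else repr(v)
            w = rec.lfq_intensity.get(s, np.nan)
            row[dialect.lfq_prefix + s] = "0" if not np.isfinite(w) else repr(w)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def filter_records(
    records: Sequence[ProteinRecord],
    remove_only_by_site: bool = True,
) -> tuple[list[ProteinRecord], dict[str, int]]:
    """Drop decoy, contaminant and (optionally) site-only identifications.

    Returns the surviving records in their original order plus per-reason
    removal counts; a record carrying several flags is removed once but
    counted under every reason that applies.
    """
    counts = {"reverse": 0, "contaminant": 0, "only_identified_by_site": 0}
    survivors: list[ProteinRecord] = []
    for rec in records:
        drop = False
        if rec.is_reverse:
            counts["reverse"] += 1
            drop = True
        if rec.is_contaminant:
            counts["contaminant"] += 1
            drop = True
        if remove_only_by_site and rec.only_identified_by_site:
            counts["only_identified_by_site"] += 1
            drop = True
        if not drop:
            survivors.append(rec)
    return survivors, counts


def filter_report(
    records: Sequence[ProteinRecord], remove_only_by_site: bool = True
) -> pd.DataFrame:
    """Per-record filter outcome as a table with a filter-reason column."""
    rows = []
    for rec in records:
        reasons = []
        if rec.is_reverse:
            reasons.append("reverse")
        if rec.is_contaminant:
            reasons.append("contaminant")
        if remove_only_by_site and rec.only_identified_by_site:
            reasons.append("only_identified_by_site")
        rows.append(
            {
                "protein": rec.accession,
                "gene": rec.gene_name,
                "kept": not reasons,
                "filter_reason": ";".join(reasons),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# sample design


def read_design(path: str | Path) -> SampleDesign:
    """Read a tab- or comma-separated sample design table."""
    frame = pd.read_csv(path, sep=None, engine="python")
    return SampleDesign(frame)


# ---------------------------------------------------------------------------
# annotations


def read_gmt(path: str | Path, namespace: str = "") -> AnnotationMap:
    """Read a GMT file: one term per line, ``term<TAB>description<TAB>members...``."""
    members: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    namespaces: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            term, desc, *prots = parts
            members[term] = {p for p in prots if p}
            names[term] = desc
            namespaces[term] = namespace
    return AnnotationMap(members, names, namespaces)


def write_gmt(annotations: AnnotationMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for term in annotations.terms():
            desc = annotations.names.get(term, term)
            prots = "\t".join(sorted(annotations.members[term]))
            fh.write(f"{term}\t{desc}\t{prots}\n")


def read_annotation_tsv(path: str | Path, namespace: str = "") -> AnnotationMap:
    """Two-column protein<TAB>term mapping as an alternative to GMT."""
    frame = pd.read_csv(path, sep="\t", header=None, names=["protein", "term"])
    members: dict[str, set[str]] = {}
    for _, row in frame.iterrows():
        members.setdefault(row["term"], set()).add(row["protein"])
    return AnnotationMap(members, namespaces={t: namespace for t in members})
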