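"""From spike-in ratios to a replicate-aggregated log2 quantification matrix.

With a heavy spike-in standard, a protein's H/L ratio is standard/sample, so
log2(sample/standard) = -log2(H/L). Everything downstream works on
log2(sample/standard): comparisons between samples are then plain
subtractions ("ratios of ratios" to the common standard), and the sign
convention is structural — positive group differences mean higher expression
in the second group.

The processing order mirrors the study workflow: log2-transform, median-center
each sample column, take the median over technical replicates per biological
replicate, and keep proteins quantified in enough biological replicates.
"""

from __future__ import annotations

from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .io import ProteinRecord, SampleDesign

__all__ = [
    "QuantMatrix",
    "to_log2_sample_ratio",
    "build_matrix",
    "median_center",
    "aggregate_technical",
    "min_valid_filter",
    "group_difference",
    "prepare_matrix",
    "format_fold",
]

Scope = Literal["each", "any"]


class QuantMatrix:
    """Proteins x samples matrix of log2 values with explicit missingness.

    Wraps a pandas DataFrame (rows: protein accessions, columns: sample ids)
    where NaN marks a missing quantification. ``source`` records whether the
    values derive from spike-in ratios or label-free intensities.
    """

    def __init__(self, data: pd.DataFrame, source: str = "silac-ratio"):
        self.data = data.astype(float)
        self.source = source

    @property
    def proteins(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean frame, True where the value is observed."""
        return self.data.notna()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def copy(self) -> "QuantMatrix":
        return QuantMatrix(self.data.copy(), self.source)

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="protein")

    @classmethod
    def from_tsv(cls, path, source: str = "silac-ratio") -> "QuantMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col="protein"), source)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        n_missing = int(self.data.isna().to_numpy().sum())
        return f"<QuantMatrix {self.shape[0]}x{self.shape[1]} ({self.source}), {n_missing} missing>"


def to_log2_sample_ratio(ratio_hl: float, standard_channel: str = "heavy") -> float:
    """log2(sample/standard) from an H/L ratio.

    If the spike-in standard is the heavy channel the sample is the light
    one, so the sample/standard ratio is 1/(H/L) and the log2 value is
    ``-log2(ratio_hl)``; with a light standard it is ``+log2(ratio_hl)``.
    """
    if not ratio_hl > 0:
        raise ValueError(f"ratio must be strictly positive, got {ratio_hl}")
    if standard_channel not in ("heavy", "light"):
        raise ValueError("standard_channel must be 'heavy' or 'light'")
    sign = -1.0 if standard_channel == "heavy" else 1.0
    return sign * float(np.log2(ratio_hl))


def build_matrix(
    records: Sequence[ProteinRecord],
    design: SampleDesign,
    source: str = "silac-ratio",
    standard_channel: str = "heavy",
) -> QuantMatrix:
    """Assemble a log2 QuantMatrix from protein records.

    For ``source="silac-ratio"`` the values are log2(sample/standard) from
    the H/L ratios; for ``source="label-free"`` they are log2 of the LFQ
    intensities (used for presence/absence and complementary quantification).
    """
    samples = design.samples
    data = np.full((len(records), len(samples)), np.nan)
    index = []
    for i, rec in enumerate(records):
        index.append(rec.accession)
        if source == "silac-ratio":
            for j, s in enumerate(samples):
                if s in rec.ratio_hl:
                    data[i, j] = to_log2_sample_ratio(rec.ratio_hl[s], standard_channel)
        elif source == "label-free":
            for j, s in enumerate(samples):
                v = rec.lfq_intensity.get(s)
                if v is not None and v > 0:
                    data[i, j] = np.log2(v)
        else:
            raise ValueError(f"unknown source {source!r}")
    if len(set(index)) != len(index):
        raise ValueError("duplicate protein accessions in records")
    return QuantMatrix(pd.DataFrame(data, index=index, columns=samples), source)


def median_center(matrix: QuantMatrix) -> QuantMatrix:
    """Subtract each sample column's median over its observed entries.

    Equalizes overall protein load between runs; after centering, each
    column's median over observed entries is exactly 0.
    """
    data = matrix.data
    if (data.notna().sum(axis=0) == 0).any():
        empty = [c for c in data.columns if data[c].notna().sum() == 0]
        raise ValueError(f"cannot center columns with no observed values: {empty}")
    return QuantMatrix(data - data.median(axis=0, skipna=True), matrix.source)


def aggregate_technical(matrix: QuantMatrix, design: SampleDesign) -> QuantMatrix:
    """Median over technical replicates, one output column per biological replicate.

    The median is taken over observed values only; a biological replicate
    whose technical replicates are all missing stays missing. Output columns
    are named ``{group}_b{bio}`` in design order.
    """
    unknown = [c for c in matrix.samples if c not in set(design.samples)]
    if unknown:
        raise ValueError(f"matrix columns not present in design: {unknown}")
    cols = {}
    for (group, bio), tech_samples in design.bio_replicates().items():
        present = [s for s in tech_samples if s in matrix.data.columns]
        if not present:
            continue
        cols[f"{group}_b{bio}"] = matrix.data[present].median(axis=1, skipna=True)
    return QuantMatrix(pd.DataFrame(cols), matrix.source)


def bio_design(design: SampleDesign) -> SampleDesign:
    """Design for the aggregated matrix: one 'sample' per biological replicate."""
    rows = [
        {
            "sample_id": f"{group}_b{bio}",
            "group": group,
            "biological_replicate": bio,
            "technical_replicate": 1,
        }
        for (group, bio) in design.bio_replicates()
    ]
    return SampleDesign(pd.DataFrame(rows))


def min_valid_filter(
    matrix: QuantMatrix,
    design: SampleDesign,
    min_valid: int = 2,
    scope: Scope = "each",
) -> QuantMatrix:
    """Keep proteins quantified in at least ``min_valid`` biological replicates.

    ``scope="each"`` requires the minimum in every group (the stricter
    reading, appropriate when testing without imputation); ``scope="any"``
    requires it in at least one group (appropriate when missing values will
    be imputed, so a protein absent from one group — a candidate on/off
    event — is retained).
    """
    if scope not in ("each", "any"):
        raise ValueError("scope must be 'each' or 'any'")
    counts = {}
    for g in design.groups:
        cols = [c for c in matrix.samples if c in design.samples and design.group_of(c) == g]
        if min_valid > len(cols):
            raise ValueError(
                f"min_valid={min_valid} exceeds the {len(cols)} replicates of group {g!r}"
            )
        counts[g] = matrix.data[cols].notna().sum(axis=1)
    a, b = design.groups
    if scope == "each":
        keep = (counts[a] >= min_valid) & (counts[b] >= min_valid)
    else:
        keep = (counts[a] >= min_valid) | (counts[b] >= min_valid)
    return QuantMatrix(matrix.data.loc[keep], matrix.source)


def group_difference(matrix: QuantMatrix, design: SampleDesign) -> pd.DataFrame:
    """Per-protein log2 group difference and fold change.

    delta = mean over observed values in the second design group minus mean
    over the first (so with groups (MM, sPCL): positive delta = higher in
    sPCL, negative = higher in MM). ``fold_change`` is 2**delta — the
    ratio convention in which 21.2 means 21.2-fold up and 0.045 means
    22.2-fold down. Proteins with no observed value in a group get NaN delta
    rather than a fabricated number.
    """
    a, b = design.groups
    cols_a = [c for c in matrix.samples if design.group_of(c) == a]
    cols_b = [c for c in matrix.samples if design.group_of(c) == b]
    mean_a = matrix.data[cols_a].mean(axis=1, skipna=True)
    mean_b = matrix.data[cols_b].mean(axis=1, skipna=True)
    delta = mean_b - mean_a
    out = pd.DataFrame(
        {
            "delta": delta,
            "fold_change": np.power(2.0, delta),
            f"n_valid_{a}": matrix.data[cols_a].notna().sum(axis=1),
            f"n_valid_{b}": matrix.data[cols_b].notna().sum(axis=1),
        }
    )
    return out


def format_fold(delta: float) -> str:
    """Human-readable fold change: '21.2-fold up' / '22.2-fold down'."""
    if np.isnan(delta):
        return "undefined"
    if delta >= 0:
        return f"{2 ** delta:.1f}-fold up"
    return f"{2 ** (-delta):.1f}-fold down"


def prepare_matrix(
    records: Sequence[ProteinRecord],
    design: SampleDesign,
    source: str = "silac-ratio",
    standard_channel: str = "heavy",
    normalize: bool = True,
    min_valid: int = 2,
    scope: Scope = "each",
) -> tuple[QuantMatrix, SampleDesign]:
    """Full quantification preprocessing: log2 -> center -> aggregate -> filter.

    Returns the biological-replicate-level matrix and its matching design.
    """
    m = build_matrix(records, design, source=source, standard_channel=standard_channel)
    if normalize:
        m = median_center(m)
    m = aggregate_technical(m, design)
    bdesign = bio_design(design)
    m = min_valid_filter(m, bdesign, min_valid=min_valid, scope=scope)
    return m, bdesign
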