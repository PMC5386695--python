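"""Synthetic spike-in experiments with known ground truth.

Emulates the data structure of a super-SILAC patient comparison so every
pipeline stage can be exercised end to end: two groups (MM vs sPCL) x 3
biological replicates x k technical replicates of log2 sample/standard
ratios, a planted fraction of true differential effects (symmetric up/down
by default), Gaussian biological and technical noise, intensity-dependent
missingness (lower values are more often unobserved, the pattern that
motivates downshift imputation), annotation terms — optionally with a mean
shift planted on their members — and incomplete heavy-label incorporation
in the spike-in standard.

Values are serialized through the same protein-groups dialect the real
data arrives in (H/L ratios with a heavy standard), so the generator
round-trips through the production readers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .io import AnnotationMap, ProteinRecord, SampleDesign, write_gmt, write_protein_groups

__all__ = [
    "GeneratorConfig",
    "SyntheticTruth",
    "generate_experiment",
    "write_experiment",
    "recovery_metrics",
]


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic experiment.

    Defaults mirror the study's shape: 2 groups x 3 biological replicates
    (MM bone-marrow vs sPCL blood time points) x 2 technical MS replicates;
    ~2000 quantified proteins with log2 ratios centered on zero; 10% true
    differential effects of 1.0 log2 units (2-fold, comfortably above the
    0.58 calling threshold); biological scatter 0.3 and technical scatter
    0.15 log2 units; missing-not-at-random dropout rising as values fall
    below the detection region; heavy-label incorporation 95% in the
    spike-in standard.
    """

    n_proteins: int = 2000
    de_fraction: float = 0.10
    effect_log2: float = 1.0
    fraction_down: float = 0.5  # study observed 64% down-regulated; 0.64 mimics it
    sigma_bio: float = 0.3
    sigma_tech: float = 0.15
    n_bio_per_group: int = 3
    n_tech: int = 2
    baseline_mean: float = 0.0
    baseline_sd: float = 1.0
    missing_mnar_location: float = -2.0
    missing_mnar_slope: float = -1.0
    n_terms: int = 20
    term_size: int = 50
    term_shift: float = 0.0
    n_shifted_terms: int = 1
    incorporation: float = 0.95
    lfq_log2_offset: float = 25.0
    groups: tuple[str, str] = ("MM", "sPCL")
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must lie in [0, 1]")
        if self.effect_log2 <= 0:
            raise ValueError("effect_log2 must be > 0")
        if not 0.0 < self.incorporation <= 1.0:
            raise ValueError("incorporation must lie in (0, 1]")
        if self.n_bio_per_group < 2:
            raise ValueError("need >= 2 biological replicates per group")
        if self.n_tech < 1:
            raise ValueError("need >= 1 technical replicate")
        if 0.0 < self.de_fraction and self.de_fraction * self.n_proteins < 2:
            raise ValueError("de_fraction * n_proteins must be >= 2 (or 0 for a null)")
        if self.missing_mnar_slope > 0:
            raise ValueError("missing_mnar_slope must be <= 0 (lower values drop out more)")


@dataclass
class SyntheticTruth:
    """Ground truth aligned with the emitted protein table."""

    table: pd.DataFrame  # protein, true_delta, is_de, mean_missing_prob
    config: GeneratorConfig
    values: pd.DataFrame = field(repr=False)  # noise-free+noise log2 values pre-missingness

    @property
    def de_proteins(self) -> list[str]:
        return list(self.table.loc[self.table["is_de"], "protein"])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _make_design(config: GeneratorConfig) -> SampleDesign:
    rows = []
    for g in config.groups:
        for b in range(1, config.n_bio_per_group + 1):
            for t in range(1, config.n_tech + 1):
                rows.append(
                    {
                        "sample_id": f"{g}_b{b}_t{t}",
                        "group": g,
                        "biological_replicate": b,
                        "technical_replicate": t,
                    }
                )
    return SampleDesign(pd.DataFrame(rows))


def generate_experiment(
    config: GeneratorConfig | None = None,
) -> tuple[list[ProteinRecord], SampleDesign, AnnotationMap, SyntheticTruth]:
    """Draw one synthetic experiment; bit-reproducible given ``config.seed``.

    Per protein i: baseline ``a_i ~ N(baseline_mean, baseline_sd^2)`` on the
    log2 sample/standard scale; a planted effect ``+-effect_log2`` added to
    the second group for a ``de_fraction`` subset (``fraction_down`` of them
    down); per-biological-replicate noise ``N(0, sigma_bio^2)`` shared by
    that replicate's technical runs, plus per-run noise ``N(0,
    sigma_tech^2)``. Each cell goes missing with probability
    ``logistic(slope * (value - location))`` — monotone increasing as the
    value falls when slope < 0. Ratios are written with the heavy standard
    (H/L = incorporation / (2^value + 1 - incorporation)), label-free
    intensities as ``2^(value + lfq_log2_offset)`` under the same dropout.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    n = config.n_proteins
    proteins = [f"P{i:06d}" for i in range(n)]
    genes = [f"GENE{i}" for i in range(n)]
    design = _make_design(config)

    # planted effects: half (or fraction_down) of the DE set down-regulated
    true_delta = np.zeros(n)
    n_de = int(round(config.de_fraction * n))
    if n_de:
        de_idx = rng.choice(n, size=n_de, replace=False)
        n_down = int(round(config.fraction_down * n_de))
        down = rng.choice(de_idx, size=n_down, replace=False)
        true_delta[de_idx] = config.effect_log2
        true_delta[down] = -config.effect_log2

    # annotation terms; the first n_shifted_terms get an extra mean shift
    members: dict[str, set[str]] = {}
    namespaces: dict[str, str] = {}
    for j in range(config.n_terms):
        term = f"TERM{j:03d}"
        idx = rng.choice(n, size=min(config.term_size, n), replace=False)
        members[term] = {proteins[i] for i in idx}
        namespaces[term] = "cellular-component"
        if config.term_shift != 0.0 and j < config.n_shifted_terms:
            true_delta[idx] = true_delta[idx] + config.term_shift
    annotations = (
        AnnotationMap(members, names={t: t for t in members}, namespaces=namespaces)
        if members
        else AnnotationMap({})
    )
    is_de = true_delta != 0.0

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=n)
    samples = design.samples
    values = np.empty((n, len(samples)))
    col_of = {s: j for j, s in enumerate(samples)}
    group_b = config.groups[1]
    for (g, b), tech_samples in design.bio_replicates().items():
        bio_noise = rng.normal(0.0, config.sigma_bio, size=n)
        shift = true_delta if g == group_b else 0.0
        for s in tech_samples:
            tech_noise = rng.normal(0.0, config.sigma_tech, size=n)
            values[:, col_of[s]] = baseline + shift + bio_noise + tech_noise

    p_missing = expit(config.missing_mnar_slope * (values - config.missing_mnar_location))
    missing = rng.random(values.shape) < p_missing

    inc = config.incorporation
    ratio_hl = inc / (np.power(2.0, values) + (1.0 - inc))
    lfq = np.power(2.0, values + config.lfq_log2_offset)

    records = []
    for i, acc in enumerate(proteins):
        obs = {s: float(ratio_hl[i, col_of[s]]) for s in samples if not missing[i, col_of[s]]}
        lfq_obs = {s: float(lfq[i, col_of[s]]) for s in samples if not missing[i, col_of[s]]}
        records.append(
            ProteinRecord(
                protein_ids=[acc],
                gene_name=genes[i],
                ratio_hl=obs,
                lfq_intensity=lfq_obs,
                terms=annotations.terms_of(acc) if members else set(),
            )
        )

    truth = SyntheticTruth(
        table=pd.DataFrame(
            {
                "protein": proteins,
                "gene": genes,
                "true_delta": true_delta,
                "is_de": is_de,
                "mean_missing_prob": p_missing.mean(axis=1),
            }
        ),
        config=config,
        values=pd.DataFrame(values, index=proteins, columns=samples),
    )
    return records, design, annotations, truth


def write_experiment(config: GeneratorConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate and serialize one experiment (protein groups, design, GMT, truth)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records, design, annotations, truth = generate_experiment(config)
    paths = {
        "protein_groups": outdir / "proteinGroups.tsv",
        "design": outdir / "design.tsv",
        "annotations": outdir / "annotations.gmt",
        "truth": outdir / "truth.tsv",
    }
    write_protein_groups(records, paths["protein_groups"], design.samples)
    design.to_tsv(paths["design"])
    if len(annotations):
        write_gmt(annotations, paths["annotations"])
    else:
        paths.pop("annotations")
    truth.to_tsv(paths["truth"])
    return paths


def recovery_metrics(
    calls: pd.DataFrame,
    truth: SyntheticTruth,
    flag: str = "sig_fdr",
) -> dict[str, float]:
    """Sensitivity, observed FDR and sign accuracy of a set of DE calls.

    ``calls`` is a results table indexed by protein accession with a boolean
    ``flag`` column and a ``delta`` column. Proteins absent from the table
    (e.g. removed by the minimum-valid filter) count as not called. Sign
    accuracy is the fraction of *called true-DE* proteins whose estimated
    direction matches the planted one.
    """
    truth_tab = truth.table.set_index("protein")
    common = calls.index.intersection(truth_tab.index)
    if len(common) == 0:
        raise ValueError("calls and truth share no protein accessions")
    called = calls.loc[common, flag].astype(bool)
    called = called.reindex(truth_tab.index, fill_value=False)
    is_de = truth_tab["is_de"].astype(bool)

    tp = int((called & is_de).sum())
    fp = int((called & ~is_de).sum())
    fn = int((~called & is_de).sum())
    sensitivity = tp / (tp + fn) if (tp + fn) else float("nan")
    observed_fdr = fp / max(1, tp + fp)

    de_called = called & is_de
    if de_called.any():
        est = calls["delta"].reindex(truth_tab.index)
        signs_ok = np.sign(est[de_called]) == np.sign(truth_tab.loc[de_called, "true_delta"])
        sign_accuracy = float(signs_ok.mean())
    else:
        sign_accuracy = float("nan")
    return {
        "sensitivity": sensitivity,
        "observed_fdr": observed_fdr,
        "sign_accuracy": sign_accuracy,
        "n_called": int(called.sum()),
        "n_true_de": int(is_de.sum()),
    }
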