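"""End-to-end orchestration: read -> filter -> quantify -> test -> enrich -> QC.

One :class:`PipelineConfig` drives the whole analysis; every stage's
effective parameters, per-stage record counts and derived seeds are written
to a JSON run manifest so a run can be audited and reproduced exactly.
A single global seed is expanded deterministically into per-stage seeds.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .diffexpr import (
    DifferentialExpression,
    ImputationParams,
    exclusive_detection,
)
from .enrichment import annotation_enrichment
from .io import (
    read_design,
    read_gmt,
    read_protein_groups,
    filter_records,
)
from .quality import cocluster_score, hcluster, pearson_matrix
from .quant import build_matrix, median_center, prepare_matrix

logger = logging.getLogger("supersilac")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    protein_groups: str
    design: str
    outdir: str
    annotations: str | None = None
    standard_channel: str = "heavy"
    normalize: bool = True
    min_valid: int = 2
    min_valid_scope: str | None = None  # None -> 'any' with imputation, 'each' without
    impute: bool = True
    downshift: float = 1.5
    width: float = 0.5
    log2_cut: float = 0.58
    p_cut: float = 0.05
    fdr_alpha: float = 0.05
    n_perm: int = 250
    s0: float = 0.0
    min_term_size: int = 10
    min_pairs: int = 200
    seed: int = 0

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the global one."""
        order = ["impute", "test", "enrich", "qc"]
        child = np.random.SeedSequence(self.seed).spawn(len(order))[order.index(stage)]
        return int(child.generate_state(1)[0] % (2**31))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in fixed order and write outputs + manifest.

    Outputs in ``config.outdir``: de_results.tsv, volcano.tsv,
    enrichment.tsv (if annotations given), correlation.tsv, qc.json,
    exclusive_detection.json and manifest.json. Identical config and seed
    produce byte-identical result tables.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": asdict(config),
        "stages": {},
    }

    def fail(stage: str, err: Exception):
        logger.error("stage %s failed: %s", stage, err)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    # --- read + filter
    try:
        records = read_protein_groups(config.protein_groups)
        design = read_design(config.design)
        survivors, removed = filter_records(records)
        manifest["stages"]["read_filter"] = {
            "n_rows": len(records),
            "n_kept": len(survivors),
            "removed": removed,
        }
        logger.info("read %d rows, kept %d after filtering", len(records), len(survivors))
    except Exception as err:  # noqa: BLE001
        fail("read_filter", err)

    # --- quantify
    try:
        scope = config.min_valid_scope or ("any" if config.impute else "each")
        matrix, bdesign = prepare_matrix(
            survivors,
            design,
            standard_channel=config.standard_channel,
            normalize=config.normalize,
            min_valid=config.min_valid,
            scope=scope,  # type: ignore[arg-type]
        )
        matrix.to_tsv(out / "quant_matrix.tsv")
        manifest["stages"]["quantify"] = {
            "n_proteins": matrix.shape[0],
            "n_bio_replicates": matrix.shape[1],
            "scope": scope,
        }
    except Exception as err:  # noqa: BLE001
        fail("quantify", err)

    # --- differential expression
    try:
        model = DifferentialExpression(
            matrix,
            bdesign,
            impute=config.impute,
            imputation=ImputationParams(config.downshift, config.width),
            log2_cut=config.log2_cut,
            p_cut=config.p_cut,
            fdr_alpha=config.fdr_alpha,
            n_perm=config.n_perm,
            s0=config.s0,
        )
        results = model.fit(seed=config.stage_seed("test"))
        results.to_tsv(out / "de_results.tsv")
        results.volcano_table().to_csv(out / "volcano.tsv", sep="\t", index_label="protein")
        manifest["stages"]["test"] = {
            "seed": config.stage_seed("test"),
            "n_tested": results.n_tested,
            "n_sig_p_fc": results.n_sig_p_fc,
            "n_sig_fdr": results.n_sig_fdr,
        }
        logger.info(
            "%d tested, %d significant (p & fold), %d at permutation FDR",
            results.n_tested, results.n_sig_p_fc, results.n_sig_fdr,
        )
    except Exception as err:  # noqa: BLE001
        fail("test", err)

    # --- exclusive detection on the label-free channel
    try:
        lfq = build_matrix(survivors, design, source="label-free")
        exclusive = exclusive_detection(lfq, design)
        with open(out / "exclusive_detection.json", "w") as fh:
            json.dump(exclusive, fh, indent=1)
        manifest["stages"]["exclusive"] = {g: len(v) for g, v in exclusive.items()}
    except Exception as err:  # noqa: BLE001
        fail("exclusive", err)

    # --- enrichment
    if config.annotations:
        try:
            annotations = read_gmt(config.annotations, namespace="cellular-component")
            enr = annotation_enrichment(
                results.table["delta"], annotations, min_term_size=config.min_term_size
            )
            enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
            manifest["stages"]["enrich"] = {
                "n_terms_tested": len(enr),
                "n_terms_fdr05": int((enr["fdr"] < 0.05).sum()) if len(enr) else 0,
            }
        except Exception as err:  # noqa: BLE001
            fail("enrich", err)

    # --- QC
    try:
        sample_matrix = build_matrix(survivors, design)
        if config.normalize:
            sample_matrix = median_center(sample_matrix)
        corr = pearson_matrix(sample_matrix, min_pairs=min(config.min_pairs, matrix.shape[0]))
        corr.to_tsv(out / "correlation.tsv")
        qc: dict = {"complete": corr.is_complete()}
        if corr.is_complete() and len(corr.labels) > 2:
            link = hcluster(corr)
            groups: dict[str, list[str]] = {}
            for (g, b), tech in design.bio_replicates().items():
                groups[f"{g}_b{b}"] = list(tech)
            if any(len(v) >= 2 for v in groups.values()):
                qc["cocluster_score"] = cocluster_score(link, groups)
            qc["leaf_order"] = link.leaf_order
        with open(out / "qc.json", "w") as fh:
            json.dump(qc, fh, indent=1)
        manifest["stages"]["qc"] = {k: v for k, v in qc.items() if k != "leaf_order"}
    except Exception as err:  # noqa: BLE001
        fail("qc", err)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
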