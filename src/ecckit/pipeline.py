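"""End-to-end pipeline over a serialized cohort directory.

Stage order: filter -> annotate -> quantify -> compare -> diagnose ->
prognose. Every run writes its resolved configuration (with a content hash)
next to the outputs, so any output file is re-derivable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotation, features, filters, prognostic
from .diagnostic import HarnessConfig, run_harness
from .io_formats import (
    read_candidate_frame,
    read_clinical_table,
    read_gene_model,
    read_genome_layout,
    read_repeat_table,
    write_feature_matrix,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "load_tracks"]

_BED_COLUMNS = ["chrom", "start", "end", "name"]


@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    data_dir: str
    out_dir: str
    seed: int = 0
    thresholds: filters.FilterThresholds = filters.FilterThresholds()
    harness: HarnessConfig | None = None
    flank_bp: int = 2000
    min_group_size: int = 3
    stages: tuple[str, ...] = (
        "filter", "annotate", "quantify", "compare", "diagnose", "prognose"
    )


def load_tracks(tracks_dir: Path, layout):
    def _bed(path):
        frame = pd.read_csv(path, sep="\t", header=None)
        frame = frame.iloc[:, : len(_BED_COLUMNS)]
        frame.columns = _BED_COLUMNS[: frame.shape[1]]
        return frame

    return {
        "gene_model": read_gene_model(tracks_dir / "gene_model.tsv", layout),
        "repeats": read_repeat_table(tracks_dir / "repeats.tsv", layout),
        "enhancer": _bed(tracks_dir / "enhancer.bed"),
        "dhs": _bed(tracks_dir / "dhs.bed"),
        "cpg_island": _bed(tracks_dir / "cpg_island.bed"),
    }


def _config_hash(resolved: dict) -> str:
    blob = json.dumps(resolved, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the staged analysis; returns paths and headline numbers."""
    data = Path(config.data_dir)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    clinical_path = data / "clinical.tsv"
    if not clinical_path.exists():
        raise FileNotFoundError(f"clinical table not found: {clinical_path}")

    resolved = dataclasses.asdict(config)
    if config.harness is not None:
        resolved["harness"] = dataclasses.asdict(config.harness)
    resolved["config_hash"] = _config_hash(resolved)
    with open(out / "resolved_config.json", "w") as fh:
        json.dump(resolved, fh, indent=2, sort_keys=True, default=str)

    layout = read_genome_layout(data / "tracks" / "genome.chrom.sizes")
    clinical = read_clinical_table(clinical_path)
    tracks = load_tracks(data / "tracks", layout)
    catalog = annotation.build_catalog(
        tracks["gene_model"], tracks["enhancer"], tracks["dhs"],
        tracks["cpg_island"], tracks["repeats"], layout, flank_bp=config.flank_bp,
    )

    result: dict = {"config_hash": resolved["config_hash"], "out_dir": str(out)}
    overlaps, mapped = {}, {}
    clin_idx = clinical.set_index("sample_id")
    audits = {}
    for sid in clinical["sample_id"]:
        try:
            table = read_candidate_frame(data / "samples" / f"{sid}.tsv", layout)
            if "filter" in config.stages:
                kept, audit = filters.apply_filters(table, config.thresholds)
                audits[sid] = audit
            else:
                kept = table
            if "annotate" in config.stages:
                overlaps[sid] = annotation.annotate(kept, catalog)
                mapped[sid] = int(clin_idx.loc[sid, "mapped_reads"])
        except Exception as exc:
            raise RuntimeError(f"stage filter/annotate failed for sample {sid}: {exc}") from exc

    if audits:
        pd.DataFrame(
            {
                "sample_id": list(audits),
                "n_input": [a.n_input for a in audits.values()],
                "n_kept": [a.n_kept for a in audits.values()],
            }
        ).to_csv(out / "filter_summary.tsv", sep="\t", index=False)
        result["n_kept_total"] = int(sum(a.n_kept for a in audits.values()))

    if "quantify" in config.stages:
        matrix = features.quantify_cohort(overlaps, mapped)
        matrix = matrix.loc[clinical["sample_id"]]
        write_feature_matrix(matrix, out / "features.tsv")
        result["feature_matrix"] = str(out / "features.tsv")
        result["n_features"] = int(matrix.shape[1])
    else:
        return result

    labels = clin_idx.loc[matrix.index, "tissue_label"]

    if "compare" in config.stages:
        comparison = features.compare_groups(matrix, labels)
        comparison.to_csv(out / "wilcoxon.tsv", sep="\t", float_format="%.6g")
        result["n_significant_features"] = int((comparison["p_value"] < 0.05).sum())

    if "diagnose" in config.stages:
        harness = config.harness or HarnessConfig(seed=config.seed)
        y = (labels == "tumor").astype(int).to_numpy()
        report = run_harness(matrix, y, harness)
        if report["attribution"] is not None:
            report["attribution"].to_csv(
                out / "diagnostic_attribution.tsv", sep="\t", index=False
            )
        diag = {
            "selected_model": report["selected_model"],
            "cv_auc": report["cv_auc"],
            "test_metrics": report["test_metrics"],
        }
        with open(out / "diagnostic_report.json", "w") as fh:
            json.dump(diag, fh, indent=2, sort_keys=True)
        result["diagnostic_auc"] = report["test_metrics"]["auc"]
        result["diagnostic_model"] = report["selected_model"]

    if "prognose" in config.stages:
        tumor = clin_idx.loc[labels[labels == "tumor"].index]
        followed = tumor["dfs_time"].notna() & tumor["dfs_event"].notna()
        if followed.sum() == 0 or tumor.loc[followed, "dfs_event"].sum() < 1:
            logger.warning("prognostic stage skipped: no usable survival records")
        else:
            tm = matrix.loc[tumor.index[followed]]
            times = tumor.loc[followed, "dfs_time"].to_numpy(float)
            events = tumor.loc[followed, "dfs_event"].to_numpy(int)
            screen = prognostic.survival_screen(
                tm, times, events, min_group_size=config.min_group_size
            )
            screen.to_csv(out / "survival_screen.tsv", sep="\t", float_format="%.6g")
            result["n_prognostic_features"] = int(screen["significant"].sum())
            try:
                harness = config.harness or HarnessConfig(seed=config.seed)
                report = prognostic.prognostic_classifier(
                    matrix.loc[tumor.index], tumor.reset_index(), harness
                )
                result["prognostic_auc"] = report["test_metrics"]["auc"]
                with open(out / "prognostic_report.json", "w") as fh:
                    json.dump(
                        {
                            "selected_model": report["selected_model"],
                            "cv_auc": report["cv_auc"],
                            "test_metrics": report["test_metrics"],
                            "n_excluded_lost_to_followup": report[
                                "n_excluded_lost_to_followup"
                            ],
                        },
                        fh, indent=2, sort_keys=True,
                    )
            except ValueError as exc:
                logger.warning("prognostic classifier skipped: %s", exc)

    with open(out / "pipeline_summary.json", "w") as fh:
        json.dump(result, fh, indent=2, sort_keys=True, default=str)
    return result
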