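#!/usr/bin/env python
"""Annotate kept eccDNA against the 24-category catalog and build the
58-feature matrix; also summarize length structure and genomic density.

Writes features.tsv, length_summary.tsv, window_density.tsv and
chromosome_proportions.tsv under results/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from ecckit import annotation, features
from ecckit.filters import apply_filters
from ecckit.io_formats import (
    read_candidate_frame,
    read_clinical_table,
    read_genome_layout,
    write_feature_matrix,
)
from ecckit.pipeline import load_tracks

ROOT = Path(__file__).resolve().parent.parent / "results"
COHORT = ROOT / "cohort"


def main():
    if not COHORT.exists():
        raise SystemExit("run 01_simulate_cohort.py first")
    layout = read_genome_layout(COHORT / "tracks" / "genome.chrom.sizes")
    clinical = read_clinical_table(COHORT / "clinical.tsv").set_index("sample_id")
    tracks = load_tracks(COHORT / "tracks", layout)
    catalog = annotation.build_catalog(
        tracks["gene_model"], tracks["enhancer"], tracks["dhs"],
        tracks["cpg_island"], tracks["repeats"], layout,
    )

    overlaps, mapped, kept_frames, lengths = {}, {}, [], {"tumor": [], "normal": []}
    for sid, row in clinical.iterrows():
        frame = read_candidate_frame(COHORT / "samples" / f"{sid}.tsv", layout)
        kept, _ = apply_filters(frame)
        overlaps[sid] = annotation.annotate(kept, catalog)
        mapped[sid] = int(row["mapped_reads"])
        kept_frames.append(kept)
        lengths[row["tissue_label"]].append((kept["end"] - kept["start"]).to_numpy())

    matrix = features.quantify_cohort(overlaps, mapped)
    write_feature_matrix(matrix, ROOT / "features.tsv")

    summary = features.length_summary(
        {g: np.concatenate(v) for g, v in lengths.items()}, bin_bp=10
    )
    rows = []
    for g, d in summary["groups"].items():
        peaks = features.histogram_peaks(d["hist_counts"], d["hist_edges"])
        rows.append((g, d["n"], d["mean"], d["median"], peaks[0], peaks[-1]))
    pd.DataFrame(
        rows, columns=["group", "n", "mean_bp", "median_bp", "peak1_bp", "peak2_bp"]
    ).to_csv(ROOT / "length_summary.tsv", sep="\t", index=False)
    print("length summary:", rows, f"(rank-sum p = {summary['p_value']:.2e})")

    pooled = pd.concat(kept_frames, ignore_index=True)
    annotation.window_density(pooled, layout).to_csv(
        ROOT / "window_density.tsv", sep="\t", index=False
    )
    annotation.per_chromosome_proportions(pooled, layout).rename("proportion").to_csv(
        ROOT / "chromosome_proportions.tsv", sep="\t"
    )
    print(f"feature matrix {matrix.shape}; wrote results under {ROOT}")


if __name__ == "__main__":
    main()
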