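#!/usr/bin/env python
"""Apply the five acceptance criteria to every sample's candidate table.

Writes a per-sample filter summary and reports per-criterion failure
counts over the pooled cohort.
"""

from pathlib import Path

import pandas as pd

from ecckit.filters import CRITERIA, apply_filters
from ecckit.io_formats import read_candidate_frame, read_clinical_table, read_genome_layout

ROOT = Path(__file__).resolve().parent.parent / "results"
COHORT = ROOT / "cohort"


def main():
    if not COHORT.exists():
        raise SystemExit("run 01_simulate_cohort.py first")
    layout = read_genome_layout(COHORT / "tracks" / "genome.chrom.sizes")
    clinical = read_clinical_table(COHORT / "clinical.tsv")

    rows, failures = [], {c: 0 for c in CRITERIA}
    for sid in clinical["sample_id"]:
        frame = read_candidate_frame(COHORT / "samples" / f"{sid}.tsv", layout)
        kept, audit = apply_filters(frame)
        rows.append((sid, audit.n_input, audit.n_kept))
        for c in CRITERIA:
            failures[c] += audit.failure_counts[c]
    summary = pd.DataFrame(rows, columns=["sample_id", "n_input", "n_kept"])
    summary.to_csv(ROOT / "filter_summary.tsv", sep="\t", index=False)

    total_in, total_kept = summary["n_input"].sum(), summary["n_kept"].sum()
    print(f"kept {total_kept}/{total_in} candidates "
          f"({total_kept / total_in:.1%} pass rate)")
    print("failures per criterion:", failures)
    print(f"wrote {ROOT / 'filter_summary.tsv'}")


if __name__ == "__main__":
    main()
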