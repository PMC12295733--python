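#!/usr/bin/env python
"""Prognostic stage over the tumor arm: optimal-cutoff log-rank screen,
univariate Cox hazard-ratio table, and the DFS-event classifier.

Writes survival_screen.tsv, km_curves.tsv and prognostic_report.json.
"""

import json
from pathlib import Path

import pandas as pd

from ecckit.diagnostic import HarnessConfig
from ecckit.io_formats import read_clinical_table, read_feature_matrix
from ecckit.prognostic import km_estimate, prognostic_classifier, survival_screen

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 11


def main():
    matrix = read_feature_matrix(ROOT / "features.tsv")
    clinical = read_clinical_table(ROOT / "cohort" / "clinical.tsv").set_index("sample_id")
    tumor = clinical[clinical["tissue_label"] == "tumor"]
    followed = tumor["dfs_time"].notna()
    print(f"{int(followed.sum())} tumors with follow-up "
          f"({int((~followed).sum())} lost), "
          f"{int(tumor.loc[followed, 'dfs_event'].sum())} events")

    tm = matrix.loc[tumor.index[followed]]
    times = tumor.loc[followed, "dfs_time"].to_numpy(float)
    events = tumor.loc[followed, "dfs_event"].to_numpy(int)

    screen = survival_screen(tm, times, events)
    screen.to_csv(ROOT / "survival_screen.tsv", sep="\t", float_format="%.6g")
    sig = screen[screen["significant"]].sort_values("logrank_p")
    print(f"{len(sig)} features at (selection-biased) log-rank p < 0.05; top rows:")
    print(sig[["cutoff", "hazard_ratio", "hr_ci_low", "hr_ci_high", "logrank_p"]]
          .head(9).to_string())

    # KM curves for the strongest feature's high/low groups
    if len(sig):
        feat = sig.index[0]
        cut = sig.loc[feat, "cutoff"]
        high = tm[feat] > cut
        curves = []
        for name, mask in (("high", high), ("low", ~high)):
            km = km_estimate(times[mask.to_numpy()], events[mask.to_numpy()])
            km["group"] = name
            km["feature"] = feat
            curves.append(km)
        pd.concat(curves).to_csv(ROOT / "km_curves.tsv", sep="\t", index=False)

    report = prognostic_classifier(
        matrix.loc[tumor.index], tumor.reset_index(), HarnessConfig(seed=SEED)
    )
    print(f"prognostic model: {report['selected_model']}, "
          f"test AUC {report['test_metrics']['auc']:.3f}")
    (ROOT / "prognostic_report.json").write_text(json.dumps(
        {
            "selected_model": report["selected_model"],
            "cv_auc": report["cv_auc"],
            "test_metrics": report["test_metrics"],
            "n_excluded_lost_to_followup": report["n_excluded_lost_to_followup"],
        },
        indent=2, sort_keys=True,
    ))


if __name__ == "__main__":
    main()
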