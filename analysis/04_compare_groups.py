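#!/usr/bin/env python
"""Tumor-vs-normal rank-sum comparison of every feature (raw Wilcoxon p).

Writes wilcoxon.tsv and prints the most shifted features.
"""

from pathlib import Path

from ecckit.features import compare_groups
from ecckit.io_formats import read_clinical_table, read_feature_matrix

ROOT = Path(__file__).resolve().parent.parent / "results"


def main():
    matrix = read_feature_matrix(ROOT / "features.tsv")
    clinical = read_clinical_table(ROOT / "cohort" / "clinical.tsv").set_index("sample_id")
    labels = clinical.loc[matrix.index, "tissue_label"]
    table = compare_groups(matrix, labels)
    table.to_csv(ROOT / "wilcoxon.tsv", sep="\t", float_format="%.6g")
    n_sig = int((table["p_value"] < 0.05).sum())
    print(f"{n_sig}/{len(table)} features differ at p < 0.05")
    print(table.nsmallest(10, "p_value").to_string())


if __name__ == "__main__":
    main()
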