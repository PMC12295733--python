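"""Per-sample feature quantification and group-wise comparisons.

The default roster yields exactly 58 features per sample:

* ``total_per_million`` — eccDNA count scaled by 1e6 / mapped reads (1);
* for each of the 24 annotation categories, the per-million count and the
  proportion of eccDNA overlapping the category (48);
* raw overlap counts for nine categories of particular interest
  (gene, enhancer, DHS, all repeats, SINE, LINE, LTR, Alu, MIR) (9).

The roster is data, not code: an alternative enumeration can be passed to
every function that takes one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import CATEGORIES

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureDef",
    "default_roster",
    "roster_names",
    "quantify_sample",
    "quantify_cohort",
    "compare_groups",
    "length_summary",
    "histogram_peaks",
]

RAW_COUNT_CATEGORIES = (
    "gene", "enhancer", "dhs", "repeat_all", "sine", "line", "ltr", "alu", "mir",
)

KINDS = ("total_per_million", "count_per_million", "proportion", "raw_count")


@dataclass(frozen=True)
class FeatureDef:
    name: str
    kind: str
    category: str | None  # None only for total_per_million

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.kind != "total_per_million" and self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


def default_roster() -> list[FeatureDef]:
    """The default 58-feature roster."""
    roster = [FeatureDef("total_per_million", "total_per_million", None)]
    for cat in CATEGORIES:
        roster.append(FeatureDef(f"{cat}_per_million", "count_per_million", cat))
        roster.append(FeatureDef(f"{cat}_proportion", "proportion", cat))
    for cat in RAW_COUNT_CATEGORIES:
        roster.append(FeatureDef(f"{cat}_count", "raw_count", cat))
    names = [f.name for f in roster]
    assert len(roster) == 58 and len(set(names)) == 58
    return roster


def roster_names(roster: Sequence[FeatureDef] | None = None) -> list[str]:
    return [f.name for f in (roster or default_roster())]


def quantify_sample(
    overlap: pd.DataFrame,
    n_ecc: int,
    mapped_reads: int,
    roster: Sequence[FeatureDef] | None = None,
) -> pd.Series:
    """Compute the feature vector for one sample from its overlap matrix."""
    roster = roster or default_roster()
    if mapped_reads <= 0:
        raise ValueError("mapped_reads must be positive")
    if n_ecc != len(overlap):
        raise ValueError(f"n_ecc={n_ecc} does not match overlap rows ({len(overlap)})")
    if n_ecc == 0:
        logger.warning("sample has zero eccDNA; proportions reported as 0")

    counts = overlap.sum(axis=0) if n_ecc else pd.Series(0, index=overlap.columns)
    scale = 1e6 / mapped_reads
    values = {}
    for f in roster:
        if f.kind == "total_per_million":
            values[f.name] = n_ecc * scale
        elif f.kind == "count_per_million":
            values[f.name] = float(counts[f.category]) * scale
        elif f.kind == "proportion":
            values[f.name] = float(counts[f.category]) / n_ecc if n_ecc else 0.0
        else:  # raw_count
            values[f.name] = float(counts[f.category])
    return pd.Series(values, dtype=float)


def quantify_cohort(
    overlaps: Mapping[str, pd.DataFrame],
    mapped_reads: Mapping[str, int],
    roster: Sequence[FeatureDef] | None = None,
) -> pd.DataFrame:
    """Stack per-sample feature vectors into a samples x features matrix."""
    roster = roster or default_roster()
    rows = {
        sid: quantify_sample(ov, len(ov), int(mapped_reads[sid]), roster)
        for sid, ov in overlaps.items()
    }
    matrix = pd.DataFrame.from_dict(rows, orient="index")
    matrix.index.name = "sample_id"
    return matrix.loc[:, roster_names(roster)]


def _ranksum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Mann-Whitney/Wilcoxon rank-sum p with tie correction."""
    if np.ptp(np.concatenate([a, b])) == 0:
        return 1.0  # all values identical: no evidence of a shift
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)


def compare_groups(
    matrix: pd.DataFrame,
    labels: pd.Series | Sequence[str],
    adjust: str | None = None,
) -> pd.DataFrame:
    """Per-feature tumor-vs-normal rank-sum tests with group medians.

    No multiplicity adjustment by default; ``adjust='bh'`` appends
    Benjamini-Hochberg q-values.
    """
    labels = pd.Series(np.asarray(labels), index=matrix.index)
    groups = labels.unique()
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, got {list(groups)}")
    g1, g2 = sorted(groups)
    a_idx, b_idx = labels == g1, labels == g2
    if a_idx.sum() == 0 or b_idx.sum() == 0:
        raise ValueError("both groups must be non-empty")

    rows = []
    for name in matrix.columns:
        a = matrix.loc[a_idx, name].to_numpy(dtype=float)
        b = matrix.loc[b_idx, name].to_numpy(dtype=float)
        rows.append((name, float(np.median(a)), float(np.median(b)), _ranksum_p(a, b)))
    out = pd.DataFrame(rows, columns=["feature", f"median_{g1}", f"median_{g2}", "p_value"])
    if adjust == "bh":
        out["q_value"] = _bh_adjust(out["p_value"].to_numpy())
    elif adjust is not None:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return out.set_index("feature")


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def length_summary(
    lengths_by_group: Mapping[str, np.ndarray], bin_bp: int = 10
) -> dict:
    """Per-group mean eccDNA length, a fixed-width histogram, and the
    two-group rank-sum p-value (when exactly two groups are given)."""
    if bin_bp <= 0:
        raise ValueError("bin_bp must be positive")
    summary: dict = {"bin_bp": bin_bp, "groups": {}}
    arrays = {}
    for group, lengths in lengths_by_group.items():
        lengths = np.asarray(lengths, dtype=float)
        if lengths.size == 0:
            raise ValueError(f"group {group!r} is empty")
        arrays[group] = lengths
        edges = np.arange(0, lengths.max() + bin_bp, bin_bp)
        counts, edges = np.histogram(lengths, bins=edges)
        summary["groups"][group] = {
            "n": int(lengths.size),
            "mean": float(lengths.mean()),
            "median": float(np.median(lengths)),
            "hist_counts": counts,
            "hist_edges": edges,
        }
    if len(arrays) == 2:
        a, b = arrays.values()
        summary["p_value"] = _ranksum_p(a, b)
    return summary


def histogram_peaks(
    counts: np.ndarray, edges: np.ndarray, n_peaks: int = 2, min_separation_bp: float = 60
) -> list[float]:
    """Locate the ``n_peaks`` highest local maxima of a histogram (bin
    centers), enforcing a minimum separation; for inspecting the bimodal
    length profile."""
    centers = (edges[:-1] + edges[1:]) / 2
    order = np.argsort(counts)[::-1]
    peaks: list[float] = []
    for i in order:
        c = centers[i]
        if all(abs(c - p) >= min_separation_bp for p in peaks):
            peaks.append(float(c))
        if len(peaks) == n_peaks:
            break
    return sorted(peaks)
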