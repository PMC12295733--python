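"""Five-criterion acceptance filter for eccDNA candidate calls.

A candidate is kept only when all of the following hold:

  C1  split reads >= 2
  C2  split + discordant reads >= 3
  C3  caller score >= 50
  C4  breakpoint depth ratio > 0.33 at both breakpoints (min of the two,
      switchable to the mean)
  C5  uncovered-base fraction inside the circle < 0.1

C1-C3 use inclusive inequalities; the two coverage-derived criteria are
strict, exactly as the thresholds are stated. Candidates lacking the
coverage statistics pass C4/C5 in the default ``permissive`` mode (with a
logged warning) and fail them in ``strict`` mode.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import EccCandidate, candidates_from_frame, candidates_to_frame

logger = logging.getLogger(__name__)

__all__ = [
    "FilterThresholds",
    "FilterAudit",
    "CRITERIA",
    "apply_filters",
    "compute_coverage_stats",
]

CRITERIA = ("C1", "C2", "C3", "C4", "C5")


@dataclass(frozen=True)
class FilterThresholds:
    min_split_reads: int = 2
    min_total_support: int = 3
    min_score: float = 50.0
    min_breakpoint_depth_ratio: float = 0.33   # strict >
    max_uncovered_fraction: float = 0.1        # strict <

    def __post_init__(self):
        if self.min_split_reads < 0 or self.min_total_support < 0:
            raise ValueError("count thresholds must be non-negative")
        if not 0.0 <= self.min_breakpoint_depth_ratio <= 1.0:
            raise ValueError("min_breakpoint_depth_ratio outside [0, 1]")
        if not 0.0 <= self.max_uncovered_fraction <= 1.0:
            raise ValueError("max_uncovered_fraction outside [0, 1]")


@dataclass
class FilterAudit:
    """Per-candidate verdicts plus per-criterion failure counts.

    ``table`` has one row per input candidate, boolean columns C1..C5
    (True = criterion passed) and a ``kept`` column.
    """

    table: pd.DataFrame
    failure_counts: dict = field(default_factory=dict)

    @property
    def n_kept(self) -> int:
        return int(self.table["kept"].sum())

    @property
    def n_input(self) -> int:
        return len(self.table)

    def failed_criteria(self, idx) -> list[str]:
        row = self.table.loc[idx]
        return [c for c in CRITERIA if not row[c]]


def _criterion_masks(
    frame: pd.DataFrame,
    thresholds: FilterThresholds,
    missing_stats: str,
    breakpoint_mode: str,
) -> dict[str, np.ndarray]:
    split = frame["split_reads"].to_numpy()
    disc = frame["discordant_reads"].to_numpy()
    score = frame["score"].to_numpy(dtype=float)
    sdr = frame["start_depth_ratio"].to_numpy(dtype=float)
    edr = frame["end_depth_ratio"].to_numpy(dtype=float)
    unc = frame["uncovered_fraction"].to_numpy(dtype=float)

    if breakpoint_mode == "min":
        bp = np.fmin(sdr, edr)  # fmin: propagates a value when one side is NaN
    elif breakpoint_mode == "mean":
        bp = np.nanmean(np.vstack([sdr, edr]), axis=0)
    else:
        raise ValueError(f"breakpoint_mode must be 'min' or 'mean', got {breakpoint_mode!r}")

    bp_missing = np.isnan(sdr) & np.isnan(edr)
    unc_missing = np.isnan(unc)
    missing_pass = missing_stats == "permissive"
    if missing_stats not in ("permissive", "strict"):
        raise ValueError(f"missing_stats must be 'permissive' or 'strict', got {missing_stats!r}")
    if missing_pass and (bp_missing.any() or unc_missing.any()):
        logger.warning(
            "%d candidates lack breakpoint-depth and %d lack uncovered-fraction "
            "statistics; permissive mode skips C4/C5 for them",
            int(bp_missing.sum()), int(unc_missing.sum()),
        )

    with np.errstate(invalid="ignore"):
        c4 = bp > thresholds.min_breakpoint_depth_ratio
        c5 = unc < thresholds.max_uncovered_fraction
    c4 = np.where(bp_missing, missing_pass, c4)
    c5 = np.where(unc_missing, missing_pass, c5)

    return {
        "C1": split >= thresholds.min_split_reads,
        "C2": (split + disc) >= thresholds.min_total_support,
        "C3": score >= thresholds.min_score,
        "C4": c4.astype(bool),
        "C5": c5.astype(bool),
    }


def apply_filters(
    candidates,
    thresholds: FilterThresholds | None = None,
    *,
    missing_stats: str = "permissive",
    breakpoint_mode: str = "min",
):
    """Apply the five acceptance criteria.

    ``candidates`` may be a canonical candidate DataFrame or a sequence of
    :class:`~ecckit.io_formats.EccCandidate`; the kept set is returned in the
    same form, with relative input order preserved, alongside a
    :class:`FilterAudit`.
    """
    thresholds = thresholds or FilterThresholds()
    as_records = not isinstance(candidates, pd.DataFrame)
    frame = candidates_to_frame(list(candidates)) if as_records else candidates
    if frame.empty:
        audit = FilterAudit(
            pd.DataFrame(columns=[*CRITERIA, "kept"]),
            {c: 0 for c in CRITERIA},
        )
        return ([] if as_records else frame.copy()), audit

    masks = _criterion_masks(frame, thresholds, missing_stats, breakpoint_mode)
    kept_mask = np.logical_and.reduce([masks[c] for c in CRITERIA])

    table = pd.DataFrame({c: masks[c] for c in CRITERIA}, index=frame.index)
    table["kept"] = kept_mask
    audit = FilterAudit(table, {c: int((~masks[c]).sum()) for c in CRITERIA})

    kept_frame = frame.loc[kept_mask]
    if as_records:
        return candidates_from_frame(kept_frame.reset_index(drop=True)), audit
    return kept_frame, audit


def compute_coverage_stats(
    coverage: np.ndarray,
    left_flank: int,
    right_flank: int | None = None,
    window_bp: int = 100,
) -> tuple[float, float, float]:
    """Derive the two breakpoint depth ratios and the uncovered fraction.

    ``coverage`` is per-base depth over ``[start - left_flank, end +
    right_flank)`` of the candidate (flanks clipped at chromosome ends, so
    they may be shorter than ``window_bp``). The depth ratio at a breakpoint
    is ``(mean_in - mean_out) / mean_in`` over windows of up to ``window_bp``
    bases just inside and just outside it, clipped to [0, 1] and defined as 0
    when the inside mean is 0. The uncovered fraction is the share of
    zero-depth bases strictly inside the interval.
    """
    coverage = np.asarray(coverage, dtype=float)
    if right_flank is None:
        right_flank = left_flank
    if left_flank < 0 or right_flank < 0:
        raise ValueError("flanks must be non-negative")
    if (coverage < 0).any():
        raise ValueError("negative depth in coverage array")
    n_inside = coverage.size - left_flank - right_flank
    if n_inside <= 0:
        raise ValueError("coverage array shorter than interval plus flanks")
    inside = coverage[left_flank : left_flank + n_inside]
    win = min(window_bp, n_inside)

    def _ratio(mean_in: float, out: np.ndarray) -> float:
        if mean_in <= 0:
            return 0.0
        mean_out = float(out.mean()) if out.size else 0.0
        return float(np.clip((mean_in - mean_out) / mean_in, 0.0, 1.0))

    start_ratio = _ratio(
        float(inside[:win].mean()),
        coverage[max(0, left_flank - window_bp) : left_flank],
    )
    end_ratio = _ratio(
        float(inside[-win:].mean()),
        coverage[left_flank + n_inside : left_flank + n_inside + window_bp],
    )
    uncovered = float(np.count_nonzero(inside == 0) / n_inside)
    return start_ratio, end_ratio, uncovered
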