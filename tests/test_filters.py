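import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecckit.filters import (
    CRITERIA,
    FilterThresholds,
    apply_filters,
    compute_coverage_stats,
)
from ecckit.io_formats import CANDIDATE_COLUMNS


def make_frame(rows):
    """rows: (split, disc, score, sdr, edr, unc)."""
    data = []
    for i, (split, disc, score, sdr, edr, unc) in enumerate(rows):
        data.append(("chr1", i * 1000, i * 1000 + 500, disc, split, score,
                     10.0, 3.0, sdr, edr, unc))
    return pd.DataFrame(data, columns=list(CANDIDATE_COLUMNS))


def brute_force_verdicts(frame, t=FilterThresholds()):
    """Plain per-row re-statement of the five acceptance predicates."""
    verdicts = []
    for r in frame.itertuples(index=False):
        ratios = [x for x in (r.start_depth_ratio, r.end_depth_ratio) if not pd.isna(x)]
        ok = (
            r.split_reads >= t.min_split_reads
            and r.split_reads + r.discordant_reads >= t.min_total_support
            and r.score >= t.min_score
            and (not ratios or min(ratios) > t.min_breakpoint_depth_ratio)
            and (pd.isna(r.uncovered_fraction)
                 or r.uncovered_fraction < t.max_uncovered_fraction)
        )
        verdicts.append(ok)
    return np.asarray(verdicts)


class TestCoverageStats:
    def test_sharp_circle_gives_unit_ratios_and_full_coverage(self):
        cov = np.concatenate([np.zeros(100), np.full(500, 10.0), np.zeros(100)])
        sdr, edr, unc = compute_coverage_stats(cov, 100)
        assert (sdr, edr, unc) == (1.0, 1.0, 0.0)

    def test_flat_coverage_gives_zero_ratios(self):
        cov = np.full(700, 7.0)
        sdr, edr, unc = compute_coverage_stats(cov, 100)
        assert (sdr, edr) == (0.0, 0.0) and unc == 0.0

    def test_uncovered_fraction_counts_zero_depth_bases(self):
        inside = np.full(10, 5.0)
        inside[[2, 5, 8]] = 0.0
        cov = np.concatenate([np.full(4, 5.0), inside, np.full(4, 5.0)])
        assert compute_coverage_stats(cov, 4)[2] == pytest.approx(0.3)

    def test_zero_inside_depth_defines_ratio_zero(self):
        cov = np.concatenate([np.full(5, 3.0), np.zeros(10), np.full(5, 3.0)])
        sdr, edr, unc = compute_coverage_stats(cov, 5)
        assert sdr == 0.0 and edr == 0.0 and unc == 1.0

    def test_rejects_bad_arrays(self):
        with pytest.raises(ValueError, match="negative"):
            compute_coverage_stats(np.array([-1.0, 2.0, 3.0]), 0)
        with pytest.raises(ValueError, match="shorter"):
            compute_coverage_stats(np.ones(5), 3, 3)


class TestApplyFilters:
    @pytest.mark.parametrize(
        "row,kept,failed",
        [
            # boundary pass: inclusive on counts and score
            ((2, 1, 50.0, 0.34, 0.40, 0.05), True, []),
            ((1, 5, 90.0, 0.9, 0.9, 0.0), False, ["C1"]),
            # strict > on the depth ratio: 0.33 at one breakpoint fails
            ((3, 2, 80.0, 0.33, 0.50, 0.0), False, ["C4"]),
            # strict < on uncovered fraction
            ((3, 2, 80.0, 0.5, 0.5, 0.1), False, ["C5"]),
            ((2, 0, 80.0, 0.5, 0.5, 0.0), False, ["C2"]),
            ((3, 2, 49.99, 0.5, 0.5, 0.0), False, ["C3"]),
        ],
    )
    def test_criterion_boundaries(self, row, kept, failed):
        frame = make_frame([row])
        kept_frame, audit = apply_filters(frame)
        assert (len(kept_frame) == 1) is kept
        assert audit.failed_criteria(0) == failed

    def test_missing_stats_permissive_vs_strict(self):
        frame = make_frame([(3, 2, 80.0, np.nan, np.nan, np.nan)])
        kept, _ = apply_filters(frame, missing_stats="permissive")
        assert len(kept) == 1
        kept, audit = apply_filters(frame, missing_stats="strict")
        assert len(kept) == 0 and audit.failed_criteria(0) == ["C4", "C5"]

    def test_one_present_breakpoint_ratio_is_used(self):
        # min over breakpoints with one side missing: the present side decides
        frame = make_frame([(3, 2, 80.0, 0.2, np.nan, 0.0)])
        _, audit = apply_filters(frame)
        assert audit.failed_criteria(0) == ["C4"]

    def test_record_api_round_trips(self):
        from ecckit.io_formats import candidates_from_frame

        cands = candidates_from_frame(
            make_frame([(2, 1, 50.0, 0.4, 0.4, 0.0), (1, 1, 90.0, 0.9, 0.9, 0.0)])
        )
        kept, audit = apply_filters(cands)
        assert isinstance(kept, list) and len(kept) == 1
        assert audit.n_input == 2 and audit.n_kept == 1

    def test_empty_input_gives_empty_output(self):
        kept, audit = apply_filters(make_frame([]))
        assert len(kept) == 0 and audit.n_input == 0

    def test_matches_brute_force_on_simulated_candidates(self, default_cohort):
        table = next(iter(default_cohort.samples.values()))
        frame = table.loc[:, list(CANDIDATE_COLUMNS)]
        _, audit = apply_filters(frame)
        np.testing.assert_array_equal(
            audit.table["kept"].to_numpy(), brute_force_verdicts(frame)
        )


candidate_rows = st.tuples(
    st.integers(0, 6),                      # split
    st.integers(0, 6),                      # disc
    st.floats(0, 100, allow_nan=False),     # score
    st.floats(0, 1, allow_nan=False),       # sdr
    st.floats(0, 1, allow_nan=False),       # edr
    st.floats(0, 1, allow_nan=False),       # unc
)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(rows=st.lists(candidate_rows, min_size=1, max_size=25),
       d_split=st.integers(0, 2), d_score=st.floats(0, 30, allow_nan=False))
def test_tightening_thresholds_never_grows_kept_set(rows, d_split, d_score):
    frame = make_frame(rows)
    base = FilterThresholds()
    tight = FilterThresholds(
        min_split_reads=base.min_split_reads + d_split,
        min_score=base.min_score + d_score,
    )
    kept_base, audit_base = apply_filters(frame, base)
    kept_tight, _ = apply_filters(frame, tight)
    assert set(kept_tight.index) <= set(kept_base.index)
    # audit conservation and idempotence
    assert audit_base.n_kept + int((~audit_base.table["kept"]).sum()) == len(frame)
    re_kept, _ = apply_filters(kept_base, base)
    pd.testing.assert_frame_equal(re_kept, kept_base)
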