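"""Survival stage: Kaplan-Meier curves, log-rank tests, optimal-cutoff
binarization, univariate Cox hazard ratios, and a DFS-event classifier.

The optimal cutoff for a feature is the exhaustive log-rank scan: every
midpoint between consecutive sorted unique values inside the percentile
bounds is a candidate; the cutoff maximizing the two-group log-rank
statistic wins (ties to the lower cutoff). The naive log-rank p at the
selected cutoff is selection-biased — it is reported with an explicit flag
and an optional permutation-corrected p.

Kaplan-Meier estimation and Cox fits are delegated to lifelines (Efron tie
handling); the log-rank statistic inside the scan is computed here,
vectorized over event times.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats

from .diagnostic import HarnessConfig, run_harness

__all__ = [
    "CutpointResult",
    "CoxResult",
    "km_estimate",
    "logrank_statistic",
    "logrank_test",
    "optimal_cutpoint",
    "univariate_cox",
    "survival_screen",
    "prognostic_classifier",
]


@dataclass(frozen=True)
class CutpointResult:
    feature: str | None
    cutoff: float
    n_high: int
    n_low: int
    statistic: float
    p_value: float               # naive log-rank p at the selected cutoff
    selection_biased: bool = True
    p_permutation: float | None = None


@dataclass(frozen=True)
class CoxResult:
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    n_events: int
    converged: bool = True


def km_estimate(times, events) -> pd.DataFrame:
    """Product-limit survival estimate; columns time, survival."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("no records")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()})


def logrank_statistic(times, events, in_group_a) -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df) and its two-sided p.

    Vectorized over distinct event times; ``in_group_a`` is a boolean mask.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    a = np.asarray(in_group_a, dtype=bool)
    if events.sum() == 0:
        raise ValueError("log-rank undefined: no events in either group")

    event_times = np.unique(times[events == 1])
    # at-risk counts: subjects with time >= t
    order = np.sort(times)
    order_a = np.sort(times[a])
    n_at = times.size - np.searchsorted(order, event_times, side="left")
    n_at_a = a.sum() - np.searchsorted(order_a, event_times, side="left")
    # events at exactly t
    d = np.array([(times[events == 1] == t).sum() for t in event_times], dtype=float)
    d_a = np.array(
        [((times == t) & (events == 1) & a).sum() for t in event_times], dtype=float
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        expected = d * n_at_a / n_at
        var = d * (n_at_a / n_at) * (1 - n_at_a / n_at) * (n_at - d) / (n_at - 1)
    var = np.where(n_at > 1, var, 0.0)
    v = var.sum()
    if v <= 0:
        return 0.0, 1.0
    stat = float((d_a - expected).sum() ** 2 / v)
    return stat, float(stats.chi2.sf(stat, df=1))


def logrank_test(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Convenience wrapper over :func:`logrank_statistic` for two cohorts."""
    times = np.concatenate([np.asarray(times_a, float), np.asarray(times_b, float)])
    events = np.concatenate([np.asarray(events_a, int), np.asarray(events_b, int)])
    mask = np.zeros(times.size, dtype=bool)
    mask[: len(np.asarray(times_a))] = True
    return logrank_statistic(times, events, mask)


def _candidate_cutoffs(values, bounds, min_group_size):
    values = np.asarray(values, dtype=float)
    lo_q, hi_q = np.quantile(values, bounds)
    uniq = np.unique(values)
    mids = (uniq[:-1] + uniq[1:]) / 2
    out = []
    for c in mids:
        if not lo_q <= c <= hi_q:
            continue
        n_high = int((values > c).sum())
        n_low = values.size - n_high
        if n_high >= min_group_size and n_low >= min_group_size:
            out.append(float(c))
    return out


def optimal_cutpoint(
    values,
    times,
    events,
    bounds: tuple[float, float] = (0.10, 0.90),
    min_group_size: int = 3,
    feature: str | None = None,
    n_permutations: int = 0,
    rng: np.random.Generator | None = None,
) -> CutpointResult:
    """Exhaustive log-rank scan for the high/low binarization cutoff.

    Candidates are midpoints between consecutive sorted unique feature
    values whose quantile lies within ``bounds`` and whose groups both reach
    ``min_group_size``. Ties in the statistic break toward the lower cutoff.
    ``n_permutations > 0`` adds a permutation-corrected p (feature values
    shuffled, max statistic re-scanned).
    """
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if events.sum() < 1:
        raise ValueError("optimal cutpoint needs at least one event")

    def _scan(v):
        cands = _candidate_cutoffs(v, bounds, min_group_size)
        best = None
        for c in cands:
            stat, p = logrank_statistic(times, events, v > c)
            if best is None or stat > best[1]:
                best = (c, stat, p)
        return best

    best = _scan(values)
    if best is None:
        raise ValueError("no admissible cutoff (constant feature or groups too small)")
    cutoff, stat, p = best

    p_perm = None
    if n_permutations > 0:
        rng = rng or np.random.default_rng(0)
        exceed = 0
        for _ in range(n_permutations):
            hit = _scan(rng.permutation(values))
            if hit is not None and hit[1] >= stat:
                exceed += 1
        p_perm = (exceed + 1) / (n_permutations + 1)

    n_high = int((values > cutoff).sum())
    return CutpointResult(
        feature=feature,
        cutoff=float(cutoff),
        n_high=n_high,
        n_low=int(values.size - n_high),
        statistic=float(stat),
        p_value=float(p),
        p_permutation=p_perm,
    )


def univariate_cox(group_high, times, events) -> CoxResult:
    """Univariate Cox PH fit on a binary group indicator (Efron ties).

    Non-convergence (e.g. complete separation with no events in a group) is
    reported distinctly via ``converged=False`` and NaN estimates.
    """
    df = pd.DataFrame(
        {
            "group": np.asarray(group_high, dtype=float),
            "time": np.asarray(times, dtype=float),
            "event": np.asarray(events, dtype=int),
        }
    )
    if df["event"].sum() < 1:
        raise ValueError("Cox fit needs at least one event")
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
    except (ConvergenceError, np.linalg.LinAlgError):
        return CoxResult(float("nan"), float("nan"), float("nan"), float("nan"),
                         int(df["event"].sum()), converged=False)
    s = cph.summary.loc["group"]
    return CoxResult(
        hazard_ratio=float(s["exp(coef)"]),
        ci_low=float(s["exp(coef) lower 95%"]),
        ci_high=float(s["exp(coef) upper 95%"]),
        p_value=float(s["p"]),
        n_events=int(df["event"].sum()),
    )


def survival_screen(
    matrix: pd.DataFrame,
    times,
    events,
    p_threshold: float = 0.05,
    bounds: tuple[float, float] = (0.10, 0.90),
    min_group_size: int = 3,
    adjust: str | None = None,
) -> pd.DataFrame:
    """Per-feature optimal-cutoff log-rank screen plus univariate Cox on the
    binarized groups; one row per feature that admits a cutoff.

    Mirrors the hazard-ratio table layout: feature, cutoff, HR, CI, log-rank
    p (naive, selection-biased), Cox p, and a significance flag at
    ``p_threshold`` on the raw log-rank p (``adjust='bh'`` adds q-values).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    rows = []
    for name in matrix.columns:
        v = matrix[name].to_numpy(dtype=float)
        try:
            cp = optimal_cutpoint(v, times, events, bounds, min_group_size, feature=name)
        except ValueError:
            continue
        cox = univariate_cox(v > cp.cutoff, times, events)
        rows.append(
            (
                name, cp.cutoff, cp.n_high, cp.n_low, cp.statistic, cp.p_value,
                cox.hazard_ratio, cox.ci_low, cox.ci_high, cox.p_value, cox.converged,
            )
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "feature", "cutoff", "n_high", "n_low", "logrank_stat", "logrank_p",
            "hazard_ratio", "hr_ci_low", "hr_ci_high", "cox_p", "cox_converged",
        ],
    ).set_index("feature")
    if adjust == "bh":
        from .features import _bh_adjust

        out["logrank_q"] = _bh_adjust(out["logrank_p"].to_numpy())
    out["significant"] = out["logrank_p"] < p_threshold
    return out


def prognostic_classifier(
    matrix: pd.DataFrame,
    clinical: pd.DataFrame,
    config: HarnessConfig | None = None,
) -> dict:
    """DFS-event (1) vs event-free (0) classifier over tumor samples,
    reusing the diagnostic harness. Samples with missing follow-up are
    excluded; their count is reported in the result."""
    clin = clinical.set_index("sample_id").loc[matrix.index]
    followed = clin["dfs_time"].notna() & clin["dfs_event"].notna()
    n_excluded = int((~followed).sum())
    X = matrix.loc[followed]
    y = clin.loc[followed, "dfs_event"].to_numpy(dtype=int)
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("need at least 2 events and 2 non-events")
    config = config or HarnessConfig()
    # events are rare relative to the cohort: stratified folds can hold at
    # most one minority member each, so cap the fold count accordingly
    minority_train = int(min((y == 1).sum(), (y == 0).sum()) * config.split_ratio)
    if minority_train < config.cv_folds:
        import dataclasses
        import logging

        logging.getLogger(__name__).warning(
            "reducing CV folds from %d to %d (minority class too small)",
            config.cv_folds, max(2, minority_train),
        )
        config = dataclasses.replace(config, cv_folds=max(2, minority_train))
    report = run_harness(X, y, config)
    report["n_excluded_lost_to_followup"] = n_excluded
    return report
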