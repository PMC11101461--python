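"""Prognostic and diagnostic validation of candidate biomarkers.

Expression of each candidate is dichotomized around the cohort mean
(cutoffs mean ± 0.25·SD); the resulting low/high groups are compared by
Kaplan–Meier curves with a log-rank test, association with tumor stage is
assessed by a Pearson chi-square test on the group×stage contingency table
(no continuity correction, raw p-values), and diagnostic discrimination is
quantified by the ROC AUC computed as the Mann–Whitney rank statistic with
a fixed direction (higher score predicts case; an AUC below 0.5 is reported
as-is, never flipped).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats


@dataclass
class ExpressionGroups:
    """Low/high/excluded split of patients by expression.

    ``lower`` and ``upper`` are the cutoffs mean − δ·SD and mean + δ·SD.
    """

    group: pd.Series  # per patient: "low" | "high" | "excluded"
    lower: float
    upper: float


def dichotomize(values: pd.Series, delta: float = 0.25,
                mid: str = "exclude") -> ExpressionGroups:
    """Split patients into low/high expression around mean ± delta·SD.

    ``mid`` controls patients falling strictly between the two cutoffs:
    ``"exclude"`` leaves them out of the two-group comparison (default);
    ``"assign"`` sends them to the nearer side of the mean, yielding a
    single-cutoff split with no exclusions.  SD is the sample standard
    deviation (ddof=1).
    """
    values = pd.Series(values).astype(float)
    if len(values) < 3:
        raise ValueError("need at least 3 patients")
    sd = values.std(ddof=1)
    if sd == 0:
        raise ValueError("constant expression vector cannot be dichotomized")
    mu = values.mean()
    lower, upper = mu - delta * sd, mu + delta * sd
    group = pd.Series("excluded", index=values.index, dtype=object)
    group[values < lower] = "low"
    group[values > upper] = "high"
    if mid == "assign":
        group[(group == "excluded") & (values < mu)] = "low"
        group[group == "excluded"] = "high"
    elif mid != "exclude":
        raise ValueError("mid must be 'exclude' or 'assign'")
    return ExpressionGroups(group=group, lower=float(lower), upper=float(upper))


def km_estimate(times, events) -> pd.DataFrame:
    """Kaplan–Meier product-limit estimate.

    Returns a DataFrame with columns ``time`` and ``survival``; the curve is
    right-continuous, starts at 1 and is nonincreasing.  With every subject
    censored the curve stays flat at 1.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("no records")
    if (times <= 0).any():
        raise ValueError("survival times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(dtype=float),
                         "survival": sf.iloc[:, 0].to_numpy(dtype=float)})


def logrank(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p-value).

    Uses the hypergeometric-variance form with event times grouped for
    ties.  With no event in either group the test is undefined; returns
    (0, 1) with a warning.
    """
    times_a = np.asarray(times_a, dtype=float)
    times_b = np.asarray(times_b, dtype=float)
    events_a = np.asarray(events_a, dtype=int)
    events_b = np.asarray(events_b, dtype=int)
    if times_a.size == 0 or times_b.size == 0:
        raise ValueError("both groups must be nonempty")
    if events_a.sum() + events_b.sum() == 0:
        warnings.warn("no events in either group; log-rank undefined",
                      stacklevel=2)
        return 0.0, 1.0
    res = logrank_test(times_a, times_b, event_observed_A=events_a,
                       event_observed_B=events_b)
    return float(res.test_statistic), float(res.p_value)


def chi_square_association(groups: ExpressionGroups,
                           stages: pd.Series) -> tuple[float, float, int]:
    """Pearson chi-square of expression group vs tumor stage.

    Excluded patients are dropped; zero-margin rows/columns are removed with
    a warning.  Returns (statistic, p-value, degrees of freedom).
    """
    g = groups.group[groups.group != "excluded"]
    stages = pd.Series(stages).reindex(g.index)
    table = pd.crosstab(g, stages)
    empty_rows = table.sum(axis=1) == 0
    empty_cols = table.sum(axis=0) == 0
    if empty_rows.any() or empty_cols.any():
        warnings.warn("dropping zero-margin rows/columns from contingency table",
                      stacklevel=2)
        table = table.loc[~empty_rows, ~empty_cols]
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need >= 2 group levels and >= 2 stage levels")
    stat, p, dof, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
    return float(stat), float(p), int(dof)


def roc_auc(scores, labels) -> tuple[float, pd.DataFrame]:
    """ROC AUC by the Mann–Whitney rank statistic, plus the ROC points.

    ``labels`` are 1 for cases, 0 for controls.  AUC = P(score_case >
    score_control) + ½ P(tie), with the fixed convention that a higher
    score predicts a case — an anti-discriminating marker is reported with
    AUC < 0.5 rather than flipped.  The second return value holds the ROC
    curve as (fpr, tpr, threshold) rows.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_case = int((labels == 1).sum())
    n_ctrl = int((labels == 0).sum())
    if n_case == 0 or n_ctrl == 0:
        raise ValueError("both cases and controls are required")
    ranks = stats.rankdata(scores)  # midranks handle ties
    u = ranks[labels == 1].sum() - n_case * (n_case + 1) / 2.0
    auc = float(u / (n_case * n_ctrl))

    order = np.argsort(-scores, kind="stable")
    s_sorted, y_sorted = scores[order], labels[order]
    distinct = np.r_[np.flatnonzero(np.diff(s_sorted)), s_sorted.size - 1]
    tp = np.cumsum(y_sorted)[distinct]
    fp = np.cumsum(1 - y_sorted)[distinct]
    curve = pd.DataFrame({
        "fpr": np.r_[0.0, fp / n_ctrl],
        "tpr": np.r_[0.0, tp / n_case],
        "threshold": np.r_[np.inf, s_sorted[distinct]],
    })
    return auc, curve


def survival_validation(expression: pd.Series, clinical: pd.DataFrame,
                        delta: float = 0.25, mid: str = "exclude") -> dict:
    """Full prognostic panel for one candidate: dichotomize, log-rank, chi-square.

    ``clinical`` must have columns ``os_time_days``, ``os_event``,
    ``inss_stage`` indexed by patient ID matching ``expression``.
    """
    groups = dichotomize(expression, delta=delta, mid=mid)
    low = groups.group[groups.group == "low"].index
    high = groups.group[groups.group == "high"].index
    out: dict = {
        "n_low": int(len(low)),
        "n_high": int(len(high)),
        "n_excluded": int((groups.group == "excluded").sum()),
        "cutoff_low": groups.lower,
        "cutoff_high": groups.upper,
    }
    if len(low) and len(high):
        stat, p = logrank(
            clinical.loc[low, "os_time_days"], clinical.loc[low, "os_event"],
            clinical.loc[high, "os_time_days"], clinical.loc[high, "os_event"])
        out["logrank_stat"], out["logrank_p"] = stat, p
    try:
        chi, p, dof = chi_square_association(groups, clinical["inss_stage"])
        out["chisq_stat"], out["chisq_p"], out["chisq_dof"] = chi, p, dof
    except ValueError:
        out["chisq_stat"] = out["chisq_p"] = None
    return out
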