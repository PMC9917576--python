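"""Longitudinal summaries and correlation analyses over subject x timepoint tables.

Tables are tidy: one row per (subject_id, timepoint, parameter) with a
``value`` column. Paired contrasts use the classical paired t test
(complete-case); correlations are sample Pearson r with the two-sided
t-based p value on n-2 degrees of freedom. No multiple-testing correction
is applied and all p values are two-sided.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .errors import DataError

__all__ = ["paired_change", "pearson_with_p", "change_correlation",
           "summary_table", "pivot_parameter"]

_TIDY_COLUMNS = ("subject_id", "timepoint", "parameter", "value")


class PairedChange(NamedTuple):
    mean: float
    sd: float
    t: float
    p: float
    n: int
    degenerate: bool = False


class Correlation(NamedTuple):
    r: float
    p: float
    n: int


def _check_tidy(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _TIDY_COLUMNS if c not in records.columns]
    if missing:
        raise DataError(f"tidy cohort table lacks columns {missing}")
    return records


def pivot_parameter(records: pd.DataFrame, parameter: str) -> pd.DataFrame:
    """Wide subjects x timepoints view of one parameter."""
    _check_tidy(records)
    sub = records[records["parameter"] == parameter]
    if sub.empty:
        raise DataError(f"parameter {parameter!r} absent from the table")
    dup = sub.duplicated(["subject_id", "timepoint"])
    if dup.any():
        raise DataError(
            f"duplicate (subject_id, timepoint) rows for {parameter!r}")
    return sub.pivot(index="subject_id", columns="timepoint", values="value")


def paired_change(records: pd.DataFrame, parameter: str,
                  t_from: str, t_to: str) -> PairedChange:
    """Complete-case paired differences (t_to - t_from) with a paired t test.

    A constant difference (SD = 0) is degenerate for the t statistic; the
    result is flagged and p is reported as 0.0 for a nonzero mean change
    (the statistic diverges) and 1.0 for an all-zero change.
    """
    wide = pivot_parameter(records, parameter)
    for tp in (t_from, t_to):
        if tp not in wide.columns:
            raise DataError(f"timepoint {tp!r} absent for {parameter!r}")
    pairs = wide[[t_from, t_to]].dropna()
    n = len(pairs)
    if n < 2:
        raise DataError(
            f"paired_change needs >= 2 complete pairs, got {n}")
    delta = (pairs[t_to] - pairs[t_from]).to_numpy(dtype=float)
    mean = float(delta.mean())
    sd = float(delta.std(ddof=1))
    if sd == 0.0:
        p = 1.0 if mean == 0.0 else 0.0
        t = 0.0 if mean == 0.0 else float(np.inf * np.sign(mean))
        return PairedChange(mean, sd, t, p, n, degenerate=True)
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * _stats.t.sf(abs(t), df=n - 1)
    return PairedChange(mean, sd, float(t), float(p), n)


def pearson_with_p(x, y) -> Correlation:
    """Sample Pearson r with the two-sided t-based p value (df = n - 2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("x and y must be 1-d arrays of equal length")
    if x.size < 3:
        raise DataError(f"pearson_with_p needs n >= 3, got n = {x.size}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise DataError("pearson_with_p requires finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DataError("pearson_with_p: zero variance in x or y")
    res = _stats.pearsonr(x, y)
    return Correlation(r=float(res.statistic), p=float(res.pvalue), n=x.size)


def change_correlation(records: pd.DataFrame, param_a: str, param_b: str,
                       t_from: str, t_to: str) -> Correlation:
    """Pearson correlation between the changes of two parameters.

    Changes are (t_to - t_from) per subject, complete-case over subjects
    observed at both timepoints for both parameters.
    """
    wa = pivot_parameter(records, param_a)
    wb = pivot_parameter(records, param_b)
    for w, p in ((wa, param_a), (wb, param_b)):
        for tp in (t_from, t_to):
            if tp not in w.columns:
                raise DataError(f"timepoint {tp!r} absent for {p!r}")
    da = (wa[t_to] - wa[t_from]).rename("da")
    db = (wb[t_to] - wb[t_from]).rename("db")
    both = pd.concat([da, db], axis=1).dropna()
    return pearson_with_p(both["da"].to_numpy(), both["db"].to_numpy())


def summary_table(records: pd.DataFrame,
                  timepoints: list[str] | None = None,
                  baseline: str = "1999",
                  pretreat: str = "0M") -> pd.DataFrame:
    """Per-parameter mean +/- SD per timepoint with paired p values.

    One tidy row per (parameter, timepoint) carrying mean, sd, n, and -
    where at least two timepoints exist - the paired p of that timepoint
    against the decade-earlier baseline and against the pre-treatment
    timepoint. p columns are omitted entirely for single-timepoint tables.
    """
    _check_tidy(records)
    if records.empty:
        raise DataError("summary_table: empty records")
    if timepoints is None:
        timepoints = list(pd.unique(records["timepoint"]))
    params = list(pd.unique(records["parameter"]))
    single = len(timepoints) < 2
    rows = []
    for param in params:
        wide = pivot_parameter(records, param)
        for tp in timepoints:
            if tp not in wide.columns:
                continue
            vals = wide[tp].dropna()
            row = {"parameter": param, "timepoint": tp,
                   "mean": float(vals.mean()),
                   "sd": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
                   "n": int(len(vals))}
            if not single:
                for ref, col in ((baseline, "p_vs_baseline"),
                                 (pretreat, "p_vs_pretreat")):
                    row[col] = np.nan
                    if tp != ref and ref in wide.columns:
                        try:
                            row[col] = paired_change(records, param, ref, tp).p
                        except DataError:
                            pass
            rows.append(row)
    return pd.DataFrame(rows)
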