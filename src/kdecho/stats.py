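"""Cohort-level statistics: group x day summaries, dose/time comparisons,
vessel correlations and the percent-Z classification table.

The comparisons mirror a conventional small-animal echo analysis: values
are reported as mean +/- SEM per dose group and day, pairwise group
contrasts use the pooled-variance two-tailed Student's t-test (Welch
available behind a flag), associations use the Pearson product-moment
correlation with a t-transform p-value, and no multiple-testing correction
is applied (the number of tests performed is reported alongside).
Missing values are dropped cellwise/pairwise, never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .normative import percent_above

ALPHA = 0.05


@dataclass(frozen=True)
class GroupDaySummary:
    """Per dose-group x day aggregate of one measurement."""

    group: str
    day: int
    measurement: str
    n: int
    mean: float
    sem: float  # NaN when n == 1
    percent_z_gt_cutoff: Optional[float] = None


@dataclass(frozen=True)
class TTestResult:
    """Two-tailed Student's t contrast between two groups at one day."""

    group_a: str
    group_b: str
    measurement: str
    day: int
    t: float
    df: float
    p: float
    significant: bool  # p <= ALPHA


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation between two variables at one day."""

    x_name: str
    y_name: str
    n: int
    r: float
    p: float


def summarize(
    df: pd.DataFrame,
    measurement: str,
    z_col: str | None = None,
    cutoff: float = 3.0,
) -> pd.DataFrame:
    """Mean, SEM and n per (group, day) cell, dropping missing values.

    Cells with no data are absent from the output (never reported as 0);
    single-value cells carry a missing SEM.  When ``z_col`` is given, the
    percent of Z-scores strictly above ``cutoff`` is added per cell.
    """
    rows: list[GroupDaySummary] = []
    for (group, day), sub in df.groupby(["group", "day"], sort=True):
        vals = sub[measurement].dropna().to_numpy(dtype=float)
        if vals.size == 0:
            continue
        sem = float(np.std(vals, ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else float("nan")
        pct = None
        if z_col is not None:
            z = sub[z_col].to_numpy(dtype=float)
            pct = percent_above(z, cutoff) if np.isfinite(z).any() else None
        rows.append(
            GroupDaySummary(str(group), int(day), measurement,
                            int(vals.size), float(np.mean(vals)), sem, pct)
        )
    out = pd.DataFrame([r.__dict__ for r in rows])
    if z_col is None and not out.empty:
        out = out.drop(columns=["percent_z_gt_cutoff"])
    return out


def two_sample_t(
    df: pd.DataFrame,
    group_a: str,
    group_b: str,
    measurement: str,
    day: int,
    welch: bool = False,
) -> TTestResult:
    """Two-tailed Student's t-test between two groups at one study day.

    Pooled-variance by default (df = n_a + n_b - 2); ``welch=True`` uses
    the unequal-variance form.  Significance is declared at p <= 0.05.
    """
    a = df.loc[(df["group"] == group_a) & (df["day"] == day), measurement].dropna()
    b = df.loc[(df["group"] == group_b) & (df["day"] == day), measurement].dropna()
    if len(a) < 2 or len(b) < 2:
        raise ValueError(
            f"two_sample_t needs >= 2 values per group "
            f"(got {len(a)} in {group_a!r}, {len(b)} in {group_b!r} at day {day})"
        )
    res = sps.ttest_ind(a.to_numpy(), b.to_numpy(), equal_var=not welch)
    return TTestResult(
        group_a, group_b, measurement, int(day),
        float(res.statistic), float(res.df), float(res.pvalue),
        bool(res.pvalue <= ALPHA),
    )


def pearson_corr(
    df: pd.DataFrame, x_name: str, y_name: str, day: int | None = None
) -> CorrelationResult:
    """Pearson r between two columns (optionally at one day), pairwise-complete.

    The two-tailed p-value uses the t-transform with n - 2 degrees of
    freedom.
    """
    sub = df if day is None else df.loc[df["day"] == day]
    pairs = sub[[x_name, y_name]].dropna()
    if len(pairs) < 3:
        raise ValueError("pearson_corr needs >= 3 complete pairs")
    x = pairs[x_name].to_numpy(dtype=float)
    y = pairs[y_name].to_numpy(dtype=float)
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise ValueError("pearson_corr: zero variance in an input variable")
    res = sps.pearsonr(x, y)
    return CorrelationResult(x_name, y_name, len(pairs),
                             float(res.statistic), float(res.pvalue))


@dataclass(frozen=True)
class DoseResponse:
    """Group means per day, ordered by dose rank, with monotonicity flags."""

    measurement: str
    means: pd.DataFrame  # rows = day, columns = groups in dose order
    monotone: dict[int, bool]  # day -> means non-decreasing in dose rank
    single_group: bool


def dose_response_table(
    df: pd.DataFrame,
    measurement: str,
    dose_by_group: Mapping[str, float],
) -> DoseResponse:
    """Group-mean table ordered by dose rank and a per-day monotonicity flag.

    The flag at a day is True iff the cell means are non-decreasing in
    dose rank (vacuously true with a single group).
    """
    order = [g for g, _ in sorted(dose_by_group.items(), key=lambda kv: kv[1])]
    present = [g for g in order if (df["group"] == g).any()]
    if len(present) == 0:
        raise ValueError("dose_response_table: no configured group present")
    summaries = summarize(df[df["group"].isin(present)], measurement)
    means = summaries.pivot(index="day", columns="group", values="mean")
    means = means.reindex(columns=present)
    monotone: dict[int, bool] = {}
    for day, row in means.iterrows():
        vals = row.dropna().to_numpy(dtype=float)
        monotone[int(day)] = bool(np.all(np.diff(vals) >= 0)) if vals.size else True
    return DoseResponse(measurement, means, monotone, len(present) == 1)


def percent_z_table(
    scored: pd.DataFrame,
    z_col: str,
    cutoff: float = 3.0,
    groups: Sequence[str] | None = None,
    days: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Percent of Z > cutoff per dose group (rows) and day (columns)."""
    groups = list(groups) if groups is not None else sorted(scored["group"].unique())
    days = list(days) if days is not None else sorted(scored["day"].unique())
    table = pd.DataFrame(index=pd.Index(groups, name="group"),
                         columns=pd.Index(days, name="day"), dtype=float)
    for g in groups:
        for d in days:
            z = scored.loc[
                (scored["group"] == g) & (scored["day"] == d), z_col
            ].to_numpy(dtype=float)
            if np.isfinite(z).any():
                table.loc[g, d] = percent_above(z, cutoff)
    return table
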