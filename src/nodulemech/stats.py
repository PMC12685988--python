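"""Cohort summaries: stress quartile tables, CS/CE summaries, CT
correlations, and two-group contrasts.

Quantiles use linear interpolation of order statistics (the default
convention of R, where the source analyses of this kind are typically run,
and of numpy).  Ratio rows of the quartile table are computed from the
unrounded statistics; rounding is display-only and kept separable.  p
values are reported raw, without multiple-testing correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .mechanics import StiffnessProfile, StressStrainCurve

QUANTILE_METHOD = "linear"  # R type 7

STAT_ROWS = (
    "maximum",
    "p75",
    "median",
    "p25",
    "minimum",
    "p75_over_p25",
    "max_over_min",
    "n",
)


def quartile_ratios(p25: float, p75: float, minimum: float, maximum: float) -> tuple[float, float]:
    """Ratio rows of the stress table: (p75/p25, max/min).

    A zero denominator (a curve still at zero stress at that strain) yields
    an infinite ratio rather than an error.
    """
    iqr_ratio = p75 / p25 if p25 > 0 else float("inf")
    range_ratio = maximum / minimum if minimum > 0 else float("inf")
    return iqr_ratio, range_ratio


def stress_quartile_table(
    curves: Sequence[StressStrainCurve],
    increment: float = 0.05,
    max_strain: float = 0.70,
) -> pd.DataFrame:
    """Quartile distribution of stress across curves at every grid strain.

    Rows: maximum, p75, median, p25, minimum, the two ratio rows and the
    number of contributing curves; columns: strain grid points from
    ``increment`` to ``max_strain``.  A curve contributes to a column iff it
    reaches that strain; columns with no contributing curve are omitted.
    """
    if not curves:
        raise ValueError("empty cohort: no curves to summarize")
    grid = np.round(
        np.arange(increment, max_strain + increment / 2, increment), 10
    )
    columns: dict[float, list[float]] = {}
    for point in grid:
        values = [
            float(np.interp(point, c.strain, c.stress_mpa))
            for c in curves
            if c.max_strain >= point - 1e-9
        ]
        if values:
            columns[float(point)] = values
    table = {}
    for point, values in columns.items():
        arr = np.asarray(values)
        q25, q50, q75 = np.quantile(arr, [0.25, 0.5, 0.75], method=QUANTILE_METHOD)
        ratio_iqr, ratio_range = quartile_ratios(q25, q75, arr.min(), arr.max())
        table[point] = [
            arr.max(),
            q75,
            q50,
            q25,
            arr.min(),
            ratio_iqr,
            ratio_range,
            float(arr.size),
        ]
    return pd.DataFrame(table, index=list(STAT_ROWS))


@dataclass(frozen=True)
class SummaryRow:
    """Median [p25, p75] of one stiffness parameter across the cohort."""

    parameter: str
    median: float
    p25: float
    p75: float
    n: int


def stiffness_summary(
    profiles: Sequence[StiffnessProfile] | pd.DataFrame,
    parameters: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Median and IQR of each CS/CE parameter over non-missing values.

    Accepts either a list of :class:`StiffnessProfile` or a results-style
    DataFrame with CS*/CE* columns (e.g. a supplementary table re-analysis).
    Parameters with no non-missing value are omitted with a warning.
    """
    if isinstance(profiles, pd.DataFrame):
        frame = profiles
        if parameters is None:
            parameters = [
                c for c in frame.columns if c.startswith(("CS", "CE")) and c[2:].isdigit()
            ]
    else:
        records = {}
        for p in profiles:
            row = {}
            for level in p.levels:
                row[f"CS{round(level * 100):d}"] = p.cs(level)
                row[f"CE{round(level * 100):d}"] = p.ce(level)
            records[p.nodule_id] = row
        frame = pd.DataFrame.from_dict(records, orient="index")
        if parameters is None:
            parameters = list(frame.columns)
    rows = []
    for name in parameters:
        values = pd.to_numeric(frame[name], errors="coerce").dropna().to_numpy()
        if values.size == 0:
            warnings.warn(f"parameter {name}: all values missing; omitted", stacklevel=2)
            continue
        q25, q50, q75 = np.quantile(values, [0.25, 0.5, 0.75], method=QUANTILE_METHOD)
        rows.append(
            {"parameter": name, "median": q50, "p25": q25, "p75": q75, "n": values.size}
        )
    return pd.DataFrame(rows, columns=["parameter", "median", "p25", "p75", "n"])


def correlate_with_ct(
    results: pd.DataFrame,
    parameters: Sequence[str] | None = None,
    ct_column: str = "ct_hu",
) -> pd.DataFrame:
    """Pearson correlation of each stiffness parameter with the mean CT
    number, with two-sided p from the t transform.

    Pairs with a missing value in either variable are excluded listwise per
    parameter; parameters with fewer than 3 complete pairs are omitted with
    a warning.
    """
    if parameters is None:
        parameters = [
            c for c in results.columns if c.startswith(("CS", "CE")) and c[2:].isdigit()
        ]
    ct = pd.to_numeric(results[ct_column], errors="coerce")
    rows = []
    for name in parameters:
        x = pd.to_numeric(results[name], errors="coerce")
        mask = x.notna() & ct.notna()
        n = int(mask.sum())
        if n < 3:
            warnings.warn(
                f"parameter {name}: only {n} complete pairs; correlation omitted",
                stacklevel=2,
            )
            continue
        r, p = sps.pearsonr(x[mask], ct[mask])
        rows.append({"parameter": name, "r": float(r), "p": float(p), "n": n})
    return pd.DataFrame(rows, columns=["parameter", "r", "p", "n"])


@dataclass(frozen=True)
class GroupComparison:
    """Two-group contrast result (Fisher's exact or Mann-Whitney U)."""

    test: str
    statistic: float
    p_value: float
    group_summaries: dict[str, float]
    table: tuple[tuple[int, int], tuple[int, int]] | None = None


def compare_groups(labels: Sequence, outcome: Sequence) -> GroupComparison:
    """Contrast an outcome between the two groups defined by ``labels``.

    Boolean outcome: two-sided Fisher's exact test on the 2x2 table, with
    per-group proportions.  Continuous outcome: two-sided Mann-Whitney U
    (normal approximation with tie correction), with group medians.
    """
    labels = np.asarray(labels)
    outcome = np.asarray(outcome)
    groups = pd.unique(labels)
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {list(groups)}")
    in_a, in_b = labels == groups[0], labels == groups[1]
    if not in_a.any() or not in_b.any():
        raise ValueError("one group is empty")

    if outcome.dtype == bool or set(np.unique(outcome)) <= {0, 1, True, False}:
        out = outcome.astype(bool)
        table = (
            (int((in_a & out).sum()), int((in_a & ~out).sum())),
            (int((in_b & out).sum()), int((in_b & ~out).sum())),
        )
        res = sps.fisher_exact(table, alternative="two-sided")
        summaries = {
            str(groups[0]): out[in_a].mean(),
            str(groups[1]): out[in_b].mean(),
        }
        return GroupComparison(
            test="fisher_exact",
            statistic=float(res.statistic),
            p_value=float(res.pvalue),
            group_summaries=summaries,
            table=table,
        )

    a, b = outcome[in_a].astype(float), outcome[in_b].astype(float)
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    summaries = {
        str(groups[0]): float(np.median(a)),
        str(groups[1]): float(np.median(b)),
    }
    return GroupComparison(
        test="mann_whitney_u",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        group_summaries=summaries,
    )


def display_round(frame: pd.DataFrame, decimals: int = 2) -> pd.DataFrame:
    """Round a numeric table for display.  Kept separate from computation:
    ratio rows are always ratios of unrounded statistics."""
    return frame.round(decimals)
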