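"""Correlation-level twin statistics.

Within-twin Pearson correlations by zygosity (pairs ordered by birth
order, no double entry), the Fisher r-to-z two-sample comparison of an
MZ against a DZ correlation, Bonferroni-corrected correlation tables for
the scanner-distress ratings, and a one-way repeated-measures ANOVA for
distress across the three measurement moments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ace_model import TwinPairTable
from .errors import DegenerateDataError, InsufficientDataError, ValidationError


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    p: float


@dataclass(frozen=True)
class FisherZResult:
    z: float
    p: float
    r1: float
    n1: int
    r2: float
    n2: int


def _pearson(x: np.ndarray, y: np.ndarray) -> CorrelationResult:
    if x.size < 3:
        raise InsufficientDataError("need at least 3 complete cases")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(r=float(r), n=int(x.size), p=float(p))


def within_twin_correlation(
    pairs: TwinPairTable, zygosity: str, double_entry: bool = False
) -> CorrelationResult:
    """Pearson correlation between twin 1 and twin 2 of one zygosity group.

    With ``double_entry=True`` every pair enters twice in both orders
    (an intraclass-style sensitivity variant; the reported n stays the
    number of pairs).
    """
    if zygosity == "MZ":
        arr = pairs.mz
    elif zygosity == "DZ":
        arr = pairs.dz
    else:
        raise ValidationError(f"unknown zygosity: {zygosity!r}")
    if arr.shape[0] < 3 or arr.size == 0:
        raise InsufficientDataError("need at least 3 complete pairs")
    x, y = arr[:, 0], arr[:, 1]
    if double_entry:
        res = _pearson(np.concatenate([x, y]), np.concatenate([y, x]))
        return CorrelationResult(r=res.r, n=arr.shape[0], p=res.p)
    return _pearson(x, y)


def fisher_z_compare(r1: float, n1: int, r2: float, n2: int) -> FisherZResult:
    """Two-sample comparison of independent correlations via Fisher's z.

    z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)), referred to
    the standard normal (two-sided p).
    """
    for r in (r1, r2):
        if abs(r) >= 1.0:
            raise ValidationError("|r| must be < 1 for the Fisher transform")
    for n in (n1, n2):
        if n <= 3:
            raise InsufficientDataError("need n > 3 in both groups")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = 2.0 * stats.norm.sf(abs(z))
    return FisherZResult(z=float(z), p=float(p), r1=r1, n1=n1, r2=r2, n2=n2)


def bonferroni_correlations(
    distress: pd.DataFrame, outcome: pd.Series, m_tests: int = 6
) -> pd.DataFrame:
    """Correlate each distress column with an outcome, Bonferroni-flagged.

    Each correlation uses pairwise-complete cases and is flagged
    significant iff p < 0.05 / m_tests (the family-wise 5% level across
    the six distress estimates by default, adjusted alpha ~= 0.0083).
    """
    if m_tests < 1:
        raise ValidationError("m_tests must be >= 1")
    alpha = 0.05 / m_tests
    rows = []
    for col in distress.columns:
        mask = distress[col].notna() & outcome.notna()
        res = _pearson(
            distress.loc[mask, col].to_numpy(dtype=float),
            outcome.loc[mask].to_numpy(dtype=float),
        )
        rows.append(
            {
                "measure": col,
                "r": res.r,
                "n": res.n,
                "p": res.p,
                "alpha_adjusted": alpha,
                "significant": res.p < alpha,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class RepeatedMeasuresResult:
    f: float
    df_effect: int
    df_error: int
    p: float
    pairwise: pd.DataFrame  # Bonferroni-corrected paired follow-ups


def repeated_measures_f(values: np.ndarray) -> RepeatedMeasuresResult:
    """One-way within-subject ANOVA over k repeated timepoints.

    ``values`` is subjects x timepoints; rows with any missing value are
    dropped (listwise).  F has (k-1, (k-1)(n-1)) degrees of freedom.
    Follow-ups are all pairwise paired t-tests with Bonferroni-corrected
    p-values.  Data with zero within-subject error variance are rejected
    rather than reported as an unbounded F.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[1] < 2:
        raise ValidationError("values must be subjects x timepoints with k >= 2")
    values = values[~np.isnan(values).any(axis=1)]
    n, k = values.shape
    if n < 3:
        raise InsufficientDataError("need at least 3 complete subjects")

    grand = values.mean()
    ss_time = n * ((values.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((values.mean(axis=1) - grand) ** 2).sum()
    ss_total = ((values - grand) ** 2).sum()
    ss_error = ss_total - ss_time - ss_subj
    tiny = 1e-12 * max(ss_total, 1.0)
    if ss_error <= tiny:
        if ss_time <= tiny:
            # every subject flat over time: no effect, no error -> F = 0
            pairwise = pd.DataFrame(
                [
                    {"timepoint_a": i, "timepoint_b": j, "mean_diff": 0.0,
                     "t": 0.0, "p_bonferroni": 1.0}
                    for i in range(k) for j in range(i + 1, k)
                ]
            )
            return RepeatedMeasuresResult(
                f=0.0, df_effect=k - 1, df_error=(k - 1) * (n - 1), p=1.0,
                pairwise=pairwise,
            )
        raise DegenerateDataError("zero within-subject error variance: F unbounded")

    from statsmodels.stats.anova import AnovaRM

    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n), k),
            "time": np.tile(np.arange(k), n),
            "value": values.ravel(),
        }
    )
    table = AnovaRM(long, depvar="value", subject="subject", within=["time"]).fit()
    row = table.anova_table.iloc[0]
    f = float(row["F Value"])
    df_effect, df_error = int(row["Num DF"]), int(row["Den DF"])
    p = float(row["Pr > F"])

    m = k * (k - 1) // 2
    follow = []
    for i in range(k):
        for j in range(i + 1, k):
            t, p_raw = stats.ttest_rel(values[:, i], values[:, j])
            follow.append(
                {
                    "timepoint_a": i,
                    "timepoint_b": j,
                    "mean_diff": float(values[:, i].mean() - values[:, j].mean()),
                    "t": float(t),
                    "p_bonferroni": float(min(1.0, p_raw * m)),
                }
            )
    return RepeatedMeasuresResult(
        f=f, df_effect=df_effect, df_error=df_error, p=p,
        pairwise=pd.DataFrame(follow),
    )
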