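"""Normality-routed two-group comparisons and Pearson correlation screening.

Each biomarker comparison runs a Shapiro–Wilk normality test on both samples:
if both p-values exceed the normality alpha (0.05) a two-sided two-sample
t test (Welch form by default) is applied, otherwise the Wilcoxon rank-sum
test.  The rank-sum test is evaluated exactly when both samples have at most
20 observations and by the continuity-corrected normal approximation
otherwise.  No multiple-testing correction is applied; raw p-values are
reported per biomarker and region.

Correlation screening computes pairwise Pearson r over complete cases and
flags signed r > 0.3 as moderate-to-strong; negative correlations are reported
but never flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["GroupComparison", "CorrelationReport", "compare_groups", "correlation_screen"]

MODERATE_R = 0.3


@dataclass
class GroupComparison:
    biomarker: str
    region: str
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    n_a: int
    n_b: int
    shapiro_p_a: float
    shapiro_p_b: float
    test: str  # 't' | 'wilcoxon'
    statistic: float
    p_value: float

    def as_dict(self) -> Dict[str, object]:
        return self.__dict__.copy()


@dataclass
class CorrelationReport:
    var_a: str
    var_b: str
    r: float
    n: int
    flagged_moderate: bool
    note: str = ""

    def as_dict(self) -> Dict[str, object]:
        return self.__dict__.copy()


def compare_groups(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    normality_alpha: float = 0.05,
    biomarker: str = "",
    region: str = "",
    equal_var: bool = False,
) -> GroupComparison:
    """Shapiro–Wilk-routed two-group test.

    Both samples normal (p > ``normality_alpha``) -> two-sided t test
    (Welch unless ``equal_var``); otherwise the Wilcoxon rank-sum test.
    Requires n >= 3 per group (the normality test is undefined below that).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each sample needs at least 3 observations")
    pa = float(sps.shapiro(a).pvalue) if np.ptp(a) > 0 else 0.0
    pb = float(sps.shapiro(b).pvalue) if np.ptp(b) > 0 else 0.0
    if pa > normality_alpha and pb > normality_alpha:
        res = sps.ttest_ind(a, b, equal_var=equal_var)
        test = "t"
    else:
        pooled = np.concatenate([a, b])
        has_ties = np.unique(pooled).size < pooled.size
        method = "exact" if max(a.size, b.size) <= 20 and not has_ties else "asymptotic"
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
        test = "wilcoxon"
    return GroupComparison(
        biomarker=biomarker,
        region=region,
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)),
        mean_b=float(b.mean()),
        sd_b=float(b.std(ddof=1)),
        n_a=int(a.size),
        n_b=int(b.size),
        shapiro_p_a=pa,
        shapiro_p_b=pb,
        test=test,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
    )


def correlation_screen(
    records: pd.DataFrame, columns: Optional[Sequence[str]] = None
) -> List[CorrelationReport]:
    """Pairwise Pearson correlations over complete cases.

    ``records`` is a biomarker table (one row per eye/scan/region); numeric
    columns are screened unless ``columns`` narrows the set.  Pairs with fewer
    than 3 complete observations or a zero-variance member report r = NaN with
    a note.
    """
    df = records[list(columns)] if columns is not None else records.select_dtypes("number")
    reports: List[CorrelationReport] = []
    for va, vb in combinations(df.columns, 2):
        sub = df[[va, vb]].dropna()
        n = len(sub)
        if n < 3:
            reports.append(CorrelationReport(va, vb, float("nan"), n, False, "fewer than 3 complete cases"))
            continue
        x, y = sub[va].to_numpy(), sub[vb].to_numpy()
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            reports.append(CorrelationReport(va, vb, float("nan"), n, False, "zero-variance variable"))
            continue
        r = float(sps.pearsonr(x, y).statistic)
        note = "negative correlation: reported, never flagged" if r < 0 else ""
        reports.append(CorrelationReport(va, vb, r, n, r > MODERATE_R, note))
    return reports
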