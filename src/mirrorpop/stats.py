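"""Population-level inferential statistics.

One-way repeated-measures ANOVA (unit as subject, task as the four-level
within factor) on epoch-averaged net soft-normalized activity, with
Tukey–Kramer post hoc comparisons on the repeated-measures error term, and a
1-df goodness-of-fit χ² comparing the counts of units preferring OBSb vs.
OBSnb against equal expected frequencies.

The ANOVA is computed from the explicit sums-of-squares decomposition

    SS_total = SS_subject + SS_task + SS_error,
    F = (SS_task / (k−1)) / (SS_error / ((k−1)(n−1))),   η² = SS_task / SS_total,

which matches the η² convention of reporting effect SS over total SS.  No
sphericity correction is applied; the report flags that sphericity is
untested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

TASK_ORDER = ("EXE", "OBSb", "OBSnb", "NOGO")


@dataclass
class AnovaResult:
    f: float
    df_effect: int
    df_error: int
    p: float
    eta_squared: float
    ss_task: float
    ss_subject: float
    ss_error: float
    ms_error: float
    n_subjects: int
    sphericity_tested: bool = False


@dataclass
class PosthocComparison:
    task_a: str
    task_b: str
    mean_diff: float
    q: float
    p: float
    significant: bool


@dataclass
class StatsReport:
    anova: AnovaResult
    posthoc: list[PosthocComparison]
    preference_counts: dict        # prefers_OBSb / prefers_OBSnb / no_difference
    chisq: float | None
    chisq_p: float | None


def rm_anova(table: pd.DataFrame, alpha: float = 0.05
             ) -> tuple[AnovaResult, list[PosthocComparison]]:
    """One-way repeated-measures ANOVA plus Tukey–Kramer post hocs.

    ``table``: rows = units (subjects), columns = the four tasks; must be
    complete.
    """
    cols = [c for c in TASK_ORDER if c in table.columns]
    if len(cols) < 2:
        raise ValueError("need at least two task columns")
    data = table[cols]
    bad = data.index[data.isna().any(axis=1)].tolist()
    if bad:
        raise ValueError(f"incomplete rows for units: {bad[:10]}")
    x = data.to_numpy(dtype=float)
    n, k = x.shape
    if n < 2:
        raise ValueError("need >= 2 units")

    grand = x.mean()
    ss_total = float(((x - grand) ** 2).sum())
    ss_subject = float(k * ((x.mean(axis=1) - grand) ** 2).sum())
    ss_task = float(n * ((x.mean(axis=0) - grand) ** 2).sum())
    ss_error = ss_total - ss_subject - ss_task

    df_effect = k - 1
    df_error = (k - 1) * (n - 1)
    ms_task = ss_task / df_effect
    ms_error = ss_error / df_error
    if ms_error <= 0:
        f = np.inf if ms_task > 0 else 0.0
        p = 0.0 if ms_task > 0 else 1.0
    else:
        f = ms_task / ms_error
        p = float(stats.f.sf(f, df_effect, df_error))
    eta2 = ss_task / ss_total if ss_total > 0 else 0.0

    anova = AnovaResult(f=float(f), df_effect=df_effect, df_error=df_error,
                        p=p, eta_squared=float(eta2), ss_task=ss_task,
                        ss_subject=ss_subject, ss_error=ss_error,
                        ms_error=float(ms_error), n_subjects=n)

    posthoc = []
    means = x.mean(axis=0)
    for i in range(k):
        for j in range(i + 1, k):
            diff = means[i] - means[j]
            se = np.sqrt(ms_error * (1.0 / n + 1.0 / n) / 2.0)
            q = abs(diff) / se if se > 0 else (np.inf if diff != 0 else 0.0)
            p_q = float(stats.studentized_range.sf(q, k, df_error)) \
                if np.isfinite(q) else 0.0
            posthoc.append(PosthocComparison(
                task_a=cols[i], task_b=cols[j], mean_diff=float(diff),
                q=float(q), p=p_q, significant=p_q < alpha))
    return anova, posthoc


def preference_chisq(n_obsb: int, n_obsnb: int) -> tuple[float, float]:
    """1-df goodness-of-fit χ² of the two preference counts against equal
    expected frequencies."""
    if n_obsb < 0 or n_obsnb < 0:
        raise ValueError("counts must be non-negative")
    total = n_obsb + n_obsnb
    if total == 0:
        raise ValueError("both preference counts are zero")
    expected = total / 2.0
    chi2 = (n_obsb - expected) ** 2 / expected + (n_obsnb - expected) ** 2 / expected
    return float(chi2), float(stats.chi2.sf(chi2, 1))
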