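"""Unit inclusion and modulation classification.

A unit is compared to its own baseline (500 ms before object presentation)
with a sliding t test — 200-ms windows stepped by 20 ms across −600/+600 ms
around the alignment event, tested one-tailed in each direction at α = 0.05,
uncorrected.  A unit is *facilitated* (*suppressed*) if at least five
consecutive windows are significantly above (below) baseline; otherwise it is
unmodulated.  Only units modulated during OBSb and/or OBSnb enter the
population analyses; the others are accounted for as execution-only or
never-active.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .config import PipelineConfig
from .datamodel import Dataset, TASKS
from .preprocessing import baseline_rates, epoch_mean, net_activity

FACILITATED = "facilitated"
SUPPRESSED = "suppressed"
UNMODULATED = "unmodulated"


@dataclass
class ModulationLabel:
    unit_id: object
    task: str
    label: str
    first_sig_bin: float | None   # center time (s) of the first window of the run


@dataclass
class InclusionSet:
    included_unit_ids: list
    excluded_reason: dict         # unit_id -> "exe_only" | "never_active"


@dataclass
class SlidingTestResult:
    """Sign-tagged decision per window: +1 above baseline, −1 below, 0 n.s."""
    centers: np.ndarray
    decisions: np.ndarray


def window_rates(ds: Dataset, unit_id, task: str, cfg: PipelineConfig,
                 obj: str | None = None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-trial rates in each sliding window plus per-trial baseline rates.

    Returns (centers, rates[trials × windows], baseline[trials]).  Windows of
    length ``ttest_window`` start at the left edge of ``ttest_interval`` and
    step by ``ttest_step`` while fully inside the interval; decisions are
    indexed to window centers.
    """
    trials = ds.correct_trials(task, obj)
    if len(trials) < 2:
        raise ValueError(f"need >= 2 trials for ({unit_id}, {task})")
    lo, hi = cfg.ttest_interval
    starts = []
    s = lo
    while s + cfg.ttest_window <= hi + 1e-9:
        starts.append(s)
        s += cfg.ttest_step
    starts = np.asarray(starts)
    centers = starts + cfg.ttest_window / 2.0

    rates = np.zeros((len(trials), len(starts)))
    base = np.zeros(len(trials))
    b0, b1 = cfg.baseline_window
    for i, (_, tr) in enumerate(trials.iterrows()):
        st = ds.spike_times(unit_id, tr["trial_id"])
        align = tr["align_event_s"]
        left = np.searchsorted(st, align + starts)
        right = np.searchsorted(st, align + starts + cfg.ttest_window)
        rates[i] = (right - left) / cfg.ttest_window
        obj_t = tr["object_presentation_s"]
        base[i] = (np.searchsorted(st, obj_t + b1)
                   - np.searchsorted(st, obj_t + b0)) / (b1 - b0)
    return centers, rates, base


def sliding_decisions(rates: np.ndarray, base: np.ndarray,
                      alpha: float) -> np.ndarray:
    """Per-window {+1, −1, 0} decisions: two-sample t of each window's
    per-trial rates (columns of ``rates``) against the per-trial baseline
    rates, one-tailed in each direction at ``alpha``.

    Degenerate windows (zero variance and identical means, t undefined)
    yield 0.
    """
    decisions = np.zeros(rates.shape[1], dtype=int)
    import warnings
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # near-constant windows trigger scipy's precision warning; such
        # windows are resolved to decision 0 below
        warnings.simplefilter("ignore", RuntimeWarning)
        t_stat, _ = stats.ttest_ind(rates, base[:, None], axis=0)
        df = rates.shape[0] + base.shape[0] - 2
        p_greater = stats.t.sf(t_stat, df)
        p_less = stats.t.cdf(t_stat, df)
    valid = np.isfinite(t_stat)
    decisions[valid & (p_greater < alpha)] = 1
    decisions[valid & (p_less < alpha)] = -1
    return decisions


def sliding_ttest(ds: Dataset, unit_id, task: str,
                  cfg: PipelineConfig) -> SlidingTestResult:
    """Sign-tagged sliding-window significance series for one unit/task."""
    centers, rates, base = window_rates(ds, unit_id, task, cfg)
    return SlidingTestResult(centers=centers,
                             decisions=sliding_decisions(rates, base,
                                                         cfg.alpha))


def _runs(decisions: np.ndarray, sign: int, min_len: int) -> int | None:
    """Index of the first window starting a run of >= min_len of ``sign``."""
    run = 0
    for i, d in enumerate(decisions):
        run = run + 1 if d == sign else 0
        if run >= min_len:
            return i - min_len + 1
    return None


def classify_unit(series: SlidingTestResult, cfg: PipelineConfig,
                  unit_id=None, task: str | None = None) -> ModulationLabel:
    """Facilitated/suppressed/unmodulated from the sign-tagged series.

    If both signs have qualifying runs, the earlier run wins (ties cannot
    occur: a window has one decision).
    """
    pos = _runs(series.decisions, 1, cfg.consec_bins)
    neg = _runs(series.decisions, -1, cfg.consec_bins)
    if pos is None and neg is None:
        return ModulationLabel(unit_id, task, UNMODULATED, None)
    if neg is None or (pos is not None and pos < neg):
        return ModulationLabel(unit_id, task, FACILITATED,
                               float(series.centers[pos]))
    return ModulationLabel(unit_id, task, SUPPRESSED,
                           float(series.centers[neg]))


def classify_dataset(ds: Dataset, cfg: PipelineConfig,
                     tasks=TASKS) -> list[ModulationLabel]:
    """ModulationLabel for every unit × task present in the dataset."""
    present = [t for t in tasks if t in set(ds.trials["task"])]
    out = []
    for u in ds.unit_ids:
        for task in present:
            series = sliding_ttest(ds, u, task, cfg)
            out.append(classify_unit(series, cfg, unit_id=u, task=task))
    return out


def select_population(labels: list[ModulationLabel]) -> InclusionSet:
    """Included iff modulated during OBSb and/or OBSnb; excluded units are
    split into execution-only (modulated somewhere else) vs. never active."""
    by_unit: dict = {}
    for lab in labels:
        by_unit.setdefault(lab.unit_id, {})[lab.task] = lab.label
    included, reasons = [], {}
    for u, task_labels in by_unit.items():
        obs_mod = any(task_labels.get(t, UNMODULATED) != UNMODULATED
                      for t in ("OBSb", "OBSnb"))
        if obs_mod:
            included.append(u)
        elif any(v != UNMODULATED for v in task_labels.values()):
            reasons[u] = "exe_only"
        else:
            reasons[u] = "never_active"
    return InclusionSet(included_unit_ids=sorted(included),
                        excluded_reason=reasons)


def sign_by_epoch(ds: Dataset, unit_ids: list, cfg: PipelineConfig
                  ) -> dict[str, dict]:
    """Facilitated/suppressed grouping per task from the sign of the mean net
    soft-normalized activity over the sign epoch (±600 ms around the align
    event).  An exactly-zero mean is labeled facilitated (measure-zero case).
    """
    nets = net_activity(ds, unit_ids, cfg)
    out: dict[str, dict] = {}
    for task, net in nets.items():
        means = epoch_mean(net, cfg.sign_epoch)
        out[task] = {u: (FACILITATED if m >= 0 else SUPPRESSED)
                     for u, m in zip(unit_ids, means)}
    return out


def paired_preference(values_obsb: np.ndarray, values_obsnb: np.ndarray,
                      alpha: float = 0.05) -> str:
    """Two-tailed paired t on per-trial epoch-averaged net activity.

    Trials are paired by chronological order; unequal counts are an error
    (pairing undefined).  Returns 'prefers_OBSb' | 'prefers_OBSnb' |
    'no_difference'.
    """
    a = np.asarray(values_obsb, dtype=float)
    b = np.asarray(values_obsnb, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired test requires equal trial counts in both tasks")
    if a.size < 2:
        raise ValueError("need >= 2 trial pairs")
    d = a - b
    if np.ptp(d) == 0.0:
        # zero spread: either no effect at all, or an exact constant shift
        if d[0] == 0.0:
            return "no_difference"
        return "prefers_OBSb" if d[0] > 0 else "prefers_OBSnb"
    _, p = stats.ttest_rel(a, b)
    if not np.isfinite(p) or p >= alpha:
        return "no_difference"
    return "prefers_OBSb" if d.mean() > 0 else "prefers_OBSnb"


def preference_test(ds: Dataset, unit_id, cfg: PipelineConfig,
                    divisor: np.ndarray, unit_ids: list) -> str:
    """OBSb-vs-OBSnb preference of one unit from its ring-object trials."""
    from .preprocessing import epoch_trial_values
    j = unit_ids.index(unit_id)
    vb = epoch_trial_values(ds, "OBSb", "ring", unit_ids, cfg, divisor)[:, j]
    vn = epoch_trial_values(ds, "OBSnb", "ring", unit_ids, cfg, divisor)[:, j]
    return paired_preference(vb, vn, cfg.alpha)
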