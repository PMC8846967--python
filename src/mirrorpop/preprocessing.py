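"""From spike events to analysis matrices.

The pipeline per condition is: bin spike counts in 20-ms half-open bins
anchored on the alignment event → average across trials → smooth with a
60-ms-s.d. Gaussian kernel → soft-normalize each unit by its absolute maximum
across all conditions and tasks plus a 5-spk/s floor.  The full design yields
10 time-bins × units matrices (three objects each for EXE, OBSb and NOGO, one
for OBSnb), 70 bins at the default −600/+800-ms window.

Net activity is the soft-normalized trace minus the unit's soft-normalized
baseline rate (500 ms before object presentation, estimated per trial and
trial-averaged), averaged over objects within a task.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .datamodel import Dataset, TASK_OBJECTS, ValidationError


@dataclass
class BinnedActivity:
    """Trial-averaged (optionally smoothed/normalized) rates for one
    task×object condition: values is time-bins × units."""
    task: str
    object: str
    t0: float
    t1: float
    bin_width: float
    values: np.ndarray
    unit_ids: list

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    @property
    def bin_centers(self) -> np.ndarray:
        return self.t0 + (np.arange(self.n_bins) + 0.5) * self.bin_width


@dataclass
class NetActivity:
    """Object-averaged net soft-normalized activity for one task
    (dimensionless, baseline-subtracted)."""
    task: str
    t0: float
    t1: float
    bin_width: float
    values: np.ndarray            # T × N
    unit_ids: list
    baseline: np.ndarray          # N, the subtracted soft-normalized baseline

    @property
    def bin_centers(self) -> np.ndarray:
        return self.t0 + (np.arange(self.values.shape[0]) + 0.5) * self.bin_width


# ---------------------------------------------------------------- primitives

def bin_rates(spike_times: np.ndarray, align: float,
              window: tuple[float, float], bin_width: float) -> np.ndarray:
    """Spike counts per half-open bin [left, right), anchored so a bin edge
    falls exactly on the align event, divided by the bin width (spk/s)."""
    t0, t1 = window
    n = (t1 - t0) / bin_width
    if abs(n - round(n)) > 1e-9:
        raise ValueError("bin_width must divide the window length")
    edges = align + t0 + np.arange(round(n) + 1) * bin_width
    counts = np.diff(np.searchsorted(spike_times, edges))
    return counts / bin_width


def smooth(series: np.ndarray, sd: float, bin_width: float) -> np.ndarray:
    """Gaussian smoothing along axis 0 with a unit-sum kernel.

    The kernel is truncated at ±3 s.d. and renormalized over its valid
    support at the edges (no padding), so a constant series is preserved
    exactly everywhere.
    """
    if sd <= 0:
        raise ValueError("sd must be > 0")
    sd_bins = sd / bin_width
    radius = int(np.ceil(3.0 * sd_bins))
    x = np.arange(-radius, radius + 1)
    kernel = np.exp(-0.5 * (x / sd_bins) ** 2)
    kernel /= kernel.sum()

    arr = np.asarray(series, dtype=float)
    squeeze = arr.ndim == 1
    if squeeze:
        arr = arr[:, None]
    out = np.empty_like(arr)
    norm = np.convolve(np.ones(arr.shape[0]), kernel, mode="same")
    for j in range(arr.shape[1]):
        out[:, j] = np.convolve(arr[:, j], kernel, mode="same") / norm
    return out[:, 0] if squeeze else out


def soft_normalize(rates_by_condition: dict[tuple, np.ndarray],
                   floor: float) -> tuple[dict[tuple, np.ndarray], np.ndarray]:
    """Divide every unit's rates by (its max |rate| across all conditions
    and tasks + floor); the per-unit divisor is returned for audit."""
    stacked = np.concatenate([m for m in rates_by_condition.values()], axis=0)
    divisor = np.abs(stacked).max(axis=0) + floor
    normed = {k: m / divisor for k, m in rates_by_condition.items()}
    return normed, divisor


# ------------------------------------------------------------- trial-level

def _trial_avg_rates(ds: Dataset, task: str, obj: str, unit_ids: list,
                     cfg: PipelineConfig,
                     window: tuple[float, float]) -> np.ndarray:
    """Bin → trial-average for one condition; T × N raw rates (no smoothing)."""
    trials = ds.correct_trials(task, obj)
    if trials.empty:
        raise ValidationError(f"no correct trials for condition ({task}, {obj})")
    n_bins = int(round((window[1] - window[0]) / cfg.bin_width))
    acc = np.zeros((n_bins, len(unit_ids)))
    for _, tr in trials.iterrows():
        align = tr["align_event_s"]
        for j, u in enumerate(unit_ids):
            acc[:, j] += bin_rates(ds.spike_times(u, tr["trial_id"]),
                                   align, window, cfg.bin_width)
    return acc / len(trials)


def baseline_rates(ds: Dataset, task: str, obj: str, unit_ids: list,
                   cfg: PipelineConfig) -> np.ndarray:
    """Per-trial baseline rates (window before object presentation);
    trials × units, spk/s."""
    trials = ds.correct_trials(task, obj)
    b0, b1 = cfg.baseline_window
    dur = b1 - b0
    out = np.zeros((len(trials), len(unit_ids)))
    for i, (_, tr) in enumerate(trials.iterrows()):
        lo = tr["object_presentation_s"] + b0
        hi = tr["object_presentation_s"] + b1
        for j, u in enumerate(unit_ids):
            st = ds.spike_times(u, tr["trial_id"])
            out[i, j] = (np.searchsorted(st, hi) - np.searchsorted(st, lo)) / dur
    return out


def epoch_trial_values(ds: Dataset, task: str, obj: str, unit_ids: list,
                       cfg: PipelineConfig, divisor: np.ndarray) -> np.ndarray:
    """Per-trial net soft-normalized activity averaged over the movement
    epoch; trials × units, dimensionless.  Chronological trial order."""
    trials = ds.correct_trials(task, obj)
    e0, e1 = cfg.movement_epoch
    dur = e1 - e0
    rates = np.zeros((len(trials), len(unit_ids)))
    for i, (_, tr) in enumerate(trials.iterrows()):
        lo = tr["align_event_s"] + e0
        hi = tr["align_event_s"] + e1
        for j, u in enumerate(unit_ids):
            st = ds.spike_times(u, tr["trial_id"])
            rates[i, j] = (np.searchsorted(st, hi) - np.searchsorted(st, lo)) / dur
    base = baseline_rates(ds, task, obj, unit_ids, cfg)
    return (rates - base) / divisor


# ----------------------------------------------------------- matrix builders

def raw_condition_matrices(ds: Dataset, unit_ids: list, cfg: PipelineConfig,
                           tasks=None) -> dict[tuple, np.ndarray]:
    """Bin → trial-average → smooth for every task×object cell (raw spk/s)."""
    tasks = tasks or sorted({t for t in ds.trials["task"].unique()},
                            key=lambda t: ("EXE", "OBSb", "OBSnb", "NOGO").index(t))
    out = {}
    for task in tasks:
        for obj in TASK_OBJECTS[task]:
            m = _trial_avg_rates(ds, task, obj, unit_ids, cfg, cfg.epoch_window)
            out[(task, obj)] = smooth(m, cfg.smooth_sd, cfg.bin_width)
    return out


def build_task_matrices(ds: Dataset, unit_ids: list, cfg: PipelineConfig
                        ) -> tuple[dict[tuple, BinnedActivity], np.ndarray]:
    """The condition matrices of the subspace analysis: 10 soft-normalized
    T × N matrices with a shared unit order, plus the per-unit divisors.

    Raises if any task×object cell of the full design has no correct trials.
    """
    if not unit_ids:
        raise ValidationError("no units included; cannot build matrices")
    present = {(t, o) for t, o in
               ds.correct_trials()[["task", "object"]].itertuples(index=False)}
    needed = [(t, o) for t in ("EXE", "OBSb", "OBSnb", "NOGO")
              for o in TASK_OBJECTS[t]]
    missing = [c for c in needed if c not in present]
    if missing:
        raise ValidationError(f"missing task×object conditions: {missing}")

    raw = raw_condition_matrices(ds, unit_ids, cfg,
                                 tasks=("EXE", "OBSb", "OBSnb", "NOGO"))
    normed, divisor = soft_normalize(raw, cfg.soft_norm_floor)
    t0, t1 = cfg.epoch_window
    matrices = {
        (task, obj): BinnedActivity(task=task, object=obj, t0=t0, t1=t1,
                                    bin_width=cfg.bin_width, values=v,
                                    unit_ids=list(unit_ids))
        for (task, obj), v in normed.items()
    }
    return matrices, divisor


def net_activity(ds: Dataset, unit_ids: list, cfg: PipelineConfig,
                 divisor: np.ndarray | None = None) -> dict[str, NetActivity]:
    """Object-averaged net soft-normalized activity per task.

    The subtracted baseline is each unit's trial-averaged pre-object rate
    (soft-normalized), so re-estimating the baseline of the output gives
    exactly zero by construction.
    """
    raw = raw_condition_matrices(ds, unit_ids, cfg,
                                 tasks=("EXE", "OBSb", "OBSnb", "NOGO"))
    if divisor is None:
        _, divisor = soft_normalize(raw, cfg.soft_norm_floor)
    t0, t1 = cfg.epoch_window
    out = {}
    for task in ("EXE", "OBSb", "OBSnb", "NOGO"):
        nets, bases = [], []
        for obj in TASK_OBJECTS[task]:
            base = baseline_rates(ds, task, obj, unit_ids, cfg).mean(axis=0)
            nets.append((raw[(task, obj)] - base) / divisor)
            bases.append(base / divisor)
        out[task] = NetActivity(task=task, t0=t0, t1=t1,
                                bin_width=cfg.bin_width,
                                values=np.mean(nets, axis=0),
                                unit_ids=list(unit_ids),
                                baseline=np.mean(bases, axis=0))
    return out


def _window_bins(t0: float, bin_width: float, n_bins: int,
                 window: tuple[float, float]) -> np.ndarray:
    centers = t0 + (np.arange(n_bins) + 0.5) * bin_width
    return (centers >= window[0]) & (centers < window[1])


def epoch_mean(net: NetActivity, epoch: tuple[float, float]) -> np.ndarray:
    """Per-unit mean of the net trace over the bins inside ``epoch``."""
    if epoch[0] < net.t0 - 1e-9 or epoch[1] > net.t1 + 1e-9:
        raise ValueError(f"epoch {epoch} outside matrix window ({net.t0}, {net.t1})")
    mask = _window_bins(net.t0, net.bin_width, net.values.shape[0], epoch)
    return net.values[mask].mean(axis=0)


def heatmap_order(net: NetActivity, window: tuple[float, float]) -> list:
    """Units sorted by descending mean net activity in ``window``; ties
    broken by unit_id (stable)."""
    means = epoch_mean(net, window)
    order = pd.DataFrame({"unit_id": net.unit_ids, "mean": means})
    order = order.sort_values(["mean", "unit_id"], ascending=[False, True],
                              kind="mergesort")
    return order["unit_id"].tolist()
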