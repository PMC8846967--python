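"""Shared fixtures: a small simulated session and a deterministic
hand-built dataset whose rates are exact step functions of time.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import mirrorpop as mp
from mirrorpop.datamodel import Dataset, TASK_OBJECTS, TASKS

settings.register_profile(
    "suite", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_cfg() -> mp.PipelineConfig:
    return mp.PipelineConfig()


@pytest.fixture(scope="session")
def session_ds() -> mp.Dataset:
    """A 40-unit simulated session with the default (format-hypothesis)
    latent structure."""
    return mp.generate_dataset(mp.LatentSpec(n_units=40, seed=7))


@pytest.fixture(scope="session")
def session_included(session_ds, default_cfg):
    labels = mp.classify_dataset(session_ds, default_cfg)
    inc = mp.select_population(labels)
    return labels, inc


@pytest.fixture(scope="session")
def session_matrices(session_ds, default_cfg, session_included):
    _, inc = session_included
    return mp.build_task_matrices(session_ds, inc.included_unit_ids,
                                  default_cfg)


# ------------------------------------------------- deterministic datasets

def regular_spikes(rate: float, t0: float, t1: float) -> np.ndarray:
    """Evenly spaced spikes at ``rate`` (spk/s) on [t0, t1), offset by half a
    period so none falls on a 20-ms bin edge when rate is a multiple of 10."""
    n = int(round(rate * (t1 - t0)))
    if n == 0:
        return np.empty(0)
    return t0 + (np.arange(n) + 0.5) / rate


def make_step_dataset(rate_fn, n_trials: int = 10,
                      tasks=TASKS) -> Dataset:
    """Build a Dataset with exact, deterministic step-function rates.

    ``rate_fn(unit_id, task, obj, trial_index) -> (pre_rate, post_rate)``
    gives the firing rate before and after the align event; the pre segment
    spans 1.5 s before the event (covering the pre-object baseline window),
    the post segment 1.0 s after.  Event times carry no jitter.  Rates that
    are multiples of 10 give exact counts in the 200-ms sliding windows;
    multiples of 50 are additionally exact per 20-ms bin.
    """
    unit_ids = list(rate_fn.unit_ids)

    trial_rows, sp_u, sp_t, sp_s = [], [], [], []
    trial_no = 0
    t_base = 10.0
    for task in tasks:
        for obj in TASK_OBJECTS[task]:
            for i in range(n_trials):
                align = t_base + 1.7
                trial_id = f"t{trial_no:04d}"
                trial_rows.append({
                    "trial_id": trial_id, "task": task, "object": obj,
                    "correct": True,
                    "fixation_onset_s": t_base,
                    "cue_onset_s": t_base + 0.5,
                    "object_presentation_s": t_base + 1.0,
                    "align_event_s": align,
                    "pulling_onset_s": np.nan if task == "NOGO" else align + 0.4,
                    "reward_s": align + 1.1,
                })
                for u in unit_ids:
                    pre, post = rate_fn(u, task, obj, i)
                    times = np.concatenate([
                        regular_spikes(pre, align - 1.5, align),
                        regular_spikes(post, align, align + 1.0)])
                    sp_u.append(np.repeat(u, times.size))
                    sp_s.append(np.repeat(trial_id, times.size))
                    sp_t.append(times)
                trial_no += 1
                t_base += 5.0

    spikes = pd.DataFrame({
        "unit_id": np.concatenate(sp_u),
        "trial_id": np.concatenate(sp_s),
        "t_s": np.concatenate(sp_t)})
    units = pd.DataFrame({"unit_id": unit_ids, "area": "F6",
                          "single_unit": True})
    ds = Dataset(units=units, trials=pd.DataFrame(trial_rows), spikes=spikes)
    ds.validate()
    return ds


class StepRates:
    """Helper: per-unit (pre, post) rate table, optionally per-task."""

    def __init__(self, table: dict):
        # table: unit_id -> (pre, post) or unit_id -> {task: (pre, post)}
        self.table = table
        self.unit_ids = sorted(table)

    def __call__(self, unit_id, task, obj, trial_index):
        entry = self.table[unit_id]
        if isinstance(entry, dict):
            entry = entry.get(task, entry.get(None, (10.0, 10.0)))
        return entry
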