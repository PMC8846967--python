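"""Shared data model: tasks, objects, trial records and the Dataset container.

A Dataset holds three pandas frames — unit registry, trial table, spike table —
with spike times in seconds, session-absolute.  Per-trial alignment (to
movement onset, or to the No-Go signal in the NOGO task) happens at use time
via the trial table's ``align_event_s`` column, so there is exactly one
canonical time frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TASKS = ("EXE", "OBSb", "OBSnb", "NOGO")
OBJECTS = ("ring", "small_cone", "big_cone")

#: objects presented in each task; the nonbiological-observation task used
#: only the ring object.
TASK_OBJECTS = {
    "EXE": OBJECTS,
    "OBSb": OBJECTS,
    "NOGO": OBJECTS,
    "OBSnb": ("ring",),
}

#: (task, object) condition cells in canonical order — 10 in the full design.
CONDITIONS = tuple((t, o) for t in TASKS for o in TASK_OBJECTS[t])

#: trial-event columns in temporal order; pulling_onset_s is nullable (NOGO
#: trials have no pull).
EVENT_COLUMNS = (
    "fixation_onset_s",
    "cue_onset_s",
    "object_presentation_s",
    "align_event_s",
    "pulling_onset_s",
    "reward_s",
)

TRIAL_COLUMNS = ("trial_id", "task", "object", "correct") + EVENT_COLUMNS
SPIKE_COLUMNS = ("unit_id", "trial_id", "t_s")
UNIT_COLUMNS = ("unit_id", "area", "single_unit")


class FormatError(ValueError):
    """A file does not follow the documented dialect (e.g. missing column)."""


class ValidationError(ValueError):
    """A structurally well-formed table violates a Dataset invariant."""


@dataclass
class Dataset:
    """Spike events plus trial metadata for one recording (or simulation).

    Attributes
    ----------
    units : DataFrame with columns (unit_id, area, single_unit)
    trials : DataFrame with columns TRIAL_COLUMNS
    spikes : DataFrame with columns (unit_id, trial_id, t_s), seconds absolute
    """

    units: pd.DataFrame
    trials: pd.DataFrame
    spikes: pd.DataFrame
    _spike_index: dict | None = field(default=None, repr=False, compare=False)

    def validate(self) -> None:
        for col in UNIT_COLUMNS:
            if col not in self.units.columns:
                raise FormatError(f"units table missing column {col!r}")
        for col in TRIAL_COLUMNS:
            if col not in self.trials.columns:
                raise FormatError(f"trials table missing column {col!r}")
        for col in SPIKE_COLUMNS:
            if col not in self.spikes.columns:
                raise FormatError(f"spikes table missing column {col!r}")

        if self.trials["trial_id"].duplicated().any():
            raise ValidationError("duplicate trial_id in trial table")
        if self.units["unit_id"].duplicated().any():
            raise ValidationError("duplicate unit_id in unit registry")

        bad_task = set(self.trials["task"]) - set(TASKS)
        if bad_task:
            raise ValidationError(f"unknown task labels: {sorted(bad_task)}")
        bad_obj = set(self.trials["object"]) - set(OBJECTS)
        if bad_obj:
            raise ValidationError(f"unknown object labels: {sorted(bad_obj)}")
        obs_nb = self.trials[self.trials["task"] == "OBSnb"]
        if not (obs_nb["object"] == "ring").all():
            raise ValidationError("OBSnb trials must use the ring object only")

        ev = self.trials[list(EVENT_COLUMNS)].to_numpy(dtype=float)
        # strictly increasing over non-null events, per trial
        for row, trial_id in zip(ev, self.trials["trial_id"]):
            times = row[~np.isnan(row)]
            if np.any(~np.isfinite(times)) or np.any(times < 0):
                raise ValidationError(f"trial {trial_id}: non-finite or negative event time")
            if np.any(np.diff(times) <= 0):
                raise ValidationError(
                    f"trial {trial_id}: event times not strictly increasing")

        t = self.spikes["t_s"].to_numpy(dtype=float)
        if t.size and (np.any(~np.isfinite(t)) or np.any(t < 0)):
            raise ValidationError("spike times must be finite and non-negative")

        orphan_trials = set(self.spikes["trial_id"]) - set(self.trials["trial_id"])
        if orphan_trials:
            raise ValidationError(
                f"spikes reference unknown trial_ids: {sorted(orphan_trials)[:10]}")
        orphan_units = set(self.spikes["unit_id"]) - set(self.units["unit_id"])
        if orphan_units:
            raise ValidationError(
                f"spikes reference unknown unit_ids: {sorted(orphan_units)[:10]}")

    # -- convenience accessors -------------------------------------------

    @property
    def unit_ids(self) -> list:
        return sorted(self.units["unit_id"].tolist())

    def correct_trials(self, task: str | None = None,
                       obj: str | None = None) -> pd.DataFrame:
        """Correct trials, optionally restricted to a task and/or object,
        in chronological (trial table) order."""
        sel = self.trials[self.trials["correct"]]
        if task is not None:
            sel = sel[sel["task"] == task]
        if obj is not None:
            sel = sel[sel["object"] == obj]
        return sel

    def condition_counts(self) -> dict[tuple[str, str], int]:
        out = {}
        for task, obj in CONDITIONS:
            out[(task, obj)] = len(self.correct_trials(task, obj))
        return out

    def require_complete(self, min_trials: int = 10) -> None:
        """Raise unless every task×object cell has >= min_trials correct trials."""
        missing = [(t, o) for (t, o), n in self.condition_counts().items()
                   if n < min_trials]
        if missing:
            raise ValidationError(
                f"incomplete design: conditions with < {min_trials} correct trials: "
                f"{missing}")

    def spike_times(self, unit_id, trial_id) -> np.ndarray:
        """Sorted spike times (s, absolute) of one unit in one trial."""
        if self._spike_index is None:
            idx: dict = {}
            for (u, tr), grp in self.spikes.groupby(["unit_id", "trial_id"], sort=False):
                idx[(u, tr)] = np.sort(grp["t_s"].to_numpy(dtype=float))
            object.__setattr__(self, "_spike_index", idx)
        return self._spike_index.get((unit_id, trial_id), np.empty(0))

    def equals(self, other: "Dataset") -> bool:
        def norm(df, cols):
            return df[list(cols)].reset_index(drop=True)
        return (norm(self.units, UNIT_COLUMNS).equals(norm(other.units, UNIT_COLUMNS))
                and norm(self.trials, TRIAL_COLUMNS).equals(norm(other.trials, TRIAL_COLUMNS))
                and norm(self.spikes, SPIKE_COLUMNS).equals(norm(other.spikes, SPIKE_COLUMNS)))
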