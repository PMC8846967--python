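"""Delimited-text I/O for spike and trial tables.

File dialect: comma-delimited, UTF-8, header row required, "." decimal.
``spikes.csv`` has columns (unit_id, trial_id, t_s); ``trials.csv`` has
columns (trial_id, task, object, correct, fixation_onset_s, cue_onset_s,
object_presentation_s, align_event_s, pulling_onset_s, reward_s); an optional
``units.csv`` carries the unit registry (unit_id, area, single_unit) and is
reconstructed from the spike table when absent.  Floats are written at full
round-trip precision so read(write(ds)) == ds bit-exactly.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (Dataset, EVENT_COLUMNS, FormatError, SPIKE_COLUMNS,
                        TRIAL_COLUMNS, UNIT_COLUMNS)

log = logging.getLogger(__name__)


def _require_columns(df: pd.DataFrame, cols, what: str) -> None:
    for col in cols:
        if col not in df.columns:
            raise FormatError(f"{what} file missing required column {col!r}")


def read_dataset(spike_path: str | Path, trial_path: str | Path,
                 unit_path: str | Path | None = None,
                 drop_incorrect: bool = True) -> Dataset:
    """Load and validate a Dataset from delimited-text files.

    Incorrect (error) trials are carried in the file format but dropped at
    load by default, with the dropped count logged; their spikes are dropped
    with them.
    """
    spike_path, trial_path = Path(spike_path), Path(trial_path)
    if not spike_path.exists():
        raise FileNotFoundError(spike_path)
    if not trial_path.exists():
        raise FileNotFoundError(trial_path)

    spikes = pd.read_csv(spike_path, float_precision="round_trip")
    trials = pd.read_csv(trial_path, float_precision="round_trip")
    _require_columns(spikes, SPIKE_COLUMNS, "spikes")
    _require_columns(trials, TRIAL_COLUMNS, "trials")
    trials = trials.astype({"correct": bool})
    # integral-valued times (e.g. "1") must come back as float64
    trials = trials.astype({c: float for c in EVENT_COLUMNS})
    spikes = spikes.astype({"t_s": float})

    if unit_path is not None and Path(unit_path).exists():
        units = pd.read_csv(unit_path)
        _require_columns(units, UNIT_COLUMNS, "units")
        units = units.astype({"single_unit": bool})
    else:
        units = pd.DataFrame({
            "unit_id": sorted(spikes["unit_id"].unique()),
            "area": "F6",
            "single_unit": True,
        })

    ds = Dataset(units=units, trials=trials, spikes=spikes)
    ds.validate()

    if drop_incorrect:
        n_bad = int((~ds.trials["correct"]).sum())
        if n_bad:
            log.info("dropping %d incorrect (error) trials at load", n_bad)
            keep = ds.trials[ds.trials["correct"]]
            ds = Dataset(units=ds.units,
                         trials=keep.reset_index(drop=True),
                         spikes=ds.spikes[ds.spikes["trial_id"].isin(
                             set(keep["trial_id"]))].reset_index(drop=True))
    return ds


def write_dataset(ds: Dataset, out_dir: str | Path) -> dict[str, Path]:
    """Write spikes.csv, trials.csv and units.csv; returns the paths."""
    ds.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "spikes": out / "spikes.csv",
        "trials": out / "trials.csv",
        "units": out / "units.csv",
    }
    # %.17g guarantees bit-exact float round-trips through the text format
    ds.spikes[list(SPIKE_COLUMNS)].to_csv(paths["spikes"], index=False,
                                          float_format="%.17g")
    ds.trials[list(TRIAL_COLUMNS)].to_csv(paths["trials"], index=False,
                                          float_format="%.17g")
    ds.units[list(UNIT_COLUMNS)].to_csv(paths["units"], index=False)
    return paths
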