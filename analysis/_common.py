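"""Shared plumbing for the analysis drivers: default paths, the session
dataset (simulated on first use), and the default configuration."""

from __future__ import annotations

from pathlib import Path

import mirrorpop as mp

ROOT = Path(__file__).resolve().parents[1]
DATA_DIR = ROOT / "results" / "data"
RESULTS_DIR = ROOT / "results"

SESSION_SEED = 1
N_UNITS = 100


def load_or_simulate() -> mp.Dataset:
    """Load the session written by 01_simulate.py, generating it if absent."""
    spikes = DATA_DIR / "spikes.csv"
    if not spikes.exists():
        spec = mp.LatentSpec(n_units=N_UNITS, seed=SESSION_SEED)
        ds = mp.generate_dataset(spec)
        mp.write_dataset(ds, DATA_DIR)
        mp.write_ground_truth(spec, DATA_DIR)
        return ds
    return mp.read_dataset(spikes, DATA_DIR / "trials.csv",
                           DATA_DIR / "units.csv")


def default_config(n_boot: int = 2000, seed: int = SESSION_SEED
                   ) -> mp.PipelineConfig:
    return mp.PipelineConfig(n_boot=n_boot, seed=seed)
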