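"""Synthetic multi-task spike datasets from low-dimensional latent dynamics.

Each task's population activity is generated as

    rate_u(t) = max(0,  baseline_u + gain * (W_task @ z_task,obj(t))_u )

where ``W_task`` is an n_units × 2 orthonormal loading matrix and ``z`` a pair
of raised-cosine latent bumps peaking after the alignment event.  The planes
spanned by the loading columns have controllable pairwise overlap, measured
with the same captured-variance index the analysis uses, so the generator's
overlap target is the ground truth the pipeline should recover.  Spikes are an
inhomogeneous Poisson process; signed loading entries produce a mix of
facilitated and suppressed units; object conditions within a task share the
task plane but differ in latent amplitude and phase, so within-task alignment
is high but below one.

Default parameters are fixed, realistic premotor values: log-normal baselines
(median 10 spk/s, σ = 0.5), gain 80 spk/s per latent unit, task amplitudes
EXE 1.0 > OBSb 0.6 ≈ OBSnb 0.55 > NOGO 0.35 (execution modulation exceeds
observation), 10 correct trials per condition, 10-ms event jitter, and the
format-hypothesis subspace structure: the OBSnb plane coincides with OBSb's
while EXE's is orthogonal to both and NOGO overlaps OBSb at 0.25.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import Dataset, TASK_OBJECTS, TASKS

_DT = 0.001  # rate-grid resolution (s) for spike placement

#: per-object amplitude multiplier and latent phase shift (s) — distinct
#: dynamics per object within the shared task plane
OBJECT_AMP = {"ring": 1.0, "small_cone": 0.85, "big_cone": 0.70}
OBJECT_PHASE = {"ring": 0.0, "small_cone": 0.05, "big_cone": -0.05}


@dataclass
class LatentSpec:
    """Ground-truth description of a simulated session."""

    n_units: int = 100
    n_latents: int = 2
    tasks: tuple[str, ...] = TASKS
    reference_task: str = "OBSb"
    #: plane-overlap targets in [0, 1] of each task against the reference task
    overlap: dict = field(default_factory=lambda: {
        "EXE": 0.0, "OBSnb": 1.0, "NOGO": 0.25})
    #: peak latent amplitude per task (dimensionless; multiplies gain)
    amplitude: dict = field(default_factory=lambda: {
        "EXE": 1.0, "OBSb": 0.60, "OBSnb": 0.55, "NOGO": 0.35})
    baseline_median: float = 10.0   # spk/s, log-normal median
    baseline_sigma: float = 0.5     # log-space s.d.
    gain: float = 80.0              # spk/s per latent unit
    trial_jitter: float = 0.010     # s, s.d. of event-time jitter
    n_trials: int = 10              # correct trials per task×object condition
    seed: int = 0

    def validate(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.n_latents != 2:
            raise ValueError("only 2 latents per task are supported")
        unknown = set(self.tasks) - set(TASKS)
        if unknown:
            raise ValueError(f"unknown tasks: {sorted(unknown)}")
        if self.reference_task not in self.tasks:
            raise ValueError("reference_task must be among tasks")
        for t, v in self.overlap.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"overlap target for {t} outside [0, 1]: {v}")

    def to_json(self) -> dict:
        d = {k: v for k, v in self.__dict__.items()}
        d["tasks"] = list(self.tasks)
        return d


def plane_overlap(W_a: np.ndarray, W_b: np.ndarray) -> float:
    """Captured-variance overlap of plane A over plane B.

    For isotropic unit-variance latents confined to the column space of
    ``W_a``, this is the alignment index of that activity over ``W_b``:
    ||W_b^T W_a||_F^2 / 2.  Equals 1 for identical planes, 0 for orthogonal.
    """
    return float(np.sum((W_b.T @ W_a) ** 2) / W_a.shape[1])


def make_loadings(n_units: int, overlap: dict, seed: int,
                  tasks: tuple[str, ...] = TASKS,
                  reference_task: str = "OBSb",
                  tol: float = 0.05) -> dict[str, np.ndarray]:
    """Build per-task orthonormal loading matrices with target plane overlaps.

    Targets are specified against ``reference_task``.  Each non-reference
    task's plane is cos(θ)·Q + sin(θ)·P with cos²θ = target, where Q spans
    the reference plane and P a complement orthogonal to Q and to every other
    task's complement, so each achieved overlap equals its target exactly.

    Raises
    ------
    ValueError
        if n_units is too small to host the required mutually orthogonal
        complements, or if the requested targets are jointly infeasible
        under this construction (achieved overlap off by more than ``tol``).
    """
    others = [t for t in tasks if t != reference_task]
    needs_complement = [t for t in others if overlap.get(t, 0.0) < 1.0]
    n_planes = 1 + len(needs_complement)
    if n_units < 2 * n_planes:
        raise ValueError(
            f"n_units = {n_units} cannot host {n_planes} mutually orthogonal "
            f"2-D planes; need at least {2 * n_planes} units")

    rng = np.random.default_rng(seed)
    # one QR gives the reference plane and all complements at once
    basis, _ = np.linalg.qr(rng.standard_normal((n_units, 2 * n_planes)))
    Q = basis[:, :2]
    loadings = {reference_task: Q}
    for i, t in enumerate(others):
        target = float(overlap.get(t, 0.0))
        if target >= 1.0:
            loadings[t] = Q.copy()
            continue
        k = needs_complement.index(t)
        P = basis[:, 2 + 2 * k: 4 + 2 * k]
        c, s = np.sqrt(target), np.sqrt(1.0 - target)
        loadings[t] = c * Q + s * P

    for t in others:
        if t not in overlap:
            continue
        got = plane_overlap(loadings[t], loadings[reference_task])
        if abs(got - overlap[t]) > tol:
            raise ValueError(
                f"infeasible overlap combination: task {t} achieved "
                f"{got:.3f} vs target {overlap[t]:.3f}; the star construction "
                f"only controls overlaps against the reference task")
    return loadings


def _bump(t: np.ndarray, peak: float, half_width: float) -> np.ndarray:
    """Raised-cosine bump: cos²(π(t−peak)/(2h)) on |t−peak| < h, else 0."""
    x = (t - peak) / half_width
    out = np.where(np.abs(x) < 1.0, np.cos(0.5 * np.pi * x) ** 2, 0.0)
    return out


def latent_trajectory(t_rel: np.ndarray, task: str, obj: str,
                      amplitude: float) -> np.ndarray:
    """Two latent time courses (2 × len(t_rel)), t_rel relative to the align
    event.  The first bump peaks 200 ms after the event, the second 450 ms;
    both vanish before −150 ms, so baseline windows see no task signal."""
    amp = amplitude * OBJECT_AMP[obj]
    phase = OBJECT_PHASE[obj]
    z1 = amp * _bump(t_rel, 0.20 + phase, 0.35)
    z2 = 0.8 * amp * _bump(t_rel, 0.45 + phase, 0.35)
    return np.vstack([z1, z2])


def _trial_events(rng: np.random.Generator, t0: float, task: str,
                  jitter: float) -> dict:
    """Event times for one trial starting at t0 (fixation onset)."""
    def j() -> float:
        if jitter == 0:
            return 0.0
        return float(np.clip(rng.normal(0.0, jitter), -3 * jitter, 3 * jitter))

    cue = t0 + 0.500 + j()
    obj = cue + 0.500 + j()
    align = obj + 0.700 + j()          # movement onset / No-Go signal
    pull = np.nan if task == "NOGO" else align + 0.400 + j()
    reward = align + 0.900 + abs(j())
    return {
        "fixation_onset_s": t0,
        "cue_onset_s": cue,
        "object_presentation_s": obj,
        "align_event_s": align,
        "pulling_onset_s": pull,
        "reward_s": reward,
    }


def generate_dataset(spec: LatentSpec) -> Dataset:
    """Simulate a full session: trial table plus Poisson spikes.

    Deterministic given ``spec.seed``; trials are laid out block-per-task in
    session time with 1–1.5-s intertrial gaps, objects interleaved
    round-robin within a block.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    baselines = spec.baseline_median * np.exp(
        rng.normal(0.0, spec.baseline_sigma, spec.n_units))
    loadings = make_loadings(spec.n_units, spec.overlap, spec.seed + 1,
                             tasks=spec.tasks,
                             reference_task=spec.reference_task)

    unit_ids = [f"u{i:04d}" for i in range(spec.n_units)]
    units = pd.DataFrame({"unit_id": unit_ids, "area": "F6",
                          "single_unit": True})

    trial_rows: list[dict] = []
    spike_unit: list[np.ndarray] = []
    spike_trial: list[np.ndarray] = []
    spike_t: list[np.ndarray] = []

    t_session = 0.0
    trial_no = 0
    for task in spec.tasks:
        objects = TASK_OBJECTS[task]
        # round-robin over objects within the task block
        sequence = [obj for _ in range(spec.n_trials) for obj in objects]
        for obj in sequence:
            trial_id = f"t{trial_no:04d}"
            ev = _trial_events(rng, t_session, task, spec.trial_jitter)
            trial_rows.append({"trial_id": trial_id, "task": task,
                               "object": obj, "correct": True, **ev})

            t_start, t_end = ev["fixation_onset_s"], ev["reward_s"] + 0.100
            grid = np.arange(t_start, t_end, _DT)
            z = latent_trajectory(grid - ev["align_event_s"], task, obj,
                                  spec.amplitude.get(task, 0.5))
            drive = spec.gain * (loadings[task] @ z)       # n_units × n_bins
            rates = np.maximum(0.0, baselines[:, None] + drive)

            lam = rates.sum(axis=1) * _DT                  # expected counts
            counts = rng.poisson(lam)
            for u in range(spec.n_units):
                c = counts[u]
                if c == 0:
                    continue
                cum = np.cumsum(rates[u])
                tot = cum[-1]
                idx = np.searchsorted(cum, rng.random(c) * tot)
                times = grid[idx] + rng.random(c) * _DT
                spike_unit.append(np.repeat(unit_ids[u], c))
                spike_trial.append(np.repeat(trial_id, c))
                spike_t.append(np.sort(times))
            trial_no += 1
            t_session = t_end + 1.0 + rng.uniform(0.0, 0.5)

    spikes = pd.DataFrame({
        "unit_id": np.concatenate(spike_unit) if spike_unit else np.array([], dtype=object),
        "trial_id": np.concatenate(spike_trial) if spike_trial else np.array([], dtype=object),
        "t_s": np.concatenate(spike_t) if spike_t else np.array([], dtype=float),
    })
    ds = Dataset(units=units, trials=pd.DataFrame(trial_rows), spikes=spikes)
    ds.validate()
    return ds


def write_ground_truth(spec: LatentSpec, out_dir: str | Path) -> Path:
    """Persist the generator's ground truth (spec + loadings) for recovery
    tests; JSON, loadings as nested lists."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    loadings = make_loadings(spec.n_units, spec.overlap, spec.seed + 1,
                             tasks=spec.tasks,
                             reference_task=spec.reference_task)
    payload = {
        "spec": spec.to_json(),
        "loadings": {t: W.tolist() for t, W in loadings.items()},
        "achieved_overlap": {
            t: plane_overlap(W, loadings[spec.reference_task])
            for t, W in loadings.items()},
    }
    path = out / "ground_truth.json"
    path.write_text(json.dumps(payload, sort_keys=True))
    return path
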