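"""Two-dimensional population trajectories comparable across tasks.

Each condition matrix is divided by the number of contributing units and then
by the square root of its total variance (sum over units of temporal
variance), so every projected trajectory has unit total variance before
projection and amplitudes are comparable across populations of different
sizes and overall modulation.  Matrices are then projected onto the top-2
principal components of a reference task's object-averaged activity and the
per-object 2-D trajectories averaged into one trajectory per task.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocessing import BinnedActivity
from .subspace import SubspaceModel, _values, pca_top2, unit_covariance


@dataclass
class Trajectory2D:
    task: str
    reference: str
    points: np.ndarray        # T × 2
    bin_times: np.ndarray     # T, seconds relative to the align event


def total_variance(X) -> float:
    """Sum over units of the temporal variance (1/(T−1), column-mean
    centered) — the trace of the unit covariance."""
    return float(np.trace(unit_covariance(X)))


def normalize_for_plot(X, n_units: int | None = None) -> np.ndarray:
    """Divide by the unit count, then by sqrt(total variance); the result has
    total variance exactly 1."""
    v = _values(X)
    n = n_units if n_units is not None else v.shape[1]
    y = v / n
    tv = total_variance(y)
    # relative threshold: constant matrices leave O(eps²) rounding residue
    if tv <= 1e-14 * max(float(np.abs(y).max()) ** 2, 1e-300):
        raise ValueError("zero total variance; cannot normalize for plotting")
    return y / np.sqrt(tv)


def reference_model(matrices: dict, reference: str) -> SubspaceModel:
    """Top-2 PCs of the reference task's object-averaged activity."""
    keys = [k for k in matrices if k[0] == reference]
    if not keys:
        raise ValueError(f"no matrices for reference task {reference!r}")
    avg = np.mean([_values(matrices[k]) for k in keys], axis=0)
    return pca_top2(avg, source=("object-averaged", reference))


def project_trajectory(matrices: dict, task: str,
                       reference: SubspaceModel,
                       reference_task: str = "") -> Trajectory2D:
    """Normalized, reference-projected, object-averaged trajectory of a task."""
    keys = [k for k in matrices if k[0] == task]
    if not keys:
        raise ValueError(f"no matrices for task {task!r}")
    V = reference.coefficients
    pts = []
    bin_times = None
    for k in keys:
        X = matrices[k]
        if isinstance(X, BinnedActivity):
            if list(X.unit_ids) and V.shape[0] != len(X.unit_ids):
                raise ValueError("unit dimension mismatch with reference model")
            bin_times = X.bin_centers
        y = normalize_for_plot(X)
        yc = y - y.mean(axis=0)
        pts.append(yc @ V)
    points = np.mean(pts, axis=0)
    if bin_times is None:
        bin_times = np.arange(points.shape[0], dtype=float)
    return Trajectory2D(task=task, reference=reference_task,
                        points=points, bin_times=bin_times)


def task_trajectories(matrices: dict, reference: str) -> dict[str, Trajectory2D]:
    """One trajectory per task, all projected onto the reference task's
    object-averaged top-2 plane."""
    ref = reference_model(matrices, reference)
    tasks = sorted({k[0] for k in matrices},
                   key=("EXE", "OBSb", "OBSnb", "NOGO").index)
    return {t: project_trajectory(matrices, t, ref, reference_task=reference)
            for t in tasks}
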