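"""PCA subspace alignment: the study's core population statistic.

For two condition matrices X_A, X_B (time bins × units, mean-centered over
time) with top-2 principal-component coefficient matrices V_A, V_B, the
alignment of A over B is

    alignment_AB = tr(V_B' cov(X_A) V_B) / tr(V_A' cov(X_A) V_A)

i.e. the variance of A's activity captured by B's principal plane, normalized
by the variance captured by A's own plane.  It ranges from 0 (orthogonal
subspaces) to 1 (perfectly aligned); it is ≤ 1 because the own top-2 plane
maximizes captured variance, and asymmetric (A over B ≠ B over A).

Between-task alignment averages the index over every ordered object pair of
the two tasks; within-task alignment averages over ordered pairs of distinct
objects of one task (null for single-object tasks).  Differences between
alignments are tested by resampling units with replacement — the same indices
applied to every matrix — recomputing all alignments 2,000 times, and calling
a difference significant when at least 97.5% of iterations agree on its sign
(two-tailed α = 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocessing import BinnedActivity

#: an alignment key is ("between", task, reference) or ("within", task)
AlignKey = tuple


@dataclass
class SubspaceModel:
    """Top-2 principal-component coefficients for one condition matrix."""
    coefficients: np.ndarray      # units × 2, orthonormal columns
    explained_variance: np.ndarray  # 2 eigenvalues (descending)
    total_variance: float
    source: tuple | None = None
    rank_deficient: bool = False

    @property
    def explained_fraction(self) -> np.ndarray:
        return self.explained_variance / self.total_variance


@dataclass
class AlignmentReport:
    estimates: dict               # AlignKey -> float (None for undefined within)
    pairwise: dict                # ((task,obj),(task,obj)) -> float
    boot: dict                    # AlignKey -> (n_boot,) array
    diffs: dict                   # (AlignKey, AlignKey) -> (n_boot,) array
    significant: dict             # contrast -> bool
    p_value: dict                 # contrast -> two-tailed bootstrap p
    seed: int = 0
    n_redrawn: int = 0
    criterion: float = 0.975

    def contrast(self, key_a: AlignKey, key_b: AlignKey
                 ) -> tuple[np.ndarray, bool, float]:
        """(difference draws, significant, two-tailed p) for a contrast in
        either stored orientation; differences are returned as A − B."""
        if (key_a, key_b) in self.diffs:
            c = (key_a, key_b)
            return self.diffs[c], self.significant[c], self.p_value[c]
        if (key_b, key_a) in self.diffs:
            c = (key_b, key_a)
            return -self.diffs[c], self.significant[c], self.p_value[c]
        raise KeyError((key_a, key_b))


def _values(X) -> np.ndarray:
    return X.values if isinstance(X, BinnedActivity) else np.asarray(X, float)


def unit_covariance(X) -> np.ndarray:
    """Unit-covariance (N × N) of the column-mean-centered T × N matrix,
    with 1/(T−1) normalization."""
    v = _values(X)
    vc = v - v.mean(axis=0)
    return vc.T @ vc / (v.shape[0] - 1)


def pca_top2(X, source=None) -> SubspaceModel:
    """Top-2 PCA of a condition matrix via eigendecomposition of the unit
    covariance.  Requires >= 2 units, >= 3 time bins and nonzero variance;
    a rank-1 matrix gets an arbitrary second component in the null space and
    is flagged.

    When there are fewer time bins than units the same spectrum is obtained
    from the T × T Gram matrix (cheaper; identical eigenvalues, coefficients
    recovered as X_c' u / sqrt((T−1) λ)).
    """
    v = _values(X)
    T, N = v.shape
    if N < 2:
        raise ValueError("PCA needs at least 2 units")
    if T < 3:
        raise ValueError("PCA needs at least 3 time bins")
    vc = v - v.mean(axis=0)
    if T < N:
        G = vc @ vc.T / (T - 1)
        total = float(np.trace(G))
        if total <= 0.0:
            raise ValueError("total variance is zero; PCA undefined")
        w, u = np.linalg.eigh(G)
        order = np.argsort(w)[::-1]
        w, u = np.maximum(w[order], 0.0), u[:, order]
        rank_def = bool(w[1] <= 1e-12 * w[0])
        coef = np.empty((N, 2))
        for i in range(2):
            if w[i] > 0:
                coef[:, i] = vc.T @ u[:, i] / np.sqrt((T - 1) * w[i])
            else:
                # null-space filler: orthonormal completion, flagged above
                q, _ = np.linalg.qr(np.column_stack(
                    [coef[:, :i], np.ones(N)]) if i else np.ones((N, 1)))
                coef[:, i] = q[:, -1]
        return SubspaceModel(coefficients=coef,
                             explained_variance=w[:2],
                             total_variance=total, source=source,
                             rank_deficient=rank_def)
    C = unit_covariance(v)
    total = float(np.trace(C))
    if total <= 0.0:
        raise ValueError("total variance is zero; PCA undefined")
    w, vecs = np.linalg.eigh(C)
    order = np.argsort(w)[::-1]
    w, vecs = w[order], vecs[:, order]
    return SubspaceModel(coefficients=vecs[:, :2],
                         explained_variance=np.maximum(w[:2], 0.0),
                         total_variance=total,
                         source=source,
                         rank_deficient=bool(w[1] <= 1e-12 * w[0]))


def alignment_index(X_A, V_A: np.ndarray | SubspaceModel,
                    V_B: np.ndarray | SubspaceModel) -> float:
    """Captured-variance ratio of A's activity in B's plane vs. A's own."""
    if isinstance(V_A, SubspaceModel):
        V_A = V_A.coefficients
    if isinstance(V_B, SubspaceModel):
        V_B = V_B.coefficients
    v = _values(X_A)
    vc = v - v.mean(axis=0)
    scale = v.shape[0] - 1
    # tr(V' cov V) == ||X_c V||_F^2 / (T-1); avoids forming the N×N covariance
    den = float(np.sum((vc @ V_A) ** 2)) / scale
    if den <= 0.0:
        raise ValueError("flat activity matrix: own-plane variance is zero")
    num = float(np.sum((vc @ V_B) ** 2)) / scale
    return num / den


# ------------------------------------------------------- aggregate indices

def _condition_keys(matrices: dict, task: str) -> list:
    return [k for k in matrices if k[0] == task]


def _alignment_of_pair(matrices: dict, models: dict, a, r) -> float:
    return alignment_index(matrices[a], models[a], models[r])


def _models(matrices: dict) -> dict:
    return {k: pca_top2(m, source=k) for k, m in matrices.items()}


def between_task_alignment(matrices: dict, task: str, reference: str,
                           models: dict | None = None) -> float:
    """Mean alignment of ``task`` over ``reference`` across every ordered
    object pair of the two tasks."""
    models = models or _models(matrices)
    pairs = [(a, r) for a in _condition_keys(matrices, task)
             for r in _condition_keys(matrices, reference)]
    if not pairs:
        raise ValueError(f"no condition matrices for ({task}, {reference})")
    return float(np.mean([_alignment_of_pair(matrices, models, a, r)
                          for a, r in pairs]))


def within_task_alignment(matrices: dict, task: str,
                          models: dict | None = None) -> float | None:
    """Mean alignment across ordered pairs of distinct objects of one task;
    None for single-object tasks (no pairs exist)."""
    models = models or _models(matrices)
    keys = _condition_keys(matrices, task)
    pairs = [(a, r) for a in keys for r in keys if a != r]
    if not pairs:
        return None
    return float(np.mean([_alignment_of_pair(matrices, models, a, r)
                          for a, r in pairs]))


def pairwise_alignment(matrices: dict, models: dict | None = None) -> dict:
    """alignment_index for every ordered pair of condition matrices."""
    models = models or _models(matrices)
    return {(a, r): _alignment_of_pair(matrices, models, a, r)
            for a in matrices for r in matrices}


def _evaluate_keys(matrices: dict, keys: list[AlignKey]) -> dict:
    models = _models(matrices)
    out = {}
    for key in keys:
        if key[0] == "between":
            out[key] = between_task_alignment(matrices, key[1], key[2], models)
        elif key[0] == "within":
            out[key] = within_task_alignment(matrices, key[1], models)
        else:
            raise ValueError(f"unknown alignment key {key!r}")
    return out


def bootstrap_alignment(matrices: dict, contrasts: list[tuple[AlignKey, AlignKey]],
                        n_boot: int = 2000, criterion: float = 0.975,
                        seed: int = 0) -> AlignmentReport:
    """Unit-resampling bootstrap over alignment contrasts.

    Per iteration one set of unit indices is drawn with replacement and
    applied identically to every matrix (paired resampling), all alignments
    named by the contrasts are recomputed, and their differences stored.  A
    contrast is significant when the fraction of iterations whose difference
    is > 0 (or < 0) reaches ``criterion``.  Iterations whose resample leaves
    any matrix with (near-)zero variance are redrawn and counted.
    Deterministic given ``seed``: iteration i consumes the i-th draw block.
    """
    keys_tasks = {t for c in contrasts for k in c for t in k[1:]}
    mats = {k: _values(m) for k, m in matrices.items() if k[0] in keys_tasks}
    n_units = next(iter(mats.values())).shape[1]
    if n_units < 2:
        raise ValueError("bootstrap needs >= 2 units")
    keys = sorted({k for c in contrasts for k in c})
    point = _evaluate_keys(matrices, keys)
    for key in keys:
        if point[key] is None:
            raise ValueError(f"contrast references undefined alignment {key!r}")

    rng = np.random.default_rng(seed)
    boot = {k: np.empty(n_boot) for k in keys}
    n_redrawn = 0
    for it in range(n_boot):
        for _attempt in range(100):
            idx = rng.integers(0, n_units, n_units)
            sub = {k: v[:, idx] for k, v in mats.items()}
            try:
                vals = _evaluate_keys(sub, keys)
            except ValueError:
                n_redrawn += 1
                continue
            break
        else:
            raise RuntimeError("bootstrap: persistent degenerate resamples")
        for k in keys:
            boot[k][it] = vals[k]

    diffs, significant, p_value = {}, {}, {}
    for ka, kb in contrasts:
        d = boot[ka] - boot[kb]
        diffs[(ka, kb)] = d
        frac_pos = float(np.mean(d > 0))
        frac_neg = float(np.mean(d < 0))
        significant[(ka, kb)] = max(frac_pos, frac_neg) >= criterion
        p_value[(ka, kb)] = min(1.0, 2.0 * min(np.mean(d <= 0), np.mean(d >= 0)))

    return AlignmentReport(estimates=point,
                           pairwise=pairwise_alignment(matrices),
                           boot=boot, diffs=diffs, significant=significant,
                           p_value=p_value, seed=seed, n_redrawn=n_redrawn,
                           criterion=criterion)
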