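"""The alignment statistic: PCA, the captured-variance ratio, aggregation
over condition pairs, and the unit-resampling bootstrap."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mirrorpop.subspace import (alignment_index, between_task_alignment,
                                bootstrap_alignment, pca_top2,
                                unit_covariance, within_task_alignment)


def _rand(T, N, seed):
    return np.random.default_rng(seed).normal(size=(T, N))


def oracle_alignment(X, V_a, V_b):
    """Explicit-summation oracle: covariance and both traces by loops."""
    X = np.asarray(X, dtype=float)
    T, N = X.shape
    mu = X.mean(axis=0)
    C = np.zeros((N, N))
    for t in range(T):
        d = X[t] - mu
        C += np.outer(d, d)
    C /= (T - 1)

    def captured(V):
        tot = 0.0
        for k in range(V.shape[1]):
            tot += float(V[:, k] @ C @ V[:, k])
        return tot

    return captured(V_b) / captured(V_a)


class TestPcaTop2:

    def test_planar_data_fraction_one(self):
        rng = np.random.default_rng(0)
        z = rng.normal(size=(30, 2))
        X = np.zeros((30, 5))
        X[:, 1] = z[:, 0]
        X[:, 3] = z[:, 1]
        m = pca_top2(X)
        assert m.explained_fraction.sum() == pytest.approx(1.0, abs=1e-12)
        # coefficients span the units {1,3} plane
        mask = np.zeros(5, dtype=bool)
        mask[[1, 3]] = True
        assert np.abs(m.coefficients[~mask]).max() < 1e-10

    def test_isotropic_three_units(self):
        # covariance proportional to identity: fraction is exactly 2/3
        X = np.vstack([np.eye(3), -np.eye(3)])
        m = pca_top2(X)
        assert m.explained_fraction.sum() == pytest.approx(2.0 / 3.0, abs=1e-12)

    def test_matches_eigendecomposition_oracle(self):
        for seed in range(20):
            X = _rand(70, 5, seed)
            m = pca_top2(X)
            C = unit_covariance(X)
            w, v = np.linalg.eigh(C)
            top = v[:, np.argsort(w)[::-1][:2]]
            # same projector => same subspace regardless of sign/rotation
            P_got = m.coefficients @ m.coefficients.T
            P_exp = top @ top.T
            assert np.abs(P_got - P_exp).max() < 1e-8
            assert np.allclose(sorted(m.explained_variance, reverse=True),
                               sorted(w, reverse=True)[:2], atol=1e-10)

    def test_gram_path_agrees_with_covariance_path(self):
        # more units than time bins triggers the Gram-matrix computation
        X = _rand(10, 25, 3)
        m = pca_top2(X)
        C = unit_covariance(X)
        w = np.sort(np.linalg.eigvalsh(C))[::-1]
        assert np.allclose(m.explained_variance, w[:2], atol=1e-10)
        assert np.allclose(m.coefficients.T @ m.coefficients, np.eye(2),
                           atol=1e-10)
        lead = C @ m.coefficients[:, 0]
        assert np.allclose(lead, w[0] * m.coefficients[:, 0], atol=1e-8)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError, match="variance"):
            pca_top2(np.ones((10, 3)))

    def test_rank_one_flagged(self):
        X = np.outer(np.linspace(0, 1, 10), np.ones(4))
        assert pca_top2(X).rank_deficient


class TestAlignmentIndex:

    def test_self_alignment_is_one(self):
        for seed in range(10):
            X = _rand(70, 6, seed)
            V = pca_top2(X)
            assert alignment_index(X, V, V) == pytest.approx(1.0, abs=1e-10)

    def test_orthogonal_planes_zero(self):
        X = np.zeros((20, 4))
        X[:, :2] = _rand(20, 2, 1)
        V_a = pca_top2(X).coefficients
        V_b = np.zeros((4, 2))
        V_b[2, 0] = V_b[3, 1] = 1.0
        assert alignment_index(X, V_a, V_b) == pytest.approx(0.0, abs=1e-12)

    def test_worked_integer_matrix_vs_oracle(self):
        X = np.array([[2, 0, 1, 3],
                      [1, 4, 0, 1],
                      [0, 2, 2, 0],
                      [3, 1, 1, 2],
                      [1, 0, 4, 1],
                      [2, 3, 0, 0]], dtype=float)
        V_a = pca_top2(X).coefficients
        V_b = pca_top2(X[::-1] * np.array([1, -1, 1, -1])).coefficients
        got = alignment_index(X, V_a, V_b)
        assert got == pytest.approx(oracle_alignment(X, V_a, V_b), abs=1e-12)
        assert 0.0 <= got <= 1.0

    @given(st.integers(0, 10_000))
    def test_bounded_on_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(rng.integers(4, 11), rng.integers(3, 9)))
        X += rng.normal(size=X.shape) * 1e-3
        V_a = pca_top2(X).coefficients
        V_b = pca_top2(rng.normal(size=X.shape)).coefficients
        a = alignment_index(X, V_a, V_b)
        assert -1e-12 <= a <= 1.0 + 1e-12


class TestAggregates:

    def _mats(self, specs):
        return {k: _rand(12, 5, s) for k, s in specs.items()}

    def test_between_matches_enumeration_oracle(self):
        mats = self._mats({("EXE", "ring"): 0, ("EXE", "small_cone"): 1,
                           ("OBSb", "ring"): 2, ("OBSb", "small_cone"): 3,
                           ("OBSb", "big_cone"): 4})
        models = {k: pca_top2(m) for k, m in mats.items()}
        vals = [alignment_index(mats[a], models[a], models[r])
                for a in mats if a[0] == "EXE"
                for r in mats if r[0] == "OBSb"]
        assert len(vals) == 6
        assert between_task_alignment(mats, "EXE", "OBSb") == \
            pytest.approx(np.mean(vals), abs=1e-12)

    def test_identical_matrices_align_one(self):
        X = _rand(12, 5, 9)
        mats = {("EXE", "ring"): X, ("OBSb", "ring"): X.copy()}
        assert between_task_alignment(mats, "EXE", "OBSb") == \
            pytest.approx(1.0, abs=1e-10)

    def test_within_excludes_self_pairs(self):
        mats = self._mats({("EXE", "ring"): 0, ("EXE", "small_cone"): 1,
                           ("EXE", "big_cone"): 2})
        models = {k: pca_top2(m) for k, m in mats.items()}
        vals = [alignment_index(mats[a], models[a], models[r])
                for a in mats for r in mats if a != r]
        assert len(vals) == 6
        assert within_task_alignment(mats, "EXE") == \
            pytest.approx(np.mean(vals), abs=1e-12)

    def test_within_single_object_is_null(self):
        mats = {("OBSnb", "ring"): _rand(12, 5, 1)}
        assert within_task_alignment(mats, "OBSnb") is None


class TestBootstrap:

    HEAD = (("between", "OBSnb", "OBSb"), ("between", "EXE", "OBSb"))

    def _condition_set(self, seed, n_units=30, noise=0.1):
        """Matrix-level generator: OBSb/OBSnb share a plane, EXE orthogonal."""
        rng = np.random.default_rng(seed)
        basis, _ = np.linalg.qr(rng.normal(size=(n_units, 4)))
        Q, P = basis[:, :2], basis[:, 2:]
        t = np.linspace(0, 1, 20)
        mats = {}
        for i, obj in enumerate(("ring", "small_cone", "big_cone")):
            z = np.column_stack([np.sin((i + 1) * np.pi * t),
                                 np.cos((i + 2) * np.pi * t)])
            mats[("OBSb", obj)] = z @ Q.T + rng.normal(size=(20, n_units)) * noise
            mats[("EXE", obj)] = 1.5 * z @ P.T + rng.normal(size=(20, n_units)) * noise
        mats[("OBSnb", "ring")] = \
            0.8 * np.column_stack([np.sin(np.pi * t + 0.3), np.cos(2.2 * np.pi * t)]) @ Q.T \
            + rng.normal(size=(20, n_units)) * noise
        return mats

    def test_reproducible_bit_exact(self):
        mats = self._condition_set(0)
        a = bootstrap_alignment(mats, [self.HEAD], n_boot=50, seed=123)
        b = bootstrap_alignment(mats, [self.HEAD], n_boot=50, seed=123)
        for k in a.boot:
            assert np.array_equal(a.boot[k], b.boot[k])
        assert a.significant == b.significant

    def test_single_iteration_degenerate(self):
        mats = self._condition_set(1)
        rep = bootstrap_alignment(mats, [self.HEAD], n_boot=1, seed=0)
        d = rep.diffs[self.HEAD]
        assert d.shape == (1,)
        assert rep.significant[self.HEAD] == bool(d[0] > 0 or d[0] < 0)

    def test_large_effect_significant(self):
        mats = self._condition_set(2, n_units=100, noise=0.05)
        rep = bootstrap_alignment(mats, [self.HEAD], n_boot=200, seed=1)
        assert rep.estimates[self.HEAD[0]] > rep.estimates[self.HEAD[1]]
        assert rep.significant[self.HEAD]

    def test_null_contrast_mostly_nonsignificant(self):
        # two structurally identical populations: same latent plane,
        # independent noise; the contrast should rarely be called
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(1000 + seed)
            basis, _ = np.linalg.qr(rng.normal(size=(40, 2)))
            t = np.linspace(0, 1, 20)
            mats = {}
            for task in ("OBSnb", "EXE"):
                for obj in (("ring",) if task == "OBSnb" else ("ring", "small_cone", "big_cone")):
                    z = np.column_stack([np.sin(np.pi * t), np.cos(2 * np.pi * t)])
                    mats[(task, obj)] = z @ basis.T + rng.normal(size=(20, 40)) * 0.2
            for obj in ("ring", "small_cone", "big_cone"):
                z = np.column_stack([np.sin(np.pi * t), np.cos(2 * np.pi * t)])
                mats[("OBSb", obj)] = z @ basis.T + rng.normal(size=(20, 40)) * 0.2
            rep = bootstrap_alignment(mats, [self.HEAD], n_boot=100, seed=seed)
            hits += rep.significant[self.HEAD]
        assert hits <= 1

    def test_too_few_units_raises(self):
        mats = {k: v[:, :1] for k, v in self._condition_set(3).items()}
        with pytest.raises(ValueError, match="2 units"):
            bootstrap_alignment(mats, [self.HEAD], n_boot=5, seed=0)
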