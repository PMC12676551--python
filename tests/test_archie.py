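"""Sparse-CCA machinery: whitening, thresholding, components, deflation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from prsprot import archie
from prsprot.archie import (SummaryStatSet, build_whitened, cc_value,
                            deflate, extract_components, inv_sqrt,
                            scca_pair, soft_threshold)


class TestInvSqrt:
    def test_identity(self):
        assert np.allclose(inv_sqrt(np.eye(4)), np.eye(4))

    def test_diagonal_closed_form(self):
        out = inv_sqrt(np.diag([4.0, 9.0]))
        assert np.allclose(out, np.diag([0.5, 1 / 3]), atol=1e-12)

    def test_rank_deficient_projects_onto_retained_space(self):
        a = np.outer([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])  # rank 1
        m = inv_sqrt(a, floor=1e-3)
        w, q = np.linalg.eigh(a)
        keep = w > 1e-3
        proj = q[:, keep] @ q[:, keep].T
        assert np.allclose(m @ m @ a, proj, atol=1e-6)

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            inv_sqrt(np.array([[1.0, 0.5], [0.0, 1.0]]))


class TestBuildWhitened:
    def _ss(self, sg, sp, sgp):
        s, p = sgp.shape
        return SummaryStatSet(sigma_G=sg, sigma_P=sp, sigma_GP=sgp,
                              snp_id=[f"r{j}" for j in range(s)],
                              analyte_id=[f"a{k}" for k in range(p)])

    def test_identity_whitening(self, rng):
        sgp = rng.normal(size=(4, 3))
        ss = self._ss(np.eye(4), np.eye(3), sgp)
        assert np.allclose(build_whitened(ss).W, sgp)

    def test_zero_cross_matrix(self):
        ss = self._ss(np.eye(4), np.eye(3), np.zeros((4, 3)))
        assert np.allclose(build_whitened(ss).W, 0.0)

    def test_matches_dense_algebra_oracle(self, rng):
        a = rng.normal(size=(4, 6))
        sg = np.corrcoef(a)
        b = rng.normal(size=(3, 6))
        sp = np.corrcoef(b)
        sgp = rng.normal(size=(4, 3))
        ss = self._ss(sg, sp, sgp)
        floor = 1e-3

        def oracle_half(m):
            w, q = np.linalg.eigh(m)
            return q @ np.diag(np.clip(w, floor, None) ** -0.5) @ q.T

        expected = oracle_half(sg) @ sgp @ oracle_half(sp)
        assert np.allclose(build_whitened(ss, floor).W, expected, atol=1e-10)

    def test_masked_cis_entries_never_contribute(self, rng):
        # two cross matrices agreeing on trans entries give identical W
        sg = np.eye(5) * 0.9 + 0.1
        sp = np.eye(7) * 0.8 + 0.2
        sgp = rng.normal(size=(5, 7))
        mask = rng.random((5, 7)) > 0.3      # True = trans (usable)
        altered = sgp + (~mask) * rng.normal(size=(5, 7))
        w1 = build_whitened(self._ss(sg, sp, np.where(mask, sgp, 0.0))).W
        w2 = build_whitened(self._ss(sg, sp, np.where(mask, altered, 0.0))).W
        assert np.allclose(w1, w2, atol=1e-12)


class TestSoftThreshold:
    def test_closed_forms(self):
        assert np.allclose(soft_threshold(np.array([0.5, 0.2]), 0.2),
                           [0.3, 0.0])
        assert np.allclose(soft_threshold(np.array([-0.1, 0.2]), 0.3),
                           [0.0, 0.0])
        x = np.array([1.0, -2.0, 0.0])
        assert np.allclose(soft_threshold(x, 0.0), x)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            soft_threshold(np.ones(3), -0.1)

    @given(arrays(float, 6, elements=st.floats(-10, 10)),
           st.floats(0, 5))
    def test_shrinkage_properties(self, x, lam):
        out = soft_threshold(x, lam)
        assert np.all(np.abs(out) <= np.maximum(np.abs(x) - lam, 0) + 1e-12)
        assert np.all(out * x >= 0)          # never flips sign


class TestSccaPair:
    def test_lambda_zero_matches_svd(self, rng):
        w = rng.normal(size=(10, 8))
        comp = scca_pair(w, 0.0, 0.0)
        u, s, vt = np.linalg.svd(w)
        sign = np.sign(comp.u @ u[:, 0])
        assert np.allclose(comp.u, sign * u[:, 0], atol=1e-8)
        assert np.allclose(comp.v, sign * vt[0], atol=1e-8)
        assert abs(comp.u @ w @ comp.v - s[0]) < 1e-8

    def test_rank_one_supports(self):
        a = np.array([0.0, 2.0, 0.0, -1.0])
        b = np.array([1.5, 0.0, -2.5])
        w = 2.0 * np.outer(a, b) / (np.linalg.norm(a) * np.linalg.norm(b))
        comp = scca_pair(w, 0.05, 0.05)
        assert set(comp.selected_snps) == {1, 3}
        assert set(comp.selected_proteins) == {0, 2}

    def test_full_shrinkage_is_empty(self, rng):
        w = rng.normal(size=(5, 4))
        comp = scca_pair(w, 10 * np.abs(w).max(), 10 * np.abs(w).max())
        assert comp.empty and comp.q2 == 0.0

    def test_penalized_objective_monotone(self, rng):
        w = rng.normal(size=(12, 9))
        comp = scca_pair(w, 0.1, 0.15)
        diffs = np.diff(comp.objective_trace)
        assert np.all(diffs >= -1e-12)


class TestCcValue:
    def test_rayleigh_form_at_singular_pair(self, rng):
        w = rng.normal(size=(6, 5))
        u, s, vt = np.linalg.svd(w)
        q2 = cc_value(w, u[:, 0], vt[0])
        assert abs(q2 - s[0] ** 2) < 1e-10

    def test_orthogonal_pair_is_zero(self):
        w = np.array([[1.0, 0.0], [0.0, 0.0]])
        # W u = (1, 0)' for u = e1; v = e2 is orthogonal to it
        assert cc_value(w, np.array([1.0, 0.0]), np.array([0.0, 1.0])) == 0.0

    def test_variants_match_quadratic_form_oracle(self, rng):
        w = rng.normal(size=(5, 4))
        u = rng.normal(size=5)
        v = rng.normal(size=4)
        num = float(u @ w @ v) ** 2
        assert abs(cc_value(w, u, v) - num / (u @ u * (v @ v))) < 1e-10
        as_printed = num / ((w.T @ u) @ (w.T @ u) * ((w @ v) @ (w @ v)))
        assert abs(cc_value(w, u, v, "as_printed") - as_printed) < 1e-10

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            cc_value(np.eye(2), np.zeros(2), np.ones(2))


class TestDeflate:
    def test_rank_one_annihilation(self):
        a = np.array([3.0, 0.0, 4.0]) / 5.0
        b = np.array([0.6, -0.8])
        w = 1.7 * np.outer(a, b)
        comp = scca_pair(w, 0.0, 0.0)
        assert np.linalg.norm(deflate(w, comp)) < 1e-8

    def test_rank_two_reveals_second_pair(self, rng):
        u, _ = np.linalg.qr(rng.normal(size=(6, 2)))
        v, _ = np.linalg.qr(rng.normal(size=(5, 2)))
        w = 3.0 * np.outer(u[:, 0], v[:, 0]) + 1.2 * np.outer(u[:, 1], v[:, 1])
        comp = scca_pair(w, 0.0, 0.0)
        w2 = deflate(w, comp)
        second = scca_pair(w2, 0.0, 0.0)
        sign = np.sign(second.u @ u[:, 1])
        assert np.allclose(second.u, sign * u[:, 1], atol=1e-6)
        assert np.allclose(second.v, sign * v[:, 1], atol=1e-6)

    def test_empty_component_rejected(self):
        w = np.ones((2, 2))
        comp = scca_pair(w, 10.0, 10.0)
        with pytest.raises(ValueError):
            deflate(w, comp)


class TestExtractComponents:
    def _block_w(self, rng, noise=0.0):
        w = np.zeros((9, 10))
        w[:4, :5] = 1.5 * np.outer([0.9, 0.8, 0.7, 0.6],
                                   [0.9, 0.8, 0.7, 0.6, 0.5])
        w[6:, 7:] = 1.0 * np.outer([0.8, 0.9, 0.7], [0.9, 0.8, 0.7])
        if noise:
            w += noise * rng.normal(size=w.shape)
        return w

    def test_block_diagonal_recovery(self, rng):
        w = self._block_w(rng, noise=0.01)
        comps = extract_components(w, K=2,
                                   lambda_grid=np.linspace(0, np.abs(w).max(), 20))
        assert len(comps) == 2
        assert set(comps[0].selected_snps) == set(range(4))
        assert set(comps[0].selected_proteins) == set(range(5))
        assert set(comps[1].selected_snps) == {6, 7, 8}
        assert set(comps[1].selected_proteins) == {7, 8, 9}

    def test_k_equals_one_matches_scca_pair(self, rng):
        w = rng.normal(size=(6, 7))
        comps = extract_components(w, K=1, lambda_grid=[0.2])
        single = scca_pair(w, 0.2, 0.2)
        assert np.allclose(comps[0].u, single.u, atol=1e-10)
        assert np.allclose(comps[0].v, single.v, atol=1e-10)

    def test_lambda_zero_gives_svd_triplets(self, rng):
        w = rng.normal(size=(8, 6))
        with pytest.warns(UserWarning, match="disjoint"):
            comps = extract_components(w, K=3, lambda_grid=[0.0])
        u, s, vt = np.linalg.svd(w)
        for k, c in enumerate(comps):
            sign = np.sign(c.u @ u[:, k])
            assert np.allclose(c.u, sign * u[:, k], atol=1e-6)
            assert np.allclose(c.v, sign * vt[k], atol=1e-6)
            assert abs(c.q2 - s[k] ** 2) < 1e-6

    def test_supports_pairwise_disjoint(self, rng):
        w = self._block_w(rng, noise=0.02)
        comps = extract_components(w, K=3)
        seen_s, seen_p = set(), set()
        for c in comps:
            assert not (set(c.selected_snps) & seen_s)
            assert not (set(c.selected_proteins) & seen_p)
            seen_s |= set(c.selected_snps)
            seen_p |= set(c.selected_proteins)

    def test_scale_equivariance(self, rng):
        w = self._block_w(rng, noise=0.02)
        grid = np.linspace(0, np.abs(w).max(), 12)
        c1 = extract_components(w, K=2, lambda_grid=grid)
        c2 = extract_components(3.0 * w, K=2, lambda_grid=3.0 * grid)
        for a, b in zip(c1, c2):
            assert abs(9.0 * a.q2 - b.q2) < 1e-8
            assert set(a.selected_snps) == set(b.selected_snps)
            assert set(a.selected_proteins) == set(b.selected_proteins)
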