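import numpy as np
import pytest

from plsbeam.beamformer import (Covariance, lcmv_localize, lcmv_weights,
                                localize, pls_lcmv_localize, regularized_inverse,
                                sample_covariance, variance_map, VarianceMap)
from plsbeam.forward import LeadField
from plsbeam.geometry import SourceGrid
from plsbeam.simulate import SourceSpec, project_dipole


def _spd(rng, m, cond=10.0):
    Q, _ = np.linalg.qr(rng.normal(size=(m, m)))
    ev = np.linspace(1.0, cond, m)
    return Q @ np.diag(ev) @ Q.T


class TestSampleCovariance:
    def test_hand_computed_two_channel_example(self):
        X = np.array([[1.0, -1.0], [2.0, -2.0]])
        cov = sample_covariance(X)
        assert np.allclose(cov.C, [[2.0, 4.0], [4.0, 8.0]])

    def test_symmetric_and_positive_semidefinite(self, rng):
        X = rng.normal(size=(12, 40))
        C = sample_covariance(X).C
        assert np.allclose(C, C.T)
        assert np.linalg.eigvalsh(C).min() >= -1e-10 * np.trace(C)

    def test_duplicating_time_axis_matches_direct_recomputation(self, rng):
        X = rng.normal(size=(6, 20))
        X2 = np.hstack([X, X])
        cov2 = sample_covariance(X2)
        Xc = X2 - X2.mean(axis=1, keepdims=True)
        assert np.allclose(cov2.C, Xc @ Xc.T / (X2.shape[1] - 1))

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            sample_covariance(np.ones((3, 1)))


class TestRegularizedInverse:
    def test_full_rank_matches_direct_inverse(self, rng):
        C = _spd(rng, 8)
        out = regularized_inverse(Covariance(C, 100), 0.0)
        assert np.allclose(out, np.linalg.inv(C), rtol=1e-8)

    def test_rank_deficient_with_loading_is_finite_symmetric(self, rng):
        v = rng.normal(size=6)
        C = np.outer(v, v)
        out = regularized_inverse(Covariance(C, 100), 0.01)
        assert np.all(np.isfinite(out))
        assert np.allclose(out, out.T)

    def test_error_shrinks_as_loading_vanishes(self, rng):
        C = _spd(rng, 8)
        exact = np.linalg.inv(C)
        errs = [np.linalg.norm(regularized_inverse(Covariance(C, 100), lam) - exact)
                for lam in (1e-2, 1e-4, 1e-6)]
        assert errs[0] > errs[1] > errs[2]

    def test_singular_without_loading_advises_loading(self, rng):
        v = rng.normal(size=6)
        with pytest.raises(np.linalg.LinAlgError, match="loading"):
            regularized_inverse(Covariance(np.outer(v, v), 100), 0.0)


class TestWeights:
    def test_identity_covariance_orthonormal_leadfield(self, rng):
        L, _ = np.linalg.qr(rng.normal(size=(10, 3)))
        w = lcmv_weights(L, np.eye(10))
        assert np.allclose(w.W, L, atol=1e-12)
        assert np.allclose(w.W.T @ L, np.eye(3), atol=1e-12)

    def test_unit_gain_for_random_spd_covariance(self, rng):
        for _ in range(20):
            L = rng.normal(size=(12, 3))
            Cinv = np.linalg.inv(_spd(rng, 12))
            w = lcmv_weights(L, Cinv)
            assert np.allclose(w.W.T @ L, np.eye(3), atol=1e-8)

    def test_minimizes_output_power_among_unit_gain_filters(self, rng):
        M = 8
        C = _spd(rng, M)
        L = rng.normal(size=(M, 3))
        W = lcmv_weights(L, np.linalg.inv(C)).W
        base = np.trace(W.T @ C @ W)
        # project random perturbations onto the constraint set W'L = I
        P = np.eye(M) - L @ np.linalg.pinv(L)
        for _ in range(100):
            Wp = W + P @ rng.normal(size=(M, 3)) * 0.3
            assert np.allclose(Wp.T @ L, np.eye(3), atol=1e-8)
            assert np.trace(Wp.T @ C @ Wp) >= base - 1e-10
        assert base > 0

    def test_degenerate_leadfield_flagged(self, rng):
        L = np.zeros((10, 3))
        with pytest.raises(np.linalg.LinAlgError, match="degenerate"):
            lcmv_weights(L, np.eye(10), point_index=5)


def _toy_lead(rng, p=4, m=10):
    gains = rng.normal(size=(p, m, 3))
    grid = SourceGrid(points=rng.normal(size=(p, 3)) * 30, spacing=10.0)
    return LeadField(gains=gains, grid=grid, channel_index=np.arange(m))


class TestVarianceMap:
    def test_orthonormal_leadfield_identity_covariance_gives_three(self, rng):
        p, m = 3, 12
        gains = np.stack([np.linalg.qr(rng.normal(size=(m, 3)))[0] for _ in range(p)])
        lead = LeadField(gains=gains,
                         grid=SourceGrid(points=np.zeros((p, 3)), spacing=1.0),
                         channel_index=np.arange(m))
        vmap = variance_map(lead, Covariance(np.eye(m), 100), 0.0)
        assert np.allclose(vmap.values, 3.0, atol=1e-10)

    def test_scaling_data_scales_map_quadratically(self, rng):
        lead = _toy_lead(rng)
        X = rng.normal(size=(10, 50))
        v1 = variance_map(lead, sample_covariance(X), 1e-4).values
        v2 = variance_map(lead, sample_covariance(3.0 * X), 1e-4).values
        assert np.allclose(v2, 9.0 * v1, rtol=1e-10)

    def test_constant_offset_per_channel_leaves_map_unchanged(self, rng):
        lead = _toy_lead(rng)
        X = rng.normal(size=(10, 50))
        off = rng.normal(size=(10, 1)) * 100
        v1 = variance_map(lead, sample_covariance(X), 1e-4).values
        v2 = variance_map(lead, sample_covariance(X + off), 1e-4).values
        assert np.allclose(v1, v2, rtol=1e-10)

    def test_degenerate_points_marked_and_excluded(self, rng):
        lead = _toy_lead(rng)
        lead.gains[2] = 0.0
        X = rng.normal(size=(10, 50))
        vmap = variance_map(lead, sample_covariance(X), 1e-4)
        assert np.isnan(vmap.values[2])
        idx, _ = localize(vmap)
        assert idx != 2


class TestLocalize:
    def test_argmax_and_tie_break(self):
        grid = SourceGrid(points=np.arange(9.0).reshape(3, 3), spacing=1.0)
        assert localize(VarianceMap(np.array([1.0, 5.0, 2.0]), grid))[0] == 1
        assert localize(VarianceMap(np.array([5.0, 5.0, 2.0]), grid))[0] == 0

    def test_empty_map_rejected(self):
        grid = SourceGrid(points=np.zeros((2, 3)), spacing=1.0)
        with pytest.raises(ValueError):
            localize(VarianceMap(np.array([np.nan, np.nan]), grid))


class TestAgainstQuadraticProgramOracle:
    """Closed-form weights/variance vs brute-force constrained minimization."""

    def _oracle(self, C, L):
        # minimize tr(W'CW) s.t. W'L = I over W = W0 + Z B, Z = null(L')
        M = L.shape[0]
        W0 = L @ np.linalg.inv(L.T @ L)
        u, s, vt = np.linalg.svd(L, full_matrices=True)
        Z = u[:, 3:]
        B = -np.linalg.solve(Z.T @ C @ Z, Z.T @ C @ W0)
        return W0 + Z @ B

    @pytest.mark.parametrize("m", [4, 5, 6])
    def test_weights_and_variance_match_oracle(self, m, rng):
        for _ in range(5):
            C = _spd(rng, m)
            L = rng.normal(size=(m, 3))
            W_oracle = self._oracle(C, L)
            W = lcmv_weights(L, np.linalg.inv(C)).W
            assert np.allclose(W, W_oracle, atol=1e-6)
            var_closed = np.trace(np.linalg.inv(L.T @ np.linalg.inv(C) @ L))
            var_oracle = np.trace(W_oracle.T @ C @ W_oracle)
            assert var_closed == pytest.approx(var_oracle, rel=1e-6)


class TestPipelines:
    def test_noiseless_dipole_recovered_exactly(self, small_context):
        ctx = small_context
        loc = ctx.grid.points[10]
        radial = loc - ctx.sphere.center
        tang = np.cross(radial, [0.0, 0.0, 1.0])
        tang /= np.linalg.norm(tang)
        clean, idx, _ = project_dipole(SourceSpec(location=loc, orientation=tang),
                                       ctx.lead)
        for res in (lcmv_localize(clean, ctx.lead),
                    pls_lcmv_localize(clean, ctx.partition, ctx.lead)):
            assert res.index == idx
            assert np.allclose(res.location, loc)

    def test_full_rank_reconstruction_degenerates_to_lcmv(self, small_context, rng):
        ctx = small_context
        loc = ctx.grid.points[10]
        radial = loc - ctx.sphere.center
        tang = np.cross(radial, [0.0, 0.0, 1.0])
        tang /= np.linalg.norm(tang)
        clean, _, _ = project_dipole(SourceSpec(location=loc, orientation=tang), ctx.lead)
        X = clean + rng.normal(size=clean.shape) * np.abs(clean).max() * 0.3
        M = X.shape[0]
        res_pls = pls_lcmv_localize(
            X, ctx.partition, ctx.lead,
            pls_config={"threshold_rel": 0.0, "max_k": M}, lambda_rel=1e-4)
        res_plain = lcmv_localize(X, ctx.lead, lambda_rel=1e-4)
        diff = np.nanmax(np.abs(res_pls.vmap.values - res_plain.vmap.values)
                         / np.abs(res_plain.vmap.values))
        assert diff < 1e-8
        assert res_pls.index == res_plain.index

    def test_channel_misalignment_rejected(self, small_context, rng):
        ctx = small_context
        X = rng.normal(size=(ctx.lead.n_channels + 1, 50))
        with pytest.raises(ValueError):
            pls_lcmv_localize(X, ctx.partition, ctx.lead)
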