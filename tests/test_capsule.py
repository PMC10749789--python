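"""Squash activation, prediction, self-attention coupling and routing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from histoexpr.autograd import Tensor
from histoexpr.capsule import (CapsuleStage, coupling_coefficients,
                               predict_capsules, primary_capsules, route,
                               squash)


def _np(x):
    return x.data if isinstance(x, Tensor) else np.asarray(x)


class TestSquash:
    def test_zero_maps_to_zero(self):
        assert np.allclose(_np(squash(np.zeros(5))), 0.0)

    def test_unit_norm_value(self):
        s = np.array([1.0, 0.0, 0.0])
        out = _np(squash(s))
        assert np.linalg.norm(out) == pytest.approx(1 - np.exp(-1), abs=1e-9)
        assert out[0] > 0 and np.allclose(out[1:], 0)

    def test_large_norm_saturates(self):
        s = np.zeros(4)
        s[2] = 10.0
        out = _np(squash(s))
        assert np.linalg.norm(out) == pytest.approx(1 - np.exp(-10), abs=1e-9)
        # direction preserved
        assert out[2] == pytest.approx(np.linalg.norm(out))

    def test_rotation_equivariance(self, rng):
        from scipy.stats import ortho_group
        s = rng.normal(size=6)
        R = ortho_group.rvs(6, random_state=1)
        assert np.allclose(_np(squash(R @ s)), R @ _np(squash(s)), atol=1e-9)

    @settings(deadline=None, max_examples=100)
    @given(st.lists(st.floats(-50, 50), min_size=2, max_size=8))
    def test_norm_in_unit_interval(self, vec):
        out = _np(squash(np.array(vec, dtype=float)))
        assert 0.0 <= np.linalg.norm(out) < 1.0 + 1e-12


class TestPredict:
    def test_identity_blocks_replicate_input(self):
        n, d = 2, 3
        W = np.zeros((n, d, 1, d))
        for i in range(n):
            W[i, :, 0, :] = np.eye(d)
        u = np.arange(n * d, dtype=float).reshape(n, d)
        U = _np(predict_capsules(u, Tensor(W)))
        assert np.allclose(U[:, 0, :], u)

    def test_zero_input_zero_predictions(self, rng):
        W = Tensor(rng.normal(size=(3, 4, 2, 5)))
        assert np.allclose(_np(predict_capsules(np.zeros((3, 4)), W)), 0)

    def test_matches_manual_matmul(self, rng):
        n, d, n2, d2 = 2, 3, 2, 2
        W = rng.normal(size=(n, d, n2, d2))
        u = rng.normal(size=(n, d))
        U = _np(predict_capsules(u, Tensor(W)))
        for i in range(n):
            for j in range(n2):
                assert np.allclose(U[i, j], u[i] @ W[i, :, j, :], atol=1e-12)


class TestCoupling:
    def test_identical_predictions_give_uniform(self, rng):
        v = rng.normal(size=4)
        U = np.tile(v, (3, 5, 1))       # same prediction for every output
        C = _np(coupling_coefficients(U, d_l=4))
        assert np.allclose(C, 1.0 / 5, atol=1e-9)

    def test_dominant_logit_saturates(self):
        U = np.zeros((2, 2, 3))
        U[:, 0, :] = 10.0               # output capsule 0 has huge agreement
        C = _np(coupling_coefficients(U, d_l=3))
        assert np.all(C[:, 0] > 0.999)

    def test_hand_example_vs_softmax_oracle(self, rng):
        n, n2, d = 2, 2, 2
        U = rng.normal(size=(n, n2, d))
        C = _np(coupling_coefficients(U, d_l=d))
        logits = np.zeros((n, n2))
        for i in range(n):
            for j in range(n2):
                logits[i, j] = sum(U[i, j] @ U[i2, j] for i2 in range(n)) / np.sqrt(d)
        expected = np.exp(logits) / np.exp(logits).sum(axis=1, keepdims=True)
        assert np.allclose(C, expected, atol=1e-10)

    @settings(deadline=None, max_examples=100)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_rows_sum_to_one_over_output_capsules(self, seed):
        r = np.random.default_rng(seed)
        U = r.normal(size=(4, 3, 5))
        C = _np(coupling_coefficients(U, d_l=5))
        assert np.allclose(C.sum(axis=-1), 1.0, atol=1e-6)
        assert (C >= 0).all()


class TestRoute:
    def test_zero_predictions_zero_output(self):
        U = np.zeros((3, 2, 4))
        C = np.full((3, 2), 0.5)
        assert np.allclose(_np(route(U, C, np.zeros((3, 2)))), 0.0)

    def test_uniform_coupling_matches_loop_oracle(self, rng):
        n, n2, d2 = 3, 2, 4
        U = rng.normal(size=(n, n2, d2))
        C = np.full((n, n2), 1.0 / n2)
        out = _np(route(U, C, np.zeros((n, n2))))
        for j in range(n2):
            s = sum(C[i, j] * U[i, j] for i in range(n))
            nrm = np.linalg.norm(s)
            expected = (1 - np.exp(-nrm)) * s / nrm
            assert np.allclose(out[j], expected, atol=1e-9)

    def test_single_capsule_identity_contraction(self, rng):
        U = rng.normal(size=(1, 3, 4))
        out = _np(route(U, np.ones((1, 3)), np.zeros((1, 3))))
        for j in range(3):
            s = U[0, j]
            expected = (1 - np.exp(-np.linalg.norm(s))) * s / np.linalg.norm(s)
            assert np.allclose(out[j], expected, atol=1e-9)


class TestPrimaryCapsules:
    def test_zero_feature_map_gives_zero_capsules(self, rng):
        conv_w = Tensor(rng.normal(size=(2, 2, 3, 3)))
        depth_w = Tensor(rng.normal(size=(2, 1, 3, 3)))
        out = _np(primary_capsules(np.zeros((1, 2, 4, 4)), conv_w, depth_w, 4))
        assert np.allclose(out, 0.0)

    def test_capsule_count_matches_reshape_rule(self, rng):
        C, H, W, d = 4, 6, 6, 8
        conv_w = Tensor(rng.normal(size=(C, C, 3, 3)))
        depth_w = Tensor(rng.normal(size=(C, 1, 3, 3)))
        out = primary_capsules(rng.normal(size=(1, C, H, W)), conv_w, depth_w, d)
        assert out.shape == (1, C * H * W // d, d)

    def test_indivisible_caps_dim_errors(self, rng):
        conv_w = Tensor(rng.normal(size=(3, 3, 3, 3)))
        depth_w = Tensor(rng.normal(size=(3, 1, 3, 3)))
        with pytest.raises(ValueError, match="divisible"):
            primary_capsules(np.zeros((1, 3, 5, 5)), conv_w, depth_w, 8)


def test_full_stage_matches_nested_loop_reference(rng):
    """The batched capsule stage agrees with a naive per-element reference."""
    stage = CapsuleStage(c_in=2, h=3, w=4, caps_dim=3, n_out=4, d_out=3,
                         rng=np.random.default_rng(5))
    x = rng.normal(size=(2, 2, 3, 4))
    out = stage(Tensor(x)).data

    def squash_np(s):
        nrm = np.sqrt((s ** 2).sum() + 1e-8)
        return (1 - np.exp(-nrm)) * s / nrm

    prim = primary_capsules(Tensor(x), stage.conv_w, stage.depth_w,
                            stage.caps_dim).data
    for b in range(2):
        u = np.array([squash_np(prim[b, i]) for i in range(stage.n_in)])
        n, n2, d2 = stage.n_in, stage.n_out, stage.d_out
        W = stage.W_route.data
        U = np.zeros((n, n2, d2))
        for i in range(n):
            for j in range(n2):
                U[i, j] = u[i] @ W[i, :, j, :]
        logits = np.zeros((n, n2))
        for i in range(n):
            for j in range(n2):
                logits[i, j] = sum(U[i, j] @ U[i2, j]
                                   for i2 in range(n)) / np.sqrt(stage.caps_dim)
        Cm = np.exp(logits - logits.max(axis=1, keepdims=True))
        Cm /= Cm.sum(axis=1, keepdims=True)
        s_next = np.zeros((n2, d2))
        for j in range(n2):
            for i in range(n):
                s_next[j] += (Cm[i, j] + stage.B_prior.data[i, j]) * U[i, j]
        expected = np.concatenate([squash_np(s_next[j]) for j in range(n2)])
        assert np.allclose(out[b], expected, atol=1e-8)


def test_coupling_inner_sum_runs_over_input_capsules(rng):
    """The agreement logit sums pairwise inner products over *input*
    capsules; the alternative reading (a per-capsule self inner product
    over the feature axis only) yields different coefficients whenever
    distinct input capsules disagree."""
    U = rng.normal(size=(3, 2, 4))
    ours = coupling_coefficients(U, d_l=4).data
    # alternative: logit_ij = <U_ij, U_ij>/sqrt(d) without cross terms
    alt_logits = (U ** 2).sum(-1) / np.sqrt(4)
    alt = np.exp(alt_logits - alt_logits.max(1, keepdims=True))
    alt /= alt.sum(1, keepdims=True)
    assert not np.allclose(ours, alt)
    # both readings coincide when all input capsules emit one prediction
    U_same = np.tile(rng.normal(size=(1, 2, 4)), (3, 1, 1))
    ours_same = coupling_coefficients(U_same, d_l=4).data
    logits_same = 3 * (U_same ** 2).sum(-1) / np.sqrt(4)
    alt_same = np.exp(logits_same - logits_same.max(1, keepdims=True))
    alt_same /= alt_same.sum(1, keepdims=True)
    assert np.allclose(ours_same, alt_same, atol=1e-10)


def test_activated_capsule_norms_below_one(rng):
    stage = CapsuleStage(c_in=2, h=4, w=4, caps_dim=4, n_out=3, d_out=5,
                         rng=np.random.default_rng(2))
    out = stage(Tensor(rng.normal(size=(8, 2, 4, 4)) * 5)).data
    caps = out.reshape(8, stage.n_out, stage.d_out)
    norms = np.linalg.norm(caps, axis=-1)
    assert (norms < 1.0).all() and (norms >= 0.0).all()
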