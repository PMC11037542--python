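"""Network building blocks against closed forms and brute-force loops."""

import numpy as np
import pytest

from hypermir.autodiff import Tensor
from hypermir.io import Config, InvalidInputError
from hypermir.model import (contrastive_pair_loss, forward, hgcn_forward,
                            init_params, integrate_all, inter_view_attention,
                            project, reconstruct, reconstruction_loss,
                            symmetric_contrastive_loss, total_loss,
                            view_attention, ViewEmbeddings)

TINY = Config(embed_dim=8, n_heads=2, n_layers=2, k=2, c=2, epochs=3,
              proj_hidden=8)


def tiny_params(seed=0, config=TINY, feat_m=9, feat_d=9):
    rng = np.random.default_rng(seed)
    return init_params(config, feat_m, feat_d, rng)


def brute_info_nce(Gu, Gv, tau):
    """Scalar double loop over the 2m-1 denominator terms per anchor."""

    def cos(a, b):
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        if na == 0 or nb == 0:
            return 0.0
        return float(a @ b) / (na * nb)

    m = Gu.shape[0]
    total = 0.0
    for i in range(m):
        pos = np.exp(cos(Gu[i], Gv[i]) / tau)
        den = pos
        for k in range(m):
            if k != i:
                den += np.exp(cos(Gu[i], Gu[k]) / tau)
                den += np.exp(cos(Gu[i], Gv[k]) / tau)
        total -= np.log(pos / den)
    return total


class TestHgcnForward:
    def test_identity_operator_identity_weights(self):
        X0 = np.abs(np.random.default_rng(0).normal(size=(3, 4)))
        out = hgcn_forward(X0, np.eye(3), [Tensor(np.eye(4))])
        assert np.allclose(out.data, X0)

    def test_rank_one_operator_collapses_rows(self):
        rng = np.random.default_rng(1)
        X0 = rng.normal(size=(5, 4))
        P = np.full((5, 5), 0.2)
        out = hgcn_forward(X0, P, [Tensor(rng.normal(size=(4, 3)))])
        assert np.allclose(out.data, out.data[0])

    def test_zero_input_zero_output(self):
        rng = np.random.default_rng(2)
        thetas = [Tensor(rng.normal(size=(4, 4))) for _ in range(3)]
        out = hgcn_forward(np.zeros((3, 4)), np.eye(3), thetas)
        assert np.array_equal(out.data, np.zeros((3, 4)))

    def test_width_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            hgcn_forward(np.zeros((3, 4)), np.eye(3),
                         [Tensor(np.zeros((5, 2)))])


class TestContrastiveLoss:
    def test_identical_embeddings_closed_form(self):
        Z = np.tile(np.array([1.0, 2.0, 0.5]), (3, 1))
        loss = contrastive_pair_loss(Z, Z.copy(), tau=0.5)
        assert loss.item() == pytest.approx(3 * np.log(5), abs=1e-9)

    @pytest.mark.parametrize("m", [2, 5, 11, 20])
    def test_matches_bruteforce_double_loop(self, m):
        rng = np.random.default_rng(m)
        U = rng.normal(size=(m, 6))
        V = rng.normal(size=(m, 6))
        loss = contrastive_pair_loss(U, V, tau=0.5)
        assert loss.item() == pytest.approx(brute_info_nce(U, V, 0.5),
                                            abs=1e-10)

    def test_projection_head_applied(self):
        rng = np.random.default_rng(4)
        params = tiny_params()
        U = rng.normal(size=(5, 8))
        V = rng.normal(size=(5, 8))
        projector = lambda Z: project(params, "m", Z)
        loss = contrastive_pair_loss(U, V, tau=0.5, projector=projector)
        Gu = projector(Tensor(U)).data
        Gv = projector(Tensor(V)).data
        assert loss.item() == pytest.approx(brute_info_nce(Gu, Gv, 0.5),
                                            abs=1e-10)

    def test_cosine_scale_invariance(self):
        rng = np.random.default_rng(5)
        U = rng.normal(size=(4, 3))
        V = rng.normal(size=(4, 3))
        a = contrastive_pair_loss(U, V, tau=0.5)
        b = contrastive_pair_loss(10 * U, 10 * V, tau=0.5)
        assert a.item() == pytest.approx(b.item(), abs=1e-9)

    def test_mean_reduction(self):
        rng = np.random.default_rng(6)
        U, V = rng.normal(size=(2, 3, 4))
        s = contrastive_pair_loss(U, V, 0.5, reduction="sum").item()
        m = contrastive_pair_loss(U, V, 0.5, reduction="mean").item()
        assert m == pytest.approx(s / 3, abs=1e-12)


class TestSymmetricContrastive:
    def test_eta_one_equals_single_direction(self):
        rng = np.random.default_rng(7)
        Z1, Z2 = rng.normal(size=(2, 4, 3))
        assert symmetric_contrastive_loss(Z1, Z2, 0.5, eta=1.0).item() == \
            pytest.approx(contrastive_pair_loss(Z1, Z2, 0.5).item(), abs=1e-12)

    def test_identical_views_balanced(self):
        rng = np.random.default_rng(8)
        Z = rng.normal(size=(4, 3))
        both = symmetric_contrastive_loss(Z, Z.copy(), 0.5, eta=0.5).item()
        one = contrastive_pair_loss(Z, Z.copy(), 0.5).item()
        assert both == pytest.approx(one, abs=1e-10)

    def test_swap_invariance_at_half(self):
        rng = np.random.default_rng(9)
        Z1, Z2 = rng.normal(size=(2, 5, 3))
        a = symmetric_contrastive_loss(Z1, Z2, 0.5, eta=0.5).item()
        b = symmetric_contrastive_loss(Z2, Z1, 0.5, eta=0.5).item()
        assert a == pytest.approx(b, abs=1e-10)

    def test_fused_equals_two_directional_calls(self):
        # the shared-cosine fast path must match two independent evaluations
        rng = np.random.default_rng(10)
        params = tiny_params()
        projector = lambda Z: project(params, "d", Z)
        Z1, Z2 = rng.normal(size=(2, 6, 8))
        eta = 0.3
        fused = symmetric_contrastive_loss(Z1, Z2, 0.5, eta,
                                           projector=projector).item()
        split = (eta * contrastive_pair_loss(Z1, Z2, 0.5, projector).item()
                 + (1 - eta) * contrastive_pair_loss(Z2, Z1, 0.5,
                                                     projector).item())
        assert fused == pytest.approx(split, abs=1e-10)


class TestViewAttention:
    def test_gate_in_unit_interval(self):
        rng = np.random.default_rng(11)
        params = tiny_params()
        Z1, Z2 = rng.normal(size=(2, 5, 8))
        _, _, (a1, a2) = view_attention(Z1, Z2, params, "m")
        assert 0.0 < a1.item() < 1.0
        assert 0.0 < a2.item() < 1.0

    def test_nonnegative_embedding_scaled_exactly(self):
        rng = np.random.default_rng(12)
        params = tiny_params()
        Z1 = np.abs(rng.normal(size=(5, 8)))
        Z2 = np.abs(rng.normal(size=(5, 8)))
        Zt1, Zt2, (a1, a2) = view_attention(Z1, Z2, params, "m")
        assert np.allclose(Zt1.data, a1.item() * Z1)
        assert np.allclose(Zt2.data, a2.item() * Z2)

    def test_zero_initialized_fnn_gives_half(self):
        params = tiny_params()
        for name in ("va_m_W1", "va_m_b1", "va_m_W2", "va_m_b2"):
            params[name].data[:] = 0.0
        rng = np.random.default_rng(13)
        _, _, (a1, a2) = view_attention(rng.normal(size=(4, 8)),
                                        rng.normal(size=(4, 8)), params, "m")
        assert a1.item() == a2.item() == 0.5


class TestInterViewAttention:
    def test_rows_stochastic(self):
        rng = np.random.default_rng(14)
        params = tiny_params()
        A, h = inter_view_attention(rng.normal(size=8), rng.normal(size=8),
                                    params, "m", TINY)
        assert np.allclose(A.sum(axis=1), 1.0, atol=1e-12)
        assert h.shape == (8,)

    def test_equal_views_give_uniform_attention(self):
        rng = np.random.default_rng(15)
        params = tiny_params()
        z = rng.normal(size=8)
        A, _ = inter_view_attention(z, z.copy(), params, "m", TINY)
        assert np.allclose(A, 0.5, atol=1e-12)

    def test_identical_heads_average_to_single_head(self):
        cfg = Config(embed_dim=8, n_heads=4, proj_hidden=8)
        params = tiny_params(config=cfg)
        for p in range(1, 4):
            for w in ("Wq", "Wk", "Wv"):
                params[f"att_m_{w}{p}"].data[:] = \
                    params[f"att_m_{w}0"].data
        rng = np.random.default_rng(16)
        z1 = rng.normal(size=8)
        z2 = rng.normal(size=8)
        _, h = inter_view_attention(z1, z2, params, "m", cfg)
        # manual single-head computation with head 0's parameters
        Wq = params["att_m_Wq0"].data
        Wk = params["att_m_Wk0"].data
        Wv = params["att_m_Wv0"].data
        d_f = 2
        q = np.vstack([z1 @ Wq, z2 @ Wq])
        k = np.vstack([z1 @ Wk, z2 @ Wk])
        v = np.vstack([z1 @ Wv, z2 @ Wv])
        scores = q @ k.T / np.sqrt(d_f)
        A = np.exp(scores - scores.max(axis=1, keepdims=True))
        A /= A.sum(axis=1, keepdims=True)
        vec = (A @ v).reshape(-1)
        expected = vec @ params["att_m_Wh"].data + params["att_m_bh"].data[0]
        assert np.allclose(h, expected, atol=1e-10)


class TestIntegration:
    def _views(self, rng, m, d=8):
        Z1 = Tensor(np.abs(rng.normal(size=(m, d))))
        Z2 = Tensor(np.abs(rng.normal(size=(m, d))))
        return ViewEmbeddings(Z1, Z2, weighted_knn=Z1, weighted_kmeans=Z2)

    def test_output_shapes(self):
        rng = np.random.default_rng(17)
        params = tiny_params()
        H_m, G_d = integrate_all(self._views(rng, 6), self._views(rng, 4),
                                 params, TINY)
        assert H_m.shape == (6, 8)
        assert G_d.shape == (4, 8)

    def test_row_permutation_equivariance(self):
        rng = np.random.default_rng(18)
        params = tiny_params()
        vm = self._views(rng, 6)
        vd = self._views(rng, 4)
        H_m, _ = integrate_all(vm, vd, params, TINY)
        perm = rng.permutation(6)
        vm_p = ViewEmbeddings(None, None,
                              weighted_knn=Tensor(vm.weighted_knn.data[perm]),
                              weighted_kmeans=Tensor(
                                  vm.weighted_kmeans.data[perm]))
        H_m_p, _ = integrate_all(vm_p, vd, params, TINY)
        assert np.allclose(H_m_p.data, H_m.data[perm], atol=1e-12)

    def test_concat_ablation_stacks_views(self):
        rng = np.random.default_rng(19)
        cfg = TINY.replace(ablation="hgclam_concat")
        params = tiny_params(config=cfg)
        vm = self._views(rng, 6)
        vd = self._views(rng, 4)
        H_m, G_d = integrate_all(vm, vd, params, cfg)
        assert H_m.shape == (6, 16)
        assert np.array_equal(H_m.data[:, :8], vm.weighted_knn.data)


class TestDecoderAndLosses:
    def test_reconstruct_hand_example(self):
        cfg = Config(embed_dim=2, n_heads=1, proj_hidden=2)
        params = tiny_params(config=cfg, feat_m=2, feat_d=2)
        params["dec_m_W"].data[:] = np.eye(2)
        params["dec_m_b"].data[:] = 0.0
        params["dec_d_W"].data[:] = np.eye(2)
        params["dec_d_b"].data[:] = 0.0
        T_hat = reconstruct(np.eye(2), np.array([[2.0, 0.0], [0.0, 3.0]]),
                            params)
        assert np.allclose(T_hat.data, [[2.0, 0.0], [0.0, 3.0]])

    def test_zero_factor_zero_scores(self):
        params = tiny_params()
        T_hat = reconstruct(np.zeros((3, 8)), np.zeros((2, 8)), params)
        # zero input with zero bias and ReLU gives exactly zero factors
        assert np.array_equal(T_hat.data, np.zeros((3, 2)))

    def test_rank_bounded_by_inner_dimension(self):
        rng = np.random.default_rng(20)
        params = tiny_params()
        T_hat = reconstruct(rng.normal(size=(12, 8)),
                            rng.normal(size=(9, 8)), params)
        assert np.linalg.matrix_rank(T_hat.data) <= 8

    def test_perfect_reconstruction_zero_loss(self):
        T = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert reconstruction_loss(T, Tensor(T.copy()), 0.11).item() == 0.0

    def test_identity_target_hand_value(self):
        T = np.eye(2)
        loss = reconstruction_loss(T, Tensor(np.zeros((2, 2))), alpha=0.11)
        assert loss.item() == pytest.approx(0.89, abs=1e-12)

    def test_alpha_half_is_quarter_frobenius(self):
        rng = np.random.default_rng(21)
        T = (rng.random((3, 4)) < 0.5).astype(float)
        T_hat = rng.normal(size=(3, 4))
        loss = reconstruction_loss(T, Tensor(T_hat), alpha=0.5)
        assert loss.item() == pytest.approx(
            0.25 * ((T - T_hat) ** 2).sum(), abs=1e-10)

    def test_total_loss_composition(self):
        l_re = Tensor(0.5)
        total, bd = total_loss(l_re, Tensor(0.2), Tensor(0.3), 1.0, 1.0)
        assert total.item() == pytest.approx(1.0)
        assert bd.reconstruction == 0.5
        total0, _ = total_loss(l_re, Tensor(0.2), Tensor(0.3), 0.0, 0.0)
        assert total0.item() == pytest.approx(0.5)


class TestFullForward:
    def _inputs(self, seed=0, M=5, D=4):
        rng = np.random.default_rng(seed)
        T = (rng.random((M, D)) < 0.4).astype(float)
        T[0, 0] = 1
        Xm = rng.normal(size=(M, M + D))
        Xd = rng.normal(size=(D, M + D))
        Pm = np.eye(M)
        Pd = np.eye(D)
        return T, Xm, Xd, Pm, Pd

    def test_deterministic_given_seed(self):
        cfg = TINY
        T, Xm, Xd, Pm, Pd = self._inputs()
        outs = []
        for _ in range(2):
            params = init_params(cfg, Xm.shape[1], Xd.shape[1],
                                 np.random.default_rng(42))
            _, _, T_hat = forward(params, cfg, Xm, Xd, Pm, Pm, Pd, Pd, T)
            outs.append(T_hat.data)
        assert np.array_equal(outs[0], outs[1])

    def test_contrastive_terms_vanish_without_weights(self):
        cfg = TINY.replace(lam=0.0, gam=0.0)
        T, Xm, Xd, Pm, Pd = self._inputs()
        params = tiny_params(feat_m=Xm.shape[1], feat_d=Xd.shape[1])
        total, bd, _ = forward(params, cfg, Xm, Xd, Pm, Pm, Pd, Pd, T)
        assert bd.contrastive_mirna == bd.contrastive_disease == 0.0
        assert total.item() == pytest.approx(bd.reconstruction)

    def test_hgcn_amir_ablation_disables_contrastive(self):
        cfg = TINY.replace(ablation="hgcn_amir", lam=1.0, gam=1.0)
        T, Xm, Xd, Pm, Pd = self._inputs()
        params = tiny_params(feat_m=Xm.shape[1], feat_d=Xd.shape[1])
        _, bd, _ = forward(params, cfg, Xm, Xd, Pm, Pm, Pd, Pd, T)
        assert bd.contrastive_mirna == bd.contrastive_disease == 0.0

    def test_gradients_match_central_differences(self):
        """End-to-end gradient of the composite loss, spot-checked."""
        cfg = TINY
        T, Xm, Xd, Pm, Pd = self._inputs()
        params = tiny_params(feat_m=Xm.shape[1], feat_d=Xd.shape[1])

        def loss_value():
            total, _, _ = forward(params, cfg, Xm, Xd, Pm, Pm, Pd, Pd, T)
            return total.item()

        total, _, _ = forward(params, cfg, Xm, Xd, Pm, Pm, Pd, Pd, T)
        total.backward()
        eps = 1e-6
        for name in ("hgcn_m1_l0", "g_m_W1", "att_m_Wq0", "att_d_Wh",
                     "dec_d_W", "va_m_W2"):
            p = params[name]
            rng = np.random.default_rng(99)
            flat_idx = rng.choice(p.data.size, size=min(6, p.data.size),
                                  replace=False)
            for fi in flat_idx:
                idx = np.unravel_index(fi, p.data.shape)
                orig = p.data[idx]
                p.data[idx] = orig + eps
                hi = loss_value()
                p.data[idx] = orig - eps
                lo = loss_value()
                p.data[idx] = orig
                num = (hi - lo) / (2 * eps)
                assert p.grad[idx] == pytest.approx(num, abs=2e-4,
                                                    rel=1e-3), name
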