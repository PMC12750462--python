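"""LMSF: alignment, decomposition, queue contrast, gating, training step."""

import numpy as np
import pytest

from fedcpi.backbones import SmallResNet
from fedcpi.lmsf import (ContrastQueue, LMSFConfig, LMSFHead, SubspaceBundle,
                         alignment_loss, binary_cross_entropy, enqueue,
                         local_training_step, queue_contrastive_loss)
from fedcpi.nn import SGD, Tensor

TINY = LMSFConfig(d_large=2, d_small=2, d_shared=2, d_sub=2, d_fuse=2,
                  gate_hidden=2, queue_capacity=8, seed=0)


def _tiny_head(zero=False):
    head = LMSFHead(TINY)
    if zero:
        head.set_params({k: np.zeros_like(v) for k, v in head.get_params().items()})
    return head


def _softmax(x, axis=1):
    e = np.exp(x - x.max(axis=axis, keepdims=True))
    return e / e.sum(axis=axis, keepdims=True)


class TestProjectAlign:
    def test_zero_inputs_zero_weights_give_zero(self):
        head = _tiny_head(zero=True)
        al, asm = head.project_align(np.zeros((3, 2)), np.zeros((3, 2)))
        assert np.allclose(al.data, 0) and np.allclose(asm.data, 0)

    def test_single_sample_residual_plus_value(self, rng):
        # one key: attention softmax is exactly 1, output = proj + value proj
        head = _tiny_head()
        fl, fs = rng.normal(size=(1, 2)), rng.normal(size=(1, 2))
        p = head.get_params()
        pl = fl @ p["proj_large.w"] + p["proj_large.b"]
        ps = fs @ p["proj_small.w"] + p["proj_small.b"]
        expect_l = pl + (ps @ p["attn_v_small.w"] + p["attn_v_small.b"])
        expect_s = ps + (pl @ p["attn_v_large.w"] + p["attn_v_large.b"])
        al, asm = head.project_align(fl, fs)
        assert np.allclose(al.data, expect_l, atol=1e-12)
        assert np.allclose(asm.data, expect_s, atol=1e-12)

    def test_matches_hand_computed_attention(self, rng):
        head = _tiny_head()
        fl, fs = rng.normal(size=(2, 2)), rng.normal(size=(2, 2))
        p = head.get_params()
        lin = lambda x, name: x @ p[f"{name}.w"] + p[f"{name}.b"]
        pl, ps = lin(fl, "proj_large"), lin(fs, "proj_small")
        scale = 1 / np.sqrt(2)
        a_ls = _softmax(lin(pl, "attn_q_large") @ lin(ps, "attn_k_small").T * scale)
        a_sl = _softmax(lin(ps, "attn_q_small") @ lin(pl, "attn_k_large").T * scale)
        expect_l = pl + a_ls @ lin(ps, "attn_v_small")
        expect_s = ps + a_sl @ lin(pl, "attn_v_large")
        al, asm = head.project_align(fl, fs)
        assert np.allclose(al.data, expect_l, atol=1e-10)
        assert np.allclose(asm.data, expect_s, atol=1e-10)

    def test_batch_mismatch_rejected(self):
        with pytest.raises(ValueError):
            _tiny_head().project_align(np.zeros((2, 2)), np.zeros((3, 2)))


class TestAlignmentLoss:
    def test_identical_inputs_zero(self, rng):
        x = rng.normal(size=(5, 3))
        assert float(alignment_loss(x, x).data) == pytest.approx(0.0, abs=1e-9)

    def test_orthogonal_rows_one(self):
        a = np.array([[1.0, 0.0], [0.0, 2.0]])
        b = np.array([[0.0, 3.0], [4.0, 0.0]])
        assert float(alignment_loss(a, b).data) == pytest.approx(1.0)

    def test_known_angle(self):
        a = np.array([[1.0, 0.0]])
        b = np.array([[1.0, 1.0]]) / np.sqrt(2)
        assert float(alignment_loss(a, b).data) == pytest.approx(1 - np.sqrt(2) / 2,
                                                                 abs=1e-9)

    def test_bounded_zero_two(self, rng):
        for _ in range(20):
            v = float(alignment_loss(rng.normal(size=(4, 3)),
                                     rng.normal(size=(4, 3))).data)
            assert 0.0 <= v <= 2.0

    def test_zero_norm_row_counts_similarity_zero(self):
        a = np.array([[0.0, 0.0], [1.0, 0.0]])
        b = np.array([[1.0, 0.0], [1.0, 0.0]])
        assert float(alignment_loss(a, b).data) == pytest.approx(0.5, abs=1e-6)


class TestDecompose:
    def test_identical_branches_common_idempotent(self, rng):
        head = _tiny_head()
        x = Tensor(rng.normal(size=(3, 2)))
        bundle = head.decompose(x, x)
        p = head.get_params()
        expect = x.data @ p["common_head.w"] + p["common_head.b"]
        assert np.allclose(bundle.common.data, expect, atol=1e-12)

    def test_zero_everything_gives_zero_bundle(self):
        head = _tiny_head(zero=True)
        b = head.decompose(Tensor(np.zeros((2, 2))), Tensor(np.zeros((2, 2))))
        for block in b.blocks():
            assert np.allclose(block.data, 0)

    def test_matches_matrix_arithmetic(self, rng):
        head = _tiny_head()
        al, asm = Tensor(rng.normal(size=(2, 2))), Tensor(rng.normal(size=(2, 2)))
        p = head.get_params()
        b = head.decompose(al, asm)
        common = ((al.data @ p["common_head.w"] + p["common_head.b"])
                  + (asm.data @ p["common_head.w"] + p["common_head.b"])) / 2
        inter = (np.concatenate([al.data, asm.data], axis=1)
                 @ p["interactive_head.w"] + p["interactive_head.b"])
        assert np.allclose(b.common.data, common, atol=1e-12)
        assert np.allclose(b.interactive.data, inter, atol=1e-12)
        assert np.allclose(b.personal_large.data,
                           al.data @ p["personal_large_head.w"] + p["personal_large_head.b"])

    def test_bundle_batch_size_mismatch_rejected(self):
        with pytest.raises(ValueError):
            SubspaceBundle(Tensor(np.zeros((2, 2))), Tensor(np.zeros((3, 2))),
                           Tensor(np.zeros((2, 2))), Tensor(np.zeros((2, 2))))


class TestQueue:
    def test_fifo_eviction(self):
        q = ContrastQueue(capacity=2)
        enqueue(q, np.array([[1.0, 0], [2.0, 0], [3.0, 0]]), np.array([0, 1, 0]))
        embs, labs = q.matrix()
        assert len(q) == 2
        assert np.allclose(embs[:, 0], [2.0, 3.0])
        assert list(labs) == [1, 0]

    def test_order_preserved_under_capacity(self):
        q = ContrastQueue(capacity=8)
        assert len(q) == 0
        q.push(np.arange(6, dtype=float).reshape(3, 2), np.array([0, 1, 1]))
        embs, labs = q.matrix()
        assert np.allclose(embs, np.arange(6).reshape(3, 2))
        assert list(labs) == [0, 1, 1]

    def test_dim_mismatch_rejected(self):
        q = ContrastQueue(capacity=4)
        q.push(np.zeros((1, 3)), np.array([0]))
        with pytest.raises(ValueError):
            q.push(np.zeros((1, 2)), np.array([1]))


class TestQueueContrastiveLoss:
    def test_single_matching_entry_zero_loss(self):
        q = ContrastQueue(capacity=4, tau=1.0)
        q.push(np.array([[1.0, 0.0]]), np.array([1]))
        v = queue_contrastive_loss(np.array([[1.0, 0.0]]), np.array([1]), q, 1.0)
        assert float(v.data) == pytest.approx(0.0, abs=1e-12)

    def test_one_positive_one_negative_softmax_value(self):
        q = ContrastQueue(capacity=4, tau=1.0)
        q.push(np.array([[1.0, 0.0], [0.0, 1.0]]), np.array([1, 0]))
        v = queue_contrastive_loss(np.array([[1.0, 0.0]]), np.array([1]), q, 1.0)
        assert float(v.data) == pytest.approx(np.log(1 + np.exp(-1)), abs=1e-9)

    def test_symmetric_anchors_equal_loss(self):
        q = ContrastQueue(capacity=4, tau=0.5)
        q.push(np.array([[1.0, 0.0], [0.0, 1.0]]), np.array([0, 1]))
        va = queue_contrastive_loss(np.array([[1.0, 0.0]]), np.array([0]), q, 0.5)
        vb = queue_contrastive_loss(np.array([[0.0, 1.0]]), np.array([1]), q, 0.5)
        assert float(va.data) == pytest.approx(float(vb.data), abs=1e-12)

    def test_no_positive_anchor_returns_zero(self):
        q = ContrastQueue(capacity=4, tau=1.0)
        q.push(np.array([[1.0, 0.0]]), np.array([0]))
        v = queue_contrastive_loss(np.array([[1.0, 0.0]]), np.array([1]), q, 1.0)
        assert float(v.data) == 0.0

    def test_invariant_under_common_rotation(self, rng):
        anchors = rng.normal(size=(3, 4))
        entries = rng.normal(size=(6, 4))
        labels = np.array([0, 1, 1])
        qlabels = np.array([0, 1, 0, 1, 1, 0])
        theta = np.linalg.qr(rng.normal(size=(4, 4)))[0]   # orthogonal
        v1 = queue_contrastive_loss(anchors, labels,
                                    _filled_queue(entries, qlabels), 0.3)
        v2 = queue_contrastive_loss(anchors @ theta, labels,
                                    _filled_queue(entries @ theta, qlabels), 0.3)
        assert float(v1.data) == pytest.approx(float(v2.data), abs=1e-9)


def _filled_queue(embs, labs):
    q = ContrastQueue(capacity=len(labs), tau=0.3)
    q.push(embs, labs)
    return q


class TestGateFuse:
    def test_equal_logits_uniform_weights(self, rng):
        head = _tiny_head(zero=True)
        bundle = head.decompose(Tensor(rng.normal(size=(3, 2))),
                                Tensor(rng.normal(size=(3, 2))))
        _, w = head.gate_fuse(bundle)
        assert np.allclose(w, 0.25)

    def test_weights_form_simplex(self, rng):
        head = _tiny_head()
        bundle = head.decompose(Tensor(rng.normal(size=(5, 2))),
                                Tensor(rng.normal(size=(5, 2))))
        _, w = head.gate_fuse(bundle)
        assert (w >= 0).all()
        assert np.allclose(w.sum(axis=1), 1.0, atol=1e-6)

    def test_known_gate_logits(self, rng):
        head = _tiny_head(zero=True)
        params = head.get_params()
        params["gate_out.b"] = np.array([1.0, 0.0, 0.0, 0.0])
        head.set_params(params)
        bundle = head.decompose(Tensor(rng.normal(size=(2, 2))),
                                Tensor(rng.normal(size=(2, 2))))
        _, w = head.gate_fuse(bundle)
        e = np.e
        assert np.allclose(w[:, 0], e / (e + 3), atol=1e-9)
        assert np.allclose(w[:, 1:], 1 / (e + 3), atol=1e-9)

    def test_dominant_logit_selects_block(self, rng):
        head = _tiny_head()
        params = head.get_params()
        params["gate_in.w"] = np.zeros_like(params["gate_in.w"])
        params["gate_in.b"] = np.zeros_like(params["gate_in.b"])
        params["gate_out.w"] = np.zeros_like(params["gate_out.w"])
        params["gate_out.b"] = np.array([50.0, 0.0, 0.0, 0.0])
        head.set_params(params)
        bundle = head.decompose(Tensor(rng.normal(size=(2, 2))),
                                Tensor(rng.normal(size=(2, 2))))
        fused, w = head.gate_fuse(bundle)
        p = head.get_params()
        phi_c = bundle.common.data @ p["phi_common.w"] + p["phi_common.b"]
        assert w[0, 0] > 1 - 1e-15
        assert np.allclose(fused.data, phi_c, atol=1e-9)


class TestClassify:
    def test_zero_head_gives_half(self):
        head = _tiny_head(zero=True)
        probs = head.classify(Tensor(np.ones((3, 2)))).data
        assert np.allclose(probs, 0.5)

    def test_logistic_link_value_and_monotonicity(self):
        head = _tiny_head(zero=True)
        params = head.get_params()
        params["classifier.w"] = np.array([[1.0], [0.0]])
        head.set_params(params)
        p1 = head.classify(Tensor(np.array([[1.0, 0.0]]))).data[0, 0]
        p2 = head.classify(Tensor(np.array([[2.0, 0.0]]))).data[0, 0]
        assert p1 == pytest.approx(1 / (1 + np.exp(-1)), abs=1e-12)
        assert 0.0 < p1 < p2 < 1.0


class TestLocalTrainingStep:
    @staticmethod
    def _setup(seed=0):
        cfg = LMSFConfig(d_large=8, d_small=8, d_shared=8, d_sub=4, d_fuse=4,
                         gate_hidden=4, queue_capacity=16, seed=seed)
        head = LMSFHead(cfg)
        small = SmallResNet(dim=8, width_mult=0.1, seed=seed + 1)
        rng = np.random.default_rng(3)
        imgs = np.clip(0.5 + rng.normal(0, 0.1, size=(6, 16, 16)), 0, 1)
        imgs[:3, 4:12, 4:12] = 0.95
        labels = np.array([1, 1, 1, 0, 0, 0])
        f_large = rng.normal(size=(6, 8))
        return cfg, head, small, imgs, labels, f_large

    def test_zero_aux_weights_reduce_to_plain_ce_trajectory(self):
        from dataclasses import replace

        cfg, head, small, imgs, labels, f_large = self._setup()
        cfg0 = replace(cfg, lambda_align=0.0, lambda_queue=0.0, lambda_kd=0.0)
        head2 = LMSFHead(cfg0)
        head2.set_params(head.get_params())
        small2 = SmallResNet(dim=8, width_mult=0.1, seed=1)
        small2.set_params(small.get_params())

        opt1 = SGD({**head.named_parameters(),
                    **{f"s.{k}": v for k, v in small.named_parameters().items()}},
                   lr=0.05, momentum=0.9)
        opt2 = SGD({**head2.named_parameters(),
                    **{f"s.{k}": v for k, v in small2.named_parameters().items()}},
                   lr=0.05, momentum=0.9)
        queue = ContrastQueue(capacity=16)
        for _ in range(2):
            local_training_step(head2, small2, f_large, imgs, labels, opt2,
                                queue, cfg=cfg0)
            out = head.forward(f_large, small.forward(imgs))
            ce = binary_cross_entropy(out["logits"], labels)
            opt1.zero_grad()
            ce.backward()
            opt1.step()
        p1, p2 = head.get_params(), head2.get_params()
        assert all(np.array_equal(p1[k], p2[k]) for k in p1)

    def test_no_teacher_means_zero_distill_term(self):
        cfg, head, small, imgs, labels, f_large = self._setup()
        opt = SGD({**head.named_parameters(), **small.named_parameters()}, lr=0.01)
        queue = ContrastQueue(capacity=16)
        breakdown = local_training_step(head, small, f_large, imgs, labels,
                                        opt, queue, cfg=cfg)
        assert breakdown.distill == 0.0
        assert breakdown.total == pytest.approx(
            breakdown.ce + cfg.lambda_align * breakdown.align
            + cfg.lambda_queue * breakdown.contrast, abs=1e-9)

    def test_ce_decreases_on_separable_toy(self):
        cfg, head, small, imgs, labels, f_large = self._setup()
        opt = SGD({**head.named_parameters(),
                   **{f"s.{k}": v for k, v in small.named_parameters().items()}},
                  lr=0.05, momentum=0.9)
        queue = ContrastQueue(capacity=16)
        ces = [local_training_step(head, small, f_large, imgs, labels, opt,
                                   queue, cfg=cfg).ce for _ in range(6)]
        assert ces[-1] < ces[0]

    def test_queue_receives_common_embeddings(self):
        cfg, head, small, imgs, labels, f_large = self._setup()
        opt = SGD(head.named_parameters(), lr=0.01)
        queue = ContrastQueue(capacity=16)
        local_training_step(head, small, f_large, imgs, labels, opt, queue, cfg=cfg)
        assert len(queue) == len(labels)
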