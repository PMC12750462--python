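"""Large-small model feature decomposition and fusion (LMSF).

Client-side representation machinery: the frozen large-encoder features and
the trainable small-CNN features are

1. projected to a shared width and **aligned** by single-head cross-attention
   in both directions (attention runs over the batch: each sample attends to
   every sample of the other branch) with a residual connection, pulled
   together by a cosine alignment loss;
2. **decomposed** into four subspace blocks — common (shared head applied to
   both branches, averaged), personal-large, personal-small (branch-specific
   heads), and interactive (head on the concatenated aligned pair);
3. regularized by a **queue-based supervised contrastive loss** (InfoNCE
   against a FIFO memory of past common-space embeddings with labels);
4. **fused** by a gating network emitting per-sample convex weights over the
   four projected blocks, followed by a logistic risk-score head.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass

import numpy as np

from .nn import (Linear, Module, SGD, Tensor, as_tensor, concat, layer_norm,
                 logsumexp, softmax, softplus)

log = logging.getLogger(__name__)

__all__ = [
    "LMSFConfig", "SubspaceBundle", "ContrastQueue", "LossBreakdown",
    "LMSFHead", "alignment_loss", "enqueue", "queue_contrastive_loss",
    "binary_cross_entropy", "local_training_step",
]


@dataclass(frozen=True)
class LMSFConfig:
    d_large: int = 768
    d_small: int = 512
    d_shared: int = 256
    d_sub: int = 128
    d_fuse: int = 128
    gate_hidden: int = 32
    queue_capacity: int = 1024
    tau: float = 0.1              # contrastive temperature
    lambda_align: float = 0.1
    lambda_queue: float = 0.1
    lambda_kd: float = 0.5
    kd_temperature: float = 2.0
    seed: int = 0


@dataclass
class SubspaceBundle:
    """The four decomposed feature blocks for a batch (autograd tensors)."""

    common: Tensor
    personal_large: Tensor
    personal_small: Tensor
    interactive: Tensor

    def __post_init__(self):
        ns = {b.shape[0] for b in self.blocks()}
        if len(ns) != 1:
            raise ValueError("all blocks must share the batch size")

    def blocks(self) -> tuple[Tensor, Tensor, Tensor, Tensor]:
        return (self.common, self.personal_large, self.personal_small, self.interactive)

    def numpy(self) -> dict[str, np.ndarray]:
        return {k: getattr(self, k).data.copy()
                for k in ("common", "personal_large", "personal_small", "interactive")}


class ContrastQueue:
    """FIFO memory of (embedding, label) pairs for supervised contrast."""

    def __init__(self, capacity: int = 1024, tau: float = 0.1):
        if capacity < 1 or tau <= 0:
            raise ValueError("capacity must be >= 1 and tau > 0")
        self.capacity = capacity
        self.tau = tau
        self._store: deque[tuple[np.ndarray, int]] = deque(maxlen=capacity)

    def __len__(self) -> int:
        return len(self._store)

    def push(self, embeddings: np.ndarray, labels: np.ndarray) -> None:
        embeddings = np.asarray(embeddings, dtype=np.float64)
        if self._store and embeddings.shape[1] != self._store[0][0].shape[0]:
            raise ValueError("embedding dim differs from stored entries")
        for e, y in zip(embeddings, np.asarray(labels)):
            self._store.append((e.copy(), int(y)))

    def matrix(self) -> tuple[np.ndarray, np.ndarray]:
        embs = np.stack([e for e, _ in self._store])
        labs = np.array([y for _, y in self._store])
        return embs, labs

    def clear(self) -> None:
        """Drop all entries (stored embeddings go stale when the encoder's
        parameters are replaced, e.g. after a federated broadcast)."""
        self._store.clear()


def enqueue(queue: ContrastQueue, embeddings: np.ndarray,
            labels: np.ndarray) -> ContrastQueue:
    queue.push(embeddings, labels)
    return queue


@dataclass
class LossBreakdown:
    ce: float
    align: float
    contrast: float
    distill: float
    total: float


def _row_norms(x: Tensor, eps: float = 1e-12) -> Tensor:
    return ((x * x).sum(axis=1, keepdims=True) + eps) ** 0.5


def alignment_loss(aligned_large, aligned_small) -> Tensor:
    """1 - mean per-sample cosine similarity; in [0, 2].

    A zero-norm row contributes similarity 0 (loss contribution 1) and is
    logged.
    """
    a, b = as_tensor(aligned_large), as_tensor(aligned_small)
    if a.shape != b.shape:
        raise ValueError("aligned batches must share shape")
    if (np.linalg.norm(a.data, axis=1) < 1e-12).any() or \
       (np.linalg.norm(b.data, axis=1) < 1e-12).any():
        log.warning("alignment_loss: zero-norm row encountered")
    cos = (a * b).sum(axis=1, keepdims=True) / (_row_norms(a) * _row_norms(b))
    return 1.0 - cos.mean()


def queue_contrastive_loss(anchors, labels, queue: ContrastQueue,
                           tau: float | None = None) -> Tensor:
    """Supervised InfoNCE of anchors against the queue.

    Anchors with no same-label entry in the queue are skipped; if none has a
    positive the loss is 0 (warm-up) with a logged warning.
    """
    a = as_tensor(anchors)
    labels = np.asarray(labels)
    tau = queue.tau if tau is None else tau
    if tau <= 0:
        raise ValueError("tau must be positive")
    if len(queue) == 0:
        log.warning("queue_contrastive_loss: empty queue, returning 0")
        return Tensor(0.0)
    q_emb, q_lab = queue.matrix()
    pos = (labels[:, None] == q_lab[None, :]).astype(np.float64)
    n_pos = pos.sum(axis=1)
    contributing = n_pos > 0
    if not contributing.any():
        log.warning("queue_contrastive_loss: no anchor has a positive, returning 0")
        return Tensor(0.0)
    a_n = a / _row_norms(a)
    q_n = q_emb / np.maximum(np.linalg.norm(q_emb, axis=1, keepdims=True), 1e-12)
    logits = (a_n @ Tensor(q_n.T)) * (1.0 / tau)
    logp = logits - logsumexp(logits, axis=1)
    weights = np.where(contributing[:, None], pos / np.maximum(n_pos, 1.0)[:, None], 0.0)
    return -(logp * Tensor(weights)).sum() * (1.0 / contributing.sum())


def binary_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean BCE-with-logits; labels 0/1, logits (n, 1) or (n,)."""
    y = np.asarray(labels, dtype=np.float64).reshape(-1, 1)
    z = logits if logits.ndim == 2 else logits.reshape(-1, 1)
    return (softplus(z) - z * Tensor(y)).mean()


class LMSFHead(Module):
    """All trainable LMSF machinery above the two feature extractors."""

    def __init__(self, cfg: LMSFConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        d = cfg.d_shared
        self.proj_large = Linear(cfg.d_large, d, rng)
        self.proj_small = Linear(cfg.d_small, d, rng)
        self.attn_q_large = Linear(d, d, rng)
        self.attn_k_small = Linear(d, d, rng)
        self.attn_v_small = Linear(d, d, rng)
        self.attn_q_small = Linear(d, d, rng)
        self.attn_k_large = Linear(d, d, rng)
        self.attn_v_large = Linear(d, d, rng)
        self.common_head = Linear(d, cfg.d_sub, rng)
        self.personal_large_head = Linear(d, cfg.d_sub, rng)
        self.personal_small_head = Linear(d, cfg.d_sub, rng)
        self.interactive_head = Linear(2 * d, cfg.d_sub, rng)
        self.phi_common = Linear(cfg.d_sub, cfg.d_fuse, rng)
        self.phi_personal_large = Linear(cfg.d_sub, cfg.d_fuse, rng)
        self.phi_personal_small = Linear(cfg.d_sub, cfg.d_fuse, rng)
        self.phi_interactive = Linear(cfg.d_sub, cfg.d_fuse, rng)
        self.gate_in = Linear(4 * cfg.d_sub, cfg.gate_hidden, rng)
        # zero-init final layers: the gate starts uniform (1/4 each) and the
        # risk head starts at probability 1/2, so early rounds are stable
        self.gate_out = Linear(cfg.gate_hidden, 4, rng, zero_init=True)
        self.classifier = Linear(cfg.d_fuse, 1, rng, zero_init=True)

    # -- forward pieces ---------------------------------------------------
    def project_align(self, f_large, f_small, context=None) -> tuple[Tensor, Tensor]:
        """Shared-width projection + bidirectional single-head cross-attention
        with residual connections.

        By default attention runs over the batch (each sample attends to
        every sample of the other branch).  Passing ``context`` — a pair of
        raw (f_large_ctx, f_small_ctx) feature sets — draws keys and values
        from that fixed set instead, which makes inference per-sample
        deterministic and independent of how the evaluation data is batched.
        """
        fl, fs = as_tensor(f_large), as_tensor(f_small)
        if fl.shape[0] != fs.shape[0]:
            raise ValueError("batch size mismatch between branches")
        pl, ps = self.proj_large(fl), self.proj_small(fs)
        if context is None:
            pl_ctx, ps_ctx = pl, ps
        else:
            pl_ctx = self.proj_large(as_tensor(context[0]))
            ps_ctx = self.proj_small(as_tensor(context[1]))
        scale = 1.0 / np.sqrt(self.cfg.d_shared)
        attn_ls = softmax((self.attn_q_large(pl) @ self.attn_k_small(ps_ctx).T) * scale, axis=1)
        attn_sl = softmax((self.attn_q_small(ps) @ self.attn_k_large(pl_ctx).T) * scale, axis=1)
        aligned_large = pl + attn_ls @ self.attn_v_small(ps_ctx)
        aligned_small = ps + attn_sl @ self.attn_v_large(pl_ctx)
        return aligned_large, aligned_small

    def decompose(self, aligned_large: Tensor, aligned_small: Tensor) -> SubspaceBundle:
        common = (self.common_head(aligned_large) + self.common_head(aligned_small)) * 0.5
        return SubspaceBundle(
            common=common,
            personal_large=self.personal_large_head(aligned_large),
            personal_small=self.personal_small_head(aligned_small),
            interactive=self.interactive_head(concat([aligned_large, aligned_small])),
        )

    def gate_fuse(self, bundle: SubspaceBundle) -> tuple[Tensor, np.ndarray]:
        """Per-sample convex combination of the four projected blocks."""
        cat = concat(list(bundle.blocks()))
        w = softmax(self.gate_out(self.gate_in(cat).relu()), axis=1)
        projected = [self.phi_common(bundle.common),
                     self.phi_personal_large(bundle.personal_large),
                     self.phi_personal_small(bundle.personal_small),
                     self.phi_interactive(bundle.interactive)]
        fused = projected[0] * w[:, 0:1]
        for i in (1, 2, 3):
            fused = fused + projected[i] * w[:, i:i + 1]
        return fused, w.data.copy()

    def classify(self, fused: Tensor) -> Tensor:
        """Risk probability in (0, 1)."""
        return self.logits(fused).sigmoid()

    def logits(self, fused: Tensor) -> Tensor:
        return self.classifier(fused)

    def forward(self, f_large, f_small, context=None) -> dict:
        al, asm = self.project_align(f_large, f_small, context=context)
        # standardize the aligned features before the subspace heads: the
        # attention residual can drift in scale, the heads should not
        bundle = self.decompose(layer_norm(al), layer_norm(asm))
        fused, gate_w = self.gate_fuse(bundle)
        z = self.logits(fused)
        return {"aligned_large": al, "aligned_small": asm, "bundle": bundle,
                "fused": fused, "gate_weights": gate_w, "logits": z,
                "probs": 1.0 / (1.0 + np.exp(-np.clip(z.data[:, 0], -500, 500)))}


def local_training_step(head: LMSFHead, small, f_large_np: np.ndarray,
                        images: np.ndarray, labels: np.ndarray,
                        optimizer: SGD, queue: ContrastQueue,
                        teacher_outputs: dict | None = None,
                        cfg: LMSFConfig | None = None) -> LossBreakdown:
    """One optimizer step on the composite objective.

    ``f_large_np`` are the frozen large-encoder features (no gradient flows
    into the frozen branch); the distillation term is active only when
    ``teacher_outputs`` is provided.  The queue is updated with the current
    (detached) common-space embeddings after the step.
    """
    from .facm import distillation_loss  # facm never imports lmsf

    cfg = cfg or head.cfg
    f_small = small.forward(images)
    out = head.forward(f_large_np, f_small)
    ce = binary_cross_entropy(out["logits"], labels)
    align = alignment_loss(out["aligned_large"], out["aligned_small"])
    contrast = queue_contrastive_loss(out["bundle"].common, labels, queue, cfg.tau)
    if teacher_outputs is not None:
        distill = distillation_loss(
            {"common": out["bundle"].common, "interactive": out["bundle"].interactive,
             "logits": out["logits"]},
            teacher_outputs, T=cfg.kd_temperature)
    else:
        distill = Tensor(0.0)
    total = (ce + cfg.lambda_align * align + cfg.lambda_queue * contrast
             + cfg.lambda_kd * distill)
    if not np.isfinite(total.data):
        raise RuntimeError(
            f"non-finite training loss (ce={ce.data}, align={align.data}, "
            f"contrast={contrast.data}, distill={distill.data}); aborting round")
    optimizer.zero_grad()
    total.backward()
    optimizer.step()
    queue.push(out["bundle"].common.data, labels)
    return LossBreakdown(ce=float(ce.data), align=float(align.data),
                         contrast=float(contrast.data), distill=float(distill.data),
                         total=float(total.data))
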