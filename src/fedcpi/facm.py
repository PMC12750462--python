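"""Federated adaptive communication mechanism (FACM): server-side,
subspace-aware aggregation.

Every trainable tensor carries exactly one aggregation tag:

* ``COMMON``  — common head, fusion projections, classifier: uniform (or
  optionally sample-weighted) global averaging;
* ``PERSONAL`` — personal heads and gate: **never leaves the client**;
* ``INTERACTIVE`` — interactive head and cross-attention: weighted mean with
  performance-driven (softmax over validation AUC) client weights;
* ``BACKBONE`` — the small CNN: classic FedAvg (sample-count weighted mean).

After aggregation the global encoder acts as a teacher for module-level
knowledge distillation on each client's own batches.  Broadcast payloads
round-trip through bytes and are guaranteed free of PERSONAL tensors.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

from .nn import Tensor, as_tensor, softplus

__all__ = [
    "TAGS", "ParamSet", "ClientUpdate", "ServerState", "PrivacyError",
    "aggregate_common", "interactive_weights", "aggregate_interactive",
    "aggregate_backbone", "distillation_loss", "server_round",
    "serialize_fragment", "deserialize_fragment",
]

TAGS = ("COMMON", "PERSONAL", "INTERACTIVE", "BACKBONE")
SHAREABLE = ("COMMON", "INTERACTIVE", "BACKBONE")


class PrivacyError(RuntimeError):
    """A PERSONAL-tagged tensor reached a server-side structure."""


@dataclass
class ParamSet:
    """Named tensors with aggregation tags."""

    tensors: dict[str, np.ndarray]
    tags: dict[str, str]

    def __post_init__(self):
        if set(self.tensors) != set(self.tags):
            raise ValueError("tensors and tags must cover the same names")
        bad = {t for t in self.tags.values()} - set(TAGS)
        if bad:
            raise ValueError(f"unknown tags: {sorted(bad)}")

    def fragment(self, *tags: str) -> "ParamSet":
        keep = {k for k, t in self.tags.items() if t in tags}
        return ParamSet({k: self.tensors[k] for k in keep},
                        {k: self.tags[k] for k in keep})

    def names(self) -> list[str]:
        return sorted(self.tensors)


@dataclass
class ClientUpdate:
    client_id: str
    params: ParamSet          # shareable fragments only
    n_train: int
    val_perf: float           # validation AUC in [0, 1]

    def __post_init__(self):
        if not 0.0 <= self.val_perf <= 1.0:
            raise ValueError("val_perf must lie in [0, 1]")
        if self.n_train < 1:
            raise ValueError("n_train must be >= 1")
        _assert_no_personal(self.params)


@dataclass
class ServerState:
    round_index: int = 0
    global_params: ParamSet | None = None
    weight_log: list[dict] = field(default_factory=list)


def _assert_no_personal(ps: ParamSet) -> None:
    personal = [k for k, t in ps.tags.items() if t == "PERSONAL"]
    if personal:
        raise PrivacyError(
            f"PERSONAL tensors must never reach the server: {sorted(personal)}")


def _check_congruent(frags: list[ParamSet]) -> list[str]:
    names = frags[0].names()
    for f in frags[1:]:
        if f.names() != names:
            raise ValueError("updates carry different tensor names")
    for name in names:
        shapes = {f.tensors[name].shape for f in frags}
        if len(shapes) != 1:
            raise ValueError(f"shape mismatch for tensor {name!r}: {shapes}")
    return names


def _weighted_mean(frags: list[ParamSet], weights: np.ndarray) -> ParamSet:
    names = _check_congruent(frags)
    out = {name: sum(w * f.tensors[name] for w, f in zip(weights, frags))
           for name in names}
    return ParamSet(out, dict(frags[0].tags))


def aggregate_common(updates: list[ClientUpdate], n_weighted: bool = False) -> ParamSet:
    """Element-wise mean of the COMMON fragments (uniform by default)."""
    if not updates:
        raise ValueError("need at least one update")
    frags = [u.params.fragment("COMMON") for u in updates]
    if n_weighted:
        n = np.array([u.n_train for u in updates], dtype=np.float64)
        w = n / n.sum()
    else:
        w = np.full(len(updates), 1.0 / len(updates))
    return _weighted_mean(frags, w)


def interactive_weights(val_perfs, tau_w: float = 0.1) -> np.ndarray:
    """Softmax over client validation performances at temperature ``tau_w``."""
    if tau_w <= 0:
        raise ValueError("tau_w must be positive")
    p = np.asarray(val_perfs, dtype=np.float64)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("val_perfs must lie in [0, 1]")
    z = p / tau_w
    z -= z.max()
    e = np.exp(z)
    return e / e.sum()


def aggregate_interactive(updates: list[ClientUpdate], weights) -> ParamSet:
    weights = np.asarray(weights, dtype=np.float64)
    if len(weights) != len(updates):
        raise ValueError("one weight per update required")
    if abs(weights.sum() - 1.0) > 1e-8:
        raise ValueError("weights must sum to 1")
    return _weighted_mean([u.params.fragment("INTERACTIVE") for u in updates], weights)


def aggregate_backbone(updates: list[ClientUpdate]) -> ParamSet:
    """FedAvg rule: sample-count weighted mean of the small-CNN tensors."""
    if not updates:
        raise ValueError("need at least one update")
    n = np.array([u.n_train for u in updates], dtype=np.float64)
    return _weighted_mean([u.params.fragment("BACKBONE") for u in updates], n / n.sum())


def _binary_log_softmax(z: Tensor, T: float) -> tuple[Tensor, Tensor]:
    """log-probabilities of the 2-class distribution softmax((0, z/T))."""
    zt = z * (1.0 / T)
    sp = softplus(zt)
    return -sp, zt - sp  # log p(class 0), log p(class 1)


def distillation_loss(student: dict, teacher: dict, T: float = 2.0) -> Tensor:
    """MSE on common and interactive blocks plus T^2-scaled KL between
    temperature-softened class distributions, KL(teacher || student).

    ``student`` holds autograd tensors; ``teacher`` holds plain arrays (the
    teacher is the freshly aggregated global encoder, gradients blocked).
    Exactly 0 when student equals teacher on all compared outputs.
    """
    loss = Tensor(0.0)
    for key in ("common", "interactive"):
        s = as_tensor(student[key])
        t = np.asarray(teacher[key].data if isinstance(teacher[key], Tensor)
                       else teacher[key], dtype=np.float64)
        diff = s - Tensor(t)
        loss = loss + (diff * diff).mean()
    zs = as_tensor(student["logits"]).reshape(-1, 1)
    zt = np.asarray(teacher["logits"].data if isinstance(teacher["logits"], Tensor)
                    else teacher["logits"], dtype=np.float64).reshape(-1, 1)
    log_s0, log_s1 = _binary_log_softmax(zs, T)
    pt1 = 1.0 / (1.0 + np.exp(-zt / T))
    pt0 = 1.0 - pt1
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = np.where(pt0 > 0, pt0 * np.log(pt0), 0.0) + \
              np.where(pt1 > 0, pt1 * np.log(pt1), 0.0)
    kl = (Tensor(ent) - Tensor(pt0) * log_s0 - Tensor(pt1) * log_s1).mean()
    return loss + (T ** 2) * kl


def server_round(server: ServerState, updates: list[ClientUpdate],
                 tau_w: float = 0.1, common_n_weighted: bool = False) -> ServerState:
    """Apply all aggregation rules, increment the round, log the weights."""
    if not updates:
        raise ValueError("server_round requires at least one update")
    for u in updates:
        _assert_no_personal(u.params)
    perfs = [u.val_perf for u in updates]
    w_int = interactive_weights(perfs, tau_w=tau_w)
    common = aggregate_common(updates, n_weighted=common_n_weighted)
    interactive = aggregate_interactive(updates, w_int)
    backbone = aggregate_backbone(updates)
    merged = ParamSet(
        {**common.tensors, **interactive.tensors, **backbone.tensors},
        {**common.tags, **interactive.tags, **backbone.tags},
    )
    log_entry = {"round": server.round_index + 1,
                 "clients": [u.client_id for u in updates],
                 "val_perfs": list(map(float, perfs)),
                 "interactive_weights": w_int.tolist()}
    return ServerState(round_index=server.round_index + 1,
                       global_params=merged,
                       weight_log=server.weight_log + [log_entry])


# -- serialization boundary (broadcast payloads must round-trip bytes) ----

def serialize_fragment(ps: ParamSet) -> bytes:
    """Serialize a shareable fragment; refuses PERSONAL tensors."""
    _assert_no_personal(ps)
    buf = io.BytesIO()
    np.savez(buf, **{f"{ps.tags[k]}::{k}": v for k, v in ps.tensors.items()})
    return buf.getvalue()


def deserialize_fragment(payload: bytes) -> ParamSet:
    tensors: dict[str, np.ndarray] = {}
    tags: dict[str, str] = {}
    with np.load(io.BytesIO(payload), allow_pickle=False) as z:
        for key in z.files:
            tag, name = key.split("::", 1)
            tensors[name] = z[key]
            tags[name] = tag
    ps = ParamSet(tensors, tags)
    _assert_no_personal(ps)
    return ps
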