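"""Multi-round federated training: the full framework, baselines, ablations.

Strategies
----------
``fedcpi``   frozen large encoder + small CNN + LMSF head per client; server
             applies the subspace-aware FACM rules and the broadcast global
             model acts as a distillation teacher during the next round.
``fedavg``   small CNN + linear classifier; sample-count-weighted averaging
             of all trainable tensors.
``fedprox``  FedAvg plus the proximal term mu/2 * ||theta - theta_g||^2
             (applied as a gradient penalty toward the broadcast model).
``moon``     FedAvg plus model-contrastive loss pulling the local embedding
             toward the global model's and away from the previous local one.
``local``    no communication at all (per-center training).

Ablations (``fedcpi`` only): ``no_lmsf`` drops the decomposition/fusion head
(small-CNN features go straight into a linear classifier; FACM's backbone
aggregation and teacher distillation remain); ``no_facm`` keeps the full LMSF
model but replaces the server with a plain uniform average of all shareable
tensors (no performance weighting, no distillation).

All randomness derives from ``FedConfig.seed``; reruns are bit-identical.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np

from . import facm
from .backbones import LargeEncoder, SmallResNet
from .clineval import MetricReport, ScoreSet, confusion_report, youden_threshold
from .facm import ClientUpdate, ParamSet, ServerState, deserialize_fragment, serialize_fragment
from .lmsf import (ContrastQueue, LMSFConfig, LMSFHead, binary_cross_entropy,
                   local_training_step)
from .nn import Linear, Module, SGD, Tensor, as_tensor, no_grad, softplus
from .synth import CenterDataset

__all__ = [
    "FedConfig", "ExperimentResult", "desk_lmsf_config", "run_experiment",
    "fedavg_aggregate", "fedprox_penalty", "moon_contrast", "resolve_variant",
    "FedCPIModel", "PlainModel", "subspace_tables",
]

STRATEGIES = ("fedcpi", "fedavg", "fedprox", "moon", "local")


def desk_lmsf_config(seed: int = 0) -> LMSFConfig:
    """Desk-scale preset: dimensions small enough for minutes of CPU per
    federated run, auxiliary-loss weights calibrated so the contrastive /
    alignment / distillation terms guide rather than dominate the short
    training schedule.  All values are configurable."""
    return LMSFConfig(d_large=96, d_small=64, d_shared=64, d_sub=32,
                      d_fuse=32, gate_hidden=16, queue_capacity=256,
                      lambda_align=0.05, lambda_queue=0.02, lambda_kd=0.1,
                      seed=seed)


@dataclass(frozen=True)
class FedConfig:
    strategy: str = "fedcpi"
    rounds: int = 15
    local_epochs: int = 3
    batch_size: int = 16
    lr: float = 0.03
    momentum: float = 0.9
    seed: int = 0
    mu_prox: float = 0.01
    moon_mu: float = 1.0
    moon_tau: float = 0.5
    no_lmsf: bool = False
    no_facm: bool = False
    tau_w: float = 0.1
    common_n_weighted: bool = False
    val_fraction: float = 0.2
    queue_reset: bool = True     # clear the contrast queue after each broadcast
    precision: str = "float32"   # engine dtype for the run; "float64" for exact
    d_large: int = 96
    large_widths: tuple = (8, 16, 32)
    large_seed: int = 0            # frozen encoder is seed-pinned, not per-run
    d_small: int = 64
    width_mult: float = 0.25
    lmsf: LMSFConfig | None = None

    def __post_init__(self):
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.rounds < 1 or self.local_epochs < 1:
            raise ValueError("rounds and local_epochs must be >= 1")
        if (self.no_lmsf or self.no_facm) and self.strategy != "fedcpi":
            raise ValueError("ablation flags are only valid with strategy fedcpi")
        if self.no_lmsf and self.no_facm:
            raise ValueError("set at most one ablation flag per variant run")
        if self.mu_prox < 0:
            raise ValueError("mu_prox must be >= 0")
        if self.precision not in ("float32", "float64"):
            raise ValueError("precision must be float32 or float64")


def resolve_variant(config: FedConfig) -> str:
    """Name of the wiring the config selects."""
    if config.strategy != "fedcpi":
        return config.strategy
    if config.no_lmsf:
        return "fedcpi_no_lmsf"
    if config.no_facm:
        return "fedcpi_no_facm"
    return "fedcpi"


# -- models ----------------------------------------------------------------

_TAG_PREFIXES = [
    ("small.", "BACKBONE"),
    ("head.personal_", "PERSONAL"),
    ("head.gate_", "PERSONAL"),
    ("head.common_head.", "COMMON"),
    ("head.phi_", "COMMON"),
    ("head.classifier.", "COMMON"),
    ("head.proj_", "INTERACTIVE"),
    ("head.attn_", "INTERACTIVE"),
    ("head.interactive_head.", "INTERACTIVE"),
    ("clf.", "COMMON"),
]


def _tag_of(name: str, overrides: dict[str, str] | None = None) -> str:
    if overrides:
        for prefix, tag in overrides.items():
            if name.startswith(prefix):
                return tag
    for prefix, tag in _TAG_PREFIXES:
        if name.startswith(prefix):
            return tag
    raise ValueError(f"no aggregation tag for parameter {name!r}")


class FedCPIModel(Module):
    """Small CNN + LMSF head (the frozen large encoder is shared externally)."""

    def __init__(self, cfg: FedConfig, init_seed: int):
        lmsf_cfg = cfg.lmsf or desk_lmsf_config()
        lmsf_cfg = replace(lmsf_cfg, d_large=cfg.d_large, d_small=cfg.d_small,
                           seed=init_seed)
        self.small = SmallResNet(dim=cfg.d_small, width_mult=cfg.width_mult,
                                 seed=init_seed + 1)
        self.head = LMSFHead(lmsf_cfg)
        self.cfg = lmsf_cfg

    def forward(self, large: LargeEncoder, images: np.ndarray) -> dict:
        f_large = large.forward(images).data    # frozen: no gradient flows back
        out = self.head.forward(f_large, self.small.forward(images))
        out["f_large"] = f_large
        return out

    def param_set(self, overrides: dict[str, str] | None = None) -> ParamSet:
        tensors = self.get_params()
        return ParamSet(tensors, {k: _tag_of(k, overrides) for k in tensors})

    def load_fragment(self, ps: ParamSet) -> None:
        self.set_params(ps.tensors)


class PlainModel(Module):
    """Small CNN feeding a linear classifier (baselines and no-LMSF)."""

    def __init__(self, cfg: FedConfig, init_seed: int):
        self.small = SmallResNet(dim=cfg.d_small, width_mult=cfg.width_mult,
                                 seed=init_seed + 1)
        self.clf = Linear(cfg.d_small, 1, np.random.default_rng(init_seed + 2))

    def forward(self, images: np.ndarray) -> tuple[Tensor, Tensor]:
        emb = self.small.forward(images)
        return emb, self.clf(emb)

    def param_set(self, overrides: dict[str, str] | None = None) -> ParamSet:
        tensors = self.get_params()
        return ParamSet(tensors, {k: _tag_of(k, overrides) for k in tensors})

    def load_fragment(self, ps: ParamSet) -> None:
        self.set_params(ps.tensors)


# -- baseline primitives ---------------------------------------------------

def fedavg_aggregate(param_sets: list[dict[str, np.ndarray]], n_list) -> dict[str, np.ndarray]:
    """Sample-count-weighted element-wise mean over all tensors."""
    if not param_sets:
        raise ValueError("need at least one parameter set")
    n = np.asarray(n_list, dtype=np.float64)
    if len(n) != len(param_sets):
        raise ValueError("one count per parameter set required")
    w = n / n.sum()
    names = sorted(param_sets[0])
    for ps in param_sets[1:]:
        if sorted(ps) != names:
            raise ValueError("parameter sets carry different names")
    out = {}
    for name in names:
        shapes = {ps[name].shape for ps in param_sets}
        if len(shapes) != 1:
            raise ValueError(f"shape mismatch for {name!r}")
        out[name] = sum(wi * ps[name] for wi, ps in zip(w, param_sets))
    return out


def fedprox_penalty(local_params: dict[str, np.ndarray],
                    global_params: dict[str, np.ndarray], mu: float) -> float:
    """mu/2 * sum of squared parameter differences."""
    if mu < 0:
        raise ValueError("mu must be >= 0")
    total = 0.0
    for name, p in local_params.items():
        g = global_params[name]
        if np.shape(p) != np.shape(g):
            raise ValueError(f"shape mismatch for {name!r}")
        total += float(((np.asarray(p) - np.asarray(g)) ** 2).sum())
    return 0.5 * mu * total


def _row_cosine(a: Tensor, b: np.ndarray) -> Tensor:
    bn = b / np.maximum(np.linalg.norm(b, axis=1, keepdims=True), 1e-12)
    an = a * (((a * a).sum(axis=1, keepdims=True) + 1e-12) ** -0.5)
    return (an * Tensor(bn)).sum(axis=1, keepdims=True)


def moon_contrast(z_local, z_global, z_prev, tau: float) -> Tensor:
    """Model-contrastive loss, mean over the batch."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    zl = as_tensor(z_local)
    zg = np.atleast_2d(np.asarray(z_global.data if isinstance(z_global, Tensor)
                                  else z_global, dtype=np.float64))
    zp = np.atleast_2d(np.asarray(z_prev.data if isinstance(z_prev, Tensor)
                                  else z_prev, dtype=np.float64))
    if zl.ndim == 1:
        zl = zl.reshape(1, -1)
    cos_g = _row_cosine(zl, zg)
    cos_p = _row_cosine(zl, zp)
    # -log softmax = softplus of the margin
    return softplus((cos_p - cos_g) * (1.0 / tau)).mean()


def _logit_distillation(student_logits: Tensor, teacher_logits: np.ndarray,
                        T: float) -> Tensor:
    return facm.distillation_loss(
        {"common": student_logits * 0.0, "interactive": student_logits * 0.0,
         "logits": student_logits},
        {"common": np.zeros_like(teacher_logits), "interactive": np.zeros_like(teacher_logits),
         "logits": teacher_logits}, T=T)


# -- clients ---------------------------------------------------------------

class _Client:
    def __init__(self, center: CenterDataset, config: FedConfig,
                 large: LargeEncoder, init_seed: int, client_seed: int):
        self.center_id = center.center_id
        self.config = config
        self.large = large
        train_idx = np.flatnonzero(center.split == "train")
        test_idx = np.flatnonzero(center.split == "test")
        if len(train_idx) == 0 or len(test_idx) == 0:
            raise ValueError(f"center {center.center_id}: missing train or test split")
        self.images = center.images
        self.labels = center.labels
        self.test_idx = test_idx
        rng = np.random.default_rng(client_seed)
        self.fit_idx, self.val_idx = self._carve_val(train_idx, rng)
        self.train_idx = train_idx
        self.rng = rng
        self.used_idx: set[int] = set()

        variant = resolve_variant(config)
        # "local" is per-center training of the full model, no communication
        if variant in ("fedcpi", "fedcpi_no_facm", "local"):
            self.model: Module = FedCPIModel(config, init_seed)
            self.queue = ContrastQueue(self.model.cfg.queue_capacity, self.model.cfg.tau)
        else:
            self.model = PlainModel(config, init_seed)
            self.queue = None
        self.optimizer = SGD(self.model.named_parameters(), lr=config.lr,
                             momentum=config.momentum)
        self.teacher: Module | None = None
        self.prev_params = self.model.get_params()   # MOON's z_prev source
        # the frozen encoder has no cross-sample ops, so its features are
        # batch-independent and can be computed once per client
        if isinstance(self.model, FedCPIModel):
            feats = []
            with no_grad():
                for i in range(0, len(self.images), 64):
                    feats.append(large.forward(self.images[i:i + 64]).data)
            self.f_large_all = np.concatenate(feats)
            # fixed class-balanced reference batch from the fit data: the
            # cross-attention context at inference time (per-sample
            # deterministic predictions, no test-test interaction)
            ref_rng = np.random.default_rng([client_seed, 7])
            ref = []
            for cls in (0, 1):
                idx = self.fit_idx[self.labels[self.fit_idx] == cls]
                k = min(len(idx), 16)
                ref.extend(ref_rng.choice(idx, size=k, replace=False))
            self.ref_idx = np.sort(np.array(ref, dtype=int))
        else:
            self.f_large_all = None
            self.ref_idx = None

    def _carve_val(self, train_idx: np.ndarray, rng) -> tuple[np.ndarray, np.ndarray]:
        if self.config.val_fraction <= 0:
            return train_idx, np.array([], dtype=int)
        fit, val = [], []
        for cls in (0, 1):
            idx = train_idx[self.labels[train_idx] == cls]
            idx = idx[rng.permutation(len(idx))]
            k = int(round(self.config.val_fraction * len(idx)))
            val.extend(idx[:k])
            fit.extend(idx[k:])
        return np.sort(np.array(fit, dtype=int)), np.sort(np.array(val, dtype=int))

    # -- training ---------------------------------------------------------
    def _batches(self):
        order = self.fit_idx[self.rng.permutation(len(self.fit_idx))]
        bs = self.config.batch_size
        for i in range(0, len(order), bs):
            yield order[i:i + bs]

    def snapshot_teacher(self) -> None:
        self.teacher = copy.deepcopy(self.model)

    def train_round(self, global_params: dict[str, np.ndarray] | None = None,
                    prev_params: dict[str, np.ndarray] | None = None,
                    distill: bool = False) -> float:
        cfg = self.config
        variant = resolve_variant(cfg)
        totals = []
        for _ in range(cfg.local_epochs):
            for batch in self._batches():
                self.used_idx.update(batch.tolist())
                labs = self.labels[batch]
                if isinstance(self.model, FedCPIModel):
                    totals.append(self._step_fedcpi(batch, labs, distill))
                else:
                    totals.append(self._step_plain(self.images[batch], labs,
                                                   global_params, prev_params,
                                                   distill))
        return float(np.mean(totals)) if totals else 0.0

    def _step_fedcpi(self, batch, labs, distill: bool) -> float:
        imgs = self.images[batch]
        f_large = self.f_large_all[batch]
        with no_grad():
            teacher_outputs = None
            if distill and self.teacher is not None:
                t_out = self.teacher.head.forward(
                    f_large, self.teacher.small.forward(imgs))
                teacher_outputs = {"common": t_out["bundle"].common.data,
                                   "interactive": t_out["bundle"].interactive.data,
                                   "logits": t_out["logits"].data}
        breakdown = local_training_step(
            self.model.head, self.model.small, f_large, imgs, labs,
            self.optimizer, self.queue, teacher_outputs=teacher_outputs,
            cfg=self.model.cfg)
        return breakdown.total

    def _step_plain(self, imgs, labs, global_params, prev_params, distill) -> float:
        cfg = self.config
        emb, logits = self.model.forward(imgs)
        loss = binary_cross_entropy(logits, labs)
        if cfg.strategy == "moon" and global_params is not None and prev_params is not None:
            zg = self._embed_with(global_params, imgs)
            zp = self._embed_with(prev_params, imgs)
            loss = loss + cfg.moon_mu * moon_contrast(emb, zg, zp, cfg.moon_tau)
        if distill and self.teacher is not None:
            with no_grad():
                _, t_logits = self.teacher.forward(imgs)
            lmsf_cfg = cfg.lmsf or desk_lmsf_config()
            loss = loss + lmsf_cfg.lambda_kd * _logit_distillation(
                logits, t_logits.data, lmsf_cfg.kd_temperature)
        if not np.isfinite(loss.data):
            raise RuntimeError("non-finite training loss; aborting round")
        self.optimizer.zero_grad()
        loss.backward()
        if cfg.strategy == "fedprox" and global_params is not None:
            for name, p in self.model.named_parameters().items():
                pen = (cfg.mu_prox * (p.data - global_params[name])).astype(p.data.dtype)
                p.grad = pen if p.grad is None else p.grad + pen
        self.optimizer.step()
        return float(loss.data)

    def _embed_with(self, params: dict[str, np.ndarray], imgs) -> np.ndarray:
        tmp = copy.deepcopy(self.model)
        tmp.set_params(params)
        with no_grad():
            emb, _ = tmp.forward(imgs)
        return emb.data

    # -- inference --------------------------------------------------------
    def _context(self):
        """(f_large, f_small) of the reference batch under current params."""
        return (self.f_large_all[self.ref_idx],
                self.model.small.forward(self.images[self.ref_idx]))

    def predict(self, idx: np.ndarray, chunk: int = 32) -> np.ndarray:
        probs = []
        with no_grad():
            ctx = self._context() if isinstance(self.model, FedCPIModel) else None
            for i in range(0, len(idx), chunk):
                sel = idx[i:i + chunk]
                imgs = self.images[sel]
                if isinstance(self.model, FedCPIModel):
                    out = self.model.head.forward(self.f_large_all[sel],
                                                  self.model.small.forward(imgs),
                                                  context=ctx)
                    probs.append(out["probs"])
                else:
                    _, z = self.model.forward(imgs)
                    probs.append(1.0 / (1.0 + np.exp(-z.data[:, 0])))
        return np.concatenate(probs)

    def val_auc(self) -> float:
        if len(self.val_idx) == 0:
            return 0.5
        labs = self.labels[self.val_idx]
        if len(np.unique(labs)) < 2:
            return 0.5
        from .clineval import auc_delong
        auc, _, _ = auc_delong(ScoreSet(self.predict(self.val_idx), labs))
        return auc

    def n_train(self) -> int:
        return len(self.fit_idx)


# -- experiment ------------------------------------------------------------

@dataclass
class ExperimentResult:
    reports: dict[str, MetricReport]
    curves: dict[str, list[float]]
    test_scores: dict[str, tuple[np.ndarray, np.ndarray]]
    config: FedConfig
    seed: int
    server: ServerState | None = None
    clients: list = field(default_factory=list, repr=False)

    @property
    def mean_auc(self) -> float:
        return float(np.mean([r.auc for r in self.reports.values()
                              if r.auc is not None]))


def run_experiment(config: FedConfig, federation: list[CenterDataset]) -> ExperimentResult:
    """Train under ``config.strategy`` and evaluate on untouched test splits."""
    from .nn.autograd import default_dtype

    dtype = np.float32 if config.precision == "float32" else np.float64
    with default_dtype(dtype):
        return _run_experiment(config, federation)


def _run_experiment(config: FedConfig, federation: list[CenterDataset]) -> ExperimentResult:
    if not federation:
        raise ValueError("federation must contain at least one center")
    ss = np.random.SeedSequence(config.seed)
    init_seed = int(ss.generate_state(1)[0] % (2 ** 31))
    client_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(len(federation))]

    lmsf_cfg = config.lmsf or desk_lmsf_config()
    large = LargeEncoder(dim=config.d_large, seed=config.large_seed,
                         widths=config.large_widths)
    clients = [_Client(c, config, large, init_seed, cs)
               for c, cs in zip(federation, client_seeds)]
    variant = resolve_variant(config)

    server = ServerState()
    curves: dict[str, list[float]] = {c.center_id: [] for c in clients}
    global_params = clients[0].model.get_params()

    for rnd in range(config.rounds):
        distill = variant in ("fedcpi", "fedcpi_no_lmsf") and rnd > 0
        if distill:
            for c in clients:
                c.snapshot_teacher()
        for c in clients:
            loss = c.train_round(global_params=global_params,
                                 prev_params=c.prev_params, distill=distill)
            curves[c.center_id].append(loss)
        if config.strategy == "moon":
            for c in clients:
                c.prev_params = c.model.get_params()

        if variant == "local":
            continue
        if variant == "fedcpi":
            updates = [ClientUpdate(c.center_id,
                                    c.model.param_set().fragment(*facm.SHAREABLE),
                                    c.n_train(), c.val_auc())
                       for c in clients]
            server = facm.server_round(server, updates, tau_w=config.tau_w,
                                       common_n_weighted=config.common_n_weighted)
            broadcast = deserialize_fragment(serialize_fragment(server.global_params))
        elif variant == "fedcpi_no_facm":
            frags = [c.model.param_set().fragment(*facm.SHAREABLE) for c in clients]
            mean = fedavg_aggregate([f.tensors for f in frags], np.ones(len(clients)))
            broadcast = deserialize_fragment(serialize_fragment(
                ParamSet(mean, dict(frags[0].tags))))
        else:  # plain-model strategies: fedavg / fedprox / moon / no_lmsf
            frags = [c.model.param_set().fragment(*facm.SHAREABLE) for c in clients]
            mean = fedavg_aggregate([f.tensors for f in frags],
                                    [c.n_train() for c in clients])
            broadcast = deserialize_fragment(serialize_fragment(
                ParamSet(mean, dict(frags[0].tags))))
        for c in clients:
            c.model.load_fragment(broadcast)
            if config.queue_reset and c.queue is not None:
                c.queue.clear()
        global_params = dict(broadcast.tensors)

    # -- evaluation on untouched test splits ------------------------------
    reports, test_scores = {}, {}
    for c in clients:
        if c.used_idx & set(c.test_idx.tolist()):
            raise RuntimeError(f"test leakage at center {c.center_id}")
        train_scores = c.predict(c.train_idx)
        thr = youden_threshold(ScoreSet(train_scores, c.labels[c.train_idx]))
        thr = min(max(thr, 1e-6), 1 - 1e-6)
        scores = c.predict(c.test_idx)
        labs = c.labels[c.test_idx]
        reports[c.center_id] = confusion_report(ScoreSet(scores, labs), thr)
        test_scores[c.center_id] = (scores, labs)
    return ExperimentResult(reports=reports, curves=curves,
                            test_scores=test_scores, config=config,
                            seed=config.seed,
                            server=server if variant == "fedcpi" else None,
                            clients=clients)


def subspace_tables(result: ExperimentResult, on: str = "test"):
    """Extract per-center FeatureTables of the four subspaces (fedcpi only)."""
    from .feature_analysis import FeatureTable
    from .nn.autograd import default_dtype

    dtype = np.float32 if result.config.precision == "float32" else np.float64
    tables = {g: [] for g in ("common", "personal_large", "personal_small", "interactive")}
    for c in result.clients:
        if not isinstance(c.model, FedCPIModel):
            raise ValueError("subspace tables require the full fedcpi model")
        idx = c.test_idx if on == "test" else c.train_idx
        chunks = {g: [] for g in tables}
        with default_dtype(dtype), no_grad():
            ctx = c._context()
            for i in range(0, len(idx), 32):
                sel = idx[i:i + 32]
                out = c.model.head.forward(c.f_large_all[sel],
                                           c.model.small.forward(c.images[sel]),
                                           context=ctx)
                for g, mat in out["bundle"].numpy().items():
                    chunks[g].append(mat)
        for g in tables:
            tables[g].append(FeatureTable(np.vstack(chunks[g]), g, c.center_id))
    return tables
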