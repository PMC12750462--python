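"""Run configuration: defaults, YAML loading, seed fan-out.

A single global seed fans out deterministically (via ``numpy``'s
``SeedSequence``) to the data generator, the split, and the training run, so
one integer reproduces an entire experiment.  The fully resolved config is
written verbatim into every run directory.
"""

from __future__ import annotations

import copy

import numpy as np
import yaml

from .federation import FedConfig
from .lmsf import LMSFConfig

__all__ = ["DEFAULTS", "load_config", "resolve_config", "fan_out_seeds",
           "build_fed_config", "ConfigError"]


class ConfigError(ValueError):
    pass


DEFAULTS: dict = {
    "seed": 0,
    "data": {
        "preset": "lung4",
        "scale": 1.0,
        "image_size": 32,
        "effect_size": 1.8,
        "split_ratio": 0.5,
        "stratified": True,
    },
    "backbones": {
        "d_large": 96,
        "large_widths": [8, 16, 32],
        "large_seed": 0,
        "d_small": 64,
        "width_mult": 0.25,
    },
    "lmsf": {
        "d_shared": 64,
        "d_sub": 32,
        "d_fuse": 32,
        "gate_hidden": 16,
        "queue_capacity": 256,
        "tau": 0.1,
        "lambda_align": 0.05,
        "lambda_queue": 0.02,
        "lambda_kd": 0.1,
        "kd_temperature": 2.0,
    },
    "facm": {
        "tau_w": 0.1,
        "common_n_weighted": False,
    },
    "federation": {
        "strategy": "fedcpi",
        "rounds": 15,
        "local_epochs": 2,
        "batch_size": 16,
        "lr": 0.02,
        "momentum": 0.9,
        "mu_prox": 0.01,
        "moon_mu": 1.0,
        "moon_tau": 0.5,
        "no_lmsf": False,
        "no_facm": False,
        "val_fraction": 0.2,
    },
    "eval": {
        "alpha": 0.05,
        "dca_grid": [0.05, 0.5, 10],   # lo, hi, count
    },
}


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        here = f"{path}.{key}" if path else key
        if key not in base:
            raise ConfigError(f"unknown config key: {here}")
        if isinstance(base[key], dict):
            if not isinstance(val, dict):
                raise ConfigError(f"expected a mapping at {here}")
            out[key] = _merge(base[key], val, here)
        else:
            out[key] = val
    return out


def load_config(path: str | None) -> dict:
    """Defaults merged with a YAML file; unknown keys are rejected by name."""
    if path is None:
        return copy.deepcopy(DEFAULTS)
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ConfigError("top-level config must be a mapping")
    return _merge(DEFAULTS, user)


def resolve_config(path: str | None = None, **overrides) -> dict:
    cfg = load_config(path)
    for key, val in overrides.items():
        if val is None:
            continue
        section, _, leaf = key.partition("__")
        if leaf:
            cfg[section][leaf] = val
        else:
            cfg[section] = val
    return cfg


def fan_out_seeds(seed: int) -> dict[str, int]:
    ss = np.random.SeedSequence(seed)
    names = ("data", "split", "train", "analysis")
    return {n: int(s.generate_state(1)[0] % (2 ** 31))
            for n, s in zip(names, ss.spawn(len(names)))}


def build_fed_config(cfg: dict, strategy: str | None = None,
                     seed: int | None = None, **flags) -> FedConfig:
    fed = cfg["federation"]
    bb = cfg["backbones"]
    lm = cfg["lmsf"]
    lmsf = LMSFConfig(d_large=bb["d_large"], d_small=bb["d_small"],
                      d_shared=lm["d_shared"], d_sub=lm["d_sub"],
                      d_fuse=lm["d_fuse"], gate_hidden=lm["gate_hidden"],
                      queue_capacity=lm["queue_capacity"], tau=lm["tau"],
                      lambda_align=lm["lambda_align"],
                      lambda_queue=lm["lambda_queue"],
                      lambda_kd=lm["lambda_kd"],
                      kd_temperature=lm["kd_temperature"])
    return FedConfig(
        strategy=strategy or fed["strategy"],
        rounds=fed["rounds"], local_epochs=fed["local_epochs"],
        batch_size=fed["batch_size"], lr=fed["lr"], momentum=fed["momentum"],
        seed=fan_out_seeds(cfg["seed"] if seed is None else seed)["train"],
        mu_prox=fed["mu_prox"], moon_mu=fed["moon_mu"], moon_tau=fed["moon_tau"],
        no_lmsf=flags.get("no_lmsf", fed["no_lmsf"]),
        no_facm=flags.get("no_facm", fed["no_facm"]),
        tau_w=cfg["facm"]["tau_w"],
        common_n_weighted=cfg["facm"]["common_n_weighted"],
        val_fraction=fed["val_fraction"],
        d_large=bb["d_large"], large_widths=tuple(bb["large_widths"]),
        large_seed=bb["large_seed"], d_small=bb["d_small"],
        width_mult=bb["width_mult"], lmsf=lmsf,
    )


def dump_config(cfg: dict, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def prepare_federation(cfg: dict, seed: int | None = None):
    """Generate and split the configured synthetic federation."""
    from .synth import generate_federation, lung4_specs, split_train_test

    data = cfg["data"]
    if data["preset"] != "lung4":
        raise ConfigError(f"unknown data preset: {data['preset']}")
    seeds = fan_out_seeds(cfg["seed"] if seed is None else seed)
    specs = lung4_specs(scale=data["scale"], image_size=data["image_size"],
                        effect_size=data["effect_size"])
    datasets = generate_federation(specs, seeds["data"])
    return [split_train_test(ds, data["split_ratio"], seeds["split"] + i,
                             stratified=data["stratified"])
            for i, ds in enumerate(datasets)]
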