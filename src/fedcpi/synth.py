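"""Synthetic multi-center lesion-image benchmark.

Real multi-center CT cohorts for early-cancer progression are private, so this
module generates surrogate grayscale lesion patches with two controllable
ingredients:

* a **class signal** — an elliptical lesion whose diameter, margin-irregularity
  amplitude and internal texture variance are drawn from class-conditional
  Gaussians separated by ``effect_size`` standard deviations (echoing the
  clinical discriminators maximum diameter / lobulation / spiculation);
* a **center effect** — per-center covariate shift applied after lesion
  compositing, in the fixed order gamma -> intensity offset -> Gaussian blur ->
  additive Gaussian noise -> clip to [0, 1], emulating scanner and protocol
  differences between hospitals.

Everything is a pure function of the specs and the master seed.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "CenterSpec",
    "CenterDataset",
    "generate_center",
    "generate_federation",
    "split_train_test",
    "lung4_specs",
    "write_dataset",
    "read_dataset",
    "save_federation_npz",
    "load_federation_npz",
]


@dataclass(frozen=True)
class CenterSpec:
    """Generation recipe for one center."""

    center_id: str
    n_samples: int
    prevalence: float
    image_size: int = 64
    intensity_offset: float = 0.0
    gamma: float = 1.0
    blur_sigma: float = 0.0
    noise_sigma: float = 0.0
    effect_size: float = 1.5
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie in (0, 1)")
        if self.image_size < 8:
            raise ValueError("image_size must be >= 8")
        if not -0.3 <= self.intensity_offset <= 0.3:
            raise ValueError("intensity_offset must lie in [-0.3, 0.3]")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.blur_sigma < 0 or self.noise_sigma < 0 or self.effect_size < 0:
            raise ValueError("blur_sigma, noise_sigma, effect_size must be >= 0")


@dataclass
class CenterDataset:
    """One center's images with labels, split tags and provenance."""

    center_id: str
    images: np.ndarray          # (n, s, s) float64 in [0, 1]
    labels: np.ndarray          # (n,) int 0/1
    split: np.ndarray           # (n,) unicode in {train, test, none}
    spec: CenterSpec

    def __post_init__(self):
        if not (len(self.images) == len(self.labels) == len(self.split)):
            raise ValueError("images, labels and split must have equal length")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be 0/1")

    def subset(self, tag: str) -> tuple[np.ndarray, np.ndarray]:
        idx = np.flatnonzero(self.split == tag)
        return self.images[idx], self.labels[idx]


# -- lesion rendering -----------------------------------------------------

#: class-0 means and common SDs of the three lesion parameters, in units of
#: image side (diameter-related radius) or intensity.  Class-1 means are
#: shifted by effect_size * sd.
_RADIUS_MEAN, _RADIUS_SD = 0.14, 0.030
_IRREG_MEAN, _IRREG_SD = 0.08, 0.050
_TEXSD_MEAN, _TEXSD_SD = 0.05, 0.020


def _render_image(rng: np.random.Generator, label: int, spec: CenterSpec) -> np.ndarray:
    s = spec.image_size
    shift = spec.effect_size * label

    radius = rng.normal(_RADIUS_MEAN + shift * _RADIUS_SD, _RADIUS_SD) * s
    irreg = rng.normal(_IRREG_MEAN + shift * _IRREG_SD, _IRREG_SD)
    tex_sd = rng.normal(_TEXSD_MEAN + shift * _TEXSD_SD, _TEXSD_SD)
    radius = max(radius, 0.05 * s)
    irreg = float(np.clip(irreg, 0.0, 0.5))
    tex_sd = max(tex_sd, 0.0)
    n_lobes = rng.integers(3, 8)
    phase = rng.uniform(0, 2 * np.pi)
    cx, cy = (s - 1) / 2 + rng.normal(0, 0.04 * s, size=2)

    yy, xx = np.mgrid[0:s, 0:s].astype(np.float64)
    dx, dy = xx - cx, yy - cy
    dist = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx)
    boundary = radius * (1.0 + irreg * np.sin(n_lobes * theta + phase))
    # soft lesion edge, ~1 px transition
    mask = 1.0 / (1.0 + np.exp(-(boundary - dist) / 0.8))

    background = 0.35 + 0.06 * gaussian_filter(rng.standard_normal((s, s)), s / 8.0)
    texture = gaussian_filter(rng.standard_normal((s, s)), 1.0)
    tstd = texture.std()
    if tstd > 0:
        texture *= tex_sd / tstd
    lesion = 0.68 + texture

    img = background * (1.0 - mask) + lesion * mask

    # center effects, fixed order: gamma -> offset -> blur -> noise -> clip
    img = np.clip(img, 0.0, 1.0) ** spec.gamma
    img = img + spec.intensity_offset
    if spec.blur_sigma > 0:
        img = gaussian_filter(img, spec.blur_sigma)
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    return np.clip(img, 0.0, 1.0)


def generate_center(spec: CenterSpec) -> CenterDataset:
    """Render one center's dataset; deterministic given ``spec.seed``.

    The positive count is exactly ``round(prevalence * n_samples)``.
    """
    rng = np.random.default_rng(spec.seed)
    n_pos = int(round(spec.prevalence * spec.n_samples))
    labels = np.zeros(spec.n_samples, dtype=np.int64)
    labels[:n_pos] = 1
    labels = labels[rng.permutation(spec.n_samples)]
    images = np.stack([_render_image(rng, int(y), spec) for y in labels])
    split = np.full(spec.n_samples, "none", dtype="U5")
    return CenterDataset(spec.center_id, images, labels, split, spec)


def generate_federation(specs: list[CenterSpec], master_seed: int) -> list[CenterDataset]:
    """Generate all centers; per-center seeds derive from ``master_seed``."""
    ids = [s.center_id for s in specs]
    if len(set(ids)) != len(ids):
        raise ValueError("center_ids must be unique")
    out = []
    for i, spec in enumerate(specs):
        seed = int(np.random.SeedSequence([master_seed, i]).generate_state(1)[0])
        out.append(generate_center(dataclasses.replace(spec, seed=seed)))
    return out


def split_train_test(ds: CenterDataset, ratio: float, seed: int,
                     stratified: bool = True) -> CenterDataset:
    """Assign train/test tags; stratified mode preserves prevalence.

    Returns a new dataset; the input is left untouched.
    """
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must lie in (0, 1)")
    n = len(ds.labels)
    rng = np.random.default_rng(seed)
    split = np.full(n, "test", dtype="U5")
    if stratified:
        if len(np.unique(ds.labels)) < 2:
            raise ValueError("stratified split requires both classes")
        for cls in (0, 1):
            idx = np.flatnonzero(ds.labels == cls)
            idx = idx[rng.permutation(len(idx))]
            k = int(round(ratio * len(idx)))
            split[idx[:k]] = "train"
    else:
        idx = rng.permutation(n)
        split[idx[:int(round(ratio * n))]] = "train"
    return CenterDataset(ds.center_id, ds.images, ds.labels, split, ds.spec)


# -- presets ---------------------------------------------------------------

#: Four-center preset mirroring the cohort imbalance of a published
#: four-hospital early-lung-cancer study: unequal sizes (465/198/148/115) and
#: low positive prevalence per center (82/465, 40/198, 27/148, 18/115), with
#: strong, distinct acquisition shifts per center.
_LUNG4 = [
    ("A", 465, 82 / 465, -0.12, 0.80, 0.0, 0.02),
    ("B", 198, 40 / 198, -0.04, 1.00, 0.6, 0.05),
    ("C", 148, 27 / 148, +0.05, 1.20, 1.0, 0.08),
    ("D", 115, 18 / 115, +0.12, 1.45, 1.5, 0.12),
]


def lung4_specs(scale: float = 1.0, image_size: int = 32,
                effect_size: float = 1.8) -> list[CenterSpec]:
    """The "lung4" benchmark preset (optionally size-scaled, sizes stay
    proportional to the source cohort)."""
    specs = []
    for cid, n, prev, off, gamma, blur, noise in _LUNG4:
        specs.append(CenterSpec(
            center_id=cid,
            n_samples=max(int(round(n * scale)), 8),
            prevalence=prev,
            image_size=image_size,
            intensity_offset=off,
            gamma=gamma,
            blur_sigma=blur,
            noise_sigma=noise,
            effect_size=effect_size,
        ))
    return specs


# -- I/O -------------------------------------------------------------------

def write_dataset(ds: CenterDataset, outdir: str) -> str:
    """Write PNGs plus a CSV manifest (file, center_id, label, split)."""
    from PIL import Image
    import pandas as pd

    os.makedirs(outdir, exist_ok=True)
    rows = []
    for i, (img, lab, sp) in enumerate(zip(ds.images, ds.labels, ds.split)):
        fname = f"{ds.center_id}_{i:05d}.png"
        arr = np.round(img * 255.0).astype(np.uint8)
        Image.fromarray(arr, mode="L").save(os.path.join(outdir, fname))
        rows.append({"file": fname, "center_id": ds.center_id,
                     "label": int(lab), "split": str(sp)})
    manifest = os.path.join(outdir, "manifest.csv")
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_dataset(indir: str, center_id: str | None = None) -> list[CenterDataset]:
    """Read datasets written by :func:`write_dataset` (8-bit quantized)."""
    from PIL import Image
    import pandas as pd

    manifest = pd.read_csv(os.path.join(indir, "manifest.csv"))
    out = []
    for cid, grp in manifest.groupby("center_id", sort=True):
        if center_id is not None and cid != center_id:
            continue
        imgs = np.stack([
            np.asarray(Image.open(os.path.join(indir, f)), dtype=np.float64) / 255.0
            for f in grp["file"]
        ])
        spec = CenterSpec(center_id=str(cid), n_samples=len(grp),
                          prevalence=max(min(grp["label"].mean(), 1 - 1e-9), 1e-9),
                          image_size=imgs.shape[-1])
        out.append(CenterDataset(str(cid), imgs, grp["label"].to_numpy(np.int64),
                                 grp["split"].to_numpy("U5"), spec))
    return out


def save_federation_npz(datasets: list[CenterDataset], path: str) -> None:
    """Single-file compressed array container (fast path)."""
    payload: dict[str, np.ndarray] = {}
    for ds in datasets:
        payload[f"{ds.center_id}::images"] = ds.images
        payload[f"{ds.center_id}::labels"] = ds.labels
        payload[f"{ds.center_id}::split"] = ds.split.astype("U5")
    np.savez_compressed(path, **payload)


def load_federation_npz(path: str) -> list[CenterDataset]:
    with np.load(path, allow_pickle=False) as z:
        cids = sorted({k.split("::")[0] for k in z.files})
        out = []
        for cid in cids:
            imgs = z[f"{cid}::images"]
            labels = z[f"{cid}::labels"]
            split = z[f"{cid}::split"]
            spec = CenterSpec(center_id=cid, n_samples=len(labels),
                              prevalence=max(min(labels.mean(), 1 - 1e-9), 1e-9),
                              image_size=imgs.shape[-1])
            out.append(CenterDataset(cid, imgs, labels, split, spec))
    return out
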