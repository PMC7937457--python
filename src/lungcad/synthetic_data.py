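"""Seeded two-class chest-phantom generator and image preprocessing.

The study's 5000 hospital CT images are private; this module emulates
their *statistical roles* at desk scale so every experiment family runs
without a download.  A "normal" phantom is a dim background carrying two
bright elliptical lung fields plus Gaussian pixel noise; an "abnormal"
phantom additionally contains one small high-intensity disc (the nodule)
placed uniformly inside a randomly chosen lung field.  Realism is
deliberately minimal — two balanced classes, a small bright lesion, and
global context are what the experiments need, not radiological fidelity.

All randomness flows from ``(params.seed, draw_seed)`` so any image, and
any full dataset, regenerates bitwise identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np

__all__ = [
    "EllipseSpec",
    "PhantomParams",
    "Dataset",
    "generate_normal_image",
    "generate_abnormal_image",
    "generate_dataset",
    "preprocess",
    "save_dataset",
    "load_manifest_images",
]


@dataclass(frozen=True)
class EllipseSpec:
    """Axis-aligned ellipse; center and semi-axes as fractions of the side."""

    center: Tuple[float, float]       # (row, col) fractions
    semi_axes: Tuple[float, float]    # (row, col) fractions

    def mask(self, side: int) -> np.ndarray:
        r = np.arange(side)[:, None]
        c = np.arange(side)[None, :]
        cr, cc = self.center[0] * side, self.center[1] * side
        ar, ac = self.semi_axes[0] * side, self.semi_axes[1] * side
        return ((r - cr) / ar) ** 2 + ((c - cc) / ac) ** 2 <= 1.0


@dataclass(frozen=True)
class PhantomParams:
    """Recipe for one phantom family; intensities live in [0, 1]."""

    side: int = 64
    background: float = 0.15
    lung_intensity: float = 0.55
    lung_ellipses: Tuple[EllipseSpec, EllipseSpec] = (
        EllipseSpec(center=(0.50, 0.32), semi_axes=(0.30, 0.17)),
        EllipseSpec(center=(0.50, 0.68), semi_axes=(0.30, 0.17)),
    )
    nodule_radius_range: Tuple[float, float] = (0.03, 0.08)  # fraction of side
    nodule_contrast: float = 0.35
    noise_sd: float = 0.05
    seed: int = 0

    def template(self) -> np.ndarray:
        """Noiseless normal image: background plus the two lung fields."""
        img = np.full((self.side, self.side), self.background)
        for ell in self.lung_ellipses:
            img[ell.mask(self.side)] = self.lung_intensity
        return img

    def validate_nodule_fits(self):
        max_r = self.nodule_radius_range[1] * self.side
        for ell in self.lung_ellipses:
            min_semi = min(ell.semi_axes) * self.side
            if min_semi <= max_r:
                raise ValueError(
                    f"nodule radius up to {max_r:.1f} px cannot fit inside a "
                    f"lung ellipse with semi-minor axis {min_semi:.1f} px")


@dataclass
class Dataset:
    """Labeled image collection; images shaped (N, 1, side, side)."""

    images: np.ndarray
    labels: np.ndarray            # 0 = normal, 1 = tumor
    split: str = "train"
    manifest: Optional["pandas.DataFrame"] = None

    def __len__(self):
        return len(self.labels)


def _rng_for(params: PhantomParams, draw_seed: int) -> np.random.Generator:
    return np.random.default_rng([params.seed, draw_seed])


def _finish(img, params: PhantomParams, rng) -> np.ndarray:
    if params.noise_sd > 0:
        img = img + rng.normal(0.0, params.noise_sd, size=img.shape)
    return np.clip(img, 0.0, 1.0)[None, :, :]


def generate_normal_image(params: PhantomParams, draw_seed: int) -> np.ndarray:
    """One normal phantom as a (1, side, side) stack."""
    rng = _rng_for(params, draw_seed)
    # burn the abnormal branch's draws (ellipse choice, radius, position) so
    # a paired abnormal image with the same seeds shares its noise field
    rng.integers(0, 2)
    rng.uniform()
    rng.uniform(size=2)
    return _finish(params.template(), params, rng)


def generate_abnormal_image(params: PhantomParams, draw_seed: int) -> np.ndarray:
    """Normal phantom plus one bright nodule inside a lung field.

    The nodule radius is uniform over ``nodule_radius_range`` (in pixels,
    as a fraction of the side), the center uniform over the chosen
    ellipse shrunk so the whole disc stays inside, and the disc adds
    ``nodule_contrast`` before noise and clipping.
    """
    params.validate_nodule_fits()
    rng = _rng_for(params, draw_seed)
    which = int(rng.integers(0, 2))
    lo, hi = params.nodule_radius_range
    radius = float(rng.uniform(lo, hi)) * params.side
    ell = params.lung_ellipses[which]
    # sample a uniform point in the unit disc, map into the shrunken ellipse
    u, v = rng.uniform(size=2)
    rr = np.sqrt(u)
    theta = 2.0 * np.pi * v
    ar = ell.semi_axes[0] * params.side - radius
    ac = ell.semi_axes[1] * params.side - radius
    cr = ell.center[0] * params.side + rr * np.cos(theta) * ar
    cc = ell.center[1] * params.side + rr * np.sin(theta) * ac

    img = params.template()
    r = np.arange(params.side)[:, None]
    c = np.arange(params.side)[None, :]
    disc = (r - cr) ** 2 + (c - cc) ** 2 <= radius ** 2
    img[disc] += params.nodule_contrast
    return _finish(img, params, rng)


def generate_dataset(n_normal: int, n_abnormal: int, params: PhantomParams,
                     split_fractions: Tuple[float, float] = (0.8, 0.2),
                     seed: int = 0) -> Tuple[Dataset, Dataset]:
    """Stratified seeded train/test split of freshly drawn phantoms.

    Draw seeds are consecutive integers (normals first), so any individual
    image can be regenerated from the manifest alone.
    """
    import pandas as pd

    if n_normal < 1 or n_abnormal < 1:
        raise ValueError("need at least one image per class")
    if abs(sum(split_fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    images, labels, draw_seeds = [], [], []
    for i in range(n_normal):
        images.append(generate_normal_image(params, i))
        labels.append(0)
        draw_seeds.append(i)
    for i in range(n_abnormal):
        images.append(generate_abnormal_image(params, n_normal + i))
        labels.append(1)
        draw_seeds.append(n_normal + i)
    images = np.stack(images)
    labels = np.asarray(labels)
    draw_seeds = np.asarray(draw_seeds)

    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for cls in (0, 1):
        idx = np.flatnonzero(labels == cls)
        idx = rng.permutation(idx)
        n_train = int(round(split_fractions[0] * len(idx)))
        if n_train == 0 or n_train == len(idx):
            raise ValueError("split would leave an empty class in a partition")
        train_idx.extend(idx[:n_train])
        test_idx.extend(idx[n_train:])
    train_idx = np.asarray(train_idx)
    test_idx = np.asarray(test_idx)

    def make(split, idx):
        manifest = pd.DataFrame({
            "id": idx,
            "label": labels[idx],
            "draw_seed": draw_seeds[idx],
        })
        return Dataset(images=images[idx], labels=labels[idx],
                       split=split, manifest=manifest)

    return make("train", train_idx), make("test", test_idx)


def preprocess(image, target_side: int, normalize: bool = False) -> np.ndarray:
    """Bilinear resize to ``target_side`` square, optional min–max rescale.

    A constant image under ``normalize`` maps to all zeros (degenerate
    range).  Accepts (H, W) or (1, H, W); returns a (1, side, side) stack.
    """
    from PIL import Image

    if target_side < 1:
        raise ValueError("target side must be >= 1")
    arr = np.asarray(image, float)
    if arr.ndim == 3:
        arr = arr[0]
    if arr.shape[0] != arr.shape[1]:
        raise ValueError("images must be square")
    if arr.shape[0] != target_side:
        im = Image.fromarray(arr.astype(np.float32), mode="F")
        im = im.resize((target_side, target_side), Image.BILINEAR)
        arr = np.asarray(im, dtype=float)
    if normalize:
        lo, hi = arr.min(), arr.max()
        arr = np.zeros_like(arr) if hi - lo == 0 else (arr - lo) / (hi - lo)
    return arr[None, :, :]


def resize_dataset(ds: Dataset, target_side: int) -> Dataset:
    """Dataset with every image resized (labels and manifest shared)."""
    if ds.images.shape[-1] == target_side:
        return ds
    images = np.stack([preprocess(img, target_side) for img in ds.images])
    return Dataset(images=images, labels=ds.labels, split=ds.split,
                   manifest=ds.manifest)


def save_dataset(ds: Dataset, out_dir, stem: str = "phantom"):
    """Write 8-bit PNGs, a lossless NPY stack, and the manifest CSV."""
    from PIL import Image

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    np.save(out_dir / f"{stem}_{ds.split}.npy", ds.images)
    filenames = []
    for i, img in enumerate(ds.images):
        name = f"{stem}_{ds.split}_{i:05d}.png"
        png = (np.clip(img[0], 0, 1) * 255).round().astype(np.uint8)
        Image.fromarray(png, mode="L").save(out_dir / name)
        filenames.append(name)
    manifest = ds.manifest.copy()
    manifest.insert(1, "filename", filenames)
    manifest.to_csv(out_dir / f"{stem}_{ds.split}_manifest.csv", index=False)
    return out_dir


def load_manifest_images(manifest_path) -> Dataset:
    """Rebuild a Dataset from a manifest CSV and its sibling PNG files."""
    import pandas as pd
    from PIL import Image

    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path)
    images = []
    for name in manifest["filename"]:
        arr = np.asarray(Image.open(manifest_path.parent / name), float) / 255.0
        images.append(arr[None, :, :])
    return Dataset(images=np.stack(images),
                   labels=manifest["label"].to_numpy(),
                   split="loaded", manifest=manifest)
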