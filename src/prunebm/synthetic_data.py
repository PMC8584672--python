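"""Binary datasets with the statistical structure of natural-image patches.

Two families of fixtures are produced here:

* unlabeled mixtures of binary prototypes with independent bit-flip noise,
  standing in for binarized circular image patches with a small number of
  latent causes;
* labeled block-shape "toy digits" on a small square grid with an
  always-zero one-pixel border, emulating multi-class images whose margins
  carry no information (so that pruning should disconnect border pixels).

Also provided: binarization of real-valued images at the population median
or mean, circular patch masks, local receptive-field connectivity masks,
and IDX / PNG readers for externally supplied image data.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "BinaryDataset",
    "PrototypeMixtureSpec",
    "ConnectivityMask",
    "generate_mixture",
    "patch_mixture_spec",
    "toy_digits",
    "binarize",
    "circular_mask",
    "extract_circular_patches",
    "receptive_field_mask",
    "read_idx",
    "read_png_dir",
    "save_dataset",
    "load_dataset",
]


@dataclass
class BinaryDataset:
    """A matrix of {0,1} patterns, optionally labeled and grid-shaped.

    ``patterns`` has shape ``(n_samples, n_units)``; ``labels`` (if given)
    assigns each row a class index; ``layout`` records a (rows, cols) grid
    for image-like data with ``rows * cols == n_units``.
    """

    patterns: np.ndarray
    labels: np.ndarray | None = None
    layout: tuple[int, int] | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.patterns = np.asarray(self.patterns)
        if self.patterns.ndim != 2:
            raise ValueError("patterns must be 2-D (samples x units)")
        vals = np.unique(self.patterns)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("patterns must be binary {0,1}")
        self.patterns = self.patterns.astype(np.uint8)
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64)
            if self.labels.shape != (self.patterns.shape[0],):
                raise ValueError("labels must have one entry per sample")
        if self.layout is not None:
            r, c = self.layout
            if r * c != self.patterns.shape[1]:
                raise ValueError("layout does not match number of units")
            self.layout = (int(r), int(c))

    @property
    def n_samples(self) -> int:
        return self.patterns.shape[0]

    @property
    def n_units(self) -> int:
        return self.patterns.shape[1]

    @property
    def n_classes(self) -> int:
        if self.labels is None:
            raise ValueError("dataset is unlabeled")
        return int(self.labels.max()) + 1


@dataclass
class PrototypeMixtureSpec:
    """Mixture of binary prototypes corrupted by independent bit flips."""

    prototypes: np.ndarray
    class_weights: np.ndarray
    flip_prob: float
    n_samples: int
    seed: int

    def __post_init__(self) -> None:
        self.prototypes = np.asarray(self.prototypes, dtype=np.uint8)
        if self.prototypes.ndim != 2:
            raise ValueError("prototypes must be 2-D (K x n_units)")
        self.class_weights = np.asarray(self.class_weights, dtype=float)
        if self.class_weights.shape != (self.prototypes.shape[0],):
            raise ValueError("need one class weight per prototype")
        if abs(self.class_weights.sum() - 1.0) > 1e-12:
            raise ValueError("class_weights must sum to 1")
        if not 0.0 <= self.flip_prob <= 0.5:
            raise ValueError("flip_prob must lie in [0, 0.5]")
        if self.n_samples < 1:
            raise ValueError("n_samples must be positive")


@dataclass
class ConnectivityMask:
    """Binary pre-to-post connectivity, shape (n_pre, n_post)."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=np.uint8)
        if not np.isin(self.mask, (0, 1)).all():
            raise ValueError("mask entries must be 0/1")

    @property
    def n_connections(self) -> int:
        return int(self.mask.sum())


# -- generators ---------------------------------------------------------------


def generate_mixture(spec: PrototypeMixtureSpec) -> BinaryDataset:
    """Draw samples from a prototype mixture with per-bit flip noise.

    Each sample picks a prototype according to ``class_weights`` and flips
    every bit independently with probability ``flip_prob``; labels record
    the source prototype.  Bit-reproducible given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    k = rng.choice(spec.prototypes.shape[0], size=spec.n_samples, p=spec.class_weights)
    base = spec.prototypes[k]
    flips = rng.random(base.shape) < spec.flip_prob
    patterns = np.bitwise_xor(base, flips.astype(np.uint8))
    return BinaryDataset(
        patterns,
        labels=k,
        metadata={
            "generator": "prototype_mixture",
            "flip_prob": spec.flip_prob,
            "seed": spec.seed,
        },
    )


def patch_mixture_spec(
    n_units: int = 13,
    n_pairs: int = 6,
    weight_decay: float = 0.65,
    flip_prob: float = 0.05,
    n_samples: int = 10_000,
    seed: int = 0,
) -> PrototypeMixtureSpec:
    """Canonical unlabeled-patch fixture emulating binarized image patches.

    Latent causes come in complementary prototype pairs (a random subset
    of pixels and its complement, equally weighted), so every pixel's
    mixture marginal is exactly 1/2 — the signature of thresholding at
    the median.  Pair frequencies fall off geometrically
    (``weight_decay**k``), giving a sloppy spectrum of common and rare
    causes: detectors of rare causes develop selective weights yet fire
    rarely, which is precisely where weight magnitude and activity-based
    importance disagree.  The default 13 units match a radius-2 circular
    patch; the pattern space stays exactly enumerable.
    """
    rng = np.random.default_rng([seed, 0x70726F74])
    protos = []
    for _ in range(n_pairs):
        size = int(rng.integers(max(1, n_units * 2 // 5), max(2, n_units * 3 // 4) + 1))
        s = np.zeros(n_units, dtype=np.uint8)
        s[rng.choice(n_units, size=size, replace=False)] = 1
        protos += [s, 1 - s]
    weights = np.repeat(weight_decay ** np.arange(n_pairs), 2)
    weights = weights / weights.sum()
    return PrototypeMixtureSpec(np.stack(protos), weights, flip_prob, n_samples, seed)


def _block_prototypes(grid: int, n_classes: int, border: int) -> np.ndarray:
    """Axis-aligned block/bar shapes in the interior of a ``grid x grid`` image."""
    inner = grid - 2 * border
    protos = []
    for c in range(n_classes):
        img = np.zeros((grid, grid), dtype=np.uint8)
        kind = c % 4
        span = max(2, inner // 2)
        off = border + (c // 4) % max(1, inner - span)
        if kind == 0:  # horizontal bar
            img[off : off + span // 2, border : grid - border] = 1
        elif kind == 1:  # vertical bar
            img[border : grid - border, off : off + span // 2] = 1
        elif kind == 2:  # filled square block
            img[off : off + span, off : off + span] = 1
        else:  # hollow frame
            img[border : grid - border, border : grid - border] = 1
            hole = border + 1
            img[hole : grid - hole, hole : grid - hole] = 0
        protos.append(img.ravel())
    return np.stack(protos)


def toy_digits(
    n_classes: int = 4,
    grid: int = 12,
    border: int = 1,
    flip_prob: float = 0.05,
    n_samples: int = 2000,
    seed: int = 0,
) -> BinaryDataset:
    """Labeled block-shape images with an uninformative always-zero border.

    The border pixels are forced to zero in every sample (noise included),
    so they carry no class information — the structural analogue of image
    margins.  Used to test that importance-guided pruning disconnects them.
    """
    protos = _block_prototypes(grid, n_classes, border)
    spec = PrototypeMixtureSpec(
        protos, np.full(n_classes, 1.0 / n_classes), flip_prob, n_samples, seed
    )
    ds = generate_mixture(spec)
    img = ds.patterns.reshape(-1, grid, grid)
    img[:, :border, :] = 0
    img[:, grid - border :, :] = 0
    img[:, :, :border] = 0
    img[:, :, grid - border :] = 0
    return BinaryDataset(
        img.reshape(-1, grid * grid),
        labels=ds.labels,
        layout=(grid, grid),
        metadata={"generator": "toy_digits", "flip_prob": flip_prob, "seed": seed,
                  "border": border},
    )


# -- preprocessing ------------------------------------------------------------


def binarize(
    images: np.ndarray, method: str = "median", per_image: bool = False
) -> BinaryDataset:
    """Threshold real-valued images at the population median or mean.

    An entry becomes 1 iff it strictly exceeds the threshold; by default
    the threshold is computed over the full set of pixel intensities
    (``per_image=True`` thresholds each row separately instead).
    """
    images = np.asarray(images, dtype=float)
    if images.size == 0:
        raise ValueError("empty input")
    if not np.isfinite(images).all():
        raise ValueError("images must be finite")
    if images.ndim == 1:
        images = images[None, :]
    flat = images.reshape(images.shape[0], -1)
    stat = np.median if method == "median" else np.mean
    if method not in ("median", "mean"):
        raise ValueError("method must be 'median' or 'mean'")
    if per_image:
        thr = stat(flat, axis=1, keepdims=True)
    else:
        thr = stat(flat)
    patterns = (flat > thr).astype(np.uint8)
    layout = tuple(images.shape[1:]) if images.ndim == 3 else None
    return BinaryDataset(
        patterns,
        layout=layout,
        metadata={"binarize_method": method, "per_image": per_image},
    )


def circular_mask(radius: int) -> np.ndarray:
    """Integer grid offsets (dx, dy) with dx^2 + dy^2 <= radius^2.

    The discrete disk of radius 2 has 13 pixels — the visible-layer size of
    the small patch models.
    """
    if radius < 0:
        raise ValueError("radius must be non-negative")
    r = int(radius)
    d = np.arange(-r, r + 1)
    dx, dy = np.meshgrid(d, d, indexing="ij")
    keep = dx**2 + dy**2 <= r**2
    return np.stack([dx[keep], dy[keep]], axis=1)


def extract_circular_patches(
    images: np.ndarray, radius: int, n_patches: int, seed: int = 0
) -> np.ndarray:
    """Slice circular pixel sets at random centres out of a stack of images."""
    images = np.asarray(images, dtype=float)
    if images.ndim != 3:
        raise ValueError("images must be (n, rows, cols)")
    offs = circular_mask(radius)
    rng = np.random.default_rng(seed)
    n, rows, cols = images.shape
    cx = rng.integers(radius, rows - radius, size=n_patches)
    cy = rng.integers(radius, cols - radius, size=n_patches)
    which = rng.integers(0, n, size=n_patches)
    return images[which[:, None], cx[:, None] + offs[:, 0], cy[:, None] + offs[:, 1]]


def receptive_field_mask(
    rows: int, cols: int, field: int, stride: int = 1
) -> ConnectivityMask:
    """Local connectivity from a pixel grid to a grid of post units.

    One post unit sits at every grid position visited by the stride; it
    connects to all pre pixels inside a ``field x field`` window centred on
    its position, clipped at the image borders (no zero padding).  With
    stride 1 the post layer has one unit per pixel; a 20x20 grid with a
    5x5 field then yields 8,836 connections instead of 160,000 dense.
    """
    if field % 2 != 1:
        raise ValueError("field must be odd")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if field > rows or field > cols:
        raise ValueError("field larger than grid")
    half = field // 2
    centers_r = range(0, rows, stride)
    centers_c = range(0, cols, stride)
    n_post = len(centers_r) * len(centers_c)
    mask = np.zeros((rows * cols, n_post), dtype=np.uint8)
    post = 0
    for cr in centers_r:
        r0, r1 = max(0, cr - half), min(rows, cr + half + 1)
        for cc in centers_c:
            c0, c1 = max(0, cc - half), min(cols, cc + half + 1)
            rr, cc2 = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
            mask[rr.ravel() * cols + cc2.ravel(), post] = 1
            post += 1
    return ConnectivityMask(mask)


# -- readers / writers ---------------------------------------------------------


def read_idx(path) -> np.ndarray:
    """Read an IDX-format image or label file (the MNIST container)."""
    with open(path, "rb") as f:
        zero, dtype_code, ndim = struct.unpack(">HBB", f.read(4))
        if zero != 0:
            raise ValueError("not an IDX file")
        dims = struct.unpack(">" + "I" * ndim, f.read(4 * ndim))
        dtypes = {0x08: np.uint8, 0x09: np.int8, 0x0B: np.int16,
                  0x0C: np.int32, 0x0D: np.float32, 0x0E: np.float64}
        dt = np.dtype(dtypes[dtype_code]).newbyteorder(">")
        data = np.frombuffer(f.read(), dtype=dt)
    return data.reshape(dims)


def read_png_dir(directory) -> tuple[np.ndarray, list[str]]:
    """Load all PNGs in a directory as gray-scale float images (sorted names)."""
    from PIL import Image

    paths = sorted(Path(directory).glob("*.png"))
    if not paths:
        raise ValueError(f"no PNG files in {directory}")
    imgs = [np.asarray(Image.open(p).convert("L"), dtype=float) for p in paths]
    return np.stack(imgs), [p.name for p in paths]


def save_dataset(ds: BinaryDataset, path) -> None:
    """Archive patterns, labels, layout, and generation metadata (npz)."""
    arrays = {"patterns": ds.patterns}
    if ds.labels is not None:
        arrays["labels"] = ds.labels
    if ds.layout is not None:
        arrays["layout"] = np.asarray(ds.layout)
    arrays["metadata_json"] = np.frombuffer(
        json.dumps(ds.metadata).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_dataset(path) -> BinaryDataset:
    with np.load(path) as z:
        return BinaryDataset(
            z["patterns"],
            labels=z["labels"] if "labels" in z else None,
            layout=tuple(z["layout"]) if "layout" in z else None,
            metadata=json.loads(bytes(z["metadata_json"]).decode())
            if "metadata_json" in z
            else {},
        )
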