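"""Synthetic oriented-bar dataset, Poisson image encoding, and IDX I/O.

The primary benchmark is generated, not downloaded: 27×27 grayscale images
of a bright bar through the image centre at one of eight orientations
(0° to 157.5° in 22.5° steps).  Each sample gets a random sub-pixel
perpendicular offset so no two images are identical, and optionally a
fixed fraction of pixels is perturbed with Gaussian noise.  Pixel
intensities in [0, 1] are Poisson-rate encoded into spike trains
(intensity v → rate v·Φ_max).

An IDX reader/writer is included for the classic handwritten-digit
archive format (big-endian binary, magic 0x803 for image tensors and
0x801 for label vectors).
"""

from __future__ import annotations

import struct
from dataclasses import dataclass

import numpy as np

from .dynamics import SpikeTrain, sample_poisson_spikes

__all__ = [
    "LabeledImage",
    "ORIENTATIONS_DEG",
    "generate_oriented_bars",
    "add_pixel_noise",
    "poisson_encode_image",
    "load_idx_images",
    "load_idx_labels",
    "load_idx_dataset",
    "write_idx_images",
    "write_idx_labels",
    "dataset_to_csv",
]

ORIENTATIONS_DEG = tuple(np.arange(8) * 22.5)  # 0° … 157.5°


@dataclass(frozen=True)
class LabeledImage:
    """A grayscale image with intensities in [0, 1] and an integer label."""

    pixels: np.ndarray
    label: int

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=float)
        object.__setattr__(self, "pixels", px)
        if px.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValueError("intensities must lie in [0, 1]")
        if self.label < 0:
            raise ValueError("label must be non-negative")

    @property
    def flat(self) -> np.ndarray:
        return self.pixels.ravel()


def _render_bar(size: int, angle_deg: float, bar_width: float,
                offset: float) -> np.ndarray:
    """Anti-aliased bar through the image centre at ``angle_deg``.

    Intensity falls linearly from 1 (inside the bar core) to 0 over one
    pixel beyond the half-width; ``offset`` shifts the bar perpendicular
    to its axis (sub-pixel jitter).  Angle 0° is a horizontal bar.
    """
    c = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    theta = np.deg2rad(angle_deg)
    # unit normal to the bar axis (axis direction is (cosθ, sinθ) in (x, y))
    nx, ny = -np.sin(theta), np.cos(theta)
    d = np.abs((xx - c) * nx + (yy - c) * ny - offset)
    return np.clip(bar_width / 2.0 + 0.5 - d, 0.0, 1.0)


def generate_oriented_bars(
    n_per_class: int,
    size: int = 27,
    bar_width: float = 3.0,
    jitter: float = 0.5,
    noise_fraction: float = 0.0,
    noise_sigma: float = 0.3,
    seed: int | np.random.Generator = 0,
) -> list[LabeledImage]:
    """Generate the eight-orientation bar dataset.

    Labels 0–7 map to orientations 0°, 22.5°, …, 157.5°.  Each sample's
    bar is offset perpendicular to its axis by Uniform(−jitter, +jitter)
    pixels so samples within a class differ.  With ``noise_fraction > 0``
    that fraction of pixels per image is perturbed with N(0, σ²) noise
    (see :func:`add_pixel_noise`).  Deterministic under the seed; classes
    are interleaved (image k has label k mod 8).
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    images = []
    for k in range(n_per_class):
        for label, angle in enumerate(ORIENTATIONS_DEG):
            offset = rng.uniform(-jitter, jitter)
            px = _render_bar(size, angle, bar_width, offset)
            img = LabeledImage(px, label)
            if noise_fraction > 0:
                img = add_pixel_noise(img, noise_fraction, noise_sigma, rng)
            images.append(img)
    return images


def add_pixel_noise(img: LabeledImage, fraction: float = 0.10,
                    sigma: float = 0.3,
                    rng: np.random.Generator | None = None) -> LabeledImage:
    """Perturb a fixed fraction of pixels with Gaussian noise.

    Exactly ``round(fraction · n_pixels)`` distinct pixel coordinates are
    chosen without replacement and perturbed by N(0, σ²); the result is
    clipped back to [0, 1].  The label is unchanged.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    if fraction == 0.0:
        return img
    rng = rng if rng is not None else np.random.default_rng()
    px = img.pixels.copy()
    n_px = px.size
    k = int(round(fraction * n_px))
    idx = rng.choice(n_px, size=k, replace=False)
    flat = px.ravel()
    flat[idx] = np.clip(flat[idx] + rng.normal(0.0, sigma, size=k), 0.0, 1.0)
    return LabeledImage(px, img.label)


def poisson_encode_image(img: LabeledImage, phi_max: float, duration: float,
                         dt: float, rng: np.random.Generator
                         ) -> list[SpikeTrain]:
    """Poisson-encode pixel intensities into spike trains.

    Pixel intensity ``v`` maps to rate ``v·Φ_max`` (spikes/ms); each step
    of length ``dt`` over ``duration`` ms draws independent Bernoulli
    spikes.  Returns one :class:`SpikeTrain` per pixel (row-major order).
    """
    rates = img.flat * phi_max
    n_steps = int(round(duration / dt))
    spikes = np.empty((n_steps, rates.size), dtype=np.int8)
    for n in range(n_steps):
        spikes[n] = sample_poisson_spikes(rates, dt, rng)
    times = np.arange(1, n_steps + 1) * dt
    return [SpikeTrain(j, times[spikes[:, j] > 0])
            for j in range(rates.size)]


# -- IDX binary format -----------------------------------------------------

_IDX_IMAGES_MAGIC = 0x00000803
_IDX_LABELS_MAGIC = 0x00000801


class IdxFormatError(ValueError):
    """Malformed IDX file (bad magic, truncated payload…)."""


def load_idx_images(path) -> np.ndarray:
    """Read an IDX image tensor, scaled to float in [0, 1]."""
    with open(path, "rb") as fh:
        head = fh.read(16)
        if len(head) < 16:
            raise IdxFormatError(f"truncated IDX header at offset {len(head)}")
        magic, n, rows, cols = struct.unpack(">IIII", head)
        if magic != _IDX_IMAGES_MAGIC:
            raise IdxFormatError(
                f"bad image magic 0x{magic:08x} at offset 0 "
                f"(expected 0x{_IDX_IMAGES_MAGIC:08x})")
        payload = fh.read()
    expected = n * rows * cols
    if len(payload) != expected:
        raise IdxFormatError(
            f"truncated IDX payload at offset {16 + len(payload)}: "
            f"expected {expected} bytes")
    data = np.frombuffer(payload, dtype=np.uint8).reshape(n, rows, cols)
    return data.astype(float) / 255.0


def load_idx_labels(path) -> np.ndarray:
    """Read an IDX label vector."""
    with open(path, "rb") as fh:
        head = fh.read(8)
        if len(head) < 8:
            raise IdxFormatError(f"truncated IDX header at offset {len(head)}")
        magic, n = struct.unpack(">II", head)
        if magic != _IDX_LABELS_MAGIC:
            raise IdxFormatError(
                f"bad label magic 0x{magic:08x} at offset 0 "
                f"(expected 0x{_IDX_LABELS_MAGIC:08x})")
        payload = fh.read()
    if len(payload) != n:
        raise IdxFormatError(
            f"truncated IDX payload at offset {8 + len(payload)}")
    return np.frombuffer(payload, dtype=np.uint8).astype(np.int64)


def load_idx_dataset(images_path, labels_path) -> list[LabeledImage]:
    """Read paired IDX image/label files into :class:`LabeledImage` list."""
    imgs = load_idx_images(images_path)
    labels = load_idx_labels(labels_path)
    if imgs.shape[0] != labels.shape[0]:
        raise IdxFormatError("image/label counts disagree")
    return [LabeledImage(px, int(lb)) for px, lb in zip(imgs, labels)]


def write_idx_images(images: np.ndarray, path):
    """Write a uint8-convertible image stack as an IDX image tensor."""
    arr = np.asarray(images)
    if arr.dtype != np.uint8:
        arr = np.clip(np.round(arr * 255.0), 0, 255).astype(np.uint8)
    n, rows, cols = arr.shape
    with open(path, "wb") as fh:
        fh.write(struct.pack(">IIII", _IDX_IMAGES_MAGIC, n, rows, cols))
        fh.write(arr.tobytes())


def write_idx_labels(labels: np.ndarray, path):
    """Write an integer label vector as an IDX label file."""
    arr = np.asarray(labels).astype(np.uint8)
    with open(path, "wb") as fh:
        fh.write(struct.pack(">II", _IDX_LABELS_MAGIC, arr.size))
        fh.write(arr.tobytes())


def dataset_to_csv(images: list[LabeledImage], path):
    """Export a dataset as CSV: one row per image, pixels then label."""
    with open(path, "w") as fh:
        for img in images:
            vals = ",".join(f"{v:.6g}" for v in img.flat)
            fh.write(f"{vals},{img.label}\n")
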