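"""Seeded synthetic shape images with exact contour masks.

The generators produce the kind of input the contour-prior pipeline assumes:
a single high-contrast shape (square, ellipse or triangle) whose foreground
and background mean intensities differ by at least 0.5 on the [-1, 1] scale,
overlaid with band-limited high-frequency texture noise.  Because the noise
lives in the upper third of the spectrum, small-cutoff low-pass filters
suppress it while the shape's contour survives — the contour/texture
dichotomy the prior extraction relies on.  Every generator is a pure
function of its spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import binary_erosion

__all__ = ["ShapeSpec", "ShapeImage", "SyntheticDataset", "make_shape_image", "make_dataset"]

_FAMILIES = ("square", "ellipse", "triangle")


@dataclass(frozen=True)
class ShapeSpec:
    family: str = "square"
    height: int = 32
    width: int = 32
    foreground: float = 0.8
    background: float = -0.8
    texture_amplitude: float = 0.2

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown shape family {self.family!r}")
        if self.height < 16 or self.width < 16:
            raise ValueError("canvas must be at least 16x16")


@dataclass
class ShapeImage:
    pixels: np.ndarray  # (H, W) in [-1, 1], quantized to the uint8 grid
    contour_mask: np.ndarray  # boolean (H, W), 1-pixel-thick 8-connected boundary
    spec: ShapeSpec
    seed: int


def _shape_mask(spec: ShapeSpec, rng: np.random.Generator) -> np.ndarray:
    H, W = spec.height, spec.width
    # random center and size, kept comfortably inside the canvas
    half = rng.integers(min(H, W) // 6, min(H, W) // 3 + 1)
    cy = rng.integers(half + 1, H - half - 1)
    cx = rng.integers(half + 1, W - half - 1)
    yy, xx = np.mgrid[0:H, 0:W]
    if spec.family == "square":
        mask = (np.abs(yy - cy) <= half) & (np.abs(xx - cx) <= half)
    elif spec.family == "ellipse":
        ry, rx = half, max(2, int(half * 0.7))
        mask = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
    else:  # triangle: apex up, inside by half-plane tests
        mask = (
            (yy >= cy - half)
            & (yy <= cy + half)
            & (np.abs(xx - cx) <= (yy - (cy - half)) / 2)
        )
    if mask.sum() < 9:
        raise ValueError("shape degenerate on this canvas")
    return mask


def _texture(spec: ShapeSpec, rng: np.random.Generator) -> np.ndarray:
    """Seeded noise band-limited to the upper third of the spectrum."""
    H, W = spec.height, spec.width
    noise = rng.uniform(-1.0, 1.0, size=(H, W))
    spec2 = np.fft.fftshift(np.fft.fft2(noise))
    ch, cw = H // 2, W // 2
    r = np.abs(np.arange(H) - ch)[:, None]
    s = np.abs(np.arange(W) - cw)[None, :]
    band = np.maximum(r, s) >= min(H, W) // 3
    tex = np.fft.ifft2(np.fft.ifftshift(spec2 * band)).real
    peak = np.abs(tex).max()
    if peak > 0:
        tex *= spec.texture_amplitude / peak
    return tex


def make_shape_image(spec: ShapeSpec, seed: int) -> ShapeImage:
    """Render one shape with its exact boundary mask.

    The final pixels are quantized to the uint8 grid (the same grid PNG
    serialization uses), so a round trip through an 8-bit file is lossless.
    """
    rng = np.random.default_rng(seed)
    mask = _shape_mask(spec, rng)
    img = np.where(mask, spec.foreground, spec.background).astype(np.float64)
    if spec.texture_amplitude > 0:
        img = img + _texture(spec, rng)
    img = np.clip(img, -1.0, 1.0)
    # quantize to the 8-bit grid for lossless PNG round trips
    img = np.round((img + 1.0) * 127.5) / 127.5 - 1.0
    boundary = mask & ~binary_erosion(mask, structure=np.ones((3, 3)))
    return ShapeImage(pixels=img, contour_mask=boundary, spec=spec, seed=seed)


@dataclass
class SyntheticDataset:
    items: list[tuple[ShapeImage, int]]
    classes: int
    per_class: int
    seed: int

    def __len__(self) -> int:
        return len(self.items)

    def class_name(self, label: int) -> str:
        family = _FAMILIES[label % 3]
        polarity = "pos" if label < 3 else "neg"
        return f"{label}_{family}_{polarity}"


def make_dataset(
    C: int, per_class: int, H: int = 32, W: int = 32, seed: int = 0
) -> SyntheticDataset:
    """Balanced C-class labeled set of shape images.

    Classes 0..2 are the shape families at positive foreground polarity;
    classes 3..4 repeat families with inverted polarity (dark shape on
    bright ground), so up to 5 separable classes exist.
    """
    if not 2 <= C <= 5:
        raise ValueError(f"class count must be in 2..5, got {C}")
    ss = np.random.SeedSequence([seed, C, per_class, H, W])
    child_seeds = ss.generate_state(C * per_class)
    items: list[tuple[ShapeImage, int]] = []
    k = 0
    for label in range(C):
        family = _FAMILIES[label % 3]
        if label < 3:
            fg, bg = 0.8, -0.8
        else:
            fg, bg = -0.8, 0.8
        spec = ShapeSpec(family=family, height=H, width=W, foreground=fg, background=bg)
        for _ in range(per_class):
            items.append((make_shape_image(spec, int(child_seeds[k])), label))
            k += 1
    return SyntheticDataset(items=items, classes=C, per_class=per_class, seed=seed)
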