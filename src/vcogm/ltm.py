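"""Initial long-term-memory (LTM_0) construction from an image.

Two complementary strategies feed the memory with contour priors at the
feature-map resolution ``(H/d, W/d)``:

* Strategy 1 — run the UMA at native resolution, then average-downsample
  the stack by ``d`` (fine contours, smoothed);
* Strategy 2 — average-downsample the image first, then run the UMA at the
  reduced resolution (coarse contours, sharp).

The two stacks are concatenated along the map axis, Strategy 1 first, giving
the ``(n1 + n2, H/d, W/d)`` prior that seeds the recurrent memory state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .stats import SsimParams, select_cutoff
from .uma import uma_transform

__all__ = ["LtmPrior", "avg_downsample", "build_ltm0", "estimate_cutoffs"]


@dataclass
class LtmPrior:
    """Per-image contour prior: ``(n1+n2, H/d, W/d)`` stack of values in (0, 1]."""

    maps: np.ndarray
    n1: int
    n2: int
    d: int
    source_shape: tuple[int, int]

    def __post_init__(self):
        if self.maps.shape[0] != self.n1 + self.n2:
            raise ValueError("first axis must have length n1 + n2")


def avg_downsample(x: np.ndarray, d: int) -> np.ndarray:
    """Non-overlapping ``d x d`` block means over the trailing two axes.

    Remainder rows/columns that do not fill a block are dropped.
    Works on a single image ``(H, W)`` or a stack ``(n, H, W)``.
    """
    if d < 1:
        raise ValueError(f"downsampling factor must be >= 1, got {d}")
    x = np.asarray(x, dtype=np.float64)
    H, W = x.shape[-2], x.shape[-1]
    h, w = H // d, W // d
    if h < 1 or w < 1:
        raise ValueError(f"spatial dims {H}x{W} smaller than block size {d}")
    trimmed = x[..., : h * d, : w * d]
    shape = trimmed.shape[:-2] + (h, d, w, d)
    return trimmed.reshape(shape).mean(axis=(-3, -1))


def build_ltm0(I: np.ndarray, n1: int, n2: int, d: int) -> LtmPrior:
    """Build the initial LTM from one grayscale image.

    Strategy 1 = ``avg_downsample(UMA(I, n1), d)``;
    Strategy 2 = ``UMA(avg_downsample(I, d), n2)``; concatenated in that
    order.  Values stay in (0, 1] since block means of (0, 1] values do.
    """
    I = np.asarray(I, dtype=np.float64)
    s1 = avg_downsample(uma_transform(I, n1), d)
    small = avg_downsample(I, d)
    s2 = uma_transform(small, n2)
    if s1.shape[1:] != s2.shape[1:]:
        # UMA preserves shape, so this only trips on inconsistent cropping
        raise ValueError("strategy outputs disagree on spatial shape")
    return LtmPrior(
        maps=np.concatenate([s1, s2], axis=0),
        n1=n1,
        n2=n2,
        d=d,
        source_shape=(I.shape[0], I.shape[1]),
    )


def estimate_cutoffs(
    images: Iterable[np.ndarray], d: int, params: SsimParams = SsimParams()
) -> tuple[int, int]:
    """Estimate ``(n1, n2)`` for a population of same-size images.

    ``n1`` is the truncated-mean cutoff at native resolution; ``n2`` the
    same statistic on the ``d``-downsampled images (Strategy 2 applies the
    UMA at the reduced resolution, so its bound statistics live there).
    """
    images = list(images)
    n1, _, _ = select_cutoff(images, params)
    n2, _, _ = select_cutoff((avg_downsample(I, d) for I in images), params)
    return n1, n2
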