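"""Statistical cutoff selection for the UMA.

The number of low-pass filters ``n`` is not tuned during training; it is a
dataset-level statistic.  For each image the full stack at ``n_max`` is
computed, each map is standardized and compared with the image by SSIM, and
the per-sample bound ``N_i`` counts the maps whose SSIM falls in (0, 1] —
the largest cutoff for which the prior still resembles the image
structurally.  Over a population the bounds form a frequency distribution
``P``; ``n`` is the truncated mean of ``P`` after dropping the degenerate
endpoints ``r = 0`` (UMA fails at every cutoff) and ``r = n_max`` (every
cutoff passes), both uninformative for choosing an interior cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from skimage.metrics import structural_similarity

from .uma import uma_transform

__all__ = [
    "SsimParams",
    "n_max",
    "ssim",
    "compute_sample_bound",
    "aggregate_distribution",
    "truncated_mean",
    "select_cutoff",
]


@dataclass(frozen=True)
class SsimParams:
    """Windowed-SSIM parameters.

    Defaults follow the reference convention: 11x11 Gaussian window with
    sigma 1.5, stabilizer factors ``c1 = (k1 * data_range)^2`` and
    ``c2 = (k2 * data_range)^2`` with k1=0.01, k2=0.03.  ``data_range`` is
    fixed at 2.0, the nominal span of images in [-1, 1], and is applied
    unchanged even when one comparand is a standardized (unit-variance) map.
    """

    window: int = 11
    gaussian_sigma: float = 1.5
    c1_factor: float = 0.01
    c2_factor: float = 0.03
    data_range: float = 2.0

    def __post_init__(self):
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")
        if min(self.gaussian_sigma, self.c1_factor, self.c2_factor, self.data_range) <= 0:
            raise ValueError("SSIM constants must be strictly positive")


def n_max(H: int, W: int) -> int:
    """Upper bound on the cutoff count: ``ceil(0.5 * min(H, W)) + 1``.

    Conjugate symmetry of the real-image spectrum makes cutoffs beyond half
    the smaller side redundant.
    """
    if H < 2 or W < 2:
        raise ValueError("image must be at least 2x2")
    return math.ceil(0.5 * min(H, W)) + 1


def ssim(p: np.ndarray, q: np.ndarray, params: SsimParams = SsimParams()) -> float:
    """Mean local SSIM index between two equally-shaped images.

    Product of luminance, contrast and structure terms over sliding Gaussian
    windows; the result lies in [-1, 1].
    """
    p = np.asarray(p, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    if p.shape != q.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {q.shape}")
    # for images smaller than the window, shrink to the largest odd fit
    win = min(params.window, min(p.shape))
    if win % 2 == 0:
        win -= 1
    if win < 3:
        raise ValueError(f"image {p.shape} too small for windowed SSIM")
    return float(
        structural_similarity(
            p,
            q,
            win_size=win,
            gaussian_weights=True,
            sigma=params.gaussian_sigma,
            use_sample_covariance=False,
            K1=params.c1_factor,
            K2=params.c2_factor,
            data_range=params.data_range,
        )
    )


def compute_sample_bound(
    I: np.ndarray, params: SsimParams = SsimParams()
) -> int:
    """Per-sample bound ``N_i``: number of standardized prior maps with SSIM in (0, 1].

    Runs the UMA at the maximal cutoff, standardizes each map (subtract
    mean, divide by standard deviation) and counts the maps whose SSIM
    against the original image is strictly positive.  A map with zero
    variance (e.g. from a constant image) cannot be standardized; it is
    treated as failing the constraint, so a constant image yields
    ``N_i = 0``.
    """
    I = np.asarray(I, dtype=np.float64)
    nm = n_max(*I.shape)
    stack = uma_transform(I, nm)
    count = 0
    for r in range(nm):
        m = stack[r]
        sd = m.std()
        if sd < 1e-12:
            continue
        z = (m - m.mean()) / sd
        if 0.0 < ssim(I, z, params) <= 1.0:
            count += 1
    return count


def aggregate_distribution(bounds: Sequence[int], nmax: int) -> np.ndarray:
    """Frequency distribution ``P_r`` of the per-sample bounds, r = 0..n_max.

    Returns an integer array of length ``nmax + 1`` with
    ``sum(P) == len(bounds)``.
    """
    counts = np.zeros(nmax + 1, dtype=np.int64)
    for b in bounds:
        b = int(b)
        if not 0 <= b <= nmax:
            raise ValueError(f"bound {b} outside [0, {nmax}]")
        counts[b] += 1
    return counts


def truncated_mean(P: np.ndarray) -> int:
    """Cutoff count ``n``: truncated mean of ``P`` excluding r = 0 and r = n_max.

    ``n = round( sum_{r=1}^{nmax-1} P_r * r / sum_{r=1}^{nmax-1} P_r )``,
    rounded half away from zero and floored at 1.  Raises if all mass sits
    on the excluded endpoints.
    """
    P = np.asarray(P)
    if P.ndim != 1 or len(P) < 3:
        raise ValueError("distribution must cover r = 0 .. n_max with n_max >= 2")
    interior = P[1:-1].astype(np.float64)
    total = interior.sum()
    if total <= 0:
        raise ValueError(
            "cannot select a cutoff: every sample bound sits at r=0 or r=n_max, "
            "which are excluded as invalid data"
        )
    r = np.arange(1, len(P) - 1, dtype=np.float64)
    mean = float((interior * r).sum() / total)
    # round half away from zero; mean is positive here
    return max(1, int(math.floor(mean + 0.5)))


def select_cutoff(
    images: Iterable[np.ndarray], params: SsimParams = SsimParams()
) -> tuple[int, np.ndarray, int]:
    """Survey a population of images and solve for the cutoff count.

    Returns ``(n, counts, nmax)``.  All images must share the same
    resolution (the bound distribution is resolution-specific).
    """
    bounds: list[int] = []
    nmax = None
    for I in images:
        I = np.asarray(I, dtype=np.float64)
        nm = n_max(*I.shape)
        if nmax is None:
            nmax = nm
        elif nm != nmax:
            raise ValueError("population mixes resolutions; survey each separately")
        bounds.append(compute_sample_bound(I, params))
    if nmax is None:
        raise ValueError("empty population")
    counts = aggregate_distribution(bounds, nmax)
    return truncated_mean(counts), counts, nmax
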