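"""Unbiased Mapping Algorithm (UMA): frequency-domain contour-prior extraction.

The UMA turns a grayscale image ``I`` in [-1, 1] into a stack of *prior maps*
in (0, 1] that highlight contours and suppress texture.  Each map is produced
by an ideal square low-pass filter applied on the centered 2-D frequency
plane, followed by the nonlinear mapping ``exp(-|.|)``.  Low-pass filtering
drives the signed image toward zero at contour sign-crossings, so the
exponential mapping assigns values near 1 exactly along contours.

The cutoff count ``n`` (number of filters, hence maps) is a free parameter
here; its statistical selection lives in :mod:`vcogm.stats`.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "to_gray_norm",
    "build_filter",
    "low_pass_filter",
    "uma_transform",
]

# ITU-R 601 luma weights for RGB -> gray reduction.
_LUMA = np.array([0.299, 0.587, 0.114])


def to_gray_norm(image: np.ndarray) -> np.ndarray:
    """Convert an 8-bit raster to a normalized grayscale image in [-1, 1].

    Parameters
    ----------
    image
        ``(H, W)`` or ``(H, W, 3)`` array of dtype uint8.

    Returns
    -------
    ndarray
        ``(H, W)`` float64 array with values in [-1, 1], obtained by the
        fixed affine map ``value / 127.5 - 1`` (after ITU-R 601 luma
        weighting for 3-channel input).  The map is fixed rather than
        per-image min-max so that identical pixels map identically across a
        dataset.
    """
    arr = np.asarray(image)
    if arr.dtype != np.uint8:
        raise ValueError(f"expected 8-bit (uint8) input, got dtype {arr.dtype}")
    if arr.ndim == 3 and arr.shape[2] == 3:
        gray = arr.astype(np.float64) @ _LUMA
    elif arr.ndim == 2:
        gray = arr.astype(np.float64)
    else:
        raise ValueError(
            f"expected a (H, W) or (H, W, 3) image, got shape {arr.shape}"
        )
    return gray / 127.5 - 1.0


def _validate_gray(I: np.ndarray) -> np.ndarray:
    I = np.asarray(I, dtype=np.float64)
    if I.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {I.shape}")
    if not np.all(np.isfinite(I)):
        raise ValueError("image contains non-finite values")
    if I.min() < -1.0 - 1e-12 or I.max() > 1.0 + 1e-12:
        raise ValueError("image values must lie in [-1, 1]")
    return I


def build_filter(i: int, H: int, W: int) -> np.ndarray:
    """Ideal square low-pass mask on the centered H x W frequency plane.

    The mask is 1 inside the axis-aligned square of half-width ``L(i) = i``
    centered on the zero-frequency bin of the *shifted* (fftshift) plane,
    0 outside.  Masks are nested: ``support(i) <= support(i+1)``, and the
    DC bin is always inside the support.  Once ``i`` reaches the maximum
    Chebyshev radius of the plane the mask saturates to all ones.

    The plane center sits at ``(H//2, W//2)``, the location fftshift assigns
    to frequency zero for both even and odd sizes.
    """
    if i < 1:
        raise ValueError(f"cutoff index must be >= 1, got {i}")
    if H < 2 or W < 2:
        raise ValueError("plane must be at least 2x2")
    ch, cw = H // 2, W // 2
    r = np.abs(np.arange(H) - ch)[:, None]
    s = np.abs(np.arange(W) - cw)[None, :]
    return ((r <= i) & (s <= i)).astype(np.float64)


def low_pass_filter(
    I: np.ndarray, i: int, *, clip: bool = True
) -> np.ndarray:
    """Filter an image with the ideal low-pass mask of cutoff index ``i``.

    Computes ``real(IFFT(fftshift(FFT(I)) * mask))`` on the centered full
    plane.  For real input the imaginary residue of the inverse transform is
    numerical noise (the mask is point-symmetric, preserving conjugate
    symmetry) and is discarded.

    Ideal filters ring beyond the input range, so by default the result is
    clipped back to [-1, 1]; pass ``clip=False`` for the raw filtered image
    (used by energy-monotonicity checks).
    """
    I = _validate_gray(I)
    H, W = I.shape
    mask = build_filter(i, H, W)
    spec = np.fft.fftshift(np.fft.fft2(I))
    out = np.fft.ifft2(np.fft.ifftshift(spec * mask)).real
    if clip:
        out = np.clip(out, -1.0, 1.0)
    return out


def uma_transform(I: np.ndarray, n: int) -> np.ndarray:
    """Map an image to its ``n``-map contour-prior stack.

    Map ``i`` (1-based) is ``exp(-|I_i*|)`` where ``I_i*`` is the clipped
    low-pass filtered image at cutoff index ``i``.  Every output value lies
    in (0, 1], with value 1 exactly where the filtered image is 0 — i.e. at
    contour sign-crossings.

    Returns an ``(n, H, W)`` float64 stack.
    """
    I = _validate_gray(I)
    from .stats import n_max  # local import to avoid cycle at module load

    nm = n_max(*I.shape)
    if not 1 <= n <= nm:
        raise ValueError(f"cutoff count n={n} outside [1, {nm}] for shape {I.shape}")
    spec = np.fft.fftshift(np.fft.fft2(I))
    H, W = I.shape
    stack = np.empty((n, H, W))
    for i in range(1, n + 1):
        mask = build_filter(i, H, W)
        filt = np.fft.ifft2(np.fft.ifftshift(spec * mask)).real
        stack[i - 1] = np.exp(-np.abs(np.clip(filt, -1.0, 1.0)))
    return stack
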