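"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — explicit DFT matrices, quadruple
convolution loops, step-by-step formula transcriptions — and shares no code
with the implementation it checks.
"""

import math

import numpy as np
from scipy.special import erf


def dft_matrix(N: int) -> np.ndarray:
    k = np.arange(N)
    return np.exp(-2j * np.pi * np.outer(k, k) / N)


def direct_dft_filter(I: np.ndarray, i: int) -> np.ndarray:
    """O(N^2) direct-DFT ideal low-pass filtering; returns the complex image."""
    H, W = I.shape
    FH, FW = dft_matrix(H), dft_matrix(W)
    spec = FH @ I @ FW
    ch, cw = H // 2, W // 2
    mask = np.zeros((H, W))
    for u in range(H):
        for v in range(W):
            r = (u + ch) % H  # coordinate after centering the spectrum
            s = (v + cw) % W
            if abs(r - ch) <= i and abs(s - cw) <= i:
                mask[u, v] = 1.0
    return (np.conj(FH) / H) @ (spec * mask) @ (np.conj(FW) / W)


def enumerate_filter_mask(i: int, H: int, W: int) -> np.ndarray:
    """Coordinate-test enumeration of the centered square mask."""
    ch, cw = H // 2, W // 2
    mask = np.zeros((H, W))
    for r in range(H):
        for s in range(W):
            if abs(r - ch) <= i and abs(s - cw) <= i:
                mask[r, s] = 1.0
    return mask


def luma_affine(rgb: np.ndarray) -> np.ndarray:
    """Per-pixel ITU-R 601 luma followed by the fixed affine map."""
    H, W, _ = rgb.shape
    out = np.zeros((H, W))
    for y in range(H):
        for x in range(W):
            r, g, b = (float(v) for v in rgb[y, x])
            out[y, x] = (0.299 * r + 0.587 * g + 0.114 * b) / 127.5 - 1.0
    return out


def block_mean(x: np.ndarray, d: int) -> np.ndarray:
    """Double-loop d x d block means, remainder cropped."""
    H, W = x.shape
    h, w = H // d, W // d
    out = np.zeros((h, w))
    for a in range(h):
        for b in range(w):
            out[a, b] = x[a * d : (a + 1) * d, b * d : (b + 1) * d].mean()
    return out


def ssim_oracle(p, q, win=11, sigma=1.5, k1=0.01, k2=0.03, data_range=2.0):
    """Literal windowed-SSIM formula with an explicit Gaussian window."""
    pad = (win - 1) // 2
    ax = np.arange(-pad, pad + 1)
    g1 = np.exp(-0.5 * ax**2 / sigma**2)
    kern = np.outer(g1, g1)
    kern /= kern.sum()
    H, W = p.shape
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    vals = []
    for y in range(pad, H - pad):
        for x in range(pad, W - pad):
            wp = p[y - pad : y + pad + 1, x - pad : x + pad + 1]
            wq = q[y - pad : y + pad + 1, x - pad : x + pad + 1]
            mp = (kern * wp).sum()
            mq = (kern * wq).sum()
            vp = (kern * wp * wp).sum() - mp * mp
            vq = (kern * wq * wq).sum() - mq * mq
            cov = (kern * wp * wq).sum() - mp * mq
            vals.append(
                ((2 * mp * mq + c1) * (2 * cov + c2))
                / ((mp**2 + mq**2 + c1) * (vp + vq + c2))
            )
    return float(np.mean(vals))


def gelu_oracle(x: np.ndarray) -> np.ndarray:
    return 0.5 * x * (1.0 + erf(x / math.sqrt(2.0)))


def loop_conv2d(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Quadruple-loop same-padded stride-1 cross-correlation.

    x: (C_in, H, W); w: (C_out, C_in, k, k)."""
    Ci, H, W = x.shape
    Co, _, k, _ = w.shape
    pad = k // 2
    xp = np.zeros((Ci, H + 2 * pad, W + 2 * pad))
    xp[:, pad : pad + H, pad : pad + W] = x
    out = np.zeros((Co, H, W))
    for o in range(Co):
        for y in range(H):
            for xx in range(W):
                acc = 0.0
                for c in range(Ci):
                    for dy in range(k):
                        for dx in range(k):
                            acc += xp[c, y + dy, xx + dx] * w[o, c, dy, dx]
                out[o, y, xx] = acc
    return out


def loop_matmul(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Triple-loop matrix product."""
    n, m = A.shape
    m2, p = B.shape
    assert m == m2
    out = np.zeros((n, p))
    for i in range(n):
        for j in range(p):
            for k in range(m):
                out[i, j] += A[i, k] * B[k, j]
    return out


def perceive_oracle(x: np.ndarray, kernels: list, bias: np.ndarray) -> np.ndarray:
    """P on one sample: split channels into j groups, per-group conv, concat, bias."""
    j = len(kernels)
    D = x.shape[0]
    Dg = D // j
    parts = [
        loop_conv2d(x[i * Dg : (i + 1) * Dg], kernels[i]) for i in range(j)
    ]
    out = np.concatenate(parts, axis=0)
    return out + bias.reshape(D, 1, 1)


def recall_oracle(ltm: np.ndarray, W_m: np.ndarray, b: np.ndarray) -> np.ndarray:
    return loop_matmul(W_m, ltm) + b.reshape(-1, 1)


def batchnorm_oracle(z: np.ndarray, gamma, beta, eps=1e-5):
    """Training-mode batch statistics over (batch, positions) per channel."""
    mu = z.mean(axis=(0, 2), keepdims=True)
    var = ((z - mu) ** 2).mean(axis=(0, 2), keepdims=True)
    return (z - mu) / np.sqrt(var + eps) * gamma.reshape(1, -1, 1) + beta.reshape(1, -1, 1)


def attend_oracle(wm, mp, W_a, b, gamma, beta, eps=1e-5):
    """A on a batch: concat, batch-norm, GeLU, linear map, bias."""
    z = np.concatenate([wm, mp], axis=1)
    z = batchnorm_oracle(z, gamma, beta, eps)
    z = gelu_oracle(z)
    return np.stack([loop_matmul(W_a, zb) for zb in z]) + b.reshape(1, -1, 1)


def update_oracle(attn, ltm, W_u):
    return gelu_oracle(np.stack([loop_matmul(W_u, a) for a in attn]) + ltm)


def analyze_oracle(attn, W1, b1, W2, b2):
    h = gelu_oracle(np.stack([loop_matmul(W1, a) for a in attn]) + b1.reshape(1, -1, 1))
    return np.stack([loop_matmul(W2, hb) for hb in h]) + b2.reshape(1, -1, 1)
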