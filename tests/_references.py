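"""Unvectorized straight-line reference implementations used as oracles.

Everything here is written with explicit per-pixel loops and scalar
arithmetic, independent of the vectorized library code it checks.
"""

from __future__ import annotations

import math

import numpy as np


def reflect_window(image: np.ndarray, row: int, col: int, half: int) -> np.ndarray:
    """Window around (row, col) with reflect ('symmetric') padding."""
    h, w = image.shape
    vals = np.empty((2 * half + 1, 2 * half + 1))
    for i, dr in enumerate(range(-half, half + 1)):
        for j, dc in enumerate(range(-half, half + 1)):
            r = _reflect_index(row + dr, h)
            c = _reflect_index(col + dc, w)
            vals[i, j] = image[r, c]
    return vals


def _reflect_index(i: int, n: int) -> int:
    # scipy 'reflect' mode: (d c b a | a b c d | d c b a)
    period = 2 * n
    i = i % period
    if i < 0:
        i += period
    return i if i < n else period - 1 - i


def geometric_mean_scalar(window: np.ndarray, floor: float) -> float:
    prod = 1.0
    for v in window.ravel():
        prod *= max(float(v), floor)
    return prod ** (1.0 / window.size)


def local_stats(image: np.ndarray, half: int, floor: float):
    """Per-pixel (median, geometric mean, variance-about-geomean) maps."""
    h, w = image.shape
    med = np.empty((h, w))
    mu = np.empty((h, w))
    var = np.empty((h, w))
    for r in range(h):
        for c in range(w):
            win = reflect_window(image, r, c, half)
            med[r, c] = float(np.median(win))
            m = geometric_mean_scalar(win, floor)
            mu[r, c] = m
            var[r, c] = float(np.mean((win - m) ** 2))
    return med, mu, var


def median_map(image: np.ndarray, half: int) -> np.ndarray:
    h, w = image.shape
    out = np.empty((h, w))
    for r in range(h):
        for c in range(w):
            out[r, c] = float(np.median(reflect_window(image, r, c, half)))
    return out


def correlate_reflect(image: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Per-pixel correlation with reflect padding (odd kernel)."""
    kh, kw = kernel.shape
    hh, hw = kh // 2, kw // 2
    h, w = image.shape
    out = np.zeros((h, w))
    for r in range(h):
        for c in range(w):
            acc = 0.0
            for i in range(kh):
                for j in range(kw):
                    rr = _reflect_index(r + i - hh, h)
                    cc = _reflect_index(c + j - hw, w)
                    acc += kernel[i, j] * image[rr, cc]
            out[r, c] = acc
    return out


def improved_kernel_scalar(sigma: float, half_width: int, eps: float = 1e-6) -> np.ndarray:
    """Scalar transcription of the improved Gaussian kernel formula."""
    n = 2 * half_width + 1
    w = np.empty((n, n))
    for i, c in enumerate(range(-half_width, half_width + 1)):
        for j, r in enumerate(range(-half_width, half_width + 1)):
            d2 = c * c + r * r
            gauss = math.exp(-d2 / (2 * sigma**2)) / (2 * math.pi * sigma**2)
            log_term = (
                (d2 - 2 * sigma**2)
                / (2 * math.pi * sigma**6)
                * math.exp(-d2 / (2 * sigma**2))
            )
            radicand = max(abs(d2 - 2 * sigma**2 * math.exp(-d2)), eps)
            w[i, j] = (gauss + log_term) / math.sqrt(radicand)
    return w / np.abs(w).sum()


def conventional_wiener_ref(image: np.ndarray, window_size: int, floor: float, eps: float):
    """Per-pixel conventional Wiener about the local median, u^2 auto."""
    half = window_size // 2
    med, _mu, var = local_stats(image, half, floor)
    u2 = float(var.mean())
    h, w = image.shape
    out = np.empty((h, w))
    for r in range(h):
        for c in range(w):
            shr = min(max((var[r, c] - u2) / max(var[r, c], eps), 0.0), 1.0)
            out[r, c] = med[r, c] + shr * (image[r, c] - med[r, c])
    return np.clip(out, 0.0, 255.0)


def modified_wiener_ref(image: np.ndarray, config) -> np.ndarray:
    """Per-pixel two-branch modified Wiener mirroring the documented contract."""
    half = config.window_size // 2
    lo, hi = config.value_range
    med = median_map(image, half)
    _m2, mu, var_a = local_stats(med, half, config.epsilon_floor)
    u2 = float(var_a.mean()) if config.noise_variance == "auto" else float(config.noise_variance)

    bright = np.clip(image * config.brightness_gain, lo, hi)
    kernel = improved_kernel_scalar(config.kernel_sigma, config.kernel_half_width, config.eps)
    filtered = correlate_reflect(bright, kernel)
    med1 = median_map(filtered, half)
    _m3, rho, var_b = local_stats(filtered, half, config.epsilon_floor)

    h, w = image.shape
    q = np.empty((h, w))
    for r in range(h):
        for c in range(w):
            shr_a = min(max((var_a[r, c] - u2) / max(var_a[r, c], config.eps), 0.0), 1.0)
            shr_b = min(max((var_b[r, c] - u2) / max(var_b[r, c], config.eps), 0.0), 1.0)
            branch_a = med[r, c] + shr_a * (image[r, c] - med[r, c])
            branch_b = med1[r, c] + shr_b * (image[r, c] - rho[r, c])
            q[r, c] = branch_a + branch_b
    if config.combine == "mean":
        q = q / 2.0
    if config.output_norm == "rescale":
        p_lo, p_hi = np.percentile(q, [0.5, 99.5])
        if p_hi - p_lo <= config.eps:
            return np.full_like(q, (lo + hi) / 2.0)
        return np.clip(lo + (q - p_lo) * (hi - lo) / (p_hi - p_lo), lo, hi)
    return np.clip(q, lo, hi)


def gradients_ref(image: np.ndarray):
    """Brute-force [-1 0 1] correlations with orientation/magnitude."""
    kx = np.array([[-1.0, 0.0, 1.0]])
    ky = kx.T
    u_x = correlate_reflect(image, kx)
    u_y = correlate_reflect(image, ky)
    h, w = image.shape
    u_o = np.zeros((h, w))
    u_g = np.zeros((h, w))
    for r in range(h):
        for c in range(w):
            x, y = u_x[r, c], u_y[r, c]
            u_g[r, c] = math.hypot(x, y)
            if x == 0 and y == 0:
                u_o[r, c] = 0.0
            elif x == 0:
                u_o[r, c] = math.copysign(math.pi / 2, y)
            else:
                u_o[r, c] = math.atan(y / x)
    return u_x, u_y, u_o, u_g


def improved_entropy_masses_ref(masses, eps: float = 1e-12) -> float:
    """Scalar transcription of the evidential entropy over singleton masses."""
    num = 0.0
    den = 0.0
    for a in masses:
        if a <= 0:
            continue
        inner = a * math.log2(a)
        num += -a * math.log2((a + 2**1 - 1) / max(abs(inner), eps))
        num += a * math.log2(2**1 - 1) if (2**1 - 1) != 1 else 0.0
        den += a * math.log2(a) + 1.0 / (1.0 + math.exp(-math.log2(a)))
    if abs(den) < eps:
        den = eps
    return max(num / den, 0.0)


def improved_entropy_map_ref(gradient_map: np.ndarray, bins: int = 8) -> float:
    mags = [abs(float(v)) for v in np.asarray(gradient_map).ravel()]
    if max(mags) == 0.0:
        return 0.0
    hist, _ = np.histogram(mags, bins=bins)
    masses = [h / len(mags) for h in hist]
    return improved_entropy_masses_ref(masses)


def modified_gradients_ref(image: np.ndarray, bins: int = 8, tol: float = 1e-6):
    """Straight-line pipeline: gradients -> entropies -> select -> add."""
    u_x, u_y, _o, _g = gradients_ref(image)
    e_x = improved_entropy_map_ref(u_x, bins)
    e_y = improved_entropy_map_ref(u_y, bins)
    ie = max(e_x, e_y) if abs(e_x - e_y) > tol else (e_x + e_y) / 2.0
    u_x = u_x + ie
    u_y = u_y + ie
    h, w = image.shape
    u_g = np.empty((h, w))
    for r in range(h):
        for c in range(w):
            u_g[r, c] = math.hypot(u_x[r, c], u_y[r, c])
    return u_x, u_y, u_g


def wap_ref(window, gamma: float) -> float:
    total = 0.0
    count = 0
    for v in np.asarray(window).ravel():
        total += float(v)
        count += 1
    return (1.0 - gamma) * total / count


def wap_bn_ref(values, gamma: float, eps: float) -> np.ndarray:
    values = [float(v) for v in np.asarray(values).ravel()]
    n = len(values)
    s_j = wap_ref(values, gamma)
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / n
    den = math.sqrt(var + 1.0 / (1.0 + math.exp(-s_j)) + eps)
    return np.array([(v * s_j - mean * s_j) / den for v in values])


def mixed_pool_ref(x: np.ndarray, lam: float) -> np.ndarray:
    n, c, h, w = x.shape
    out = np.empty((n, c, h // 2, w // 2))
    for ni in range(n):
        for ci in range(c):
            for i in range(h // 2):
                for j in range(w // 2):
                    block = x[ni, ci, 2 * i : 2 * i + 2, 2 * j : 2 * j + 2]
                    out[ni, ci, i, j] = lam * block.max() + (1 - lam) * block.mean()
    return out
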