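"""Independent brute-force reference implementations used as test oracles.

Each function here re-implements an operator by direct summation/looping,
deliberately sharing no code with the package, so agreement is evidence of
correctness rather than of shared bugs.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np


def nlm_bruteforce(img: np.ndarray, patch_radius: int, search_radius: int, h: float) -> np.ndarray:
    """Direct O(N * S^2 * P^2) non-local means with mirrored borders."""
    H, W = img.shape
    s, p = search_radius, patch_radius
    pad = s + p
    P = np.pad(img, pad, mode="reflect")
    out = np.empty_like(img, dtype=float)
    offsets = [(a, b) for a in range(-p, p + 1) for b in range(-p, p + 1)]
    n_patch = len(offsets)
    for i in range(H):
        for j in range(W):
            ci, cj = i + pad, j + pad
            num = 0.0
            den = 0.0
            for dy in range(-s, s + 1):
                for dx in range(-s, s + 1):
                    d2 = 0.0
                    for a, b in offsets:
                        diff = P[ci + a, cj + b] - P[ci + dy + a, cj + dx + b]
                        d2 += diff * diff
                    d2 /= n_patch
                    w = math.exp(-d2 / (h * h))
                    num += w * P[ci + dy, cj + dx]
                    den += w
            out[i, j] = num / den
    return out


def phansalkar_bruteforce(
    img: np.ndarray, window_radius: int, k: float, r: float, p: float, q: float
) -> np.ndarray:
    """Direct sliding-window Phansalkar mask with mirrored borders."""
    H, W = img.shape
    w = window_radius
    P = np.pad(img, w, mode="reflect")
    mask = np.zeros((H, W), dtype=bool)
    for i in range(H):
        for j in range(W):
            win = P[i : i + 2 * w + 1, j : j + 2 * w + 1]
            mu = win.mean()
            sigma = win.std()  # population SD
            t = mu * (1.0 + p * math.exp(-q * mu) + k * (sigma / r - 1.0))
            mask[i, j] = img[i, j] > t
    return mask


def box_count_bruteforce(pixels: np.ndarray, size: int) -> int:
    """Triple-loop count of occupied s x s boxes anchored at (0, 0)."""
    H, W = pixels.shape
    count = 0
    for by in range(0, H, size):
        for bx in range(0, W, size):
            hit = False
            for y in range(by, min(by + size, H)):
                for x in range(bx, min(bx + size, W)):
                    if pixels[y, x]:
                        hit = True
                        break
                if hit:
                    break
            if hit:
                count += 1
    return count


def flood_fill_bruteforce(background: np.ndarray, seed: tuple[int, int]) -> np.ndarray:
    """BFS 4-connected flood fill of True pixels from a seed."""
    H, W = background.shape
    out = np.zeros_like(background, dtype=bool)
    if not background[seed]:
        return out
    queue = deque([seed])
    out[seed] = True
    while queue:
        r, c = queue.popleft()
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < H and 0 <= cc < W and background[rr, cc] and not out[rr, cc]:
                out[rr, cc] = True
                queue.append((rr, cc))
    return out


def icc_a1_bruteforce(x: np.ndarray) -> float:
    """ICC(A,1) from explicitly accumulated ANOVA sums of squares."""
    n, k = x.shape
    grand = x.sum() / (n * k)
    row_means = [x[i, :].sum() / k for i in range(n)]
    col_means = [x[:, j].sum() / n for j in range(k)]
    ssr = k * sum((m - grand) ** 2 for m in row_means)
    ssc = n * sum((m - grand) ** 2 for m in col_means)
    sst = sum((x[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))
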