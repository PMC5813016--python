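"""Independent brute-force oracles used to validate the pipeline operators.

Everything here is deliberately written with different machinery than the
implementation under test (explicit shifts/loops instead of scipy filters,
direct per-threshold statistics instead of histogram cumsums).
"""

from __future__ import annotations

import numpy as np


def nms_peaks_bruteforce(img: np.ndarray, radius: int, threshold: float
                         ) -> set[tuple[int, int]]:
    """Exhaustive non-maximal suppression with plateau deduplication.

    A candidate is a pixel >= threshold that is >= every in-bounds pixel
    within Chebyshev distance ``radius``.  Touching (8-connected)
    equal-valued candidates form a plateau; only the lexicographically
    smallest survives.
    """
    img = np.asarray(img, dtype=float)
    h, w = img.shape
    candidates = []
    for r in range(h):
        for c in range(w):
            v = img[r, c]
            if v < threshold:
                continue
            is_max = True
            for dr in range(-radius, radius + 1):
                for dc in range(-radius, radius + 1):
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w and img[rr, cc] > v:
                        is_max = False
                        break
                if not is_max:
                    break
            if is_max:
                candidates.append((r, c))
    cand_set = set(candidates)
    peaks: set[tuple[int, int]] = set()
    visited: set[tuple[int, int]] = set()
    for start in sorted(cand_set):
        if start in visited:
            continue
        stack, comp = [start], []
        visited.add(start)
        while stack:
            (r, c) = stack.pop()
            comp.append((r, c))
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    nb = (r + dr, c + dc)
                    if nb in cand_set and nb not in visited \
                            and img[nb] == img[r, c]:
                        visited.add(nb)
                        stack.append(nb)
        peaks.add(min(comp))
    return peaks


def otsu_mask_bruteforce(img: np.ndarray) -> np.ndarray:
    """Foreground mask from exhaustive 256-threshold Otsu search."""
    img = np.asarray(img)
    flat = img.ravel().astype(float)
    best_t, best_bcv = None, -np.inf
    for t in range(256):
        lower = flat[flat <= t]
        upper = flat[flat > t]
        if lower.size == 0 or upper.size == 0:
            continue
        w0, w1 = lower.size, upper.size
        bcv = w0 * w1 * (lower.mean() - upper.mean()) ** 2
        if bcv > best_bcv:
            best_bcv, best_t = bcv, t
    if best_t is None:
        raise ValueError("degenerate image")
    return img > best_t


def tophat_bruteforce(img: np.ndarray, radius: int) -> np.ndarray:
    """White top-hat via explicit min-then-max over a Euclidean disk."""
    img = np.asarray(img, dtype=float)
    h, w = img.shape
    offsets = [(dr, dc)
               for dr in range(-radius, radius + 1)
               for dc in range(-radius, radius + 1)
               if dr * dr + dc * dc <= radius * radius]

    def erode(a):
        out = np.empty_like(a)
        for r in range(h):
            for c in range(w):
                vals = [a[r + dr, c + dc] for dr, dc in offsets
                        if 0 <= r + dr < h and 0 <= c + dc < w]
                out[r, c] = min(vals)
        return out

    def dilate(a):
        out = np.empty_like(a)
        for r in range(h):
            for c in range(w):
                vals = [a[r + dr, c + dc] for dr, dc in offsets
                        if 0 <= r + dr < h and 0 <= c + dc < w]
                out[r, c] = max(vals)
        return out

    return img - dilate(erode(img))


def gaussian_response_bruteforce(img: np.ndarray, halfwidth: int,
                                 sigma: float, r: int, c: int) -> float:
    """Direct kernel sum at one pixel (reflect boundary)."""
    img = np.asarray(img, dtype=float)
    h, w = img.shape
    num = 0.0
    den = 0.0
    for dr in range(-halfwidth, halfwidth + 1):
        for dc in range(-halfwidth, halfwidth + 1):
            wgt = np.exp(-(dr * dr + dc * dc) / (2.0 * sigma ** 2))
            rr, cc = r + dr, c + dc
            if rr < 0:
                rr = -rr - 1
            if rr >= h:
                rr = 2 * h - rr - 1
            if cc < 0:
                cc = -cc - 1
            if cc >= w:
                cc = 2 * w - cc - 1
            num += wgt * img[rr, cc]
            den += wgt
    return num / den


def local_maxima_bruteforce(img: np.ndarray, k: int) -> list[tuple[int, int]]:
    """The k brightest strict local maxima (3x3 neighborhood)."""
    img = np.asarray(img, dtype=float)
    h, w = img.shape
    maxima = []
    for r in range(1, h - 1):
        for c in range(1, w - 1):
            patch = img[r - 1:r + 2, c - 1:c + 2]
            if img[r, c] == patch.max() and (patch == img[r, c]).sum() == 1:
                maxima.append((img[r, c], r, c))
    maxima.sort(reverse=True)
    return [(r, c) for _v, r, c in maxima[:k]]


def max_abs_t_null(n_per_group: int, k_treatments: int, n_draws: int,
                   seed: int) -> np.ndarray:
    """Monte-Carlo null of Dunnett's max-|t| statistic, balanced design.

    Simulates k_treatments treatment groups plus a control, all standard
    normal, computes each treatment-vs-control t with the pooled
    within-group variance, and returns the max over comparisons.
    """
    rng = np.random.default_rng(seed)
    k = k_treatments + 1
    draws = rng.standard_normal((n_draws, k, n_per_group))
    means = draws.mean(axis=2)
    ss = ((draws - means[:, :, None]) ** 2).sum(axis=(1, 2))
    df = k * (n_per_group - 1)
    s2 = ss / df
    se = np.sqrt(s2 * (2.0 / n_per_group))
    t = (means[:, :-1] - means[:, -1:]) / se[:, None]
    return np.abs(t).max(axis=1)
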