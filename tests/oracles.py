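"""Independent straight-line oracles used by the test suite.

These are deliberately naive transliterations — scalar loops, no shared
code with the package internals — so that agreement with the vectorized
implementations is a meaningful check rather than a tautology.
"""

from __future__ import annotations

import math

import numpy as np


def clahe_naive(img: np.ndarray, clip: float = 2.0, tiles: tuple[int, int] = (8, 8)) -> np.ndarray:
    """Loop-based CLAHE: clipped tile histograms, uniform excess
    redistribution, bilinear blend of the four nearest tile mappings."""
    img = np.asarray(img, dtype=np.int64)
    h, w = img.shape
    ty, tx = tiles
    row_edges = [int(round(i * h / ty)) for i in range(ty + 1)]
    col_edges = [int(round(j * w / tx)) for j in range(tx + 1)]

    luts = [[None] * tx for _ in range(ty)]
    for i in range(ty):
        for j in range(tx):
            r0, r1 = row_edges[i], row_edges[i + 1]
            c0, c1 = col_edges[j], col_edges[j + 1]
            area = (r1 - r0) * (c1 - c0)
            hist = [0.0] * 256
            for y in range(r0, r1):
                for x in range(c0, c1):
                    hist[img[y, x]] += 1
            limit = max(clip * area / 256.0, 1.0)
            excess = sum(max(v - limit, 0.0) for v in hist)
            hist = [min(v, limit) + excess / 256.0 for v in hist]
            lut = []
            acc = 0.0
            for v in hist:
                acc += v
                lut.append(min(255.0, max(0.0, math.floor(acc * 255.0 / area + 0.5))))
            luts[i][j] = lut

    cy = [(row_edges[i] + row_edges[i + 1] - 1) / 2.0 for i in range(ty)]
    cx = [(col_edges[j] + col_edges[j + 1] - 1) / 2.0 for j in range(tx)]

    def locate(coord: float, centers: list[float]) -> tuple[int, int, float]:
        if coord <= centers[0]:
            return 0, 0, 0.0
        if coord >= centers[-1]:
            return len(centers) - 1, len(centers) - 1, 0.0
        for k in range(len(centers) - 1):
            if centers[k] <= coord <= centers[k + 1]:
                frac = (coord - centers[k]) / (centers[k + 1] - centers[k])
                return k, k + 1, frac
        raise AssertionError("unreachable")

    out = np.empty((h, w), dtype=np.uint8)
    for y in range(h):
        i0, i1, fy = locate(y, cy)
        for x in range(w):
            j0, j1, fx = locate(x, cx)
            v = img[y, x]
            val = (
                (1 - fy) * (1 - fx) * luts[i0][j0][v]
                + (1 - fy) * fx * luts[i0][j1][v]
                + fy * (1 - fx) * luts[i1][j0][v]
                + fy * fx * luts[i1][j1][v]
            )
            out[y, x] = min(255, max(0, int(math.floor(val + 0.5))))
    return out


def sobel_naive(norm: np.ndarray) -> np.ndarray:
    """Gradient magnitude via explicit 3x3 cross-correlation loops with
    replicate padding."""
    sx = [[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]]
    sy = [[-1, -2, -1], [0, 0, 0], [1, 2, 1]]
    h, w = norm.shape
    gd = np.empty((h, w))
    for y in range(h):
        for x in range(w):
            gx = gy = 0.0
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    yy = min(max(y + dy, 0), h - 1)
                    xx = min(max(x + dx, 0), w - 1)
                    gx += sx[dy + 1][dx + 1] * norm[yy, xx]
                    gy += sy[dy + 1][dx + 1] * norm[yy, xx]
            gd[y, x] = math.sqrt(gx * gx + gy * gy)
    return gd


def enhancement_pipeline_naive(
    pixels: np.ndarray,
    eps: float = 1e-8,
    alpha: float = 255.0,
    clip: float = 2.0,
    tiles: tuple[int, int] = (8, 8),
) -> dict:
    """Single-function transliteration of the whole enhancement pipeline.

    Returns the 8-bit post-CLAHE raster and the defuzzified float image so
    both can be compared against the package's staged implementation.
    """
    pixels = np.asarray(pixels, dtype=np.float64)
    imin, imax = pixels.min(), pixels.max()

    # Normalization
    inorm = (pixels - imin) / (imax - imin + eps)
    # Sobel gradient magnitude
    gd = sobel_naive(inorm)
    gdmin, gdmax = gd.min(), gd.max()
    # Neutrosophic components
    T = np.clip(inorm, 0.0, 1.0)
    I = np.clip(1.0 - (gd - gdmin) / (gdmax - gdmin + eps), 0.0, 1.0)
    F = 1.0 - T
    # Similarity to the ideal (1, 0, 0)
    S = T / np.maximum(np.sqrt(T**2 + I**2 + F**2), eps)
    # 8-bit quantization, CLAHE, renormalization
    s8 = np.clip(np.floor(alpha * S + 0.5), 0, 255).astype(np.uint8)
    eq = clahe_naive(s8, clip=clip, tiles=tiles)
    e_norm = eq.astype(np.float64) / 255.0
    # Defuzzification back to the original range
    out = e_norm * (imax - imin) + imin
    return {"eq8": eq, "e_norm": e_norm, "enhanced": out}
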