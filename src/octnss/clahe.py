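"""Contrast-limited adaptive histogram equalization for 8-bit rasters.

Standard CLAHE: the image is divided into a grid of tiles; each tile's
256-bin histogram is clipped at ``clip x (mean bin count)`` with the excess
redistributed uniformly over all bins in one pass; each clipped histogram
yields an equalization lookup table; every pixel is then remapped by
bilinear interpolation between the tables of the four nearest tile centers
(clamped at the borders).  Clipping the histograms bounds the slope of the
equalization mapping, which is what prevents CLAHE from amplifying noise in
near-homogeneous tiles the way plain adaptive equalization would.
"""

from __future__ import annotations

import numpy as np


def _tile_edges(n: int, tiles: int) -> np.ndarray:
    """Integer tile boundaries: `tiles + 1` edges covering [0, n]."""
    return np.round(np.linspace(0, n, tiles + 1)).astype(np.int64)


def _tile_lut(hist: np.ndarray, area: int, clip: float) -> np.ndarray:
    """Equalization LUT for one tile from its clipped 256-bin histogram."""
    # Clip level: `clip` times the mean bin count, floored at one count so
    # tiny tiles (mean bin count < 1) do not clip every occupied bin to zero.
    limit = max(clip * area / 256.0, 1.0)
    excess = np.maximum(hist - limit, 0.0).sum()
    clipped = np.minimum(hist, limit) + excess / 256.0
    cdf = np.cumsum(clipped)
    return np.clip(np.floor(cdf * (255.0 / area) + 0.5), 0, 255)


def apply_clahe(
    img8: np.ndarray, clip: float = 2.0, tiles: tuple[int, int] = (8, 8)
) -> np.ndarray:
    """Apply CLAHE to an 8-bit raster; returns a uint8 raster of equal shape.

    Parameters
    ----------
    img8
        2-D uint8 (or integer-valued in [0, 255]) raster.
    clip
        Clip limit as a multiple of the mean tile bin count.
    tiles
        ``(rows, cols)`` of the tile grid; each tile must contain at least
        one pixel.
    """
    img8 = np.asarray(img8)
    if img8.ndim != 2:
        raise ValueError(f"raster must be 2-D, got shape {img8.shape}")
    if img8.dtype != np.uint8:
        f = np.asarray(img8, dtype=np.float64)
        if np.any(f < 0) or np.any(f > 255) or np.any(f != np.floor(f)):
            raise ValueError("raster must hold integers in [0, 255]")
        img8 = f.astype(np.uint8)
    if clip <= 0:
        raise ValueError("clip limit must be positive")
    ty, tx = tiles
    if ty < 1 or tx < 1:
        raise ValueError("tile counts must be >= 1")
    h, w = img8.shape
    if h < ty or w < tx:
        raise ValueError(
            f"image {h}x{w} too small for a {ty}x{tx} tile grid (empty tiles)"
        )

    row_edges = _tile_edges(h, ty)
    col_edges = _tile_edges(w, tx)

    # Per-tile equalization LUTs and tile-center coordinates.
    luts = np.empty((ty, tx, 256), dtype=np.float64)
    for i in range(ty):
        for j in range(tx):
            tile = img8[row_edges[i] : row_edges[i + 1], col_edges[j] : col_edges[j + 1]]
            hist = np.bincount(tile.ravel(), minlength=256).astype(np.float64)
            luts[i, j] = _tile_lut(hist, tile.size, clip)
    cy = (row_edges[:-1] + row_edges[1:] - 1) / 2.0
    cx = (col_edges[:-1] + col_edges[1:] - 1) / 2.0

    # Bilinear interpolation between the four surrounding tile mappings;
    # pixels outside the outermost centers clamp to the border tiles.
    yi0, wy = _interp_coords(np.arange(h), cy)
    xj0, wx = _interp_coords(np.arange(w), cx)

    yi0 = yi0[:, None]
    yi1 = np.minimum(yi0 + 1, ty - 1)
    wy = wy[:, None]
    xj0 = xj0[None, :]
    xj1 = np.minimum(xj0 + 1, tx - 1)
    wx = wx[None, :]

    v = img8.astype(np.int64)
    out = (
        (1 - wy) * (1 - wx) * luts[yi0, xj0, v]
        + (1 - wy) * wx * luts[yi0, xj1, v]
        + wy * (1 - wx) * luts[yi1, xj0, v]
        + wy * wx * luts[yi1, xj1, v]
    )
    return np.clip(np.floor(out + 0.5), 0, 255).astype(np.uint8)


def _interp_coords(
    coords: np.ndarray, centers: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Lower tile index and fractional weight for each pixel coordinate."""
    n = len(centers)
    i0 = np.searchsorted(centers, coords, side="right") - 1
    i0 = np.clip(i0, 0, n - 1)
    i1 = np.minimum(i0 + 1, n - 1)
    span = centers[i1] - centers[i0]
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(span > 0, (coords - centers[i0]) / np.where(span > 0, span, 1), 0.0)
    return i0.astype(np.int64), np.clip(frac, 0.0, 1.0)
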