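"""Neutrosophic-domain transform and similarity-to-ideal scoring.

A grayscale image is mapped to three aligned membership rasters:

* ``T`` (truth) — the min-max normalized intensity,
* ``I`` (indeterminacy) — one minus the normalized Sobel gradient magnitude,
  so smooth, unambiguous regions are maximally indeterminate-free of edges,
* ``F`` (falsity) — the complement ``1 - T``.

Each pixel's triple is then scored against the ideal alternative
``A* = (T=1, I=0, F=0)`` with a cosine similarity; the resulting
neutrosophic similarity score (NSS) is high for bright, low-ambiguity
structure and low for dark or edge-dominated pixels.  All divisions are
guarded by a small ``epsilon`` so flat images and flat gradient fields are
handled without special cases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import correlate

from .io import GrayImage

# 3x3 Sobel kernels, applied as cross-correlation.  Sy = Sx.T, which is what
# makes the gradient magnitude invariant under transposition of the input.
SOBEL_X = np.array([[-1.0, 0.0, 1.0], [-2.0, 0.0, 2.0], [-1.0, 0.0, 1.0]])
SOBEL_Y = SOBEL_X.T.copy()


@dataclass
class NeutroParams:
    """Numerical guard for the normalization denominators."""

    epsilon: float = 1e-8

    def __post_init__(self) -> None:
        if not self.epsilon > 0:
            raise ValueError("epsilon must be positive")


@dataclass
class GradientMap:
    """Sobel gradient magnitudes with their per-image extrema."""

    Gd: np.ndarray
    gd_min: float = field(init=False)
    gd_max: float = field(init=False)

    def __post_init__(self) -> None:
        self.Gd = np.asarray(self.Gd, dtype=np.float64)
        if np.any(self.Gd < 0):
            raise ValueError("gradient magnitudes must be non-negative")
        self.gd_min = float(self.Gd.min())
        self.gd_max = float(self.Gd.max())


@dataclass
class NeutroMaps:
    """Aligned truth / indeterminacy / falsity rasters in [0, 1]."""

    T: np.ndarray
    I: np.ndarray
    F: np.ndarray

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=np.float64)
        self.I = np.asarray(self.I, dtype=np.float64)
        self.F = np.asarray(self.F, dtype=np.float64)
        if not (self.T.shape == self.I.shape == self.F.shape):
            raise ValueError("T, I, F must share one shape")
        for name, r in (("T", self.T), ("I", self.I), ("F", self.F)):
            if r.size and (r.min() < 0 or r.max() > 1):
                raise ValueError(f"{name} values must lie in [0, 1]")


@dataclass
class NSSMap:
    """Per-pixel similarity to the ideal alternative, in [0, 1]."""

    S: np.ndarray

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=np.float64)
        if self.S.size and (self.S.min() < 0 or self.S.max() > 1):
            raise ValueError("similarity scores must lie in [0, 1]")


def normalize_image(img: GrayImage, params: NeutroParams | None = None) -> np.ndarray:
    """Min-max normalize an image to [0, 1) using its own pixel extrema.

    ``IN = (I - Imin) / (Imax - Imin + epsilon)``.  A constant image maps to
    all zeros (zero numerator over the epsilon guard).  The per-pixel min/max
    are taken from the raster itself, not the GrayImage metadata, so the
    output minimum is exactly 0.
    """
    params = params or NeutroParams()
    pixels = img.pixels
    if not np.all(np.isfinite(pixels)):
        raise ValueError("image contains non-finite pixels")
    lo = pixels.min()
    hi = pixels.max()
    return (pixels - lo) / (hi - lo + params.epsilon)


def gradient_magnitude(norm: np.ndarray) -> GradientMap:
    """Sobel gradient magnitude ``sqrt(Gx^2 + Gy^2)`` of a raster.

    Kernels are applied as cross-correlation with replicate (edge-clamp)
    padding, which avoids the spurious border edges zero padding would
    create.
    """
    norm = np.asarray(norm, dtype=np.float64)
    if norm.ndim != 2 or norm.shape[0] < 3 or norm.shape[1] < 3:
        raise ValueError(f"raster must be at least 3x3, got shape {norm.shape}")
    # The kernels sum to zero, so the correlation is invariant to a constant
    # offset; removing the mean first makes flat rasters come out exactly 0
    # instead of leaving ~1e-17 floating-point residue.
    centered = norm - norm.mean()
    gx = correlate(centered, SOBEL_X, mode="nearest")
    gy = correlate(centered, SOBEL_Y, mode="nearest")
    return GradientMap(Gd=np.hypot(gx, gy))


def tif_maps(
    norm: np.ndarray,
    grad: GradientMap,
    params: NeutroParams | None = None,
) -> NeutroMaps:
    """Build the truth / indeterminacy / falsity rasters.

    ``T`` is the normalized intensity, ``I = 1 - (Gd - Gd_min) /
    (Gd_max - Gd_min + epsilon)``, ``F = 1 - T``.  On a flat gradient field
    (constant image) the epsilon guard makes the ratio zero, so ``I`` is 1
    everywhere: maximal indeterminacy is the natural flat-image limit.  All
    rasters are clamped to [0, 1] to absorb floating-point overshoot.
    """
    params = params or NeutroParams()
    norm = np.asarray(norm, dtype=np.float64)
    if norm.shape != grad.Gd.shape:
        raise ValueError(
            f"shape mismatch: intensity {norm.shape} vs gradient {grad.Gd.shape}"
        )
    T = np.clip(norm, 0.0, 1.0)
    ratio = (grad.Gd - grad.gd_min) / (grad.gd_max - grad.gd_min + params.epsilon)
    I = np.clip(1.0 - ratio, 0.0, 1.0)
    F = 1.0 - T
    return NeutroMaps(T=T, I=I, F=F)


def pairwise_similarity(
    a: tuple[float, float, float], b: tuple[float, float, float]
) -> float:
    """Cosine similarity between two neutrosophic triples.

    ``S(a, b) = (Ta Tb + Ia Ib + Fa Fb) / (||a|| ||b||)`` with Euclidean
    norms; symmetric in its arguments and equal to 1 for identical triples.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != (3,) or b.shape != (3,):
        raise ValueError("each argument must be a (T, I, F) triple")
    for name, t in (("a", a), ("b", b)):
        if t.min() < 0 or t.max() > 1:
            raise ValueError(f"components of {name} must lie in [0, 1]")
    na = float(np.linalg.norm(a))
    nb = float(np.linalg.norm(b))
    if na == 0.0 or nb == 0.0:
        raise ValueError("similarity is undefined for a zero-norm triple")
    return float(a @ b) / (na * nb)


def nss_map(maps: NeutroMaps, params: NeutroParams | None = None) -> NSSMap:
    """Score every pixel against the ideal alternative ``A* = (1, 0, 0)``.

    With the ideal fixed, the cosine similarity collapses to
    ``S = T / sqrt(T^2 + I^2 + F^2)``.  Because ``F = 1 - T`` the denominator
    is bounded below by ``sqrt(1/2)`` and can never vanish, but it is guarded
    with epsilon regardless (``max(denom, epsilon)`` leaves regular pixels
    bit-identical to the unguarded form).
    """
    params = params or NeutroParams()
    denom = np.sqrt(maps.T**2 + maps.I**2 + maps.F**2)
    denom = np.maximum(denom, params.epsilon)
    return NSSMap(S=np.clip(maps.T / denom, 0.0, 1.0))
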