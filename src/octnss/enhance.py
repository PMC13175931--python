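"""End-to-end NSS enhancement of a grayscale OCT image.

The pipeline: per-image min-max normalization, Sobel gradient magnitude,
truth/indeterminacy/falsity maps, similarity-to-ideal scoring, 8-bit
quantization, CLAHE (clip 2.0, 8x8 tiles by default), renormalization to
[0, 1], and defuzzification back onto the source image's recorded intensity
range.  Every stage is deterministic, so the whole transform is a pure
function of the input pixels and the parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .clahe import apply_clahe
from .io import GrayImage
from .neutrosophic import (
    NeutroParams,
    gradient_magnitude,
    normalize_image,
    nss_map,
    tif_maps,
)

__all__ = [
    "EnhanceParams",
    "EnhanceResult",
    "quantize_8bit",
    "apply_clahe",
    "defuzzify",
    "enhance_image",
]


@dataclass
class EnhanceParams:
    """Constants of the enhancement pipeline.

    ``epsilon`` guards the min-max denominators, ``alpha`` is the 8-bit
    scale applied to the similarity map before CLAHE, ``clahe_clip`` and
    ``clahe_tiles`` parameterize the contrast-limited equalization.
    """

    epsilon: float = 1e-8
    alpha: float = 255.0
    clahe_clip: float = 2.0
    clahe_tiles: tuple[int, int] = (8, 8)

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.clahe_clip <= 0:
            raise ValueError("clahe_clip must be positive")
        if self.clahe_tiles[0] < 1 or self.clahe_tiles[1] < 1:
            raise ValueError("tile counts must be >= 1")

    def neutro(self) -> NeutroParams:
        return NeutroParams(epsilon=self.epsilon)


@dataclass
class EnhanceResult:
    """Enhanced image plus provenance.

    ``enhanced`` shares the source image's shape and recorded range;
    ``e_norm`` is the post-CLAHE raster rescaled to [0, 1] (the
    representation downstream training consumes); ``intermediates``
    optionally retains the T/I/F/S rasters for inspection.
    """

    enhanced: GrayImage
    e_norm: np.ndarray
    params_used: EnhanceParams
    intermediates: dict[str, np.ndarray] | None = field(default=None)


def quantize_8bit(map01: np.ndarray, alpha: float = 255.0) -> np.ndarray:
    """Scale a [0, 1] raster by ``alpha`` and round to 8-bit integers.

    Rounding is half away from zero, and the result is clamped to [0, 255].
    """
    map01 = np.asarray(map01, dtype=np.float64)
    if map01.size and (map01.min() < 0 or map01.max() > 1):
        raise ValueError("input raster must lie in [0, 1]")
    return np.clip(np.floor(alpha * map01 + 0.5), 0, 255).astype(np.uint8)


def defuzzify(e_norm: np.ndarray, orig_min: float, orig_max: float) -> np.ndarray:
    """Map a [0, 1] raster back onto the source intensity range.

    ``out = e_norm * (orig_max - orig_min) + orig_min``; a degenerate range
    (``orig_min == orig_max``) yields that constant everywhere.
    """
    e_norm = np.asarray(e_norm, dtype=np.float64)
    if orig_min > orig_max:
        raise ValueError("orig_min must not exceed orig_max")
    if e_norm.size and (e_norm.min() < 0 or e_norm.max() > 1):
        raise ValueError("e_norm must lie in [0, 1]")
    return e_norm * (orig_max - orig_min) + orig_min


def enhance_image(
    img: GrayImage,
    params: EnhanceParams | None = None,
    keep_intermediates: bool = False,
) -> EnhanceResult:
    """Run the full NSS + CLAHE enhancement on one image."""
    params = params or EnhanceParams()
    nparams = params.neutro()

    norm = normalize_image(img, nparams)
    grad = gradient_magnitude(norm)
    maps = tif_maps(norm, grad, nparams)
    score = nss_map(maps, nparams)

    s8 = quantize_8bit(score.S, params.alpha)
    eq = apply_clahe(s8, clip=params.clahe_clip, tiles=params.clahe_tiles)
    e_norm = eq.astype(np.float64) / 255.0
    out = defuzzify(e_norm, img.orig_min, img.orig_max)

    enhanced = GrayImage(
        pixels=out,
        orig_min=img.orig_min,
        orig_max=img.orig_max,
        bit_depth=img.bit_depth,
        source_path=img.source_path,
    )
    intermediates = None
    if keep_intermediates:
        intermediates = {"T": maps.T, "I": maps.I, "F": maps.F, "S": score.S}
    return EnhanceResult(
        enhanced=enhanced, e_norm=e_norm, params_used=params, intermediates=intermediates
    )
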