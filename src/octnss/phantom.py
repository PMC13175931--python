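"""Synthetic OCT retina phantoms.

A phantom is a stack of smoothly undulating horizontal bands (the retinal
layers) over a dark background, perturbed by one of eight parametric lesion
archetypes, then multiplied by mean-1 gamma speckle — the standard
first-order surrogate for the multiplicative noise of coherent imaging.
The archetypes are deliberately cartoonish stand-ins for the retinal disease
classes of public OCT collections (AMD, CNV, CSR, DME, DR, DRUSEN, MH,
NORMAL); the point is learnable, class-discriminative structure for testing
the enhancement and training pipeline, not clinical realism.

Generation is fully determined by the spec seed.  The base geometry and the
speckle field are drawn from one stream and the lesion parameters from a
second, so two phantoms that share a seed but differ in archetype are
identical outside the lesion mask.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .io import DatasetIndex, GrayImage, index_dataset, write_gray

BACKGROUND = 0.08

#: Default per-band reflectivities, top to bottom: inner retina alternates
#: moderately bright and dark bands, the RPE band (index 5) is brightest.
DEFAULT_LAYER_INTENSITIES = (0.60, 0.35, 0.55, 0.30, 0.45, 0.90, 0.50)

#: Relative band thicknesses (same order as the intensities).
_LAYER_WEIGHTS = np.array([2.0, 1.5, 1.5, 2.0, 1.5, 1.0, 2.0])


class LesionArchetype(str, Enum):
    """Class-discriminative geometric perturbations, one per disease class."""

    AMD_elevation = "AMD"
    CNV_subretinal_mass = "CNV"
    CSR_fluid_dome = "CSR"
    DME_cystoid_pockets = "DME"
    DR_hyperreflective_dots = "DR"
    DRUSEN_bumps = "DRUSEN"
    MH_foveal_gap = "MH"
    NORMAL = "NORMAL"

    @property
    def class_name(self) -> str:
        return self.value


CLASS_NAMES = sorted(a.class_name for a in LesionArchetype)


@dataclass
class PhantomSpec:
    """Parameters of one phantom image."""

    height: int = 224
    width: int = 224
    n_layers: int = 7
    layer_intensities: tuple[float, ...] = DEFAULT_LAYER_INTENSITIES
    lesion_archetype: LesionArchetype | str = LesionArchetype.NORMAL
    speckle_shape: float = 4.0
    contrast_preset: str = "normal"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 32 or self.width < 32:
            raise ValueError("phantoms must be at least 32x32")
        if len(self.layer_intensities) != self.n_layers:
            raise ValueError("layer_intensities length must equal n_layers")
        if any(v < 0 or v > 1 for v in self.layer_intensities):
            raise ValueError("layer intensities must lie in [0, 1]")
        if self.speckle_shape <= 0:
            raise ValueError("speckle shape must be positive")
        if self.contrast_preset not in ("normal", "low"):
            raise ValueError(f"unknown contrast preset {self.contrast_preset!r}")
        if isinstance(self.lesion_archetype, str):
            try:
                self.lesion_archetype = LesionArchetype[self.lesion_archetype]
            except KeyError:
                try:
                    self.lesion_archetype = LesionArchetype(self.lesion_archetype)
                except ValueError:
                    raise ValueError(
                        f"unknown lesion archetype {self.lesion_archetype!r}"
                    ) from None


@dataclass
class PhantomDatasetSpec:
    """A class-folder phantom dataset: 8 classes x per-split counts.

    The default 23/4/4 per class is a 1:100 scale model of the public
    retinal OCT collection's 2300/350/350 split.
    """

    root: Path | str = "phantom_data"
    n_per_class_train: int = 23
    n_per_class_val: int = 4
    n_per_class_test: int = 4
    height: int = 224
    width: int = 224
    contrast_preset: str = "normal"
    seed: int = 0

    def __post_init__(self) -> None:
        self.root = Path(self.root)
        for n in (self.n_per_class_train, self.n_per_class_val, self.n_per_class_test):
            if n < 1:
                raise ValueError("per-class counts must be >= 1")


def _ellipse_mask(
    h: int, w: int, cy: float, cx: float, ry: float, rx: float
) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def _render_base(spec: PhantomSpec, rng: np.random.Generator):
    """Clean (pre-lesion, pre-speckle) layer stack plus its geometry."""
    h, w = spec.height, spec.width
    x = np.arange(w)

    # Undulating top surface of the retina.
    amp = rng.uniform(0.02, 0.05) * h
    freq = rng.uniform(0.5, 1.5)
    phase = rng.uniform(0, 2 * np.pi)
    top = 0.26 * h + amp * np.sin(2 * np.pi * freq * x / w + phase)

    thickness = 0.46 * h * rng.uniform(0.9, 1.1)
    jitter = rng.uniform(0.85, 1.15, size=spec.n_layers)
    weights = _LAYER_WEIGHTS[: spec.n_layers] * jitter
    cum = np.concatenate([[0.0], np.cumsum(weights)]) / weights.sum() * thickness

    yy = np.arange(h)[:, None]
    depth = yy - top[None, :]
    layer_idx = np.searchsorted(cum, depth, side="right") - 1
    inside = (depth >= 0) & (layer_idx < spec.n_layers)
    intensities = np.asarray(spec.layer_intensities)
    img = np.full((h, w), BACKGROUND)
    img[inside] = intensities[np.clip(layer_idx, 0, spec.n_layers - 1)[inside]]
    img = gaussian_filter(img, sigma=1.0)

    geometry = {"top": top, "cum": cum, "thickness": thickness}
    return img, geometry


def _apply_lesion(
    img: np.ndarray,
    geometry: dict,
    archetype: LesionArchetype,
    rng: np.random.Generator,
) -> np.ndarray:
    """Paint the archetype's perturbation in place; returns its boolean mask."""
    h, w = img.shape
    top = geometry["top"]
    cum = geometry["cum"]
    thickness = geometry["thickness"]
    cx = rng.uniform(0.35, 0.65) * w
    cxi = int(cx)
    mask = np.zeros((h, w), dtype=bool)

    if archetype is LesionArchetype.NORMAL:
        return mask

    if archetype is LesionArchetype.MH_foveal_gap:
        # Full-thickness wedge-shaped gap at the fovea.
        half_width = rng.uniform(0.05, 0.09) * w
        yy, xx = np.mgrid[0:h, 0:w]
        depth = yy - top[None, :]
        taper = 1.0 - 0.5 * np.clip(depth / thickness, 0, 1)
        mask = (np.abs(xx - cx) <= half_width * taper) & (depth >= 0) & (
            depth <= thickness
        )
        img[mask] = BACKGROUND
    elif archetype is LesionArchetype.CSR_fluid_dome:
        # Hyporeflective fluid dome splitting the outer retina.
        cy = top[cxi] + cum[4]
        mask = _ellipse_mask(
            h, w, cy, cx, rng.uniform(0.06, 0.1) * h, rng.uniform(0.15, 0.25) * w
        )
        img[mask] = 0.12
    elif archetype is LesionArchetype.AMD_elevation:
        # Broad dome-shaped elevation brightening the RPE region.
        cy = top[cxi] + cum[5]
        mask = _ellipse_mask(
            h, w, cy, cx, rng.uniform(0.05, 0.08) * h, rng.uniform(0.18, 0.28) * w
        )
        img[mask] = np.clip(img[mask] + 0.35, 0, 1)
    elif archetype is LesionArchetype.CNV_subretinal_mass:
        # Compact bright mass beneath the RPE.
        cy = top[cxi] + cum[5] + 0.04 * h
        mask = _ellipse_mask(
            h, w, cy, cx, rng.uniform(0.05, 0.09) * h, rng.uniform(0.08, 0.14) * w
        )
        img[mask] = 0.85
    elif archetype is LesionArchetype.DME_cystoid_pockets:
        # Several hyporeflective cysts in the inner retina.
        n = rng.integers(3, 6)
        for _ in range(n):
            px = rng.uniform(0.2, 0.8) * w
            py = top[int(px)] + rng.uniform(0.2, 0.6) * thickness
            m = _ellipse_mask(
                h, w, py, px, rng.uniform(0.02, 0.04) * h, rng.uniform(0.03, 0.06) * w
            )
            img[m] = 0.10
            mask |= m
    elif archetype is LesionArchetype.DR_hyperreflective_dots:
        # Scattered small bright dots through the retina.
        n = rng.integers(12, 20)
        for _ in range(n):
            px = rng.uniform(0.1, 0.9) * w
            py = top[int(px)] + rng.uniform(0.1, 0.9) * thickness
            m = _ellipse_mask(h, w, py, px, rng.uniform(1.5, 3.0), rng.uniform(1.5, 3.0))
            img[m] = 0.95
            mask |= m
    elif archetype is LesionArchetype.DRUSEN_bumps:
        # Row of small bumps sitting on the RPE band.
        n = rng.integers(4, 7)
        for _ in range(n):
            px = rng.uniform(0.15, 0.85) * w
            py = top[int(px)] + cum[5]
            m = _ellipse_mask(
                h, w, py, px, rng.uniform(0.02, 0.035) * h, rng.uniform(0.02, 0.04) * w
            )
            img[m] = 0.80
            mask |= m
    else:  # pragma: no cover - enum is exhaustive
        raise ValueError(f"unknown archetype {archetype!r}")
    return mask


def generate_phantom(
    spec: PhantomSpec, return_mask: bool = False
) -> GrayImage | tuple[GrayImage, np.ndarray]:
    """Render one phantom; optionally also return the lesion mask.

    The base geometry and speckle derive from one seeded stream and the
    lesion from another, so phantoms sharing a seed differ only inside the
    lesion mask across archetypes.
    """
    rng_base = np.random.default_rng([spec.seed, 0x0C7])
    rng_lesion = np.random.default_rng([spec.seed, 0x1E5])

    img, geometry = _render_base(spec, rng_base)
    speckle = rng_base.gamma(spec.speckle_shape, 1.0 / spec.speckle_shape, img.shape)
    mask = _apply_lesion(img, geometry, spec.lesion_archetype, rng_lesion)

    img = np.clip(img * speckle, 0.0, 1.0)
    if spec.contrast_preset == "low":
        # Compress intensities into the middle half of the 8-bit range.
        img = 0.25 + 0.5 * img
    pixels = np.clip(img * 255.0, 0.0, 255.0)

    gray = GrayImage(
        pixels=pixels,
        orig_min=float(pixels.min()),
        orig_max=float(pixels.max()),
        bit_depth=8,
    )
    return (gray, mask) if return_mask else gray


def derive_seed(seed: int, split: str, class_name: str, k: int) -> int:
    """Stable per-image seed from (seed, split, class, index)."""
    key = f"{seed}|{split}|{class_name}|{k}".encode()
    return int.from_bytes(hashlib.blake2s(key, digest_size=4).digest(), "big")


def generate_dataset(spec: PhantomDatasetSpec) -> dict[str, DatasetIndex]:
    """Write a full class-folder phantom tree and index every split."""
    counts = {
        "train": spec.n_per_class_train,
        "val": spec.n_per_class_val,
        "test": spec.n_per_class_test,
    }
    root = Path(spec.root)
    try:
        root.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise IOError(f"cannot create dataset root {root}: {exc}") from exc

    archetypes = sorted(LesionArchetype, key=lambda a: a.class_name)
    for split, n in counts.items():
        for archetype in archetypes:
            class_dir = root / split / archetype.class_name
            class_dir.mkdir(parents=True, exist_ok=True)
            for k in range(n):
                img_seed = derive_seed(spec.seed, split, archetype.class_name, k)
                phantom = generate_phantom(
                    PhantomSpec(
                        height=spec.height,
                        width=spec.width,
                        lesion_archetype=archetype,
                        contrast_preset=spec.contrast_preset,
                        seed=img_seed,
                    )
                )
                write_gray(phantom, class_dir / f"phantom_{k:04d}.png")
    return {split: index_dataset(root, split) for split in counts}
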