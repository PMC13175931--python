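"""Image and dataset I/O.

Everything downstream operates on :class:`GrayImage`, a 2-D float raster
carrying the original intensity range (``orig_min``/``orig_max``) recorded at
read time.  Those bounds are what the enhancement pipeline's final
defuzzification step maps back onto, so they are captured once here and never
recomputed.

Datasets follow the class-folder convention used by public retinal OCT
collections: ``<root>/<split>/<CLASS_NAME>/<image files>`` with
``split`` one of ``train``/``val``/``test``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

logger = logging.getLogger(__name__)

#: Extensions enumerated by :func:`index_dataset` (lower-cased before matching).
IMAGE_EXTENSIONS = {".png", ".tif", ".tiff", ".jpg", ".jpeg"}

# ITU-R BT.601 luma weights used for RGB -> gray conversion.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class GrayImage:
    """A 2-D grayscale intensity raster with its recorded original range.

    Parameters
    ----------
    pixels
        Float array of shape ``(H, W)`` with ``H, W >= 3`` (the Sobel stage
        needs a full 3x3 neighbourhood).
    orig_min, orig_max
        The intensity range recorded when the image was read; defuzzification
        maps enhanced values back into ``[orig_min, orig_max]``.
    bit_depth
        Bit depth of the source encoding (8 or 16).
    source_path
        Where the raster came from, if it came from disk.
    """

    pixels: np.ndarray
    orig_min: float
    orig_max: float
    bit_depth: int = 8
    source_path: str | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got shape {self.pixels.shape}")
        h, w = self.pixels.shape
        if h < 3 or w < 3:
            raise ValueError(f"image must be at least 3x3, got {h}x{w}")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if self.orig_min > self.orig_max:
            raise ValueError("orig_min must not exceed orig_max")
        if np.all(np.isfinite(self.pixels)):
            lo, hi = float(self.pixels.min()), float(self.pixels.max())
            if self.orig_min > lo or self.orig_max < hi:
                raise ValueError(
                    f"recorded range [{self.orig_min}, {self.orig_max}] does not "
                    f"cover pixel range [{lo}, {hi}]"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @classmethod
    def from_array(cls, pixels: np.ndarray, **kwargs) -> "GrayImage":
        """Wrap an array, recording its own min/max as the original range."""
        pixels = np.asarray(pixels, dtype=np.float64)
        return cls(
            pixels=pixels,
            orig_min=float(pixels.min()),
            orig_max=float(pixels.max()),
            **kwargs,
        )


@dataclass
class DatasetIndex:
    """Deterministic enumeration of one split of a class-folder dataset."""

    root: Path
    split: str
    entries: list[tuple[Path, str]] = field(default_factory=list)
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if list(self.class_names) != sorted(self.class_names):
            raise ValueError("class_names must be sorted lexicographically")
        known = set(self.class_names)
        for path, label in self.entries:
            if label not in known:
                raise ValueError(f"entry {path} has unknown class label {label!r}")

    def __len__(self) -> int:
        return len(self.entries)

    def counts(self) -> dict[str, int]:
        out = {name: 0 for name in self.class_names}
        for _, label in self.entries:
            out[label] += 1
        return out

    def label_index(self, label: str) -> int:
        return self.class_names.index(label)


def read_gray(path: str | Path) -> GrayImage:
    """Read a PNG/TIFF/JPEG image as a grayscale float raster.

    RGB inputs are converted with BT.601 luma (0.299 R + 0.587 G + 0.114 B),
    rounded half away from zero.  16-bit sources keep their native scale; the
    enhancement pipeline's per-image normalization handles the range.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"image file does not exist: {path}")
    try:
        with Image.open(path) as im:
            im.load()
            mode = im.mode
            arr = np.asarray(im)
    except Exception as exc:  # pragma: no cover - exercised via corrupt-file test
        raise IOError(f"cannot read image file {path}: {exc}") from exc

    if arr.ndim == 3:
        # RGB or RGBA: drop alpha, apply luma.
        rgb = arr[..., :3].astype(np.float64)
        gray = _round_half_away(rgb @ _LUMA)
    elif arr.ndim == 2:
        gray = arr.astype(np.float64)
    else:
        raise ValueError(f"unsupported image layout {arr.shape} in {path}")

    if gray.size == 0 or gray.shape[0] < 3 or gray.shape[1] < 3:
        raise ValueError(f"image {path} is smaller than 3x3: shape {gray.shape}")

    bit_depth = 16 if mode in ("I", "I;16", "I;16B", "I;16L") else 8
    return GrayImage(
        pixels=gray,
        orig_min=float(gray.min()),
        orig_max=float(gray.max()),
        bit_depth=bit_depth,
        source_path=str(path),
    )


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round half away from zero (np.round rounds half to even)."""
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def write_gray(img: GrayImage, path: str | Path) -> None:
    """Write a raster as an 8-bit grayscale image.

    Values are clamped to [0, 255] and rounded half away from zero, so a
    read-back of a written 8-bit image reproduces the rounded values exactly.
    """
    if not np.all(np.isfinite(img.pixels)):
        raise ValueError("cannot write non-finite pixel values")
    path = Path(path)
    data = np.clip(_round_half_away(img.pixels), 0, 255).astype(np.uint8)
    try:
        Image.fromarray(data, mode="L").save(path)
    except OSError as exc:
        raise IOError(f"cannot write image to {path}: {exc}") from exc


def index_dataset(root: str | Path, split: str) -> DatasetIndex:
    """Enumerate one split of a class-folder tree.

    Entries are sorted by full path so identical trees always index
    identically, regardless of filesystem enumeration order.  Files with
    unrecognized extensions are skipped with a logged warning.
    """
    root = Path(root)
    split_dir = root / split
    if not split_dir.is_dir():
        raise ValueError(f"split directory does not exist: {split_dir}")

    class_dirs = sorted(p for p in split_dir.iterdir() if p.is_dir())
    if not class_dirs:
        raise ValueError(f"split directory has no class subdirectories: {split_dir}")

    class_names = [p.name for p in class_dirs]
    entries: list[tuple[Path, str]] = []
    for class_dir in class_dirs:
        for f in sorted(class_dir.rglob("*")):
            if not f.is_file():
                continue
            if f.suffix.lower() not in IMAGE_EXTENSIONS:
                logger.warning("skipping non-image file %s", f)
                continue
            entries.append((f, class_dir.name))
    entries.sort(key=lambda e: str(e[0]))
    return DatasetIndex(root=root, split=split, entries=entries, class_names=class_names)
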