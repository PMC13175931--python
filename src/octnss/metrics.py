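"""Image-quality and classification metrics.

Image quality is summarized the way enhancement studies report it: PSNR and
SSIM between original and enhanced image, Shannon entropy of both 8-bit
renderings, and the relative entropy improvement in percent.  Classification
performance is summarized with a confusion matrix, weighted
precision/recall/F1, and per-class one-vs-rest ROC AUC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from sklearn.metrics import (
    confusion_matrix,
    precision_recall_fscore_support,
    roc_auc_score,
)

from .io import GrayImage


@dataclass
class QualityReport:
    """One row of an enhancement-quality table."""

    psnr_db: float
    ssim: float
    entropy_orig: float
    entropy_enh: float
    entropy_improvement_pct: float


@dataclass
class ClassificationReport:
    """Multi-class evaluation bundle."""

    accuracy: float
    precision_w: float
    recall_w: float
    f1_w: float
    per_class: pd.DataFrame  # columns: class, precision, recall, f1, support
    confusion: np.ndarray  # rows = true class
    auc_ovr: list[float]
    class_names: list[str]


def psnr(ref: np.ndarray, test: np.ndarray, data_range: float = 255.0) -> float:
    """Peak signal-to-noise ratio in dB; identical inputs give +inf."""
    ref = np.asarray(ref, dtype=np.float64)
    test = np.asarray(test, dtype=np.float64)
    if ref.shape != test.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {test.shape}")
    mse = float(np.mean((ref - test) ** 2))
    if mse == 0.0:
        return float("inf")
    return 10.0 * np.log10(data_range**2 / mse)


def ssim(ref: np.ndarray, test: np.ndarray, data_range: float = 255.0) -> float:
    """Mean local structural similarity, Wang et al. parameterization.

    Gaussian window (sigma 1.5, 11x11 support), K1=0.01, K2=0.03,
    population covariance, and a filter-radius border crop before averaging.
    For two constant images the covariance term cancels and the value reduces
    to the luminance comparison ``(2 c1 c2 + C1) / (c1^2 + c2^2 + C1)``.
    """
    ref = np.asarray(ref, dtype=np.float64)
    test = np.asarray(test, dtype=np.float64)
    if ref.shape != test.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {test.shape}")
    sigma, truncate = 1.5, 3.5
    radius = int(truncate * sigma + 0.5)  # 5 -> 11x11 window
    win = 2 * radius + 1
    if min(ref.shape) < win:
        raise ValueError(f"images must be at least {win}x{win} for SSIM")

    def blur(x: np.ndarray) -> np.ndarray:
        return gaussian_filter(x, sigma=sigma, truncate=truncate, mode="reflect")

    ux, uy = blur(ref), blur(test)
    vx = blur(ref * ref) - ux * ux
    vy = blur(test * test) - uy * uy
    vxy = blur(ref * test) - ux * uy

    c1 = (0.01 * data_range) ** 2
    c2 = (0.03 * data_range) ** 2
    s = ((2 * ux * uy + c1) * (2 * vxy + c2)) / (
        (ux**2 + uy**2 + c1) * (vx + vy + c2)
    )
    return float(s[radius:-radius, radius:-radius].mean(dtype=np.float64))


def shannon_entropy(img8: np.ndarray) -> float:
    """Shannon entropy in bits of an 8-bit raster's 256-bin histogram."""
    img8 = np.asarray(img8)
    if img8.size == 0:
        raise ValueError("cannot compute entropy of an empty raster")
    f = np.asarray(img8, dtype=np.float64)
    if np.any(f < 0) or np.any(f > 255) or np.any(f != np.floor(f)):
        raise ValueError("raster must hold integers in [0, 255]")
    counts = np.bincount(f.astype(np.int64).ravel(), minlength=256)
    p = counts[counts > 0] / f.size
    return float(-(p * np.log2(p)).sum())


def entropy_improvement(h_orig: float, h_enh: float) -> float:
    """Relative entropy change in percent: ``100 (h_enh - h_orig) / h_orig``."""
    if not h_orig > 0:
        raise ValueError("original entropy must be positive")
    return 100.0 * (h_enh - h_orig) / h_orig


def format_improvement_pct(value: float) -> str:
    """Render an improvement percentage to one decimal with a leading sign."""
    return f"{value:+.1f}%"


def _to_uint8(img: GrayImage | np.ndarray) -> np.ndarray:
    """8-bit rendering of an image: clamp to [0, 255] and round."""
    pixels = img.pixels if isinstance(img, GrayImage) else np.asarray(img)
    return np.clip(np.floor(np.asarray(pixels, dtype=np.float64) + 0.5), 0, 255).astype(
        np.uint8
    )


def quality_report(
    orig: GrayImage | np.ndarray, enh: GrayImage | np.ndarray
) -> QualityReport:
    """PSNR/SSIM/entropy comparison of an original and its enhanced image.

    Both images are rendered to 8 bits first so the entropies live on the
    [0, 8]-bit scale of 256-bin histograms.
    """
    o8 = _to_uint8(orig)
    e8 = _to_uint8(enh)
    h_o = shannon_entropy(o8)
    h_e = shannon_entropy(e8)
    return QualityReport(
        psnr_db=psnr(o8, e8),
        ssim=ssim(o8, e8),
        entropy_orig=h_o,
        entropy_enh=h_e,
        entropy_improvement_pct=entropy_improvement(h_o, h_e) if h_o > 0 else 0.0,
    )


def classification_report(
    y_true,
    y_pred,
    scores: np.ndarray,
    class_names: list[str] | None = None,
) -> ClassificationReport:
    """Confusion matrix, weighted P/R/F1, and one-vs-rest AUC per class.

    ``scores`` is an ``(n_samples, n_classes)`` table of class probabilities
    whose rows must sum to 1 (within 1e-6); AUC is computed per class on the
    one-vs-rest binarization via the trapezoidal rule over the ROC curve.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    scores = np.asarray(scores, dtype=np.float64)
    if len(y_true) != len(y_pred) or len(y_true) != len(scores):
        raise ValueError("y_true, y_pred and scores must have equal lengths")
    if class_names is None:
        class_names = sorted(set(np.concatenate([y_true, y_pred]).tolist()))
    class_names = list(class_names)
    known = set(class_names)
    for label in np.concatenate([y_true, y_pred]):
        if label not in known:
            raise ValueError(f"label {label!r} outside the class set {class_names}")
    if scores.shape[1] != len(class_names):
        raise ValueError("scores must have one column per class")
    row_sums = scores.sum(axis=1)
    if np.any(np.abs(row_sums - 1.0) > 1e-6):
        raise ValueError("score rows must sum to 1 within 1e-6")

    conf = confusion_matrix(y_true, y_pred, labels=class_names)
    accuracy = float(np.trace(conf)) / float(conf.sum())
    p_w, r_w, f_w, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=class_names, average="weighted", zero_division=0
    )
    p_c, r_c, f_c, supp = precision_recall_fscore_support(
        y_true, y_pred, labels=class_names, average=None, zero_division=0
    )
    per_class = pd.DataFrame(
        {
            "class": class_names,
            "precision": p_c,
            "recall": r_c,
            "f1": f_c,
            "support": supp,
        }
    )

    auc_ovr: list[float] = []
    for k, name in enumerate(class_names):
        binary = (y_true == name).astype(int)
        if binary.min() == binary.max():
            auc_ovr.append(float("nan"))  # class absent or exhaustive: AUC undefined
        else:
            auc_ovr.append(float(roc_auc_score(binary, scores[:, k])))

    return ClassificationReport(
        accuracy=accuracy,
        precision_w=float(p_w),
        recall_w=float(r_w),
        f1_w=float(f_w),
        per_class=per_class,
        confusion=conf,
        auc_ovr=auc_ovr,
        class_names=class_names,
    )
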