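"""Image-quality scoring for reconstructed ventilation images.

Pixels of a reconstruction H are classified as 'decrease in conductivity'
when they fall below the threshold t = alpha * min(H) (alpha = 0.65 in the
reference protocol), and compared with the ground-truth ventilated mask over
a region of interest (default: the thorax interior).  The four fractions

    G1  correctly depicts decrease in conductivity
    G2  wrongly depicts decrease in conductivity
    G3  wrongly depicts no change in conductivity
    G4  correctly depicts no change in conductivity

always sum to one.  An l1 image error (sum of absolute pixel differences of
peak-normalized images) scores reconstructions against the ground truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .dctbasis import PixelElementMap
from .mesh import Mesh

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClassificationResult:
    g1: float
    g2: float
    g3: float
    g4: float
    alpha: float
    threshold: float

    @property
    def correct(self) -> float:
        return self.g1 + self.g4


def classify_pixels(H: np.ndarray, alpha: float = 0.65) -> np.ndarray:
    """Binary 'conductivity decrease' map: 1 where H < alpha * min(H)."""
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    H = np.asarray(H, float)
    lo = H.min()
    if lo >= 0:
        if np.all(H == 0):
            logger.warning("all-zero image; nothing classified as decrease")
        return np.zeros_like(H, dtype=np.uint8)
    return (H < alpha * lo).astype(np.uint8)


def confusion_fractions(predicted: np.ndarray, truth: np.ndarray,
                        roi: np.ndarray, alpha: float = 0.65,
                        threshold: float = float("nan")
                        ) -> ClassificationResult:
    """G1-G4 fractions of predicted vs true decrease maps over the roi."""
    if predicted.shape != truth.shape or predicted.shape != roi.shape:
        raise ValueError("predicted, truth and roi shapes must match")
    sel = np.asarray(roi, bool)
    n = int(sel.sum())
    if n == 0:
        raise ValueError("empty region of interest")
    p = np.asarray(predicted, bool)[sel]
    t = np.asarray(truth, bool)[sel]
    return ClassificationResult(
        g1=float(np.sum(p & t)) / n,
        g2=float(np.sum(p & ~t)) / n,
        g3=float(np.sum(~p & t)) / n,
        g4=float(np.sum(~p & ~t)) / n,
        alpha=alpha,
        threshold=threshold,
    )


def rasterize_fem_solution(mesh: Mesh, x_hat: np.ndarray,
                           pixel_map: PixelElementMap) -> np.ndarray:
    """Paint the per-element solution onto the raster of the pixel map.

    Each pixel takes the value of the element covering its center; pixels
    outside the mesh are zero.
    """
    if len(x_hat) != mesh.n_elem:
        raise ValueError("solution length != n_elem")
    elem = pixel_map.element_of
    out = np.zeros(elem.shape, float)
    inside = elem >= 0
    out[inside] = np.asarray(x_hat, float)[elem[inside]]
    return out


def peak_normalize(img: np.ndarray) -> np.ndarray:
    """Scale so the peak absolute value is 1 (no-op on an all-zero image)."""
    peak = np.max(np.abs(img))
    return img / peak if peak > 0 else img.copy()


def l1_image_difference(recon: np.ndarray, truth: np.ndarray,
                        roi: np.ndarray | None = None,
                        normalize: bool = True) -> float:
    """Sum of absolute pixel differences, by default of peak-normalized images."""
    if recon.shape != truth.shape:
        raise ValueError("image shapes must match")
    a = peak_normalize(recon) if normalize else np.asarray(recon, float)
    b = peak_normalize(truth) if normalize else np.asarray(truth, float)
    d = np.abs(a - b)
    if roi is not None:
        d = d[np.asarray(roi, bool)]
    return float(d.sum())
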