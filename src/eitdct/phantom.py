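"""Synthetic thorax phantoms and ventilation patterns.

The phantom stands in for a CT-derived thorax slice: an elliptical thorax
boundary with two elliptical lungs, rasterized to a binary lung image.  On
top of the lung mask, ventilation patterns describe which lung pixels change
conductivity between the baseline (end-expiratory) and inflated state:

* ``a`` — homogeneous ventilation of the complete lung,
* ``b`` — no ventilation in the dorsal half of the right lung,
* ``c`` — no ventilation in the most ventral and most dorsal bands of both lungs,
* ``d`` — no ventilation in the ventral left lung and the dorsal right lung,
* ``atelectasis`` — a dorsal band covering a given fraction of each lung's
  anterior-posterior extent is collapsed (non-ventilated).

Pixels use the radiological convention: column 0 (viewer's left) is the
patient's right side; row 0 is ventral.  See :mod:`eitdct.geometry`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .geometry import RasterExtent

PATTERN_IDS = ("a", "b", "c", "d", "atelectasis")


class GeometryError(ValueError):
    """Raised when phantom shapes are inconsistent (e.g. lung outside thorax)."""


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of the default two-lung elliptical phantom.

    Lengths are in arbitrary units; only ratios matter for difference EIT.
    ``lung_area_fraction``, if given, rescales both lung ellipses so the lungs
    occupy that fraction of the raster extent's area (aspect ratio preserved).
    ``pattern_c_band`` is the height of the ventral and dorsal non-ventilated
    bands of pattern ``c`` as a fraction of each lung's anterior-posterior
    extent.
    """

    thorax_radii: tuple[float, float] = (1.0, 0.75)
    lung_radii: tuple[float, float] = (0.28, 0.45)
    lung_offsets: tuple[float, float] = (0.45, -0.05)  # (|x| center, y center)
    raster_shape: tuple[int, int] = (64, 64)
    lung_area_fraction: float | None = None
    margin: float = 0.05  # extent margin relative to thorax radii
    n_boundary_points: int = 128
    pattern_c_band: float = 0.25
    patient_right_is_viewer_left: bool = True


@dataclass(frozen=True)
class ThoraxPhantom:
    """Thorax boundary polygon plus a binary lung raster.

    ``lung_mask`` is an M x N uint8 array, 1 on lung pixels.  ``extent`` maps
    pixel indices to the physical coordinates of ``boundary``.
    """

    boundary: np.ndarray  # (n_pts, 2), counter-clockwise, not repeated
    lung_mask: np.ndarray
    extent: RasterExtent
    config: PhantomConfig = field(default=PhantomConfig())

    @property
    def raster_shape(self) -> tuple[int, int]:
        return self.lung_mask.shape

    def thorax_mask(self) -> np.ndarray:
        """Binary raster of pixels whose center lies inside the thorax boundary."""
        a, b = self.config.thorax_radii
        X, Y = self.extent.pixel_centers()
        return ((X / a) ** 2 + (Y / b) ** 2 < 1.0).astype(np.uint8)


@dataclass(frozen=True)
class VentilationPattern:
    pattern_id: str
    ventilated_mask: np.ndarray
    atelectasis_fraction: float = 0.0

    def __post_init__(self):
        if self.pattern_id not in PATTERN_IDS:
            raise ValueError(f"unknown pattern_id {self.pattern_id!r}")


def _ellipse_mask(extent: RasterExtent, cx: float, cy: float,
                  rx: float, ry: float) -> np.ndarray:
    X, Y = extent.pixel_centers()
    return (((X - cx) / rx) ** 2 + ((Y - cy) / ry) ** 2 <= 1.0).astype(np.uint8)


def make_thorax_phantom(config: PhantomConfig | None = None) -> ThoraxPhantom:
    """Build the deterministic two-lung elliptical phantom.

    Raises :class:`GeometryError` if a lung ellipse does not fit strictly
    inside the thorax boundary.
    """
    cfg = config or PhantomConfig()
    M, N = cfg.raster_shape
    if M < 32 or N < 32:
        raise ValueError("raster size must be at least 32x32")
    a, b = cfg.thorax_radii
    ex = a * (1 + cfg.margin)
    ey = b * (1 + cfg.margin)
    extent = RasterExtent(-ex, ex, -ey, ey, (M, N))

    rx, ry = cfg.lung_radii
    if cfg.lung_area_fraction is not None:
        target = cfg.lung_area_fraction * (2 * ex) * (2 * ey)
        scale = np.sqrt(target / (2 * np.pi * rx * ry))
        rx, ry = rx * scale, ry * scale

    ox, oy = cfg.lung_offsets
    mask = np.zeros((M, N), dtype=np.uint8)
    for side, cx in (("right", -ox), ("left", ox)):
        # worst-case point of the lung ellipse against the thorax ellipse
        th = np.linspace(0, 2 * np.pi, 720, endpoint=False)
        px = cx + rx * np.cos(th)
        py = oy + ry * np.sin(th)
        if np.any((px / a) ** 2 + (py / b) ** 2 >= 1.0):
            raise GeometryError(
                f"{side} lung ellipse (center ({cx:+.3f},{oy:+.3f}), "
                f"radii ({rx:.3f},{ry:.3f})) intersects the thorax boundary"
            )
        mask |= _ellipse_mask(extent, cx, oy, rx, ry)

    th = np.linspace(0, 2 * np.pi, cfg.n_boundary_points, endpoint=False)
    # start at the ventral midline (0, b), counter-clockwise
    boundary = np.column_stack([-a * np.sin(th), b * np.cos(th)])
    used = replace(cfg, lung_radii=(rx, ry))
    return ThoraxPhantom(boundary=boundary, lung_mask=mask, extent=extent,
                         config=used)


def _lung_labels(phantom: ThoraxPhantom) -> tuple[np.ndarray, int]:
    labels, n = ndimage.label(phantom.lung_mask)
    return labels, n


def _split_left_right(phantom: ThoraxPhantom) -> tuple[np.ndarray, np.ndarray]:
    """Return (patient_right, patient_left) lung masks.

    Components are ordered by their mean column; with the radiological
    convention the patient's right lung sits at low column indices.
    """
    labels, n = _lung_labels(phantom)
    if n < 2:
        raise GeometryError("phantom lung mask must have >= 2 components")
    cols = ndimage.center_of_mass(phantom.lung_mask, labels, range(1, n + 1))
    order = np.argsort([c[1] for c in cols])  # ascending mean column
    low = np.isin(labels, [order[0] + 1]).astype(np.uint8)
    high = np.isin(labels, list(np.asarray(order[1:]) + 1)).astype(np.uint8)
    if phantom.config.patient_right_is_viewer_left:
        return low, high
    return high, low


def _remove_dorsal_band(mask: np.ndarray, fraction: float) -> np.ndarray:
    """Zero the dorsal-most `fraction` of the mask's row extent (per component)."""
    out = mask.copy()
    labels, n = ndimage.label(mask)
    for lab in range(1, n + 1):
        rows = np.where((labels == lab).any(axis=1))[0]
        h = rows.max() - rows.min() + 1
        k = int(np.floor(fraction * h + 1e-9))
        if k > 0:
            band = np.zeros_like(mask, dtype=bool)
            band[rows.max() - k + 1:, :] = True
            out[band & (labels == lab)] = 0
    return out


def _remove_ventral_band(mask: np.ndarray, fraction: float) -> np.ndarray:
    return _remove_dorsal_band(mask[::-1], fraction)[::-1]


def make_ventilation_pattern(phantom: ThoraxPhantom, pattern_id: str
                             ) -> VentilationPattern:
    """Build one of the four named ventilation patterns (``a``–``d``)."""
    if pattern_id not in ("a", "b", "c", "d"):
        raise ValueError(f"unknown pattern_id {pattern_id!r}; expected a, b, c or d")
    lung = phantom.lung_mask
    if pattern_id == "a":
        vent = lung.copy()
    elif pattern_id == "b":
        right, left = _split_left_right(phantom)
        vent = (_remove_dorsal_band(right, 0.5) | left).astype(np.uint8)
    elif pattern_id == "c":
        band = phantom.config.pattern_c_band
        vent = _remove_ventral_band(_remove_dorsal_band(lung, band), band)
    else:  # d
        right, left = _split_left_right(phantom)
        vent = (_remove_dorsal_band(right, 0.5)
                | _remove_ventral_band(left, 0.5)).astype(np.uint8)
    return VentilationPattern(pattern_id=pattern_id, ventilated_mask=vent)


def make_atelectasis_series(phantom: ThoraxPhantom, n_levels: int = 25,
                            max_fraction: float = 0.5
                            ) -> list[VentilationPattern]:
    """Ventilation patterns with an increasing dorsal collapsed band.

    Levels are evenly spaced from fraction 0 (fully ventilated) to
    ``max_fraction`` of each lung's anterior-posterior extent.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    if not (0 < max_fraction <= 1):
        raise ValueError("max_fraction must be in (0, 1]")
    out = []
    for f in np.linspace(0.0, max_fraction, n_levels):
        vent = _remove_dorsal_band(phantom.lung_mask, float(f))
        out.append(VentilationPattern(pattern_id="atelectasis",
                                      ventilated_mask=vent,
                                      atelectasis_fraction=float(f)))
    return out
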