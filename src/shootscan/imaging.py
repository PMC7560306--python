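"""Image preprocessing, segmentation and scale-bar calibration.

The measurement pipeline starts from a color scan of dissected seedlings (or
coleoptiles) laid out without overlap on an agar plate over a blue backing
sheet, with a horizontal scale bar of known physical length in one of the
lower corners.  This module turns that scan into labeled plant regions plus a
pixel-to-millimetre calibration factor:

* smoothing (median blur, then edge-preserving bilateral filtering) and
  conversion to HSV, where the green of the plant tissue separates cleanly
  from the blue background;
* inclusive HSV-window thresholding for seedlings, or automatic gray-level
  (between-class-variance) thresholding for coleoptiles, where color carries
  no extra information;
* 8-connected component labeling with a minimum-area noise filter;
* scale-bar detection in the configured bottom corner, whose column extent in
  pixels defines ``mm_per_px``.

Conventions: images are ``numpy`` arrays indexed ``(row, col)`` with the
origin at the top-left; rows increase downward.  RGB images are ``uint8``
``(H, W, 3)``; HSV images are float arrays with all three channels scaled to
``[0, 255]``; binary masks are boolean ``(H, W)`` arrays with ``True`` for
plant/object pixels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.color import rgb2gray, rgb2hsv
from skimage.restoration import denoise_bilateral

from .errors import (
    BarNotFoundError,
    ConfigError,
    DegenerateHistogramError,
    InvalidRectangleError,
)

logger = logging.getLogger(__name__)

# 8-connectivity structuring element shared by labeling and skeleton code.
EIGHT_CONNECTED = np.ones((3, 3), bool)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

#: Default HSV window (inclusive, channels scaled to 0-255) accepting the
#: green of seedling tissue while rejecting the blue background, pale plate
#: grid lines and the dark scale bar.
DEFAULT_HSV_BOUNDS = (55.0, 135.0, 70.0, 255.0, 50.0, 255.0)


@dataclass
class AnalysisConfig:
    """Every tunable of the analysis run.

    Parameters
    ----------
    plant_type:
        ``"seedling"`` (HSV color segmentation, spur pruning) or
        ``"coleoptile"`` (grayscale Otsu segmentation, no pruning).
    scale_bar_side:
        Which bottom corner holds the scale bar.
    scale_bar_length_mm:
        Physical length of the bar; the default 20 mm matches the 2-cm bar
        scanned with each plate.
    min_detection_area_px:
        Connected components smaller than this are treated as noise
        (default 500 px; components exactly at the minimum are kept).
    prune_threshold_px:
        Terminal skeleton edges shorter than this are removed as artifacts
        (default 50 px; the basal edge is always exempt).
    hsv_bounds:
        ``(h_lo, h_hi, s_lo, s_hi, v_lo, v_hi)`` inclusive window on the
        0-255 scale; ``h_lo > h_hi`` selects a hue window wrapping through 0.
    corner_window_frac:
        Fraction of image height and width scanned for the scale bar.
    median_kernel_px:
        Side of the square median-blur kernel; must be odd.
    bilateral_diameter / bilateral_sigma_color / bilateral_sigma_space:
        Bilateral-filter window size and range/domain sigmas (color sigma in
        8-bit intensity units).
    """

    plant_type: Literal["seedling", "coleoptile"] = "seedling"
    scale_bar_side: Literal["left", "right"] = "left"
    scale_bar_length_mm: float = 20.0
    min_detection_area_px: int = 500
    prune_threshold_px: float = 50.0
    hsv_bounds: tuple[float, float, float, float, float, float] = DEFAULT_HSV_BOUNDS
    corner_window_frac: float = 0.15
    median_kernel_px: int = 5
    bilateral_diameter: int = 5
    bilateral_sigma_color: float = 25.0
    bilateral_sigma_space: float = 3.0

    def __post_init__(self) -> None:
        if self.plant_type not in ("seedling", "coleoptile"):
            raise ConfigError(f"unknown plant_type {self.plant_type!r}")
        if self.scale_bar_side not in ("left", "right"):
            raise ConfigError(f"unknown scale_bar_side {self.scale_bar_side!r}")
        if not 0 < self.corner_window_frac <= 0.5:
            raise ConfigError("corner_window_frac must lie in (0, 0.5]")
        if self.min_detection_area_px < 1:
            raise ConfigError("min_detection_area_px must be >= 1")
        if self.prune_threshold_px < 0:
            raise ConfigError("prune_threshold_px must be >= 0")
        if self.median_kernel_px % 2 == 0 or self.median_kernel_px < 1:
            raise ConfigError("median_kernel_px must be a positive odd integer")
        if len(self.hsv_bounds) != 6:
            raise ConfigError("hsv_bounds must hold six numbers")
        h_lo, h_hi, s_lo, s_hi, v_lo, v_hi = self.hsv_bounds
        if s_lo > s_hi or v_lo > v_hi:
            raise ConfigError("saturation/value bounds must satisfy low <= high")


# ---------------------------------------------------------------------------
# geometric primitives
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScaleBar:
    """Detected scale bar: pixel extent plus physical length."""

    width_px: float
    length_mm: float
    corner: Literal["left", "right"] = "left"

    def __post_init__(self) -> None:
        if self.width_px < 10:
            raise BarNotFoundError(
                f"scale bar width {self.width_px} px below the 10 px noise guard"
            )
        if self.length_mm <= 0:
            raise ConfigError("scale bar physical length must be positive")

    @property
    def mm_per_px(self) -> float:
        return self.length_mm / self.width_px


@dataclass
class Region:
    """An 8-connected foreground component (one plant or organ)."""

    id: int
    coords: np.ndarray  # (N, 2) int array of (row, col)
    contour: list[tuple[int, int]]
    bbox: tuple[int, int, int, int]  # row_min, col_min, row_max, col_max inclusive
    image_shape: tuple[int, int]
    area_px: int = field(init=False)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.intp)
        self.area_px = int(len(self.coords))

    @property
    def pixel_set(self) -> set[tuple[int, int]]:
        return {(int(r), int(c)) for r, c in self.coords}

    def mask(self) -> np.ndarray:
        """Full-frame boolean mask of this region."""
        m = np.zeros(self.image_shape, bool)
        m[self.coords[:, 0], self.coords[:, 1]] = True
        return m


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def crop_to_workspace(
    img: np.ndarray, rect: tuple[int, int, int, int]
) -> np.ndarray:
    """Crop to the half-open rectangle ``(row0, col0, row1, col1)``.

    Scans usually cover the whole scanner bed; the caller supplies the
    rectangle that contains the plate and the scale bar.
    """
    row0, col0, row1, col1 = rect
    h, w = img.shape[:2]
    if not (0 <= row0 < row1 <= h and 0 <= col0 < col1 <= w):
        raise InvalidRectangleError(
            f"rectangle {rect} invalid for image of shape {(h, w)}"
        )
    return img[row0:row1, col0:col1].copy()


def smooth(img: np.ndarray, cfg: AnalysisConfig) -> np.ndarray:
    """Median blur then bilateral filtering; returns RGB floats in [0, 1].

    The median pass removes scanner salt noise; the bilateral pass
    homogenizes tissue color while keeping organ boundaries sharp.
    """
    if img.size == 0:
        raise InvalidRectangleError("empty image")
    if cfg.median_kernel_px % 2 == 0:
        raise ConfigError("median kernel must be odd")
    k = cfg.median_kernel_px
    smoothed = np.stack(
        [ndimage.median_filter(img[..., c], size=k) for c in range(3)], axis=-1
    )
    return denoise_bilateral(
        smoothed / 255.0,
        win_size=cfg.bilateral_diameter,
        sigma_color=cfg.bilateral_sigma_color / 255.0,
        sigma_spatial=cfg.bilateral_sigma_space,
        channel_axis=-1,
        mode="edge",  # replicate-pad: borders are not pulled toward black
    )


def preprocess(img: np.ndarray, cfg: AnalysisConfig) -> np.ndarray:
    """Smooth the scan and convert it to HSV (channels scaled to [0, 255])."""
    return rgb2hsv(smooth(img, cfg)) * 255.0


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------


def segment_color(hsv_img: np.ndarray, cfg: AnalysisConfig) -> np.ndarray:
    """Threshold an HSV image with the configured inclusive color window.

    Plants are arranged without overlap, so a plain per-pixel color window is
    sufficient to separate tissue from the blue background.  A hue window
    with ``h_lo > h_hi`` wraps around 0 (reds).
    """
    h_lo, h_hi, s_lo, s_hi, v_lo, v_hi = cfg.hsv_bounds
    h, s, v = hsv_img[..., 0], hsv_img[..., 1], hsv_img[..., 2]
    if h_lo <= h_hi:
        hue_ok = (h >= h_lo) & (h <= h_hi)
    else:  # wrap-around window
        hue_ok = (h >= h_lo) | (h <= h_hi)
    return hue_ok & (s >= s_lo) & (s <= s_hi) & (v >= v_lo) & (v <= v_hi)


def otsu_threshold(gray: np.ndarray) -> int:
    """Gray-level threshold maximizing the between-class variance.

    All integer cuts ``T`` in 0..255 are scanned; ``T`` splits pixels into the
    classes ``{v < T}`` and ``{v >= T}``.  The smallest maximizing ``T`` is
    returned, so the result is deterministic on plateaus.
    """
    gray = np.asarray(gray)
    if gray.size == 0:
        raise DegenerateHistogramError("empty image")
    vals = np.clip(np.round(gray), 0, 255).astype(np.uint8)
    hist = np.bincount(vals.ravel(), minlength=256).astype(np.float64)
    if np.count_nonzero(hist) < 2:
        raise DegenerateHistogramError("image has fewer than two gray levels")
    total = hist.sum()
    levels = np.arange(256, dtype=np.float64)
    # cum0[T] = count/levelsum of the {v < T} class, T = 0..255
    cum0 = np.concatenate(([0.0], np.cumsum(hist)))[:256]
    sum0 = np.concatenate(([0.0], np.cumsum(hist * levels)))[:256]
    w0 = cum0 / total
    w1 = 1.0 - w0
    total_sum = float((hist * levels).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = np.where(cum0 > 0, sum0 / cum0, 0.0)
        mu1 = np.where(total - cum0 > 0, (total_sum - sum0) / (total - cum0), 0.0)
    between = w0 * w1 * (mu0 - mu1) ** 2
    return int(np.argmax(between))


def segment_otsu(gray: np.ndarray) -> tuple[int, np.ndarray]:
    """Automatic grayscale segmentation for coleoptiles (and the scale bar).

    Returns the between-class-variance-maximizing threshold and the
    foreground mask.  Foreground polarity is resolved automatically: of the
    two gray-level classes, the one whose mean differs most from the mean of
    the image border is taken as the object, which works for pale coleoptiles
    on dark backing as well as dark bars on a light plate.
    """
    gray = np.asarray(gray, dtype=np.float64)
    t = otsu_threshold(gray)
    high = gray >= t
    border = np.concatenate([gray[0, :], gray[-1, :], gray[1:-1, 0], gray[1:-1, -1]])
    border_mean = float(border.mean()) if border.size else float(gray.mean())
    mean_high = float(gray[high].mean())
    mean_low = float(gray[~high].mean())
    if abs(mean_high - border_mean) >= abs(mean_low - border_mean):
        mask = high
    else:
        mask = ~high
    return t, mask


# ---------------------------------------------------------------------------
# region extraction
# ---------------------------------------------------------------------------


def corner_window(
    shape: tuple[int, int], cfg: AnalysisConfig
) -> tuple[slice, slice]:
    """Row/col slices of the bottom corner scanned for the scale bar."""
    h, w = shape[:2]
    wh = max(1, int(round(h * cfg.corner_window_frac)))
    ww = max(1, int(round(w * cfg.corner_window_frac)))
    rows = slice(h - wh, h)
    cols = slice(0, ww) if cfg.scale_bar_side == "left" else slice(w - ww, w)
    return rows, cols


def _ordered_contour(mask: np.ndarray) -> list[tuple[int, int]]:
    """Ordered outline pixels of a single-component boolean mask."""
    padded = np.pad(mask, 1)
    contours = measure.find_contours(padded.astype(float), 0.5)
    if not contours:
        return []
    trace = max(contours, key=len)
    out: list[tuple[int, int]] = []
    for rf, cf in trace:
        # map each iso-contour vertex to an adjacent foreground pixel
        r0, c0 = int(np.floor(rf)), int(np.floor(cf))
        for r, c in ((r0, c0), (r0, c0 + 1), (r0 + 1, c0), (r0 + 1, c0 + 1)):
            if 0 <= r < padded.shape[0] and 0 <= c < padded.shape[1] and padded[r, c]:
                px = (r - 1, c - 1)
                if not out or out[-1] != px:
                    out.append(px)
                break
    if len(out) > 1 and out[0] == out[-1]:
        out.pop()
    return out


def extract_regions(mask: np.ndarray, cfg: AnalysisConfig) -> list[Region]:
    """Label 8-connected components and drop sub-minimum-area noise.

    The scale-bar corner window is blanked first so the bar is never counted
    as a plant; regions are numbered 1..k in reading order of their bounding
    box top-left corners.
    """
    work = np.asarray(mask, bool).copy()
    rows, cols = corner_window(work.shape, cfg)
    work[rows, cols] = False
    labels, n = ndimage.label(work, structure=EIGHT_CONNECTED)
    regions: list[Region] = []
    for lab in range(1, n + 1):
        comp = labels == lab
        area = int(comp.sum())
        if area < cfg.min_detection_area_px:
            continue
        coords = np.argwhere(comp)
        r_min, c_min = coords.min(axis=0)
        r_max, c_max = coords.max(axis=0)
        sub = comp[r_min : r_max + 1, c_min : c_max + 1]
        contour = [
            (r + int(r_min), c + int(c_min)) for r, c in _ordered_contour(sub)
        ]
        regions.append(
            Region(
                id=0,
                coords=coords,
                contour=contour,
                bbox=(int(r_min), int(c_min), int(r_max), int(c_max)),
                image_shape=work.shape,
            )
        )
    regions.sort(key=lambda reg: (reg.bbox[0], reg.bbox[1]))
    for i, reg in enumerate(regions, start=1):
        reg.id = i
    logger.debug("extract_regions: %d/%d components kept", len(regions), n)
    return regions


def detect_scale_bar(img: np.ndarray, cfg: AnalysisConfig) -> ScaleBar:
    """Find the scale bar in the configured bottom corner.

    The corner window is thresholded in grayscale (automatic threshold,
    border-polarity rule) regardless of plant mode; the largest connected
    non-background component is taken as the bar and its column extent
    defines the calibration ``mm_per_px = length_mm / width_px``.
    """
    rows, cols = corner_window(img.shape, cfg)
    window = img[rows, cols]
    gray = rgb2gray(window) * 255.0 if window.ndim == 3 else np.asarray(window, float)
    gray = ndimage.median_filter(gray, size=3)  # suppress scanner salt noise
    try:
        _, mask = segment_otsu(gray)
    except DegenerateHistogramError as exc:
        raise BarNotFoundError(
            f"no contrast in the bottom-{cfg.scale_bar_side} corner window"
        ) from exc
    labels, n = ndimage.label(mask, structure=EIGHT_CONNECTED)
    if n == 0:
        raise BarNotFoundError("corner window contains no foreground component")
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    best = int(np.argmax(sizes)) + 1
    cols_of_bar = np.nonzero((labels == best).any(axis=0))[0]
    width = int(cols_of_bar[-1] - cols_of_bar[0] + 1)
    if width < 10:
        raise BarNotFoundError(
            f"largest corner component only {width} px wide (noise guard is 10 px)"
        )
    logger.debug("scale bar: width %d px -> %.5f mm/px", width,
                 cfg.scale_bar_length_mm / width)
    return ScaleBar(
        width_px=float(width),
        length_mm=cfg.scale_bar_length_mm,
        corner=cfg.scale_bar_side,
    )
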