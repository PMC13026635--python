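"""Cytoplasmic vacuolization scoring from confocal stacks.

Dye-filled somata image bright; lysosomal storage vacuoles exclude the dye
and image dark.  The score is the ratio of black (dark, dye-excluded) to
white (bright, dye-filled) pixels inside the soma after thresholding a
maximum projection of three consecutive planes around the nucleus level:

1. convert the stack to 8-bit grayscale (min–max rescale),
2. crop a 100 × 100 pixel region of interest around the cell,
3. maximum-project 3 consecutive planes starting at the nucleus plane,
4. segment the soma and erase the surround,
5. build the in-mask intensity histogram; the second-highest peak marks
   the cytoplasmic mode and is the *maximum* admissible threshold,
6. binarize (black strictly below the cut) and count pixels in-mask.

The automated cut used by the pipeline is the histogram valley between the
two dominant modes (vacuole-dark and cytoplasm-bright), bounded above by
the cytoplasmic peak; a unimodal histogram means no dark population, which
the pipeline scores as a B/W ratio of 0 (the strict two-peak API raises
instead, so flagged cells can also be excluded).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks
from skimage.filters import threshold_otsu
from skimage.measure import label
from skimage.morphology import convex_hull_image

from .errors import (
    DegenerateRescaleError,
    EmptyMaskError,
    InsufficientDepthError,
    InvalidParameterError,
    UndefinedRatioError,
    UnimodalHistogramError,
)
from .traceio import ImageStack

logger = logging.getLogger(__name__)

#: histogram smoothing width (bins) and minimum peak separation (bins)
HIST_SMOOTH_BINS = 5
PEAK_MIN_SEPARATION = 10
#: minimum peak prominence, as a fraction of the tallest peak — rejects
#: noise bumps and boundary-blur shoulders
PEAK_MIN_PROMINENCE = 0.05


@dataclass
class VacuolizationResult:
    nucleus_plane: int
    threshold: float            # binarization cut, 8-bit intensity
    cytoplasm_peak: float       # second-highest-peak intensity (max threshold)
    black_pixels: int
    white_pixels: int
    flag: str | None = None     # e.g. "unimodal" for vacuole-free cells

    @property
    def bw_ratio(self) -> float:
        if self.white_pixels == 0:
            raise UndefinedRatioError("zero white pixels")
        return self.black_pixels / self.white_pixels


def to_8bit(stack: ImageStack) -> ImageStack:
    """Linear min–max rescale of the whole stack to [0, 255], rounded
    half-up; 8-bit input passes through unchanged."""
    if stack.bit_depth == 8:
        return stack
    planes = stack.planes.astype(float)
    lo, hi = planes.min(), planes.max()
    if hi == lo:
        raise DegenerateRescaleError("constant-intensity stack")
    scaled = np.floor((planes - lo) / (hi - lo) * 255.0 + 0.5)
    return ImageStack(scaled.astype(np.uint8),
                      voxel_size_nm=stack.voxel_size_nm)


def crop_roi(stack: ImageStack, center: tuple[int, int],
             size: int = 100) -> ImageStack:
    """``size``×``size`` crop of every plane, centred on ``center`` (row,
    col); clipped to the image bounds with a log message when the ROI
    would overhang."""
    nz, ny, nx = stack.planes.shape
    cy, cx = center
    if not (0 <= cy < ny and 0 <= cx < nx):
        raise InvalidParameterError("ROI centre outside the image")
    half = size // 2
    y0, x0 = cy - half, cx - half
    y1, x1 = y0 + size, x0 + size
    if y0 < 0 or x0 < 0 or y1 > ny or x1 > nx:
        logger.info("ROI clipped to image bounds at centre (%d, %d)", cy, cx)
    y0c, x0c = max(0, y0), max(0, x0)
    y1c, x1c = min(ny, y1), min(nx, x1)
    return ImageStack(stack.planes[:, y0c:y1c, x0c:x1c],
                      voxel_size_nm=stack.voxel_size_nm)


def max_project3(stack: ImageStack, start_plane: int) -> np.ndarray:
    """Pixelwise maximum of planes start..start+2 (the nucleus level and
    its two neighbours)."""
    if start_plane < 0 or start_plane + 3 > stack.depth:
        raise InsufficientDepthError(
            f"planes {start_plane}..{start_plane + 2} not available in a "
            f"stack of depth {stack.depth}")
    return stack.planes[start_plane:start_plane + 3].max(axis=0)


def mask_soma(projection: np.ndarray,
              manual_mask: np.ndarray | None = None) -> np.ndarray:
    """Binary soma mask of the projection.

    Automated mode: global two-class (Otsu) threshold, largest connected
    component, then the convex hull of that component — the cell body is
    convex, and the hull keeps interior vacuoles *and* dark bays at the
    soma edge inside the mask, mimicking a manual soma outline.
    Manual mode: the supplied mask is used verbatim.
    """
    if manual_mask is not None:
        manual_mask = np.asarray(manual_mask, dtype=bool)
        if manual_mask.shape != projection.shape:
            raise InvalidParameterError("manual mask shape mismatch")
        if not manual_mask.any():
            raise EmptyMaskError("manual mask is empty")
        return manual_mask
    thr = threshold_otsu(projection)
    fg = projection > thr
    if not fg.any():
        raise EmptyMaskError("no foreground above the global threshold")
    lab = label(fg)
    largest = np.argmax(np.bincount(lab.ravel())[1:]) + 1
    return convex_hull_image(lab == largest)


def _smoothed_histogram(projection: np.ndarray, mask: np.ndarray
                        ) -> np.ndarray:
    values = projection[mask]
    hist, _ = np.histogram(values, bins=256, range=(0, 256))
    return uniform_filter1d(hist.astype(float), size=HIST_SMOOTH_BINS)


def _top_two_peaks(smoothed: np.ndarray) -> list[int]:
    """Local maxima of the smoothed 256-bin histogram (min separation 10
    bins), ranked by height; returns up to two bin indices."""
    peaks, _ = find_peaks(smoothed, distance=PEAK_MIN_SEPARATION,
                          prominence=PEAK_MIN_PROMINENCE * smoothed.max())
    if peaks.size == 0:
        return []
    order = np.argsort(smoothed[peaks])[::-1]
    return [int(peaks[i]) for i in order[:2]]


def second_peak_threshold(projection: np.ndarray, mask: np.ndarray) -> int:
    """Intensity of the second-highest peak of the smoothed in-mask
    histogram — the cytoplasmic mode, used as the maximum admissible
    threshold.  Raises :class:`UnimodalHistogramError` with fewer than two
    peaks (cell flagged, excluded)."""
    top = _top_two_peaks(_smoothed_histogram(projection, mask))
    if len(top) < 2:
        raise UnimodalHistogramError(
            "fewer than two peaks in the in-mask intensity histogram")
    return top[1]


def valley_threshold(projection: np.ndarray, mask: np.ndarray) -> int | None:
    """Binarization cut: the minimum of the smoothed histogram between the
    two dominant modes.  ``None`` when the histogram is unimodal (no dark
    population)."""
    smoothed = _smoothed_histogram(projection, mask)
    top = _top_two_peaks(smoothed)
    if len(top) < 2:
        return None
    lo, hi = sorted(top)
    return lo + int(np.argmin(smoothed[lo:hi + 1]))


def binarize_and_ratio(projection: np.ndarray, mask: np.ndarray,
                       threshold: float, nucleus_plane: int = 0,
                       cytoplasm_peak: float | None = None,
                       flag: str | None = None) -> VacuolizationResult:
    """Binarize in-mask pixels (strictly below threshold → black, boundary
    pixels equal to the threshold → white) and form the B/W ratio.

    Out-of-mask pixels never count: the surround was erased.
    """
    if not mask.any():
        raise EmptyMaskError("empty soma mask")
    vals = projection[mask]
    black = int((vals < threshold).sum())
    white = int(vals.size - black)
    if white == 0:
        raise UndefinedRatioError("zero white pixels at this threshold")
    return VacuolizationResult(
        nucleus_plane=nucleus_plane, threshold=float(threshold),
        cytoplasm_peak=float(cytoplasm_peak if cytoplasm_peak is not None
                             else threshold),
        black_pixels=black, white_pixels=white, flag=flag)


def score_vacuolization(stack: ImageStack, nucleus_plane: int,
                        roi_center: tuple[int, int] | None = None,
                        roi_size: int = 100,
                        manual_mask: np.ndarray | None = None
                        ) -> VacuolizationResult:
    """Full per-cell pipeline: 8-bit conversion, optional ROI crop,
    3-plane maximum projection, soma segmentation, histogram thresholding,
    binarization.

    A unimodal in-mask histogram (homogeneously dye-filled cytoplasm) is
    scored as zero vacuolization and flagged ``"unimodal"``.
    """
    stack8 = to_8bit(stack)
    if roi_center is not None:
        stack8 = crop_roi(stack8, roi_center, roi_size)
    proj = max_project3(stack8, nucleus_plane - 1 if nucleus_plane > 0 else 0)
    mask = mask_soma(proj, manual_mask)
    cut = valley_threshold(proj, mask)
    if cut is None:
        return VacuolizationResult(
            nucleus_plane=nucleus_plane, threshold=0.0,
            cytoplasm_peak=float(np.argmax(_smoothed_histogram(proj, mask))),
            black_pixels=0, white_pixels=int(mask.sum()), flag="unimodal")
    # the brighter of the two dominant modes is the cytoplasmic peak; the
    # valley cut can never exceed it by construction
    cytoplasm = max(_top_two_peaks(_smoothed_histogram(proj, mask)))
    return binarize_and_ratio(proj, mask, cut, nucleus_plane=nucleus_plane,
                              cytoplasm_peak=cytoplasm)
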