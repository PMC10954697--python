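"""Automated tracing of alveolar wall borders from fluorescence-like images.

Replaces manual polygon tracing for rendered (or sufficiently clean real)
wall images. The recipe is deliberately classical:

1. Gaussian-smooth the image (suppresses shot-like noise).
2. Threshold: Otsu's cut, refined to the midpoint of the two class plateaus
   (or a fixed intensity).
3. Fill holes and label connected regions of the binary wall mask; each
   region is one candidate alveolar wall band.
4. For each band, extract sub-pixel iso-contours of the *smoothed intensity*
   image at the threshold level: the largest closed contour is the outer
   border, the largest closed contour nested inside it is the lumen (inner
   border). Intensity iso-contours avoid the staircase perimeter inflation
   of binary-mask contours and keep both the area ratio (wall thickness)
   and the perimeter (circularity) nearly unbiased.
5. Contours are simplified with Douglas-Peucker to the requested tolerance.

Alveoli whose filled region touches the image border are rejected (their
areas would be truncated); regions below the minimum area are discarded and
counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import shapely
from scipy import ndimage
from skimage import measure as skmeasure
from skimage.filters import gaussian, threshold_otsu

from .errors import SegmentationAmbiguityError, SegmentationFailureError
from .geometry import DEFAULT_PIXEL_SIZE_UM, AlveolusTrace, PolygonTrace

__all__ = ["SegmentationParams", "SegmentationLog", "segment_alveolus", "segment_field"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable knobs of the border-extraction recipe.

    smoothing_sd_um
        SD of the Gaussian pre-smoothing, micrometres. 0 disables.
    threshold
        ``"otsu"`` (default) or ``"fixed"``.
    fixed_threshold
        Intensity cut used when ``threshold == "fixed"``.
    min_area_um2
        Candidate regions with filled area below this are discarded.
    simplify_tol_um
        Douglas-Peucker tolerance for the output polygons, micrometres.
        0 keeps every contour point.
    """

    smoothing_sd_um: float = 0.25
    threshold: str = "otsu"
    fixed_threshold: float = 128.0
    min_area_um2: float = 100.0
    simplify_tol_um: float = 0.02

    def __post_init__(self) -> None:
        if self.smoothing_sd_um < 0:
            raise ValueError("smoothing_sd_um must be >= 0")
        if self.simplify_tol_um < 0:
            raise ValueError("simplify_tol_um must be >= 0")
        if self.threshold not in ("otsu", "fixed"):
            raise ValueError("threshold must be 'otsu' or 'fixed'")


@dataclass
class SegmentationLog:
    """Per-field bookkeeping: how many candidate regions met which fate."""

    n_regions: int = 0
    n_traced: int = 0
    n_too_small: int = 0
    n_border_touching: int = 0
    n_failed: int = 0
    failures: list[str] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.failures is None:
            self.failures = []


def _smooth_and_threshold(
    image: np.ndarray, params: SegmentationParams
) -> tuple[np.ndarray, float]:
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a single-channel 2-D image")
    if params.smoothing_sd_um > 0:
        img = gaussian(
            img, sigma=params.smoothing_sd_um / DEFAULT_PIXEL_SIZE_UM, preserve_range=True
        )
    if params.threshold == "otsu":
        if np.ptp(img) == 0:
            raise SegmentationFailureError("image has no contrast (constant intensity)")
        thr = float(threshold_otsu(img))
        # Refine to the midpoint of the two class plateaus: for a blurred
        # step edge the midpoint iso-level crosses at the true border
        # position, removing the wall-width bias an off-midpoint Otsu cut
        # introduces. Medians (not means) estimate the plateaus so the
        # blurred edge shoulders do not drag the level.
        fg, bg = img[img > thr], img[img <= thr]
        if fg.size and bg.size:
            thr = float(0.5 * (np.median(fg) + np.median(bg)))
    else:
        thr = float(params.fixed_threshold)
    return img, thr


def _contour_area_px(c: np.ndarray) -> float:
    x, y = c[:, 1], c[:, 0]
    return abs(0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)))


def _contour_to_trace(
    contour_rc: np.ndarray,
    pixel_size: float,
    tol_um: float,
    label: str,
) -> PolygonTrace:
    if tol_um > 0:
        contour_rc = skmeasure.approximate_polygon(contour_rc, tol_um / pixel_size)
    # find_contours returns a closed loop (first == last); PolygonTrace drops
    # the duplicate. Convert (row, col) -> (x, y) um.
    verts = np.column_stack((contour_rc[:, 1], contour_rc[:, 0])) * pixel_size
    return PolygonTrace(verts, pixel_size=pixel_size, label=label)


def _region_to_trace(
    smoothed: np.ndarray,
    thr: float,
    region_filled: np.ndarray,
    params: SegmentationParams,
    pixel_size: float,
    alveolus_id: str,
) -> AlveolusTrace:
    """Sub-pixel border extraction for one candidate wall band.

    Iso-contours of the smoothed intensity image at the threshold level are
    sub-pixel and smooth, avoiding the staircase perimeter inflation a binary
    mask contour would introduce. The largest closed contour is the outer
    border; the largest closed contour nested inside it is the lumen.
    """
    halo = ndimage.binary_dilation(region_filled, iterations=4)
    masked = np.where(halo, smoothed, 0.0)
    contours = [
        c
        for c in skmeasure.find_contours(masked, thr)
        if np.allclose(c[0], c[-1])
    ]
    if not contours:
        raise SegmentationFailureError(
            f"region {alveolus_id!r}: no closed iso-contour at the threshold"
        )
    contours.sort(key=_contour_area_px, reverse=True)
    outer = _contour_to_trace(contours[0], pixel_size, params.simplify_tol_um, "outer")
    outer_poly = outer.as_shapely()
    inner_c = None
    for c in contours[1:]:
        mid = c[len(c) // 2]
        if outer_poly.contains(shapely.Point(mid[1] * pixel_size, mid[0] * pixel_size)):
            inner_c = c
            break
    if inner_c is None:
        raise SegmentationFailureError(
            f"region {alveolus_id!r}: wall band has no enclosed lumen"
        )
    inner = _contour_to_trace(inner_c, pixel_size, params.simplify_tol_um, "inner")
    return AlveolusTrace(inner=inner, outer=outer, alveolus_id=alveolus_id)


def segment_alveolus(
    image: np.ndarray,
    params: SegmentationParams = SegmentationParams(),
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM,
    alveolus_id: str = "segmented-1",
) -> AlveolusTrace:
    """Extract the single alveolus wall band in ``image`` as a trace pair.

    Raises :class:`SegmentationFailureError` if no closed band with a lumen
    is found and :class:`SegmentationAmbiguityError` if several candidate
    bands qualify.
    """
    smoothed, thr = _smooth_and_threshold(image, params)
    filled = ndimage.binary_fill_holes(smoothed > thr)
    labels, n = ndimage.label(filled)
    min_px = params.min_area_um2 / pixel_size**2
    candidates = [
        i for i in range(1, n + 1) if np.count_nonzero(labels == i) >= min_px
    ]
    if not candidates:
        raise SegmentationFailureError("no closed wall band found")
    if len(candidates) > 1:
        raise SegmentationAmbiguityError(
            f"expected one wall band, found {len(candidates)} candidate regions",
            n_regions=len(candidates),
        )
    region = labels == candidates[0]
    if _touches_border(region):
        raise SegmentationFailureError(
            "wall band touches the image border (truncated alveolus)"
        )
    return _region_to_trace(smoothed, thr, region, params, pixel_size, alveolus_id)


def _touches_border(mask: np.ndarray) -> bool:
    return bool(
        mask[0, :].any() or mask[-1, :].any() or mask[:, 0].any() or mask[:, -1].any()
    )


def segment_field(
    image: np.ndarray,
    params: SegmentationParams = SegmentationParams(),
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM,
    id_prefix: str = "segmented",
) -> tuple[list[AlveolusTrace], SegmentationLog]:
    """Extract every qualifying alveolus from a field of view.

    Non-fatal per-region failures (too small, border-touching, no lumen) are
    counted in the returned :class:`SegmentationLog` rather than raised.
    """
    smoothed, thr = _smooth_and_threshold(image, params)
    filled = ndimage.binary_fill_holes(smoothed > thr)
    labels, n = ndimage.label(filled)
    log = SegmentationLog(n_regions=n)
    min_px = params.min_area_um2 / pixel_size**2
    traces: list[AlveolusTrace] = []
    for i in range(1, n + 1):
        region = labels == i
        if np.count_nonzero(region) < min_px:
            log.n_too_small += 1
            continue
        if _touches_border(region):
            log.n_border_touching += 1
            continue
        alveolus_id = f"{id_prefix}-{len(traces) + 1:03d}"
        try:
            trace = _region_to_trace(smoothed, thr, region, params, pixel_size, alveolus_id)
        except SegmentationFailureError as exc:
            log.n_failed += 1
            log.failures.append(str(exc))
            logger.warning("segment_field: %s", exc)
            continue
        traces.append(trace)
        log.n_traced += 1
    return traces, log
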