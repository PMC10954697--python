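"""Polygon geometry and the three alveolar morphometric readouts.

An alveolus in an optical section is described by two closed polygon traces:
the *outer* border (the outside of the alveolar wall) and the *inner* border
(the lumen). From these the module computes

* **wall thickness** as a percentage of the total alveolar surface area,
  ``100 * (A_outer - A_inner) / A_outer`` — smaller means a thinner wall;
* **circularity** of the inner border, the shape descriptor
  ``4*pi*A / P**2``, equal to 1.00 for a perfect circle and strictly smaller
  for any other simple closed curve (isoperimetric inequality); values are
  capped at 1.0 to absorb discretisation overshoot on near-circular traces;
* the **morphological quotient (MQ)**, circularity divided by wall thickness
  expressed as a fraction (``circularity / (thickness_pct / 100)``) — high MQ
  means a round, thin-walled (healthy-looking) alveolus.

Coordinates follow the image convention: x to the right, y downward, origin
at the top-left of the source image, physical units in micrometres. Pixel
traces are converted with a micrometre-per-pixel calibration
(:data:`DEFAULT_PIXEL_SIZE_UM`, 208.39 nm/pixel).

All three metrics are invariant to translation, rotation and uniform scaling
of the traces (areas scale as s**2 and perimeters as s, so the ratios cancel).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import shapely

from .errors import ContainmentError, InvalidPolygonError

__all__ = [
    "DEFAULT_PIXEL_SIZE_UM",
    "Condition",
    "PolygonTrace",
    "AlveolusTrace",
    "MorphometryRecord",
    "polygon_area",
    "polygon_perimeter",
    "wall_thickness_pct",
    "circularity",
    "morphological_quotient",
    "measure_alveolus",
    "measure_cohort",
]

#: Micrometres per pixel of the reference confocal acquisition (208.39 nm/px).
DEFAULT_PIXEL_SIZE_UM = 0.20839


class Condition(str, Enum):
    """Experimental condition of an animal/alveolus."""

    BASELINE = "baseline"
    INJURY = "injury"


def _as_vertex_array(vertices: Iterable[Sequence[float]]) -> np.ndarray:
    arr = np.asarray(vertices, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise InvalidPolygonError(
            f"vertices must be an (n, 2) array of coordinates, got shape {arr.shape}"
        )
    if not np.all(np.isfinite(arr)):
        raise InvalidPolygonError("vertices contain non-finite coordinates")
    # Drop an explicit closing vertex; closure is implicit. Exact comparison:
    # a tolerance here could silently swallow a genuine (tiny) edge.
    if arr.shape[0] >= 2 and bool(np.all(arr[0] == arr[-1])):
        arr = arr[:-1]
    return arr


@dataclass(frozen=True, eq=False)
class PolygonTrace:
    """One closed wall-border trace in physical micrometres.

    Parameters
    ----------
    vertices
        Ordered ``(n, 2)`` array of ``(x, y)`` coordinates in micrometres.
        The polygon is treated as closed: the last vertex joins the first.
    pixel_size
        Micrometre-per-pixel calibration of the source image, if the trace
        originated in pixel space. Informational once converted.
    label
        Free-text label (e.g. ``"inner"`` / ``"outer"``).
    """

    vertices: np.ndarray
    pixel_size: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        arr = _as_vertex_array(self.vertices)
        object.__setattr__(self, "vertices", arr)
        self.validate()

    def validate(self) -> None:
        """Reject traces with < 3 vertices, self-intersections or zero area."""
        v = self.vertices
        if v.shape[0] < 3:
            raise InvalidPolygonError(
                f"polygon {self.label!r} needs >= 3 vertices, got {v.shape[0]}"
            )
        shoelace = _signed_area(v)
        if shoelace == 0.0:
            raise InvalidPolygonError(f"polygon {self.label!r} has zero signed area")
        poly = shapely.Polygon(v)
        if not poly.is_valid:
            reason = shapely.is_valid_reason(poly)
            raise InvalidPolygonError(
                f"polygon {self.label!r} is not simple: {reason}"
            )

    @classmethod
    def from_pixels(
        cls,
        vertices: Iterable[Sequence[float]],
        pixel_size: float = DEFAULT_PIXEL_SIZE_UM,
        label: str = "",
    ) -> "PolygonTrace":
        """Build a trace from 0-based pixel coordinates (x=col, y=row)."""
        arr = np.asarray(vertices, dtype=float) * float(pixel_size)
        return cls(vertices=arr, pixel_size=float(pixel_size), label=label)

    def as_shapely(self) -> shapely.Polygon:
        return shapely.Polygon(self.vertices)

    def transformed(
        self,
        scale: float = 1.0,
        rotation: float = 0.0,
        translation: Sequence[float] = (0.0, 0.0),
    ) -> "PolygonTrace":
        """Similarity-transformed copy (scale about the origin, then rotate,
        then translate)."""
        if scale <= 0:
            raise ValueError("scale must be positive")
        c, s = math.cos(rotation), math.sin(rotation)
        rot = np.array([[c, -s], [s, c]])
        verts = (self.vertices * scale) @ rot.T + np.asarray(translation, dtype=float)
        return replace(self, vertices=verts)


@dataclass(frozen=True, eq=False)
class AlveolusTrace:
    """Paired inner/outer border traces of one alveolus."""

    inner: PolygonTrace
    outer: PolygonTrace
    alveolus_id: str
    animal_id: str = ""
    condition: Condition = Condition.BASELINE

    def __post_init__(self) -> None:
        object.__setattr__(self, "condition", Condition(self.condition))
        self.validate()

    def validate(self) -> None:
        """Check inner area < outer area and inner ⊂ outer."""
        a_in = polygon_area(self.inner)
        a_out = polygon_area(self.outer)
        if a_in >= a_out:
            raise ContainmentError(
                f"alveolus {self.alveolus_id!r}: inner area {a_in:.6g} um^2 is not "
                f"smaller than outer area {a_out:.6g} um^2"
            )
        if not self.outer.as_shapely().covers(self.inner.as_shapely()):
            raise ContainmentError(
                f"alveolus {self.alveolus_id!r}: inner border is not contained "
                "in the outer border"
            )


@dataclass(frozen=True)
class MorphometryRecord:
    """Per-alveolus derived metrics."""

    alveolus_id: str
    animal_id: str
    condition: Condition
    area_outer: float  # um^2
    area_inner: float  # um^2
    perimeter_inner: float  # um
    wall_thickness_pct: float  # % of total alveolar surface area
    circularity: float  # dimensionless, (0, 1]
    mq: float  # dimensionless, > 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "condition", Condition(self.condition))

    def to_dict(self) -> dict:
        d = {
            "alveolus_id": self.alveolus_id,
            "animal_id": self.animal_id,
            "condition": self.condition.value,
            "area_outer": self.area_outer,
            "area_inner": self.area_inner,
            "perimeter_inner": self.perimeter_inner,
            "wall_thickness_pct": self.wall_thickness_pct,
            "circularity": self.circularity,
            "mq": self.mq,
        }
        return d


def _signed_area(v: np.ndarray) -> float:
    x, y = v[:, 0], v[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def polygon_area(trace: PolygonTrace) -> float:
    """Enclosed area in um^2 via the shoelace (surveyor's) formula.

    Orientation-independent (absolute value) and strictly positive for a
    valid trace.
    """
    return abs(_signed_area(trace.vertices))


def polygon_perimeter(trace: PolygonTrace) -> float:
    """Perimeter in um: sum of edge lengths including the closing edge."""
    v = trace.vertices
    return float(np.sum(np.hypot(*(np.roll(v, -1, axis=0) - v).T)))


def wall_thickness_pct(alveolus: AlveolusTrace) -> float:
    """Wall thickness as % of total alveolar surface area.

    Subtracts the inner-border area from the outer-border area and expresses
    the difference relative to the outer (total) area:
    ``100 * (A_outer - A_inner) / A_outer``.
    """
    a_out = polygon_area(alveolus.outer)
    a_in = polygon_area(alveolus.inner)
    if a_in >= a_out:
        raise ContainmentError(
            f"alveolus {alveolus.alveolus_id!r}: inner area >= outer area"
        )
    return 100.0 * (a_out - a_in) / a_out


def circularity(trace: PolygonTrace) -> float:
    """Shape-descriptor circularity ``4*pi*A / P**2`` of a border, capped at 1.

    Returns 1.00 for a perfect circle (in the dense-polygon limit) and
    strictly less for any non-circular simple closed curve.
    """
    area = polygon_area(trace)
    perim = polygon_perimeter(trace)
    return min(1.0, 4.0 * math.pi * area / perim**2)


def morphological_quotient(circ: float, thickness_pct: float) -> float:
    """Morphological quotient: circularity / wall thickness (as a fraction).

    ``MQ = circularity / (thickness_pct / 100)``; computed per alveolus,
    before any averaging. High MQ = round and thin-walled.
    """
    if thickness_pct <= 0:
        raise ValueError(f"wall thickness must be positive, got {thickness_pct}")
    if not 0 < circ <= 1:
        raise ValueError(f"circularity must be in (0, 1], got {circ}")
    return circ / (thickness_pct / 100.0)


def measure_alveolus(alveolus: AlveolusTrace) -> MorphometryRecord:
    """Compute the full morphometry record for one traced alveolus."""
    try:
        a_out = polygon_area(alveolus.outer)
        a_in = polygon_area(alveolus.inner)
        thickness = wall_thickness_pct(alveolus)
        circ = circularity(alveolus.inner)
        mq = morphological_quotient(circ, thickness)
        perim_in = polygon_perimeter(alveolus.inner)
    except (InvalidPolygonError, ContainmentError, ValueError) as exc:
        raise type(exc)(f"alveolus {alveolus.alveolus_id!r}: {exc}") from exc
    return MorphometryRecord(
        alveolus_id=alveolus.alveolus_id,
        animal_id=alveolus.animal_id,
        condition=alveolus.condition,
        area_outer=a_out,
        area_inner=a_in,
        perimeter_inner=perim_in,
        wall_thickness_pct=thickness,
        circularity=circ,
        mq=mq,
    )


def measure_cohort(traces: Iterable[AlveolusTrace]) -> list[MorphometryRecord]:
    """Measure every alveolus in a cohort of traces."""
    return [measure_alveolus(t) for t in traces]
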