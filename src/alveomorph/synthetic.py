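"""Synthetic alveolus traces, hierarchical cohorts, rendered wall images and
injury scores with known ground truth.

Raw confocal imagery of alveoli is rarely shareable, so this module emulates
the measured objects directly. An alveolar outline is modelled as a
star-convex radial-harmonic curve

    r(theta) = R * (1 + sum_k a_k * cos(k*theta + phi_k)),

which keeps self-intersection easy to prevent (r > 0 suffices) while giving
direct control over circularity through the harmonic amplitudes ``a_k``:
a perfect circle at ``a = 0``, progressively crumpled outlines — like
collapsed, injured alveoli — as low-order amplitudes grow. The inner border
is the outer curve scaled radially about its centre by
``s = sqrt(1 - t/100)``, so the realised wall-thickness percentage equals the
target ``t`` exactly (areas of similar polygons scale as ``s**2``).

Ground truth for every emitted trace is computed by the geometry module on
the emitted polygons themselves, so generator truth and measurement agree by
construction.

Cohorts are hierarchical: a per-animal mean is drawn around the condition
mean, and per-alveolus values are drawn around the animal mean, mirroring the
animals x alveoli structure of an in-vivo study (default 5 animals/group,
10 alveoli/animal). Default condition parameters reproduce the reference
group statistics for healthy vs. gastric-aspiration-injured porcine lung
(thickness 26.86 +/- 0.4998 vs 50.55 +/- 4.468 %; circularity
0.8783 +/- 0.01965 vs 0.4133 +/- 0.04366).

Rendered images emulate a fluorescently labelled wall: the band between the
two borders is filled at a wall intensity over background, Gaussian-blurred
(optics) and corrupted with additive Gaussian noise, then quantised to 8-bit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from skimage.draw import polygon2mask
from skimage.filters import gaussian

from .errors import FieldOfViewError
from .geometry import (
    DEFAULT_PIXEL_SIZE_UM,
    AlveolusTrace,
    Condition,
    MorphometryRecord,
    PolygonTrace,
    circularity,
    measure_alveolus,
)

__all__ = [
    "ShapeSpec",
    "ConditionParams",
    "CohortSpec",
    "RenderSpec",
    "make_alveolus",
    "make_cohort",
    "render_image",
    "make_injury_scores",
    "amplitude_for_circularity",
    "sample_animal_means",
    "records_to_frame",
]

logger = logging.getLogger(__name__)

#: Relative weights of the radial harmonics used when a single roughness
#: amplitude is mapped onto a multi-harmonic outline. The high orders add
#: perimeter quickly, so the mix spans circularity from 1.0 (amplitude 0)
#: down to ~0.15 (maximum amplitude) — wide enough for severely crumpled,
#: injured alveoli.
_HARMONIC_ORDERS = (2, 6, 12, 20)
_HARMONIC_WEIGHTS = (1.0, 0.8, 0.6, 0.5)
#: Keep min r(theta) comfortably positive: sum of amplitudes <= 0.90.
_MAX_TOTAL_AMPLITUDE = 0.90


@dataclass(frozen=True)
class ShapeSpec:
    """Parameters of one synthetic alveolus outline.

    ``roughness_amplitudes`` maps harmonic order k -> relative amplitude a_k.
    """

    base_radius: float = 30.0  # um
    target_thickness_pct: float = 27.0
    roughness_amplitudes: tuple[tuple[int, float], ...] = ()
    n_vertices: int = 256
    seed: int = 0
    center: tuple[float, float] = (0.0, 0.0)  # um, image convention

    def __post_init__(self) -> None:
        if self.base_radius <= 0:
            raise ValueError("base_radius must be positive")
        if not 0 < self.target_thickness_pct < 100:
            raise ValueError("target_thickness_pct must be in (0, 100)")
        if self.n_vertices < 32:
            raise ValueError("n_vertices must be >= 32")


@dataclass(frozen=True)
class ConditionParams:
    """Per-condition distribution parameters of the cohort generator.

    ``*_sd_animal`` is the SD of animal-level means around the condition
    mean (the spread printed as mean +/- SD at animal level);
    ``*_sd_alveolus`` is the within-animal, per-alveolus SD.
    """

    thickness_mean: float
    thickness_sd_animal: float
    thickness_sd_alveolus: float
    circularity_mean: float
    circularity_sd_animal: float
    circularity_sd_alveolus: float

    def __post_init__(self) -> None:
        for name in (
            "thickness_sd_animal",
            "thickness_sd_alveolus",
            "circularity_sd_animal",
            "circularity_sd_alveolus",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


#: Healthy-lung defaults: thin walls, near-circular lumens.
BASELINE_PARAMS = ConditionParams(
    thickness_mean=26.86,
    thickness_sd_animal=0.4998,
    thickness_sd_alveolus=3.0,
    circularity_mean=0.8783,
    circularity_sd_animal=0.01965,
    circularity_sd_alveolus=0.05,
)
#: Gastric-aspiration injury defaults: thick walls, crumpled lumens.
INJURY_PARAMS = ConditionParams(
    thickness_mean=50.55,
    thickness_sd_animal=4.468,
    thickness_sd_alveolus=8.0,
    circularity_mean=0.4133,
    circularity_sd_animal=0.04366,
    circularity_sd_alveolus=0.10,
)


@dataclass(frozen=True)
class CohortSpec:
    """Hierarchical two-condition cohort: animals x alveoli."""

    n_animals: int = 5  # per condition
    n_alveoli: int = 10  # per animal
    baseline: ConditionParams = BASELINE_PARAMS
    injury: ConditionParams = INJURY_PARAMS
    #: Alveolar radius sized so one alveolus fills most of the default
    #: 213 um field of view, as in single-alveolus acquisitions.
    base_radius: float = 50.0  # um
    n_vertices: int = 256
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_animals < 1 or self.n_alveoli < 1:
            raise ValueError("n_animals and n_alveoli must be positive")

    def params_for(self, condition: Condition) -> ConditionParams:
        return self.baseline if condition is Condition.BASELINE else self.injury


@dataclass(frozen=True)
class RenderSpec:
    """Rendering parameters for fluorescence-like 8-bit wall images."""

    width: int = 1024  # px
    height: int = 1024  # px
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM  # um/px
    wall_intensity: float = 200.0
    background_intensity: float = 20.0
    noise_sd: float = 8.0  # additive Gaussian, 8-bit counts
    blur_sd_um: float = 0.3  # optical blur, um

    def __post_init__(self) -> None:
        for name in ("wall_intensity", "background_intensity"):
            v = getattr(self, name)
            if not 0 <= v <= 255:
                raise ValueError(f"{name} must be in [0, 255] for 8-bit output")
        if self.noise_sd < 0 or self.blur_sd_um < 0:
            raise ValueError("noise_sd and blur_sd_um must be >= 0")

    @property
    def field_um(self) -> tuple[float, float]:
        """Field of view (width, height) in micrometres."""
        return (self.width * self.pixel_size, self.height * self.pixel_size)


def _radial_outline(
    radius: float,
    amplitudes: Sequence[tuple[int, float]],
    phases: dict[int, float],
    n_vertices: int,
    center: tuple[float, float],
) -> np.ndarray:
    theta = np.linspace(0.0, 2.0 * math.pi, n_vertices, endpoint=False)
    r = np.ones_like(theta)
    for k, a_k in amplitudes:
        r += a_k * np.cos(k * theta + phases[k])
    r *= radius
    cx, cy = center
    return np.column_stack((cx + r * np.cos(theta), cy + r * np.sin(theta)))


def make_alveolus(spec: ShapeSpec) -> tuple[AlveolusTrace, MorphometryRecord]:
    """Generate one alveolus trace plus its ground-truth morphometry.

    The outer border is the radial-harmonic curve of ``spec``; the inner
    border is the same curve scaled about the centre so the wall-thickness
    percentage equals ``spec.target_thickness_pct`` exactly. Amplitude sets
    whose total exceeds the star-convexity budget are damped (and logged)
    rather than allowed to self-intersect.
    """
    rng = np.random.default_rng(spec.seed)
    amplitudes = [(int(k), float(a)) for k, a in spec.roughness_amplitudes]
    phases = {k: float(rng.uniform(0, 2 * math.pi)) for k, _ in amplitudes}

    total = sum(abs(a) for _, a in amplitudes)
    if total > _MAX_TOTAL_AMPLITUDE:
        damp = _MAX_TOTAL_AMPLITUDE / total
        logger.warning(
            "alveolus seed=%d: total harmonic amplitude %.3f exceeds %.2f; "
            "damping by %.3f",
            spec.seed,
            total,
            _MAX_TOTAL_AMPLITUDE,
            damp,
        )
        amplitudes = [(k, a * damp) for k, a in amplitudes]

    outer_verts = _radial_outline(
        spec.base_radius, amplitudes, phases, spec.n_vertices, spec.center
    )
    s = math.sqrt(1.0 - spec.target_thickness_pct / 100.0)
    center = np.asarray(spec.center, dtype=float)
    inner_verts = center + s * (outer_verts - center)

    trace = AlveolusTrace(
        inner=PolygonTrace(inner_verts, label="inner"),
        outer=PolygonTrace(outer_verts, label="outer"),
        alveolus_id=f"synthetic-{spec.seed}",
    )
    return trace, measure_alveolus(trace)


def _phases_for_seed(seed: int, orders: Sequence[int]) -> dict[int, float]:
    """Harmonic phases exactly as :func:`make_alveolus` draws them."""
    rng = np.random.default_rng(seed)
    return {int(k): float(rng.uniform(0, 2 * math.pi)) for k in orders}


def _mix_circularity(
    a: float, phases: dict[int, float], n_vertices: int = 256
) -> float:
    """Circularity of the canonical multi-harmonic outline at amplitude a."""
    amps = [(k, a * w) for k, w in zip(_HARMONIC_ORDERS, _HARMONIC_WEIGHTS)]
    verts = _radial_outline(1.0, amps, phases, n_vertices, (0.0, 0.0))
    return circularity(PolygonTrace(verts))


def amplitude_for_circularity(
    target: float,
    phases: dict[int, float] | None = None,
    tol: float = 1e-4,
    n_vertices: int = 256,
) -> float:
    """Invert circularity -> roughness amplitude by bisection.

    Uses the canonical harmonic mix (:data:`_HARMONIC_ORDERS` with fixed
    relative weights); circularity decreases monotonically with the overall
    amplitude. Passing the phases the outline will actually use makes the
    realised circularity match the target to ``tol``. Targets below the
    reachable minimum clamp to the maximum amplitude.
    """
    if not 0 < target <= 1:
        raise ValueError(f"target circularity must be in (0, 1], got {target}")
    if phases is None:
        phases = {k: 0.0 for k in _HARMONIC_ORDERS}
    a_max = _MAX_TOTAL_AMPLITUDE / sum(_HARMONIC_WEIGHTS)
    lo, hi = 0.0, a_max
    if target >= _mix_circularity(0.0, phases, n_vertices):
        return 0.0
    if target <= _mix_circularity(a_max, phases, n_vertices):
        return a_max
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        c = _mix_circularity(mid, phases, n_vertices)
        if abs(c - target) < tol:
            return mid
        if c > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _spawn_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def sample_animal_means(
    params: ConditionParams,
    n_animals: int,
    n_alveoli: int,
    rng: np.random.Generator,
    variable: str = "thickness",
) -> np.ndarray:
    """Draw animal-level means from the generator's hierarchical model.

    Equivalent in distribution to averaging ``n_alveoli`` per-alveolus draws
    for each animal in :func:`make_cohort`, without building polygons. Useful
    for Monte-Carlo studies of downstream statistics.
    """
    if variable == "thickness":
        mu, sd_a, sd_w = (
            params.thickness_mean,
            params.thickness_sd_animal,
            params.thickness_sd_alveolus,
        )
    elif variable == "circularity":
        mu, sd_a, sd_w = (
            params.circularity_mean,
            params.circularity_sd_animal,
            params.circularity_sd_alveolus,
        )
    else:
        raise ValueError(f"unknown variable {variable!r}")
    animal = rng.normal(mu, sd_a, size=n_animals)
    return animal + rng.normal(0.0, sd_w / math.sqrt(n_alveoli), size=n_animals)


def make_cohort(
    spec: CohortSpec,
) -> tuple[list[AlveolusTrace], pd.DataFrame]:
    """Generate a full two-condition hierarchical cohort.

    Returns the list of traces and a ground-truth table with one row per
    alveolus: identifiers, target thickness/circularity drawn by the
    hierarchy, and the realised metrics measured by the geometry module on
    the emitted polygons.
    """
    rng = np.random.default_rng(spec.seed)
    traces: list[AlveolusTrace] = []
    rows: list[dict] = []
    for condition in (Condition.BASELINE, Condition.INJURY):
        params = spec.params_for(condition)
        for i_animal in range(spec.n_animals):
            animal_id = f"{condition.value}-{i_animal + 1:02d}"
            thick_mu = rng.normal(params.thickness_mean, params.thickness_sd_animal)
            circ_mu = rng.normal(
                params.circularity_mean, params.circularity_sd_animal
            )
            for i_alv in range(spec.n_alveoli):
                alveolus_id = f"{animal_id}-a{i_alv + 1:02d}"
                thick = float(
                    np.clip(
                        rng.normal(thick_mu, params.thickness_sd_alveolus), 2.0, 98.0
                    )
                )
                circ_target = float(
                    np.clip(
                        rng.normal(circ_mu, params.circularity_sd_alveolus),
                        0.15,
                        0.995,
                    )
                )
                shape_seed = _spawn_seed(rng)
                phases = _phases_for_seed(shape_seed, _HARMONIC_ORDERS)
                amp = amplitude_for_circularity(
                    circ_target, phases=phases, n_vertices=spec.n_vertices
                )
                shape = ShapeSpec(
                    base_radius=spec.base_radius,
                    target_thickness_pct=thick,
                    roughness_amplitudes=tuple(
                        (k, amp * w)
                        for k, w in zip(_HARMONIC_ORDERS, _HARMONIC_WEIGHTS)
                    ),
                    n_vertices=spec.n_vertices,
                    seed=shape_seed,
                )
                trace, record = make_alveolus(shape)
                trace = replace(
                    trace,
                    alveolus_id=alveolus_id,
                    animal_id=animal_id,
                    condition=condition,
                )
                record = replace(
                    record,
                    alveolus_id=alveolus_id,
                    animal_id=animal_id,
                    condition=condition,
                )
                traces.append(trace)
                row = record.to_dict()
                row["target_thickness_pct"] = thick
                row["target_circularity"] = circ_target
                rows.append(row)
    return traces, pd.DataFrame(rows)


def records_to_frame(records: Iterable[MorphometryRecord]) -> pd.DataFrame:
    """Tabulate morphometry records."""
    return pd.DataFrame([r.to_dict() for r in records])


def _trace_to_rc(verts_um: np.ndarray, pixel_size: float) -> np.ndarray:
    """Physical (x, y) um -> (row, col) pixel-index coordinates."""
    return np.column_stack((verts_um[:, 1], verts_um[:, 0])) / pixel_size


def render_image(
    traces: Iterable[AlveolusTrace],
    spec: RenderSpec = RenderSpec(),
    seed: int = 0,
) -> np.ndarray:
    """Render traced alveolar walls as an 8-bit fluorescence-like image.

    The band between each alveolus's outer and inner borders is filled at
    ``wall_intensity`` over ``background_intensity``, blurred with a Gaussian
    PSF of ``blur_sd_um`` and corrupted with additive Gaussian noise of SD
    ``noise_sd``, then clipped to [0, 255] and quantised.

    Pixel (row, col) sits at physical position (x, y) = (col, row) *
    pixel_size, matching the trace coordinate convention.
    """
    shape = (spec.height, spec.width)
    wall = np.zeros(shape, dtype=bool)
    w_um, h_um = spec.field_um
    for trace in traces:
        for border in (trace.outer, trace.inner):
            v = border.vertices
            if (
                v[:, 0].min() < 0
                or v[:, 1].min() < 0
                or v[:, 0].max() > w_um - spec.pixel_size
                or v[:, 1].max() > h_um - spec.pixel_size
            ):
                raise FieldOfViewError(
                    f"alveolus {trace.alveolus_id!r} does not fit in the "
                    f"{spec.width}x{spec.height} px field of view"
                )
        outer_mask = polygon2mask(shape, _trace_to_rc(trace.outer.vertices, spec.pixel_size))
        inner_mask = polygon2mask(shape, _trace_to_rc(trace.inner.vertices, spec.pixel_size))
        wall |= outer_mask & ~inner_mask

    img = np.where(wall, spec.wall_intensity, spec.background_intensity).astype(float)
    if spec.blur_sd_um > 0:
        img = gaussian(img, sigma=spec.blur_sd_um / spec.pixel_size, preserve_range=True)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, spec.noise_sd, size=shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def center_in_field(trace: AlveolusTrace, spec: RenderSpec) -> AlveolusTrace:
    """Translate an alveolus so its outer-border centroid sits at the field
    centre."""
    centroid = trace.outer.vertices.mean(axis=0)
    w_um, h_um = spec.field_um
    shift = np.array([w_um / 2.0, h_um / 2.0]) - centroid
    return replace(
        trace,
        inner=replace(trace.inner, vertices=trace.inner.vertices + shift),
        outer=replace(trace.outer, vertices=trace.outer.vertices + shift),
    )


def make_injury_scores(
    mq_per_animal: Sequence[float],
    slope: float = -3.5,
    intercept: float = 13.0,
    noise_sd: float = 0.3,
    seed: int = 0,
    max_score: int = 15,
) -> np.ndarray:
    """Emulate cumulative observer-based injury scores from per-animal MQ.

    ``score = round(intercept + slope * MQ + noise)`` clipped to the scoring
    grid [0, max_score]. The default grid assumes five scored histological
    features at 0-3 each (cumulative maximum 15); the slope is negative so
    healthier (high-MQ) animals score lower, emulating the strong negative
    MQ-score correlation seen in observer scoring.
    """
    if slope >= 0:
        raise ValueError("slope must be negative (injury lowers MQ, raises score)")
    rng = np.random.default_rng(seed)
    mq = np.asarray(mq_per_animal, dtype=float)
    raw = intercept + slope * mq + rng.normal(0.0, noise_sd, size=mq.shape)
    return np.clip(np.rint(raw), 0, max_score).astype(int)
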