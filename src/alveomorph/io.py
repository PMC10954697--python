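"""Readers and writers for the package's plain-text interchange formats.

Trace tables are long-format CSV, one row per vertex:

    alveolus_id, animal_id, condition, border, vertex_index, x_um, y_um

with ``border`` one of ``inner``/``outer``. Coordinates are written with six
decimal places and round-trip bit-exactly at that precision. Morphometry
records and summaries are ordinary wide CSV tables; images are single-channel
8-bit TIFF with the pixel size recorded in the TIFF resolution tags.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import TraceParseError
from .geometry import (
    DEFAULT_PIXEL_SIZE_UM,
    AlveolusTrace,
    Condition,
    MorphometryRecord,
    PolygonTrace,
)
from .segmentation import SegmentationParams
from .stats import DEFAULT_BIN_WIDTHS
from .synthetic import CohortSpec, ConditionParams, RenderSpec

__all__ = [
    "TRACE_COLUMNS",
    "write_traces",
    "read_traces",
    "write_records",
    "read_records",
    "write_image",
    "read_image",
    "PipelineConfig",
]

TRACE_COLUMNS = (
    "alveolus_id",
    "animal_id",
    "condition",
    "border",
    "vertex_index",
    "x_um",
    "y_um",
)


def write_traces(traces: Iterable[AlveolusTrace], path: str | Path) -> None:
    """Write alveolus traces to the long-format CSV dialect."""
    rows = []
    for trace in traces:
        for border_name, border in (("inner", trace.inner), ("outer", trace.outer)):
            for i, (x, y) in enumerate(border.vertices):
                rows.append(
                    (
                        trace.alveolus_id,
                        trace.animal_id,
                        trace.condition.value,
                        border_name,
                        i,
                        f"{x:.6f}",
                        f"{y:.6f}",
                    )
                )
    frame = pd.DataFrame(rows, columns=list(TRACE_COLUMNS))
    frame.to_csv(path, index=False)


def read_traces(path: str | Path) -> list[AlveolusTrace]:
    """Read alveolus traces from the long-format CSV dialect.

    Row order inside the file is irrelevant: vertices are re-ordered by
    ``vertex_index`` and alveoli are returned sorted by id. An alveolus
    missing one of its two borders raises :class:`TraceParseError`.
    """
    try:
        frame = pd.read_csv(path, dtype={"alveolus_id": str, "animal_id": str})
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise TraceParseError(f"{path}: {exc}") from exc
    missing = set(TRACE_COLUMNS) - set(frame.columns)
    if missing:
        raise TraceParseError(f"{path}: missing columns {sorted(missing)}")
    bad = frame[~frame["border"].isin(["inner", "outer"])]
    if not bad.empty:
        # +2: 1-based line numbers plus the header row
        raise TraceParseError(
            f"{path}: invalid border value {bad['border'].iloc[0]!r} "
            f"at line {bad.index[0] + 2}"
        )
    for col in ("x_um", "y_um"):
        if not np.issubdtype(frame[col].dtype, np.number):
            nonnum = pd.to_numeric(frame[col], errors="coerce").isna()
            raise TraceParseError(
                f"{path}: non-numeric {col} at line {frame.index[nonnum.idxmax()] + 2}"
            )

    traces = []
    for alveolus_id, group in sorted(frame.groupby("alveolus_id", sort=True)):
        borders = {}
        for border_name, sub in group.groupby("border"):
            sub = sub.sort_values("vertex_index")
            borders[border_name] = PolygonTrace(
                sub[["x_um", "y_um"]].to_numpy(dtype=float), label=border_name
            )
        if set(borders) != {"inner", "outer"}:
            have = ", ".join(sorted(borders)) or "none"
            raise TraceParseError(
                f"{path}: alveolus {alveolus_id!r} has border(s) {have}; "
                "need both inner and outer"
            )
        traces.append(
            AlveolusTrace(
                inner=borders["inner"],
                outer=borders["outer"],
                alveolus_id=str(alveolus_id),
                animal_id=str(group["animal_id"].iloc[0]),
                condition=Condition(group["condition"].iloc[0]),
            )
        )
    return traces


def write_records(
    records: Iterable[MorphometryRecord] | pd.DataFrame, path: str | Path
) -> None:
    """Write morphometry records as a wide CSV table."""
    if isinstance(records, pd.DataFrame):
        frame = records
    else:
        frame = pd.DataFrame([r.to_dict() for r in records])
    frame.to_csv(path, index=False)


def read_records(path: str | Path) -> pd.DataFrame:
    """Read a morphometry record table written by :func:`write_records`."""
    return pd.read_csv(path, dtype={"alveolus_id": str, "animal_id": str})


def write_image(
    image: np.ndarray, path: str | Path, pixel_size: float = DEFAULT_PIXEL_SIZE_UM
) -> None:
    """Write an 8-bit grayscale TIFF with pixel-size resolution metadata."""
    if image.dtype != np.uint8:
        raise ValueError("expected an 8-bit image")
    px_per_cm = 1e4 / pixel_size
    tifffile.imwrite(
        path,
        image,
        resolution=(px_per_cm, px_per_cm),
        resolutionunit="CENTIMETER",
    )


def read_image(path: str | Path) -> tuple[np.ndarray, float | None]:
    """Read a single-channel TIFF; returns (image, pixel size in um or None)."""
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        image = page.asarray()
        pixel_size = None
        res = page.tags.get("XResolution")
        unit = page.tags.get("ResolutionUnit")
        if res is not None and unit is not None and unit.value == 3:  # centimetre
            num, den = res.value
            if num:
                pixel_size = 1e4 * den / num
    return image, pixel_size


@dataclass
class PipelineConfig:
    """Everything one reproducible end-to-end run needs.

    Round-trips unchanged through YAML (:meth:`to_yaml` / :meth:`from_yaml`).
    """

    seed: int = 0
    out_dir: str = "alveomorph-run"
    use_segmentation: bool = False
    cohort: CohortSpec = field(default_factory=CohortSpec)
    render: RenderSpec = field(default_factory=RenderSpec)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    bin_widths: dict = field(default_factory=lambda: dict(DEFAULT_BIN_WIDTHS))
    alpha: float = 0.05
    score_slope: float = -3.5
    score_intercept: float = 13.0
    score_noise_sd: float = 0.3

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cohort"]["baseline"] = asdict(self.cohort.baseline)
        d["cohort"]["injury"] = asdict(self.cohort.injury)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "cohort" in d:
            c = dict(d["cohort"])
            for cond in ("baseline", "injury"):
                if cond in c and isinstance(c[cond], dict):
                    c[cond] = ConditionParams(**c[cond])
            d["cohort"] = CohortSpec(**c)
        if "render" in d and isinstance(d["render"], dict):
            d["render"] = RenderSpec(**d["render"])
        if "segmentation" in d and isinstance(d["segmentation"], dict):
            d["segmentation"] = SegmentationParams(**d["segmentation"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
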