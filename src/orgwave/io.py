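"""Trace containers and file formats.

Traces are per-ROI time series (time in ms, values in arbitrary units)
with a modality (``calcium`` fluorescence or ``motion`` brightfield
signal) and a position in µm relative to the organoid centroid.  Tables
are plain CSV with a schema-version header comment; image stacks are
multi-page grayscale TIFF with a companion ROI CSV.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
import tifffile

SCHEMA_VERSION = 1
_TRACE_COLUMNS = ["cell_id", "modality", "t_ms", "value_au"]
_ROI_COLUMNS = ["cell_id", "x_um", "y_um", "radius_um", "is_organoid"]
MODALITIES = ("calcium", "motion")

#: relative jitter tolerated on the uniform time grid
_TIME_RTOL = 1e-9


class TraceValidationError(ValueError):
    """A trace table violated the schema (named column / row context)."""


@dataclass
class Trace:
    """A single uniformly sampled per-ROI time series."""

    cell_id: str
    modality: str
    times_ms: np.ndarray
    values: np.ndarray
    position_um: tuple[float, float] = (0.0, 0.0)
    source: str = "table"

    def __post_init__(self) -> None:
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.modality not in MODALITIES:
            raise TraceValidationError(f"unknown modality {self.modality!r}")
        if self.times_ms.size != self.values.size:
            raise TraceValidationError("times and values must have equal length")
        if self.times_ms.size < 2:
            raise TraceValidationError("a trace needs at least 2 samples")
        dts = np.diff(self.times_ms)
        if np.any(dts <= 0):
            bad = int(np.argmax(dts <= 0))
            raise TraceValidationError(
                f"time not strictly increasing at row {bad + 1} of cell {self.cell_id}"
            )
        dt = dts[0]
        if np.any(np.abs(dts - dt) > _TIME_RTOL * max(abs(dt), 1.0) + 1e-12 * dt):
            bad = int(np.argmax(np.abs(dts - dt) > _TIME_RTOL * abs(dt)))
            raise TraceValidationError(
                f"non-uniform time grid near row {bad} of cell {self.cell_id}"
            )
        if not np.all(np.isfinite(self.values)):
            bad = int(np.argmax(~np.isfinite(self.values)))
            raise TraceValidationError(
                f"non-finite value at row {bad} of cell {self.cell_id}"
            )

    @property
    def dt_ms(self) -> float:
        return float(self.times_ms[1] - self.times_ms[0])

    @property
    def duration_ms(self) -> float:
        return float(self.times_ms[-1] - self.times_ms[0])


@dataclass(frozen=True)
class RoiSpec:
    """A disk-shaped region of interest (centroid + radius, µm)."""

    cell_id: str
    x_um: float
    y_um: float
    radius_um: float
    is_organoid: bool = False

    def __post_init__(self) -> None:
        if self.radius_um <= 0:
            raise ValueError("ROI radius must be positive")


class TraceSet:
    """A collection of traces keyed by (cell_id, modality)."""

    def __init__(self, traces: Iterable[Trace] = ()) -> None:
        self._traces: dict[tuple[str, str], Trace] = {}
        for tr in traces:
            self.add(tr)

    def add(self, trace: Trace) -> None:
        key = (trace.cell_id, trace.modality)
        if key in self._traces:
            raise TraceValidationError(f"duplicate trace for cell {key[0]!r} / {key[1]}")
        self._traces[key] = trace

    def get(self, cell_id: str, modality: str) -> Trace:
        return self._traces[(cell_id, modality)]

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self._traces

    def __len__(self) -> int:
        return len(self._traces)

    def __iter__(self) -> Iterator[Trace]:
        return iter(self._traces.values())

    def cells(self, modality: str | None = None) -> list[str]:
        seen: dict[str, None] = {}
        for cid, mod in self._traces:
            if modality is None or mod == modality:
                seen.setdefault(cid, None)
        return list(seen)

    def traces(self, modality: str) -> list[Trace]:
        return [tr for (cid, mod), tr in self._traces.items() if mod == modality]

    def to_frame(self) -> pd.DataFrame:
        chunks = []
        for tr in self:
            chunks.append(
                pd.DataFrame(
                    {
                        "cell_id": tr.cell_id,
                        "modality": tr.modality,
                        "t_ms": tr.times_ms,
                        "value_au": tr.values,
                    }
                )
            )
        if not chunks:
            return pd.DataFrame(columns=_TRACE_COLUMNS)
        return pd.concat(chunks, ignore_index=True)


def write_trace_table(traces: TraceSet, path: str | Path,
                      positions: dict[str, tuple[float, float]] | None = None) -> None:
    """Write a trace table CSV with a schema header comment."""
    path = Path(path)
    frame = traces.to_frame()
    with open(path, "w", newline="") as fh:
        fh.write(f"# orgwave-trace-table v{SCHEMA_VERSION}\n")
        frame.to_csv(fh, index=False, float_format="%.10g")


def read_trace_table(path: str | Path, *, times_in_seconds: bool = False,
                     positions: dict[str, tuple[float, float]] | None = None) -> TraceSet:
    """Read and validate a trace table CSV.

    The time column is milliseconds; pass ``times_in_seconds=True`` for
    tables recorded in seconds.  Missing columns, duplicated
    (cell_id, modality, t_ms) rows, non-monotone time grids and NaN values
    raise :class:`TraceValidationError` with the offending context.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, comment="#")
    missing = [c for c in _TRACE_COLUMNS if c not in frame.columns]
    if missing:
        raise TraceValidationError(f"missing required column(s): {', '.join(missing)}")
    if frame["value_au"].isna().any():
        bad = int(frame.index[frame["value_au"].isna()][0])
        raise TraceValidationError(f"NaN value at row {bad}")
    dup = frame.duplicated(subset=["cell_id", "modality", "t_ms"])
    if dup.any():
        bad = int(frame.index[dup][0])
        raise TraceValidationError(f"duplicate (cell_id, modality, t_ms) record at row {bad}")
    scale = 1000.0 if times_in_seconds else 1.0
    ts = TraceSet()
    for (cid, mod), grp in frame.groupby(["cell_id", "modality"], sort=False):
        pos = (positions or {}).get(str(cid), (0.0, 0.0))
        ts.add(
            Trace(
                cell_id=str(cid),
                modality=str(mod),
                times_ms=grp["t_ms"].to_numpy() * scale,
                values=grp["value_au"].to_numpy(),
                position_um=pos,
                source="table",
            )
        )
    return ts


def write_roi_table(rois: Iterable[RoiSpec], path: str | Path) -> None:
    path = Path(path)
    frame = pd.DataFrame(
        [
            {
                "cell_id": r.cell_id,
                "x_um": r.x_um,
                "y_um": r.y_um,
                "radius_um": r.radius_um,
                "is_organoid": int(r.is_organoid),
            }
            for r in rois
        ],
        columns=_ROI_COLUMNS,
    )
    with open(path, "w", newline="") as fh:
        fh.write(f"# orgwave-roi-table v{SCHEMA_VERSION}\n")
        frame.to_csv(fh, index=False, float_format="%.10g")


def read_roi_table(path: str | Path) -> list[RoiSpec]:
    frame = pd.read_csv(path, comment="#")
    missing = [c for c in _ROI_COLUMNS if c not in frame.columns]
    if missing:
        raise TraceValidationError(f"missing required column(s): {', '.join(missing)}")
    rois = [
        RoiSpec(
            cell_id=str(row.cell_id),
            x_um=float(row.x_um),
            y_um=float(row.y_um),
            radius_um=float(row.radius_um),
            is_organoid=bool(row.is_organoid),
        )
        for row in frame.itertuples()
    ]
    if sum(r.is_organoid for r in rois) != 1:
        raise TraceValidationError("exactly one ROI must be flagged is_organoid")
    return rois


def write_stack(stack: np.ndarray, path: str | Path) -> None:
    """Write a (frames, rows, cols) grayscale stack as multi-page TIFF."""
    tifffile.imwrite(Path(path), stack, photometric="minisblack")


def read_stack(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path))


def roi_mask(shape: tuple[int, int], center_px: tuple[float, float],
             radius_px: float) -> np.ndarray:
    """Disk mask over pixel centers; boundary pixels are included."""
    rows, cols = np.ogrid[: shape[0], : shape[1]]
    rr, cc = center_px
    return (rows - rr) ** 2 + (cols - cc) ** 2 <= radius_px**2


def extract_roi_traces(stack: np.ndarray, rois: Iterable[RoiSpec],
                       pixel_size_um: float, *, frame_interval_ms: float,
                       modality: str = "calcium",
                       origin_px: tuple[float, float] | None = None) -> TraceSet:
    """Mean-intensity traces for disk ROIs over a grayscale stack.

    Positions are in µm relative to the organoid centroid; ``origin_px``
    is the pixel (row, col) of that centroid (defaults to the frame
    center).  Each trace value is the mean pixel intensity of the disk in
    that frame (pixel centers, inclusive boundary).
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("stack must be (frames, rows, cols)")
    n_frames, n_rows, n_cols = stack.shape
    if origin_px is None:
        origin_px = ((n_rows - 1) / 2.0, (n_cols - 1) / 2.0)
    times = np.arange(n_frames) * frame_interval_ms
    ts = TraceSet()
    flat = stack.reshape(n_frames, -1)
    for roi in rois:
        # x to the right (columns), y down (rows)
        rr = origin_px[0] + roi.y_um / pixel_size_um
        cc = origin_px[1] + roi.x_um / pixel_size_um
        rad = roi.radius_um / pixel_size_um
        if rr - rad < -0.5 or rr + rad > n_rows - 0.5 or cc - rad < -0.5 or cc + rad > n_cols - 0.5:
            raise ValueError(f"ROI {roi.cell_id!r} extends outside the frame")
        mask = roi_mask((n_rows, n_cols), (rr, cc), rad)
        if not mask.any():
            raise ValueError(f"ROI {roi.cell_id!r} covers no pixel centers")
        values = flat[:, mask.ravel()].mean(axis=1)
        ts.add(
            Trace(
                cell_id=roi.cell_id,
                modality=modality,
                times_ms=times,
                values=values,
                position_um=(roi.x_um, roi.y_um),
                source="stack",
            )
        )
    return ts
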