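"""Concentric-ring segmentation and 2D/3D synchrony.

The field of view is partitioned into four regions by circles centred on
the organoid: ``Center`` is the organoid itself (r <= r0), ``Close``,
``Mid`` and ``Far`` are successive annuli of fixed spacing (default
185 µm).  Boundary radii belong to the inner region.  Synchrony between
the organoid and each surrounding cell is quantified by a normalized
cross-correlation over lags; synchronous beating shows its maximum at
lag zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from orgwave.presets import REGIONS

DEFAULT_RING_SPACING_UM = 185.0
DEFAULT_MAX_LAG_S = 2.0


@dataclass(frozen=True)
class RegionMap:
    """Annulus geometry around the organoid."""

    center_um: tuple[float, float]
    organoid_radius_um: float
    ring_spacing_um: float = DEFAULT_RING_SPACING_UM

    def __post_init__(self) -> None:
        if self.ring_spacing_um <= 0:
            raise ValueError("ring_spacing_um must be positive")
        if self.organoid_radius_um < 0:
            raise ValueError("organoid_radius_um must be non-negative")

    def boundaries(self) -> tuple[float, float, float]:
        r0, d = self.organoid_radius_um, self.ring_spacing_um
        return (r0, r0 + d, r0 + 2 * d)


def assign_region(position_um: tuple[float, float], region_map: RegionMap) -> str:
    """Region label for a position (µm); boundaries go to the inner region."""
    dx = position_um[0] - region_map.center_um[0]
    dy = position_um[1] - region_map.center_um[1]
    r = float(np.hypot(dx, dy))
    b0, b1, b2 = region_map.boundaries()
    if r <= b0:
        return "Center"
    if r <= b1:
        return "Close"
    if r <= b2:
        return "Mid"
    return "Far"


def region_map_from_rois(rois) -> RegionMap:
    """Geometry inferred from the ROI list: the organoid ROI sets r0."""
    organoid = [r for r in rois if r.is_organoid]
    if len(organoid) != 1:
        raise ValueError("exactly one ROI must be flagged is_organoid")
    o = organoid[0]
    return RegionMap(center_um=(o.x_um, o.y_um), organoid_radius_um=o.radius_um)


def aggregate_by_region(summaries: pd.DataFrame, metrics: list[str],
                        region_column: str = "region") -> pd.DataFrame:
    """Per-region n / mean / SEM for each metric.

    Empty regions appear with n = 0; single-cell regions report SEM 0 and
    are recognizable by n = 1.
    """
    rows = []
    for region in REGIONS:
        sub = summaries[summaries[region_column] == region]
        for metric in metrics:
            vals = sub[metric].dropna().to_numpy() if len(sub) else np.array([])
            n = len(vals)
            rows.append(
                {
                    "region": region,
                    "metric": metric,
                    "n": n,
                    "mean": float(np.mean(vals)) if n else np.nan,
                    "sem": float(np.std(vals, ddof=1) / np.sqrt(n)) if n > 1 else (0.0 if n == 1 else np.nan),
                }
            )
    return pd.DataFrame(rows)


def heatmap_table(summaries: pd.DataFrame, metric: str) -> pd.DataFrame:
    """(x, y, value) records per cell, coordinates relative to the organoid."""
    required = {"x_um", "y_um", metric}
    missing = required - set(summaries.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    out = summaries[["x_um", "y_um", metric]].copy()
    return out.rename(columns={metric: "value"}).reset_index(drop=True)


@dataclass
class XCorrResult:
    """Normalized cross-correlation over a symmetric lag range."""

    lags: np.ndarray  # sample units
    values: np.ndarray  # Pearson r per lag, in [-1, 1]
    argmax_lag: int

    @property
    def peak_value(self) -> float:
        return float(self.values[np.where(self.lags == self.argmax_lag)[0][0]])


def cross_correlate(a: np.ndarray, b: np.ndarray, max_lag: int) -> XCorrResult:
    """Pearson correlation of ``a`` and ``b`` at integer lags.

    At lag ``k`` the overlap pairs ``a[t]`` with ``b[t + k]``; ties in the
    maximum resolve toward lag 0.  Zero-variance inputs raise, since the
    correlation is undefined.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim != 1 or b.ndim != 1 or len(a) != len(b):
        raise ValueError("inputs must be 1D arrays of equal length")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("cross-correlation undefined for non-finite input")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("cross-correlation undefined for zero-variance input")
    max_lag = int(max_lag)
    lags = np.arange(-max_lag, max_lag + 1)
    values = np.empty(len(lags))
    for i, k in enumerate(lags):
        if k >= 0:
            xa, xb = a[: len(a) - k], b[k:]
        else:
            xa, xb = a[-k:], b[: len(b) + k]
        if len(xa) < 3 or np.std(xa) == 0 or np.std(xb) == 0:
            values[i] = np.nan
            continue
        values[i] = float(np.corrcoef(xa, xb)[0, 1])
    finite = np.isfinite(values)
    best = np.nanmax(values[finite])
    # ties (to numerical precision) break toward zero lag
    tied = finite & (values >= best - 1e-12)
    argmax = int(lags[tied][np.argmin(np.abs(lags[tied]))])
    return XCorrResult(lags=lags, values=values, argmax_lag=argmax)


def synchrony_table(traces, modality: str = "calcium",
                    max_lag_s: float = DEFAULT_MAX_LAG_S,
                    reference_id: str = "organoid") -> pd.DataFrame:
    """Argmax lag and peak correlation of every cell against the reference."""
    ref = traces.get(reference_id, modality)
    max_lag = int(round(max_lag_s * 1000.0 / ref.dt_ms))
    rows = []
    for tr in traces.traces(modality):
        if tr.cell_id == reference_id:
            continue
        if np.std(tr.values) == 0:
            continue
        try:
            xc = cross_correlate(ref.values, tr.values, max_lag)
        except ValueError as exc:
            raise ValueError(
                f"synchrony failed for cell {tr.cell_id!r} vs {reference_id!r}: {exc}"
            ) from exc
        rows.append(
            {
                "cell_id": tr.cell_id,
                "argmax_lag": xc.argmax_lag,
                "argmax_lag_ms": xc.argmax_lag * ref.dt_ms,
                "peak_correlation": xc.peak_value,
            }
        )
    return pd.DataFrame(rows, columns=["cell_id", "argmax_lag", "argmax_lag_ms", "peak_correlation"])
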