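"""Domain types and the default control / doxorubicin scene presets.

The preset numbers are the study conditions the generator emulates: group
mean transient and beat kinetics, cell counts, beating fractions, regional
gradients and abnormality mixes for a central cardiomyocyte organoid with
a surrounding 2D monolayer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

REGIONS = ("Center", "Close", "Mid", "Far")

ABNORMALITIES = (
    "normal",
    "bifid",
    "plateau_uptake",
    "early_second_upstroke",
    "spontaneous_release",
)

#: relative tolerance for additive width / duration identities
_SUM_RTOL = 1e-6


@dataclass(frozen=True)
class TransientShapeParams:
    """Target functionals of one calcium transient.

    Widths are measured at 20% of the peak amplitude above baseline:
    ``left_width20_ms`` (20% crossing to apex) is the release/influx time,
    ``right_width20_ms`` (apex to 20% crossing) the reuptake/efflux time,
    and their sum the full width.  ``max_rise_aupms`` is the maximum first
    derivative during the upstroke and ``auc_aums`` the area above baseline
    between the two 20% crossings.
    """

    peak_width20_ms: float
    left_width20_ms: float
    right_width20_ms: float
    max_rise_aupms: float
    auc_aums: float
    period_ms: float
    amplitude_au: float | None = None  # realized during calibration
    abnormality: str = "normal"

    def __post_init__(self) -> None:
        for name in (
            "peak_width20_ms",
            "left_width20_ms",
            "right_width20_ms",
            "max_rise_aupms",
            "auc_aums",
            "period_ms",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        total = self.left_width20_ms + self.right_width20_ms
        if not math.isclose(total, self.peak_width20_ms, rel_tol=_SUM_RTOL):
            raise ValueError(
                "left_width20_ms + right_width20_ms must equal peak_width20_ms "
                f"({total} != {self.peak_width20_ms})"
            )
        if self.abnormality not in ABNORMALITIES:
            raise ValueError(f"unknown abnormality {self.abnormality!r}")
        if self.abnormality == "normal" and self.period_ms <= self.peak_width20_ms:
            raise ValueError("period_ms must exceed peak_width20_ms for normal morphology")

    def scaled(self, time_factor: float = 1.0, abnormality: str | None = None):
        """Rescale the transient kinetics by a common time factor.

        Widths and AUC scale with ``time_factor``; the maximum rate of rise
        scales inversely (same amplitude, slower kinetics).
        """
        return replace(
            self,
            peak_width20_ms=self.peak_width20_ms * time_factor,
            left_width20_ms=self.left_width20_ms * time_factor,
            right_width20_ms=self.right_width20_ms * time_factor,
            max_rise_aupms=self.max_rise_aupms / time_factor,
            auc_aums=self.auc_aums * time_factor,
            abnormality=self.abnormality if abnormality is None else abnormality,
        )


@dataclass(frozen=True)
class BeatShapeParams:
    """Target kinetics of one contractile beat (all durations in seconds)."""

    systole_s: float
    diastole_s: float
    beat_duration_s: float
    period_s: float
    amplitude_au: float = 1.0

    def __post_init__(self) -> None:
        for name in ("systole_s", "diastole_s", "beat_duration_s", "period_s", "amplitude_au"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        total = self.systole_s + self.diastole_s
        if not math.isclose(total, self.beat_duration_s, rel_tol=_SUM_RTOL):
            raise ValueError(
                "systole_s + diastole_s must equal beat_duration_s "
                f"({total} != {self.beat_duration_s})"
            )
        if self.period_s < self.beat_duration_s:
            raise ValueError("period_s must be at least beat_duration_s")

    def scaled(self, time_factor: float = 1.0):
        return replace(
            self,
            systole_s=self.systole_s * time_factor,
            diastole_s=self.diastole_s * time_factor,
            beat_duration_s=self.beat_duration_s * time_factor,
        )


def beat_params(systole_s: float, diastole_s: float, period_s: float,
                amplitude_au: float = 1.0) -> BeatShapeParams:
    """Build BeatShapeParams with beat duration tied to systole + diastole."""
    return BeatShapeParams(
        systole_s=systole_s,
        diastole_s=diastole_s,
        beat_duration_s=systole_s + diastole_s,
        period_s=period_s,
        amplitude_au=amplitude_au,
    )


@dataclass(frozen=True)
class ScenePreset:
    """One experimental condition for the synthetic scene generator."""

    group: str
    mean_cell_count: float
    beating_fraction: float
    abnormal_fraction_by_region: tuple[float, float, float, float]
    transient_params_by_region: tuple[TransientShapeParams, ...]
    beat_params_by_region: tuple[BeatShapeParams, ...]
    organoid_radius_um: float = 150.0
    ring_spacing_um: float = 185.0
    radial_density_decay: float = 1.0 / 200.0  # per µm, rate of outward thinning
    noise_sd_frac: float = 0.02  # fluorescence noise SD as a fraction of amplitude
    # per-cell lognormal jitter (CV) on kinetic parameters
    kinetic_jitter_cv: float = 0.08
    beat_jitter_cv: float = 0.06
    #: kinetic time factor applied to cells with morphology-level
    #: abnormalities (slows widths and AUC by 1.3x and blunts the max
    #: upstroke slope to ~0.77x, reflecting impaired calcium handling)
    abnormal_width_factor: float = 1.30
    #: amplitude factor for spontaneous-release cells: a diastolic SR leak
    #: depletes the releasable pool, so the systolic transient is smaller
    #: (kinetics stay normal, which also leaves the diastolic interval
    #: free for the leak events themselves)
    spont_amplitude_factor: float = 0.75

    def __post_init__(self) -> None:
        if self.group not in ("control", "dox"):
            raise ValueError("group must be 'control' or 'dox'")
        if not 0 <= self.beating_fraction <= 1:
            raise ValueError("beating_fraction must lie in [0, 1]")
        if len(self.abnormal_fraction_by_region) != 4:
            raise ValueError("abnormal_fraction_by_region needs 4 entries (Center..Far)")
        if any(not 0 <= f <= 1 for f in self.abnormal_fraction_by_region):
            raise ValueError("abnormal fractions must lie in [0, 1]")
        if len(self.transient_params_by_region) != 4:
            raise ValueError("transient_params_by_region needs 4 entries (Center..Far)")
        if len(self.beat_params_by_region) != 4:
            raise ValueError("beat_params_by_region needs 4 entries (Center..Far)")
        if self.ring_spacing_um <= 0:
            raise ValueError("ring_spacing_um must be positive")
        if self.radial_density_decay <= 0:
            raise ValueError("radial_density_decay must be positive")


# ---------------------------------------------------------------------------
# Default group presets.
#
# Group-mean transient functionals and beat durations are the printed study
# means; the implied common rhythm is 1.1876 s (organoid beat duration
# 0.4881 s at a period-normalized ratio of 0.411 s/s).  Regional gradients
# are mild monotone multipliers (kinetics slow with distance from the
# organoid); abnormality mixes rise with distance and average to the
# group-level abnormal proportions (49.6% control, 68.6% dox) under the
# radial occupancy implied by each group's density decay.
# ---------------------------------------------------------------------------

_PERIOD_CONTROL_MS = 1187.6
_PERIOD_DOX_MS = 2000.0

_CONTROL_CA = TransientShapeParams(
    peak_width20_ms=556.2,
    left_width20_ms=182.1,
    right_width20_ms=374.1,
    max_rise_aupms=0.090,
    auc_aums=2823.0,
    period_ms=_PERIOD_CONTROL_MS,
)

_DOX_CA = TransientShapeParams(
    peak_width20_ms=1063.2,
    left_width20_ms=393.6,
    right_width20_ms=669.6,
    max_rise_aupms=0.060,
    auc_aums=4745.0,
    period_ms=_PERIOD_DOX_MS,
)

#: monotone Center→Far kinetic slowing used inside full scenes
_REGION_TIME_FACTORS = (0.94, 1.0, 1.06, 1.12)

ORGANOID_BEAT = beat_params(systole_s=0.207, diastole_s=0.281, period_s=1.1876)
CONTROL_2D_BEAT = beat_params(systole_s=0.159, diastole_s=0.252, period_s=1.1876)
# Printed dox systole/diastole (0.293 / 0.400 s) sum to 0.693 s, which the
# beat-duration identity takes precedence over the separately printed total.
DOX_2D_BEAT = beat_params(systole_s=0.293, diastole_s=0.400, period_s=_PERIOD_DOX_MS / 1000.0)
DOX_ORGANOID_BEAT = beat_params(systole_s=0.207, diastole_s=0.281, period_s=_PERIOD_DOX_MS / 1000.0)

_BEAT_REGION_FACTORS = (1.0, 1.0, 1.05, 1.10)


def _regional_transients(base: TransientShapeParams) -> tuple[TransientShapeParams, ...]:
    return tuple(base.scaled(f) for f in _REGION_TIME_FACTORS)


def _regional_beats(center: BeatShapeParams, cell: BeatShapeParams) -> tuple[BeatShapeParams, ...]:
    return (center,) + tuple(cell.scaled(f) for f in _BEAT_REGION_FACTORS[1:])


CONTROL = ScenePreset(
    group="control",
    mean_cell_count=111.2,
    beating_fraction=0.729,
    abnormal_fraction_by_region=(0.30, 0.42, 0.55, 0.68),
    transient_params_by_region=_regional_transients(_CONTROL_CA),
    beat_params_by_region=_regional_beats(ORGANOID_BEAT, CONTROL_2D_BEAT),
    radial_density_decay=1.0 / 220.0,
)

DOX = ScenePreset(
    group="dox",
    mean_cell_count=81.29,
    beating_fraction=0.485,
    abnormal_fraction_by_region=(0.45, 0.63, 0.82, 0.92),
    transient_params_by_region=_regional_transients(_DOX_CA),
    beat_params_by_region=_regional_beats(DOX_ORGANOID_BEAT, DOX_2D_BEAT),
    radial_density_decay=1.0 / 140.0,
)

PRESETS = {"control": CONTROL, "dox": DOX}
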