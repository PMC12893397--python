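"""Continuous-time kinetic templates behind the synthetic traces.

A calcium transient is modelled by a piecewise C1 template with four free
parameters: a raised-cosine upstroke of duration ``t1`` carrying the
maximum rate of rise, a quadratic "shoulder" of duration ``d`` that eases
into the apex, and an exponential recovery with time constant ``tau``
(accelerated once the signal falls below 10% of the apex so the trace
returns to baseline well before the next beat).  The template's
continuous-time functionals — left/right widths at 20% of maximum,
maximum upstroke derivative, and area above baseline between the 20%
crossings — have closed forms, so calibration to target functionals is an
exact algebraic solve rather than a black-box fit.

Contractile beats are modelled as piecewise-linear pulses; with the 10%
onset/offset convention used downstream, a linear limb of duration ``T``
contributes 0.9 T to the measured phase, which makes the ground-truth
bookkeeping exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from orgwave.presets import BeatShapeParams, TransientShapeParams

#: fraction of the apex amplitude reached by the raised-cosine upstroke
UPSTROKE_FRACTION = 0.45
#: recovery level at which the exponential tail accelerates
TAIL_SWITCH = 0.12
#: acceleration factor of the sub-threshold tail (the trace settles at the
#: diastolic baseline well before the next beat)
TAIL_ACCEL = 10.0

_LN5 = math.log(5.0)


class CalibrationError(ValueError):
    """Raised when no template matches the requested functionals."""


@dataclass(frozen=True)
class CalibratedWaveform:
    """A calibrated transient template (times in ms, values in a.u.)."""

    amplitude: float  # apex height above baseline
    upstroke_ms: float  # raised-cosine phase duration t1
    shoulder_ms: float  # quadratic phase duration d
    decay_ms: float  # recovery time constant tau
    h1: float = UPSTROKE_FRACTION

    @property
    def peak_time_ms(self) -> float:
        """Time of the apex relative to the foot of the upstroke."""
        return self.upstroke_ms + self.shoulder_ms

    @property
    def support_ms(self) -> float:
        """Duration after which the template is negligible (<0.2% apex)."""
        tail0 = self.decay_ms * math.log(1.0 / TAIL_SWITCH)
        tail1 = (self.decay_ms / TAIL_ACCEL) * math.log(TAIL_SWITCH / 2e-3)
        return self.peak_time_ms + tail0 + tail1

    def __call__(self, t: np.ndarray) -> np.ndarray:
        """Evaluate the template at times ``t`` (ms past the foot)."""
        t = np.asarray(t, dtype=float)
        A, t1, d, tau, h1 = (
            self.amplitude,
            self.upstroke_ms,
            self.shoulder_ms,
            self.decay_ms,
            self.h1,
        )
        tp = t1 + d
        y = np.zeros_like(t)

        m = (t >= 0) & (t < t1)
        y[m] = 0.5 * h1 * A * (1.0 - np.cos(np.pi * t[m] / t1))

        m = (t >= t1) & (t < tp)
        s = (t[m] - t1) / d
        y[m] = h1 * A + (1.0 - h1) * A * s * s

        switch = tau * math.log(1.0 / TAIL_SWITCH)
        u = t - tp
        m = (u >= 0) & (u < switch)
        y[m] = A * np.exp(-u[m] / tau)
        m = u >= switch
        y[m] = TAIL_SWITCH * A * np.exp(-(u[m] - switch) * TAIL_ACCEL / tau)
        return y


def _upstroke_constants(h1: float) -> tuple[float, float, float]:
    """Closed-form constants of the raised-cosine phase for height h1.

    Returns (crossing fraction of t1 where the template passes 20% of the
    apex, slope constant k with S = k*A/t1, area coefficient of the
    upstroke above the 20% crossing in units of A*t1).
    """
    if not 0.2 < h1 < 1.0:
        raise CalibrationError("upstroke fraction must exceed the 20% threshold")
    tc = math.acos(1.0 - 0.4 / h1) / math.pi  # fraction of t1
    k_slope = math.pi * h1 / 2.0
    area = 0.5 * h1 * ((1.0 - tc) + math.sin(math.pi * tc) / math.pi)
    return tc, k_slope, area


def calibrate_transient_shape(targets: TransientShapeParams,
                              h1: float = UPSTROKE_FRACTION) -> CalibratedWaveform:
    """Solve for the template matching four target functionals exactly.

    The targets are ``left_width20_ms`` (L), ``right_width20_ms`` (R),
    ``max_rise_aupms`` (S) and ``auc_aums`` (U).  With the template above:

    * the recovery constant follows from R alone, ``tau = R / ln 5``;
    * S pins the upstroke duration through ``t1 = (pi h1 / 2) A / S``;
    * L fixes the shoulder, ``d = L - (1 - tc) t1``;
    * U then reduces to a quadratic in the apex amplitude A.

    The smaller quadratic root is the physical branch (it degenerates to
    ``A = U / p`` as the upstroke becomes instantaneous).  Infeasible target
    combinations raise :class:`CalibrationError` naming the functional that
    cannot be met.
    """
    L = targets.left_width20_ms
    R = targets.right_width20_ms
    S = targets.max_rise_aupms
    U = targets.auc_aums

    tc, k_slope, a_up = _upstroke_constants(h1)
    b_sh = (1.0 + 2.0 * h1) / 3.0  # shoulder area coefficient (A*d units)
    c_fall = 0.8 / _LN5  # recovery area coefficient (A*R units)

    tau = R / _LN5

    # U = q*A^2/S + p*A with q < 0 for any h1 in (0.2, 1)
    q = k_slope * (a_up - b_sh * (1.0 - tc))
    p = b_sh * L + c_fall * R
    alpha = -q / S
    disc = p * p - 4.0 * alpha * U
    if disc < 0:
        raise CalibrationError(
            "auc_aums is too large for the requested widths and max slope "
            "(no amplitude satisfies the area functional)"
        )
    A = (p - math.sqrt(disc)) / (2.0 * alpha)
    if A <= 0:
        raise CalibrationError("area functional yields a non-positive amplitude")

    t1 = k_slope * A / S
    d = L - (1.0 - tc) * t1
    if d <= 0:
        raise CalibrationError(
            "left_width20_ms cannot be met: the upstroke implied by "
            "max_rise_aupms is longer than the requested release width"
        )
    v_end = 2.0 * (1.0 - h1) * A / d
    if v_end >= S:
        raise CalibrationError(
            "max_rise_aupms cannot be met on the upstroke: the shoulder "
            "slope at the apex would exceed the requested maximum slope"
        )
    return CalibratedWaveform(amplitude=A, upstroke_ms=t1, shoulder_ms=d,
                              decay_ms=tau, h1=h1)


def waveform_functionals(wf: CalibratedWaveform, dt_ms: float = 0.1) -> dict:
    """Measure the template's functionals on a dense time grid.

    Numerical re-measurement of the calibrated closed forms; used for
    verification and as a convenience for callers that need the realized
    functionals of a template (e.g. after composing abnormal variants).
    """
    t = np.arange(0.0, wf.support_ms + dt_ms, dt_ms)
    y = wf(t)
    i = int(np.argmax(y))
    apex = y[i]
    thr = 0.2 * apex
    above = y >= thr
    idx = np.flatnonzero(above)
    j0, j1 = idx[0], idx[-1]
    # linear interpolation at both crossings
    tl = t[j0 - 1] + (thr - y[j0 - 1]) * dt_ms / (y[j0] - y[j0 - 1]) if j0 > 0 else t[0]
    tr = t[j1] + (thr - y[j1]) * dt_ms / (y[j1 + 1] - y[j1]) if j1 + 1 < len(t) else t[-1]
    rise = slice(j0, i + 1)
    slope = float(np.diff(y[rise]).max() / dt_ms) if i > j0 else 0.0
    m = (t >= tl) & (t <= tr)
    auc = float(np.trapezoid(y[m], t[m]))
    return {
        "amplitude": float(apex),
        "left_width20_ms": float(t[i] - tl),
        "right_width20_ms": float(tr - t[i]),
        "peak_width20_ms": float(tr - tl),
        "max_rise_aupms": slope,
        "auc_aums": auc,
    }


@dataclass(frozen=True)
class BeatPulse:
    """Piecewise-linear contraction pulse (times in seconds)."""

    rise_s: float
    fall_s: float
    amplitude: float

    @property
    def peak_time_s(self) -> float:
        return self.rise_s

    @property
    def support_s(self) -> float:
        return self.rise_s + self.fall_s

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        y = np.zeros_like(t)
        m = (t >= 0) & (t < self.rise_s)
        y[m] = self.amplitude * t[m] / self.rise_s
        m = (t >= self.rise_s) & (t < self.support_s)
        y[m] = self.amplitude * (1.0 - (t[m] - self.rise_s) / self.fall_s)
        return y


def calibrate_beat_pulse(targets: BeatShapeParams,
                         threshold_frac: float = 0.1) -> BeatPulse:
    """Build the pulse whose 10%-threshold phases equal the targets.

    On a linear limb the onset (offset) sits at ``threshold_frac`` of the
    limb, so a systole of ``s`` seconds requires a rise of
    ``s / (1 - threshold_frac)``.
    """
    if not 0 < threshold_frac < 0.5:
        raise ValueError("threshold_frac must lie in (0, 0.5)")
    scale = 1.0 - threshold_frac
    pulse = BeatPulse(
        rise_s=targets.systole_s / scale,
        fall_s=targets.diastole_s / scale,
        amplitude=targets.amplitude_au,
    )
    if pulse.support_s >= targets.period_s:
        raise CalibrationError("beat pulse does not fit within the period")
    return pulse
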