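"""Arterial flow waveforms and pulsatility metrics.

A :class:`FlowWaveform` holds one cardiac cycle of volumetric flow rate
Q(t) (ml/s) for a named artery segment together with the R-R interval of
the cycle.  From it we compute the two pulsatility measures used in
cerebral 4D-flow studies:

* **Gosling's pulsatility index (PI)** — (systolic max − diastolic min)
  divided by the cycle-mean flow rate; dimensionless.
* **Flow volume pulsatility (FVP)** — the peak-to-trough range of the
  cumulative integral of the mean-subtracted waveform, i.e. the volume by
  which the downstream arterial tree expands and recoils each beat; ml.

Both measures can be standardized by the R-R interval (divided by it, in
seconds) so that subjects with faster heart rates — who experience more
pulsatile excursions per unit time — score higher for the same per-beat
excursion.

The cycle is treated as periodic: the last sample connects back to the
first at t = t0 + RR.  Cycle means and cumulative volumes are evaluated on
a periodic cubic-spline interpolant of the samples, and the volume curve's
extrema are located exactly (at the roots of Q(t) − mean), which keeps the
metrics accurate at the coarse 20-phase temporal resolution of gated
reconstructions.  PI extremes are taken over the raw samples with no
smoothing, since gated data are already temporally smoothed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import DomainError, MissingDataError, ValidationError

ARTERIES = ("ICA", "M1", "M3", "BA")
SIDES = ("left", "right", "midline", "unknown", "bilateral")

__all__ = [
    "ARTERIES",
    "SIDES",
    "FlowWaveform",
    "PulsatilityMetrics",
    "mean_flow",
    "compute_pi",
    "compute_fvp",
    "standardize_by_rr",
    "compute_metrics",
    "bilateral_average",
    "total_cbf",
]


@dataclass(frozen=True)
class FlowWaveform:
    """One cardiac cycle of flow rate for one artery segment.

    Parameters
    ----------
    times
        Sample times in seconds within the cycle; strictly increasing,
        all in ``[0, rr_interval)``.
    flow_rates
        Flow rate in ml/s at each sample time.
    rr_interval
        Cycle duration (R-R interval) in seconds.
    artery, side
        Segment labels (``ICA``/``M1``/``M3``/``BA``; ``left``/``right``/
        ``midline``/``unknown``).
    """

    times: np.ndarray
    flow_rates: np.ndarray
    rr_interval: float
    artery: str = "ICA"
    side: str = "unknown"

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        q = np.asarray(self.flow_rates, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "flow_rates", q)
        if t.ndim != 1 or q.ndim != 1 or t.size != q.size:
            raise ValidationError("times and flow_rates must be 1-D of equal length")
        if t.size < 3:
            raise ValidationError("a waveform needs at least 3 samples")
        if not np.all(np.isfinite(t)) or not np.all(np.isfinite(q)):
            raise ValidationError("times and flow_rates must be finite")
        if not (np.isfinite(self.rr_interval) and self.rr_interval > 0):
            raise ValidationError("rr_interval must be a positive finite number")
        if np.any(np.diff(t) <= 0):
            raise ValidationError("times must be strictly increasing")
        if t[0] < 0 or t[-1] >= self.rr_interval:
            raise ValidationError("times must lie in [0, rr_interval)")
        if self.artery not in ARTERIES:
            raise ValidationError(f"artery must be one of {ARTERIES}, got {self.artery!r}")
        if self.side not in SIDES:
            raise ValidationError(f"side must be one of {SIDES}, got {self.side!r}")

    @property
    def n_samples(self) -> int:
        return int(self.times.size)

    def _closed(self):
        """Samples extended with the periodic closing point (t0 + RR, Q0)."""
        t = np.append(self.times, self.times[0] + self.rr_interval)
        q = np.append(self.flow_rates, self.flow_rates[0])
        return t, q

    def periodic_spline(self) -> CubicSpline:
        """Periodic cubic-spline interpolant of one closed cycle."""
        t, q = self._closed()
        return CubicSpline(t, q, bc_type="periodic")

    def with_flow(self, flow_rates: np.ndarray) -> "FlowWaveform":
        return replace(self, flow_rates=np.asarray(flow_rates, dtype=float))


@dataclass(frozen=True)
class PulsatilityMetrics:
    """PI and FVP for one artery segment, raw and R-R standardized.

    ``pi_raw`` is dimensionless; ``pi_std`` has units 1/s. ``fvp_raw`` is
    in ml; ``fvp_std`` in ml/s.  ``mean_flow`` is the cycle-mean flow rate
    in ml/s.
    """

    pi_raw: float
    pi_std: float
    fvp_raw: float
    fvp_std: float
    mean_flow: float
    artery: str = "ICA"
    side: str = "unknown"

    def __post_init__(self):
        if self.mean_flow > 0 and self.pi_raw < 0:
            raise ValidationError("PI cannot be negative when mean flow is positive")
        if self.fvp_raw < -1e-12:
            raise ValidationError("FVP is a range and cannot be negative")


def mean_flow(waveform: FlowWaveform) -> float:
    """Time-weighted cycle-mean flow rate in ml/s.

    The integral of the periodic interpolant over one full cycle divided by
    the R-R interval.
    """
    spline = waveform.periodic_spline()
    t0 = waveform.times[0]
    return float(spline.integrate(t0, t0 + waveform.rr_interval)) / waveform.rr_interval


def compute_pi(waveform: FlowWaveform) -> float:
    """Gosling's pulsatility index: (max Q − min Q) / mean Q.

    Extremes are the raw sampled maximum and minimum.  Raises
    :class:`DomainError` when the cycle-mean flow is not positive (PI is
    undefined for zero or net-retrograde flow).
    """
    mean = mean_flow(waveform)
    if mean <= 0:
        raise DomainError(f"PI undefined for non-positive mean flow ({mean:.4g} ml/s)")
    q = waveform.flow_rates
    return float((q.max() - q.min()) / mean)


def compute_fvp(waveform: FlowWaveform) -> float:
    """Flow volume pulsatility in ml.

    The mean flow rate is subtracted from the waveform and the residual is
    integrated over the cycle; FVP is the difference between the maximum
    and minimum of that cumulative volume curve.  The volume curve's
    extrema fall where Q(t) crosses its mean, so they are located exactly
    as roots of the residual interpolant (the closing periodic segment
    included).  Invariant to adding a constant to Q.
    """
    mean = mean_flow(waveform)
    t, q = waveform._closed()
    residual = CubicSpline(t, q - mean, bc_type="periodic")
    volume = residual.antiderivative()
    crossings = residual.roots(extrapolate=False)
    candidates = np.concatenate([t[[0, -1]], np.atleast_1d(crossings)])
    candidates = candidates[(candidates >= t[0]) & (candidates <= t[-1])]
    values = volume(candidates)
    return float(values.max() - values.min())


def standardize_by_rr(metric: float, rr_interval: float) -> float:
    """Divide a per-beat pulsatility measure by the R-R interval (s).

    Normalizes to a 1-second reference cycle: a subject with a shorter
    cycle (higher heart rate) accrues the same per-beat excursion more
    often per unit time, so the standardized value is larger.
    """
    if not (np.isfinite(rr_interval) and rr_interval > 0):
        raise ValidationError("rr_interval must be positive")
    return metric / rr_interval


def compute_metrics(waveform: FlowWaveform) -> PulsatilityMetrics:
    """All pulsatility metrics for one waveform."""
    mean = mean_flow(waveform)
    pi = compute_pi(waveform)
    fvp = compute_fvp(waveform)
    rr = waveform.rr_interval
    return PulsatilityMetrics(
        pi_raw=pi,
        pi_std=standardize_by_rr(pi, rr),
        fvp_raw=fvp,
        fvp_std=standardize_by_rr(fvp, rr),
        mean_flow=mean,
        artery=waveform.artery,
        side=waveform.side,
    )


_NUMERIC_FIELDS = ("pi_raw", "pi_std", "fvp_raw", "fvp_std", "mean_flow")


def bilateral_average(
    left: Optional[PulsatilityMetrics], right: Optional[PulsatilityMetrics]
) -> PulsatilityMetrics:
    """Mean of the two sides' metrics; contralateral fallback when one is missing.

    For paired arteries the left and right measurements are averaged
    field-wise.  If one side is missing, the contralateral side's values
    are used as-is.  Both missing raises :class:`MissingDataError`, which
    propagates as a missing metric for that subject/segment.
    """
    if left is None and right is None:
        raise MissingDataError("pulsatility metric missing on both sides")
    if left is None:
        return replace(right, side="bilateral")
    if right is None:
        return replace(left, side="bilateral")
    if left.artery != right.artery:
        raise ValidationError(
            f"cannot average across arteries ({left.artery} vs {right.artery})"
        )
    means = {f: (getattr(left, f) + getattr(right, f)) / 2.0 for f in _NUMERIC_FIELDS}
    return PulsatilityMetrics(artery=left.artery, side="bilateral", **means)


def total_cbf(
    ica_left: FlowWaveform, ica_right: FlowWaveform, basilar: FlowWaveform, *, per_minute: bool = False
) -> float:
    """Total cerebral blood flow: sum of mean flows of both ICAs and the BA.

    Returned in ml/s, or ml/min with ``per_minute=True``.  There is no
    contralateral fallback for tCBF: any missing vessel raises
    :class:`MissingDataError`.
    """
    vessels = {"left ICA": ica_left, "right ICA": ica_right, "basilar artery": basilar}
    for name, wf in vessels.items():
        if wf is None:
            raise MissingDataError(f"{name} waveform is missing; tCBF has no fallback")
    tcbf = sum(mean_flow(wf) for wf in vessels.values())
    return tcbf * 60.0 if per_minute else tcbf
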