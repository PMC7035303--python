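"""Synthetic pulsatile flow: parametric waveforms, a voxelized vessel
phantom, retrospective gating, and centerline flow extraction.

This module emulates the acquisition side of a cerebral 4D-flow study on
known ground truth:

1. :func:`generate_waveform` builds a cardiac flow waveform Q(t) from a
   small set of physiological parameters (mean flow, pulse amplitude,
   systolic peak timing/width, optional dicrotic wave, noise).
2. :func:`build_phantom` fills a voxel grid with the time-resolved
   3-component velocity field of a tube carrying that waveform, with a
   fully developed (parabolic, Poiseuille) profile at every instant —
   closed-form truth at every voxel.
3. :func:`gated_reconstruction` emulates retrospective cardiac gating:
   samples acquired at pseudo-random times over many heartbeats are mapped
   to cardiac phase and binned into a small number of phases (20 by
   default) with linear temporal-interpolation weighting.
4. :func:`extract_centerline_flow` measures segment flow the way the
   post-processing scheme does: the through-plane flux averaged over six
   consecutive centerline voxels.

Units: geometry mm, velocities cm/s, flows ml/s, times s.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import (
    BoundaryError,
    ConfigurationError,
    ReconstructionError,
    ValidationError,
)
from .waveform import FlowWaveform

__all__ = [
    "WaveformParams",
    "VesselPhantom",
    "VelocityField4D",
    "generate_waveform",
    "waveform_function",
    "draw_rr_sequence",
    "straight_tube",
    "curved_tube",
    "build_phantom",
    "cross_section_flow",
    "extract_centerline_flow",
    "gated_reconstruction",
]

#: mm²·cm/s → ml/s  (1 cm/s over 1 mm² is 10 mm³/s = 0.01 ml)
CM_S_MM2_TO_ML_S = 0.01
#: ml/s over mm² → cm/s  (1 ml/s / 1 mm² is 1000 mm/s = 100 cm/s)
ML_S_PER_MM2_TO_CM_S = 100.0

_DENSE_GRID = 4096  # phase grid used to normalize the pulse shape


@dataclass(frozen=True)
class WaveformParams:
    """Parameters of the synthetic cardiac flow waveform.

    Defaults emulate an internal carotid artery of an elderly stroke
    cohort: mean flow ≈ 4.4 ml/s, pulsatility index ≈ 1.26, heart rate
    ≈ 67 bpm.  ``pulse_amplitude`` is the peak-to-trough excursion of the
    systolic pulse component in ml/s, so with no dicrotic wave the densely
    sampled PI equals ``pulse_amplitude / mean_flow``.
    """

    mean_flow: float = 4.4  # ml/s
    pulse_amplitude: float = 5.5  # ml/s, peak-to-trough
    systolic_peak_time: float = 0.16  # fraction of cycle
    peak_width: float = 0.16  # FWHM, fraction of cycle
    dicrotic_amplitude: float = 0.0  # ml/s, peak-to-trough
    rr_interval: float = 0.9  # s
    rr_jitter_sd: float = 0.0  # s
    noise_sd: float = 0.0  # ml/s
    seed: int = 0

    def __post_init__(self):
        if not self.mean_flow > 0:
            raise ValidationError("mean_flow must be positive")
        if self.pulse_amplitude < 0 or self.dicrotic_amplitude < 0:
            raise ValidationError("amplitudes must be non-negative")
        if not 0 < self.systolic_peak_time < 1:
            raise ValidationError("systolic_peak_time must be in (0, 1)")
        if not 0 < self.peak_width < 1:
            raise ValidationError("peak_width must be in (0, 1)")
        if not self.rr_interval > 0:
            raise ValidationError("rr_interval must be positive")
        if self.rr_jitter_sd < 0 or self.noise_sd < 0:
            raise ValidationError("rr_jitter_sd and noise_sd must be non-negative")


def _periodized_bump(phase: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    """Gaussian bump on the unit circle (periodized over nearby periods)."""
    sigma = fwhm / 2.3548200450309493  # FWHM → sigma
    out = np.zeros_like(phase, dtype=float)
    for k in (-2, -1, 0, 1, 2):
        out += np.exp(-0.5 * ((phase - center - k) / sigma) ** 2)
    return out


def _normalized_shape(center: float, fwhm: float):
    """Zero-mean, unit peak-to-peak pulse shape as a function of phase."""
    dense = np.arange(_DENSE_GRID) / _DENSE_GRID
    raw = _periodized_bump(dense, center, fwhm)
    offset = raw.mean()
    scale = raw.max() - raw.min()

    def shape(phase):
        return (_periodized_bump(np.asarray(phase, float), center, fwhm) - offset) / scale

    return shape


def waveform_function(params: WaveformParams) -> Callable[[np.ndarray], np.ndarray]:
    """Continuous noise-free Q(t) over one cycle, periodic in ``rr_interval``.

    The systolic pulse and the (optional) dicrotic wave are zero-mean in
    phase, so the continuous cycle mean equals ``mean_flow`` up to the
    normalization grid's resolution.
    """
    g_sys = _normalized_shape(params.systolic_peak_time, params.peak_width)
    dicrotic_center = (params.systolic_peak_time + 0.25) % 1.0
    g_dic = _normalized_shape(dicrotic_center, params.peak_width * 1.5)

    def q(t):
        phase = (np.asarray(t, float) / params.rr_interval) % 1.0
        out = (
            params.mean_flow
            + params.pulse_amplitude * g_sys(phase)
            + params.dicrotic_amplitude * g_dic(phase)
        )
        return out

    return q


def generate_waveform(
    params: WaveformParams,
    n_samples: int = 20,
    artery: str = "ICA",
    side: str = "unknown",
) -> FlowWaveform:
    """Sample the parametric waveform at ``n_samples`` uniform phases.

    Deterministic given ``params.seed`` (which drives the additive
    measurement noise).  With ``pulse_amplitude = 0`` and ``noise_sd = 0``
    the result is constant at ``mean_flow``.
    """
    if n_samples < 3:
        raise ValidationError("n_samples must be at least 3")
    times = np.arange(n_samples) / n_samples * params.rr_interval
    q = waveform_function(params)(times)
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        q = q + rng.normal(0.0, params.noise_sd, size=n_samples)
    return FlowWaveform(times, q, params.rr_interval, artery=artery, side=side)


def draw_rr_sequence(params: WaveformParams, n_cycles: int, seed: Optional[int] = None) -> np.ndarray:
    """R-R intervals for ``n_cycles`` heartbeats with Gaussian jitter."""
    if n_cycles < 1:
        raise ValidationError("n_cycles must be at least 1")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    rr = rng.normal(params.rr_interval, params.rr_jitter_sd, size=n_cycles)
    return np.clip(rr, 0.3 * params.rr_interval, None)


# ---------------------------------------------------------------------------
# Voxelized phantom
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VesselPhantom:
    """Voxelized tube geometry: an ordered centerline, lumen radius, grid.

    ``centerline_points`` are in mm, ordered along the vessel, spaced at
    most one voxel apart.  The lumen must be resolvable (radius at least
    two voxels) and must stay inside the grid with at least one radius of
    margin.
    """

    centerline_points: np.ndarray  # (N, 3) mm
    radius: float  # mm
    voxel_size: float  # mm, isotropic
    grid_shape: tuple  # (nx, ny, nz) voxels

    def __post_init__(self):
        pts = np.asarray(self.centerline_points, dtype=float)
        object.__setattr__(self, "centerline_points", pts)
        object.__setattr__(self, "grid_shape", tuple(int(s) for s in self.grid_shape))
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
            raise ValidationError("centerline_points must be (N>=2, 3)")
        if not self.voxel_size > 0:
            raise ValidationError("voxel_size must be positive")
        if self.radius < 2 * self.voxel_size:
            raise ValidationError(
                "radius must be at least 2 voxels for a resolvable lumen"
            )
        steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(steps > self.voxel_size * (1 + 1e-9)):
            raise ValidationError("consecutive centerline points must be <= 1 voxel apart")
        extent = np.asarray(self.grid_shape) * self.voxel_size
        lo = pts.min(axis=0)
        hi = pts.max(axis=0)
        if np.any(lo < self.radius - 1e-9) or np.any(hi > extent - self.radius + 1e-9):
            raise ValidationError("centerline must keep >= radius margin inside the grid")

    def tangents(self) -> np.ndarray:
        """Unit tangents at each centerline point (central differences)."""
        pts = self.centerline_points
        d = np.gradient(pts, axis=0)
        return d / np.linalg.norm(d, axis=1, keepdims=True)

    def voxel_centers_1d(self):
        h = self.voxel_size
        return tuple((np.arange(n) + 0.5) * h for n in self.grid_shape)


@dataclass(frozen=True)
class VelocityField4D:
    """Time-resolved 3-component velocity field on the phantom grid.

    ``velocities`` has shape ``(3, nx, ny, nz, n_phases)`` in cm/s;
    ``phase_times`` are the cardiac-phase sample times (s) and
    ``rr_interval`` the cycle duration used to build them.
    """

    velocities: np.ndarray  # (3, nx, ny, nz, n_phases), cm/s
    venc: float  # cm/s
    voxel_size: float  # mm
    phase_times: np.ndarray  # (n_phases,), s
    rr_interval: float  # s

    def __post_init__(self):
        v = np.asarray(self.velocities, dtype=float)
        pt = np.asarray(self.phase_times, dtype=float)
        object.__setattr__(self, "velocities", v)
        object.__setattr__(self, "phase_times", pt)
        if v.ndim != 5 or v.shape[0] != 3:
            raise ValidationError("velocities must have shape (3, nx, ny, nz, n_phases)")
        if v.shape[-1] != pt.size:
            raise ValidationError("phase_times length must match the phase axis")
        if not np.all(np.isfinite(v)):
            raise ValidationError("velocities must be finite everywhere")
        if not self.rr_interval > 0:
            raise ValidationError("rr_interval must be positive")

    @property
    def n_phases(self) -> int:
        return int(self.velocities.shape[-1])

    @property
    def grid_shape(self) -> tuple:
        return tuple(self.velocities.shape[1:4])


def straight_tube(
    radius: float = 2.0,
    voxel_size: float = 0.5,
    length: float = 8.0,
    pad: float = 1.0,
) -> VesselPhantom:
    """Axis-aligned straight tube along z, centerline on voxel centers.

    ``length`` is the centerline length in mm; ``pad`` extra transverse
    margin in mm beyond the mandatory one-radius margin.
    """
    h = voxel_size
    n_cross = int(np.ceil(2 * (radius + radius + pad) / h))
    if n_cross % 2 == 0:
        n_cross += 1  # odd → tube axis falls on a voxel center
    n_axial_pts = int(round(length / h)) + 1
    margin_vox = int(np.ceil(radius / h)) + 1
    nz = n_axial_pts + 2 * margin_vox
    cx = n_cross * h / 2.0
    z = (np.arange(n_axial_pts) + margin_vox + 0.5) * h
    pts = np.column_stack([np.full_like(z, cx), np.full_like(z, cx), z])
    return VesselPhantom(pts, radius, h, (n_cross, n_cross, nz))


def curved_tube(
    radius: float = 2.0,
    voxel_size: float = 0.5,
    curvature_radius: float = 20.0,
    arc_fraction: float = 0.25,
    pad: float = 1.0,
) -> VesselPhantom:
    """Tube bending through ``arc_fraction`` of a circle in the x-z plane."""
    h = voxel_size
    arc_len = 2 * np.pi * curvature_radius * arc_fraction
    n_pts = int(np.ceil(arc_len / h)) + 1
    theta = np.linspace(0.0, 2 * np.pi * arc_fraction, n_pts)
    margin = radius + pad
    x = curvature_radius * (1 - np.cos(theta)) + margin
    z = curvature_radius * np.sin(theta) + margin
    y = np.full_like(x, 0.0)
    pts = np.column_stack([x, y, z])
    lo = pts.min(axis=0) - margin
    pts = pts - lo  # shift so every point keeps `margin` from the origin faces
    extent = pts.max(axis=0) + margin
    grid_shape = tuple(int(np.ceil(e / h)) for e in extent)
    return VesselPhantom(pts, radius, h, grid_shape)


def build_phantom(
    phantom: VesselPhantom,
    waveform: FlowWaveform,
    venc: float = 110.0,
    aliasing: bool = False,
) -> VelocityField4D:
    """Fill the grid with the tube's Poiseuille velocity field per phase.

    At each cardiac phase the axial velocity at perpendicular distance
    ``r`` from the centerline is ``2 Q(t) / (π R²) · (1 − r²/R²)`` for
    ``r ≤ R`` and zero outside, directed along the local centerline
    tangent, so the analytic cross-sectional flux equals Q(t) exactly.

    If the peak velocity exceeds ``venc`` the construction raises
    :class:`ConfigurationError`, unless ``aliasing=True``, in which case
    velocities wrap into ``[−venc, venc)`` as phase-contrast data would.
    """
    q = waveform.flow_rates
    rr = waveform.rr_interval
    R = phantom.radius
    peak_v = 2.0 * np.abs(q).max() / (np.pi * R * R) * ML_S_PER_MM2_TO_CM_S
    if peak_v > venc and not aliasing:
        raise ConfigurationError(
            f"peak velocity {peak_v:.1f} cm/s exceeds VENC {venc:.1f} cm/s "
            "(enable aliasing to wrap)"
        )

    cx, cy, cz = phantom.voxel_centers_1d()
    X, Y, Z = np.meshgrid(cx, cy, cz, indexing="ij")
    coords = np.stack([X, Y, Z], axis=-1).reshape(-1, 3)

    pts = phantom.centerline_points
    tans = phantom.tangents()
    tree = cKDTree(pts)
    _, nearest = tree.query(coords)
    t_near = tans[nearest]
    d = coords - pts[nearest]
    axial = np.einsum("ij,ij->i", d, t_near)
    perp2 = np.einsum("ij,ij->i", d, d) - axial**2
    inside = perp2 <= R * R
    profile = np.where(inside, 1.0 - perp2 / (R * R), 0.0)

    # (voxel, component) geometric factor; flux scale applied per phase
    geom = (profile[:, None] * t_near).reshape(*phantom.grid_shape, 3)
    geom = np.moveaxis(geom, -1, 0)  # (3, nx, ny, nz)
    scale = 2.0 * q / (np.pi * R * R) * ML_S_PER_MM2_TO_CM_S  # cm/s per phase
    vel = geom[..., None] * scale  # (3, nx, ny, nz, n_phases)
    if aliasing:
        vel = np.mod(vel + venc, 2 * venc) - venc
    return VelocityField4D(
        velocities=vel,
        venc=venc,
        voxel_size=phantom.voxel_size,
        phase_times=waveform.times.copy(),
        rr_interval=rr,
    )


def cross_section_flow(
    field: VelocityField4D,
    point: Sequence[float],
    tangent: Sequence[float],
    phase: int,
) -> float:
    """Through-plane flow (ml/s) at one centerline point and phase.

    Voxels whose centers lie within half a voxel of the plane through
    ``point`` normal to ``tangent`` are selected, and the tangent-projected
    velocity is summed times the voxel cross-sectional area.
    """
    point = np.asarray(point, dtype=float)
    tangent = np.asarray(tangent, dtype=float)
    tangent = tangent / np.linalg.norm(tangent)
    h = field.voxel_size
    extent = np.asarray(field.grid_shape) * h
    if np.any(point < 0) or np.any(point > extent):
        raise BoundaryError(f"point {point} outside grid extent {extent}")

    centers = tuple((np.arange(n) + 0.5) * h for n in field.grid_shape)
    ax = (centers[0] - point[0]) * tangent[0]
    ay = (centers[1] - point[1]) * tangent[1]
    az = (centers[2] - point[2]) * tangent[2]
    dist = ax[:, None, None] + ay[None, :, None] + az[None, None, :]
    slab = np.abs(dist) <= h / 2.0
    if not slab.any():
        raise BoundaryError("cross-section plane selects no voxels")
    v = field.velocities[..., phase][:, slab]  # (3, n_slab) cm/s
    v_through = tangent @ v
    return float(v_through.sum() * h * h * CM_S_MM2_TO_ML_S)


def extract_centerline_flow(
    field: VelocityField4D,
    phantom: VesselPhantom,
    start_voxel: int = 0,
    n_voxels: int = 6,
    artery: str = "ICA",
    side: str = "unknown",
) -> FlowWaveform:
    """Segment flow waveform: cross-section flux averaged over six
    consecutive centerline voxels (the segment-length convention of the
    centerline processing scheme).
    """
    pts = phantom.centerline_points
    tans = phantom.tangents()
    if start_voxel < 0 or start_voxel + n_voxels > len(pts):
        raise ValidationError(
            f"need {n_voxels} centerline voxels from index {start_voxel}, "
            f"have {len(pts)}"
        )
    idx = range(start_voxel, start_voxel + n_voxels)
    flows = np.empty(field.n_phases)
    for p in range(field.n_phases):
        flows[p] = np.mean(
            [cross_section_flow(field, pts[i], tans[i], p) for i in idx]
        )
    return FlowWaveform(
        field.phase_times.copy(), flows, field.rr_interval, artery=artery, side=side
    )


# ---------------------------------------------------------------------------
# Retrospective gating
# ---------------------------------------------------------------------------


def gated_reconstruction(
    continuous_waveform: Callable[[np.ndarray], np.ndarray],
    rr_sequence: Sequence[float],
    n_phases: int = 20,
    samples_per_cycle: int = 200,
    seed: int = 0,
) -> FlowWaveform:
    """Emulate retrospectively gated reconstruction of a flow waveform.

    Acquisition samples are drawn at pseudo-random times across the whole
    train of heartbeats, mapped to cardiac phase within their own cycle
    (so R-R jitter smears phase), and combined into ``n_phases`` uniform
    phase bins by linear temporal interpolation: each sample contributes to
    its two nearest bin centers with triangular weights.  The returned
    waveform is evaluated at the bin centers with ``rr_interval`` set to
    the mean R-R of the train.
    """
    rr = np.asarray(rr_sequence, dtype=float)
    if rr.size == 0 or np.any(rr <= 0):
        raise ValidationError("rr_sequence must be non-empty and positive")
    if n_phases < 2:
        raise ValidationError("n_phases must be at least 2")
    rr_ref = float(rr.mean())
    starts = np.concatenate([[0.0], np.cumsum(rr)])
    total = starts[-1]

    rng = np.random.default_rng(seed)
    n_samples = int(rr.size * samples_per_cycle)
    t_acq = rng.uniform(0.0, total, size=n_samples)
    cycle = np.clip(np.searchsorted(starts, t_acq, side="right") - 1, 0, rr.size - 1)
    phase = (t_acq - starts[cycle]) / rr[cycle]
    values = np.asarray(continuous_waveform(phase * rr_ref), dtype=float)

    # triangular weights to the two nearest bin centers at (i + 0.5)/n
    u = phase * n_phases - 0.5
    i0 = np.floor(u).astype(int)
    w1 = u - i0
    lo = np.mod(i0, n_phases)
    hi = np.mod(i0 + 1, n_phases)
    wsum = np.zeros(n_phases)
    vsum = np.zeros(n_phases)
    np.add.at(wsum, lo, 1.0 - w1)
    np.add.at(vsum, lo, (1.0 - w1) * values)
    np.add.at(wsum, hi, w1)
    np.add.at(vsum, hi, w1 * values)
    if np.any(wsum <= 0):
        empty = np.nonzero(wsum <= 0)[0].tolist()
        raise ReconstructionError(f"empty phase bins after gating: {empty}")
    binned = vsum / wsum
    times = (np.arange(n_phases) + 0.5) / n_phases * rr_ref
    return FlowWaveform(times, binned, rr_ref)
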