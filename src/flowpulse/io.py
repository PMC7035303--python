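"""Readers and writers: waveform CSV (two dialects), cohort CSV,
velocity fields as NIfTI + JSON sidecar, and YAML pipeline configuration.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import List, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .cohort import CohortParams
from .errors import FormatError, ValidationError
from .phantom import VelocityField4D, WaveformParams
from .waveform import FlowWaveform

__all__ = [
    "read_waveform_csv",
    "write_waveform_csv",
    "write_waveforms_long_csv",
    "read_cohort_csv",
    "write_cohort_csv",
    "write_velocity_field",
    "read_velocity_field",
    "PhantomConfig",
    "ModelsConfig",
    "PipelineConfig",
    "load_config",
    "default_config",
]

_SIDE_CODES = {"L": "left", "R": "right", "M": "midline", "U": "unknown"}
_SIDE_TO_CODE = {v: k for k, v in _SIDE_CODES.items()}
_SIDE_TO_CODE["bilateral"] = "M"


def _decode_side(token: str, where: str) -> str:
    token = token.strip()
    if token in _SIDE_CODES:
        return _SIDE_CODES[token]
    if token in _SIDE_CODES.values():
        return token
    raise FormatError(f"unknown side code {token!r} in {where}")


# ---------------------------------------------------------------------------
# waveform CSV
# ---------------------------------------------------------------------------


def _read_single_waveform(lines: List[str], path) -> FlowWaveform:
    headers = {}
    times: List[float] = []
    flows: List[float] = []
    saw_column_row = False
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" not in body:
                raise FormatError(f"{path}:{lineno}: malformed header {line!r}")
            key, value = (s.strip() for s in body.split("=", 1))
            headers[key] = value
            continue
        if not saw_column_row:
            cols = [c.strip() for c in line.split(",")]
            if cols != ["time_s", "flow_ml_s"]:
                raise FormatError(
                    f"{path}:{lineno}: expected column row 'time_s,flow_ml_s', got {line!r}"
                )
            saw_column_row = True
            continue
        parts = line.split(",")
        if len(parts) != 2:
            raise FormatError(f"{path}:{lineno}: expected 2 fields, got {len(parts)}")
        try:
            t, q = float(parts[0]), float(parts[1])
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-numeric row {line!r}") from None
        if times and t <= times[-1]:
            raise ValidationError(
                f"{path}:{lineno}: times not strictly increasing ({t} after {times[-1]})"
            )
        times.append(t)
        flows.append(q)
    if "rr_s" not in headers:
        raise FormatError(f"{path}: missing '# rr_s=<float>' header")
    try:
        rr = float(headers["rr_s"])
    except ValueError:
        raise FormatError(f"{path}: rr_s header is not a number") from None
    artery = headers.get("artery", "ICA")
    side = _decode_side(headers.get("side", "U"), str(path))
    return FlowWaveform(np.array(times), np.array(flows), rr, artery=artery, side=side)


_LONG_COLUMNS = {"subject_id", "artery", "side", "rr_s", "time_s", "flow_ml_s"}


def _read_long_waveforms(path) -> List[FlowWaveform]:
    table = pd.read_csv(path)
    missing = _LONG_COLUMNS - set(table.columns)
    if missing:
        raise FormatError(f"{path}: long-format file lacks columns {sorted(missing)}")
    out = []
    for (subject, artery, side), group in table.groupby(
        ["subject_id", "artery", "side"], sort=True
    ):
        group = group.sort_values("time_s")
        rr = group["rr_s"].iloc[0]
        if not np.allclose(group["rr_s"], rr):
            raise FormatError(
                f"{path}: inconsistent rr_s within group ({subject}, {artery}, {side})"
            )
        wf = FlowWaveform(
            group["time_s"].to_numpy(float),
            group["flow_ml_s"].to_numpy(float),
            float(rr),
            artery=str(artery),
            side=_decode_side(str(side), str(path)),
        )
        out.append(wf)
    return out


def read_waveform_csv(path) -> List[FlowWaveform]:
    """Read flow waveforms from CSV in either supported dialect.

    Single-segment files carry ``# rr_s=``/``# artery=``/``# side=``
    comment headers followed by ``time_s,flow_ml_s`` rows; long-format
    files have one row per sample with ``subject_id,artery,side,rr_s``
    grouping columns.  Malformed content raises :class:`FormatError` (or
    :class:`ValidationError` for out-of-order times) naming the line.
    """
    path = Path(path)
    text = path.read_text()
    first = next((ln for ln in text.splitlines() if ln.strip()), "")
    if first.startswith("#"):
        return [_read_single_waveform(text.splitlines(), path)]
    return _read_long_waveforms(path)


def write_waveform_csv(waveform: FlowWaveform, path) -> None:
    """Write one waveform in the single-segment dialect."""
    path = Path(path)
    lines = [
        f"# rr_s={float(waveform.rr_interval)!r}",
        f"# artery={waveform.artery}",
        f"# side={_SIDE_TO_CODE[waveform.side]}",
        "time_s,flow_ml_s",
    ]
    lines += [
        f"{float(t)!r},{float(q)!r}"
        for t, q in zip(waveform.times, waveform.flow_rates)
    ]
    path.write_text("\n".join(lines) + "\n")


def write_waveforms_long_csv(
    waveforms: Sequence[FlowWaveform], subject_ids: Sequence[str], path
) -> None:
    """Write multiple waveforms in the long (one row per sample) dialect."""
    frames = []
    for wf, sid in zip(waveforms, subject_ids):
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": sid,
                    "artery": wf.artery,
                    "side": _SIDE_TO_CODE[wf.side],
                    "rr_s": wf.rr_interval,
                    "time_s": wf.times,
                    "flow_ml_s": wf.flow_rates,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# cohort CSV
# ---------------------------------------------------------------------------


def write_cohort_csv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# velocity fields: NIfTI + JSON sidecar
# ---------------------------------------------------------------------------

_COMPONENTS = ("x", "y", "z")


def write_velocity_field(field: VelocityField4D, out_dir, prefix: str = "velocity"):
    """One NIfTI per velocity component (4th dim = cardiac phase) + sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    h = field.voxel_size
    affine = np.diag([h, h, h, 1.0])
    for i, comp in enumerate(_COMPONENTS):
        img = nib.Nifti1Image(field.velocities[i].astype(np.float32), affine)
        nib.save(img, out_dir / f"{prefix}_{comp}.nii")
    sidecar = {
        "venc_cm_s": field.venc,
        "voxel_size_mm": field.voxel_size,
        "n_phases": field.n_phases,
        "phase_times_s": field.phase_times.tolist(),
        "rr_interval_s": field.rr_interval,
    }
    (out_dir / f"{prefix}.json").write_text(json.dumps(sidecar, indent=2))
    return out_dir


def read_velocity_field(in_dir, prefix: str = "velocity") -> VelocityField4D:
    in_dir = Path(in_dir)
    sidecar_path = in_dir / f"{prefix}.json"
    if not sidecar_path.exists():
        raise FormatError(f"missing sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    comps = []
    for comp in _COMPONENTS:
        img = nib.load(in_dir / f"{prefix}_{comp}.nii")
        comps.append(np.asarray(img.dataobj, dtype=np.float64))
    return VelocityField4D(
        velocities=np.stack(comps, axis=0),
        venc=float(meta["venc_cm_s"]),
        voxel_size=float(meta["voxel_size_mm"]),
        phase_times=np.asarray(meta["phase_times_s"], dtype=float),
        rr_interval=float(meta["rr_interval_s"]),
    )


# ---------------------------------------------------------------------------
# pipeline configuration
# ---------------------------------------------------------------------------


@dataclass
class PhantomConfig:
    """Geometry/acquisition block of the pipeline configuration."""

    shape: str = "straight"  # or "curved"
    radius: float = 2.5  # mm
    voxel_size: float = 0.5  # mm
    length: float = 8.0  # mm (straight tube)
    curvature_radius: float = 20.0  # mm (curved tube)
    venc: float = 110.0  # cm/s
    n_phases: int = 20
    n_cycles: int = 30
    samples_per_cycle: int = 200
    start_voxel: int = 2

    def __post_init__(self):
        if self.shape not in ("straight", "curved"):
            raise ValidationError("phantom shape must be 'straight' or 'curved'")


@dataclass
class ModelsConfig:
    terms: tuple = ("ICA_PI", "M1_PI", "ICA_FVP", "M1_FVP")
    include_extended: bool = True
    include_subgroup: bool = True

    def __post_init__(self):
        self.terms = tuple(self.terms)


_STAGES = ("simulate_flow", "metrics", "simulate_cohort", "analyze")


@dataclass
class PipelineConfig:
    """Full pipeline configuration: stage toggles, seeds, parameter blocks."""

    seed: int = 1
    log_level: str = "INFO"
    stages: tuple = _STAGES
    waveform: WaveformParams = field(default_factory=WaveformParams)
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    cohort: CohortParams = field(default_factory=lambda: CohortParams(n_subjects=400))
    models: ModelsConfig = field(default_factory=ModelsConfig)

    def __post_init__(self):
        if not isinstance(self.seed, (int, np.integer)) or isinstance(self.seed, bool):
            raise ValidationError("seed must be an integer")
        self.stages = tuple(self.stages)
        unknown = set(self.stages) - set(_STAGES)
        if unknown:
            raise ValidationError(f"unknown stages: {sorted(unknown)}")


def _build_dataclass(cls, data: dict, context: str):
    if not isinstance(data, dict):
        raise ValidationError(f"{context}: expected a mapping")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValidationError(f"{context}: unknown keys {sorted(unknown)}")
    return cls(**data)


def load_config(path) -> PipelineConfig:
    """Load a YAML pipeline configuration, rejecting unknown keys."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: configuration must be a mapping")
    nested = {
        "waveform": WaveformParams,
        "phantom": PhantomConfig,
        "cohort": CohortParams,
        "models": ModelsConfig,
    }
    kwargs = {}
    for key, value in raw.items():
        if key in nested:
            kwargs[key] = _build_dataclass(nested[key], value, key)
        elif key in {f.name for f in dataclasses.fields(PipelineConfig)}:
            kwargs[key] = value
        else:
            raise ValidationError(f"{path}: unknown configuration key {key!r}")
    return PipelineConfig(**kwargs)


def default_config(**overrides) -> PipelineConfig:
    """The demo configuration used by ``flowpulse run`` without ``--config``."""
    cfg = PipelineConfig()
    return replace(cfg, **overrides) if overrides else cfg
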