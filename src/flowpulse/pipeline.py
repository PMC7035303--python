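"""End-to-end pipeline: phantom simulation → metric extraction → synthetic
cohort → association battery.

A single global seed deterministically spawns one independent substream
per stage, so toggling stages on or off never changes the randomness the
remaining stages see.  Every run writes a machine-readable manifest
(seeds, package version, configuration, output hashes); rerunning the
same configuration reproduces the output files byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import run_model_battery
from .cohort import generate_cohort_frame
from .errors import FlowPulseError, ValidationError
from .io import (
    PipelineConfig,
    read_cohort_csv,
    read_velocity_field,
    read_waveform_csv,
    write_cohort_csv,
    write_velocity_field,
    write_waveform_csv,
)
from .phantom import (
    build_phantom,
    curved_tube,
    draw_rr_sequence,
    extract_centerline_flow,
    gated_reconstruction,
    generate_waveform,
    straight_tube,
    waveform_function,
)
from .waveform import compute_metrics

__all__ = ["stage_seeds", "run_pipeline"]

logger = logging.getLogger(__name__)

_STAGE_ORDER = ("simulate_flow", "metrics", "simulate_cohort", "analyze")


def stage_seeds(global_seed: int) -> dict:
    """Deterministic per-stage integer seeds spawned from the global seed."""
    children = np.random.SeedSequence(global_seed).spawn(len(_STAGE_ORDER))
    return {
        stage: int(child.generate_state(1)[0] % (2**31))
        for stage, child in zip(_STAGE_ORDER, children)
    }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _phantom_from_config(cfg):
    if cfg.phantom.shape == "curved":
        return curved_tube(
            radius=cfg.phantom.radius,
            voxel_size=cfg.phantom.voxel_size,
            curvature_radius=cfg.phantom.curvature_radius,
        )
    return straight_tube(
        radius=cfg.phantom.radius,
        voxel_size=cfg.phantom.voxel_size,
        length=cfg.phantom.length,
    )


def _stage_simulate_flow(cfg: PipelineConfig, out: Path, seed: int):
    params = replace(cfg.waveform, seed=seed)
    continuous = waveform_function(params)
    rr_seq = draw_rr_sequence(params, cfg.phantom.n_cycles, seed=seed)
    gated = gated_reconstruction(
        continuous,
        rr_seq,
        n_phases=cfg.phantom.n_phases,
        samples_per_cycle=cfg.phantom.samples_per_cycle,
        seed=seed,
    )
    phantom = _phantom_from_config(cfg)
    field = build_phantom(phantom, gated, venc=cfg.phantom.venc)
    write_velocity_field(field, out, prefix="velocity")
    dense = generate_waveform(params, n_samples=1000)
    write_waveform_csv(dense, out / "waveform_truth_dense.csv")
    write_waveform_csv(gated, out / "waveform_truth_gated.csv")
    logger.info("simulate_flow: wrote velocity field %s and truth waveforms", out)


def _stage_metrics(cfg: PipelineConfig, out: Path, seed: int):
    field = read_velocity_field(out, prefix="velocity")
    phantom = _phantom_from_config(cfg)
    extracted = extract_centerline_flow(
        field, phantom, start_voxel=cfg.phantom.start_voxel
    )
    write_waveform_csv(extracted, out / "waveform_extracted.csv")
    rows = []
    sources = {
        "dense_truth": read_waveform_csv(out / "waveform_truth_dense.csv")[0],
        "gated_truth": read_waveform_csv(out / "waveform_truth_gated.csv")[0],
        "extracted": extracted,
    }
    for name, wf in sources.items():
        m = compute_metrics(wf)
        rows.append(
            {
                "source": name,
                "mean_flow": m.mean_flow,  # ml/s
                "pi_raw": m.pi_raw,
                "pi_std": m.pi_std,  # 1/s
                "fvp_raw": m.fvp_raw,  # ml
                "fvp_std": m.fvp_std,  # ml/s
            }
        )
    table = pd.DataFrame(rows).set_index("source")
    truth = table.loc["dense_truth"]
    for col in table.columns:
        table[f"{col}_rel_err"] = (table[col] - truth[col]).abs() / abs(truth[col])
    table.reset_index().to_csv(out / "metrics.csv", index=False)
    logger.info("metrics: wrote %s", out / "metrics.csv")


def _stage_simulate_cohort(cfg: PipelineConfig, out: Path, seed: int):
    params = dataclasses.replace(cfg.cohort, seed=seed)
    frame, truth = generate_cohort_frame(params)
    write_cohort_csv(frame, out / "cohort.csv")
    (out / "cohort_truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
    logger.info("simulate_cohort: wrote cohort of %d subjects", len(frame))


def _stage_analyze(cfg: PipelineConfig, out: Path, seed: int):
    cohort_path = out / "cohort.csv"
    if not cohort_path.exists():
        raise ValidationError(f"analyze stage needs {cohort_path}")
    cohort = read_cohort_csv(cohort_path)
    results = run_model_battery(
        cohort,
        terms=cfg.models.terms,
        include_extended=cfg.models.include_extended,
        include_subgroup=cfg.models.include_subgroup,
    )
    results.to_csv(out / "results.csv", index=False)
    logger.info("analyze: wrote %d model fits", len(results))


_STAGE_FUNCS = {
    "simulate_flow": _stage_simulate_flow,
    "metrics": _stage_metrics,
    "simulate_cohort": _stage_simulate_cohort,
    "analyze": _stage_analyze,
}


def run_pipeline(config: PipelineConfig, out_dir) -> Path:
    """Execute the enabled stages in order and write a run manifest.

    On stage failure, partial outputs are preserved alongside a ``FAILED``
    marker naming the stage, and the error is re-raised.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    seeds = stage_seeds(config.seed)
    enabled = [s for s in _STAGE_ORDER if s in config.stages]
    for stage in enabled:
        try:
            _STAGE_FUNCS[stage](config, out, seeds[stage])
        except FlowPulseError as exc:
            (out / "FAILED").write_text(f"stage {stage}: {exc}\n")
            raise

    manifest = {
        "package": "flowpulse",
        "version": __version__,
        "global_seed": config.seed,
        "stage_seeds": {s: seeds[s] for s in enabled},
        "stages": list(enabled),
        "config": _config_dict(config),
        "outputs": {
            p.name: _sha256(p)
            for p in sorted(out.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out


def _config_dict(config: PipelineConfig) -> dict:
    def convert(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {f.name: convert(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        if isinstance(obj, (tuple, list)):
            return [convert(x) for x in obj]
        if isinstance(obj, dict):
            return {k: convert(v) for k, v in obj.items()}
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        return obj

    return convert(config)
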