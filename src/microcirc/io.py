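"""TIFF/CSV input-output, run configuration and pipeline dispatch.

Physical units are fixed at this boundary: seconds for ``frame_interval``,
μm/pixel for ``pixel_size``, mm/s for reported speeds.  Every output
table carries a provenance header (package version, config hash, seed,
timestamp) as ``#``-prefixed comment lines above the CSV body, and a
rerun with the same config and seed reproduces the numeric content
byte-for-byte (only the timestamp line differs).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .stack import Image, ImageStack, Mask

__all__ = [
    "read_stack",
    "read_image",
    "write_stack",
    "write_table",
    "RunConfig",
    "run_pipeline",
]


def read_stack(path: str | Path, frame_interval: float = 1.0,
               pixel_size: float | None = None,
               channel: str | None = None) -> ImageStack:
    """Read a single- or multi-frame TIFF into an :class:`ImageStack`.

    Frames come out in file order with values preserved (8/16-bit
    integer and float inputs alike).  Inconsistent frame shapes raise an
    error naming the offending frame.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        pages = [p.asarray() for p in tif.pages]
    if not pages:
        raise ValueError(f"{path}: no frames found")
    shape0 = pages[0].shape
    for i, p in enumerate(pages):
        if p.shape != shape0:
            raise ValueError(f"{path}: frame {i} has shape {p.shape}, expected {shape0}")
    frames = np.stack(pages) if len(pages) > 1 else pages[0][None]
    if frames.ndim == 4 and frames.shape[0] == 1:
        frames = frames[0]
    if frames.ndim != 3:
        raise ValueError(f"{path}: cannot interpret data of shape {frames.shape} as (t, y, x)")
    return ImageStack(frames, frame_interval=frame_interval,
                      pixel_size=pixel_size, channel=channel)


def read_image(path: str | Path, pixel_size: float | None = None) -> Image:
    """Read a single-frame TIFF as an :class:`Image` (first frame if multi)."""
    stack = read_stack(path, frame_interval=1.0, pixel_size=pixel_size)
    return Image(stack.frames[0], pixel_size=pixel_size)


def write_stack(path: str | Path, stack: ImageStack | np.ndarray,
                as_uint16: bool = False) -> Path:
    """Write frames to a multi-frame TIFF.

    Values are written as-is by default (bitwise round-trip through
    :func:`read_stack`).  ``as_uint16=True`` rounds and clips to the
    16-bit unsigned range first, the on-disk convention for simulated
    acquisitions.
    """
    path = Path(path)
    frames = stack.frames if isinstance(stack, ImageStack) else np.asarray(stack)
    if as_uint16:
        frames = np.clip(np.rint(frames), 0, 65535).astype(np.uint16)
    # explicit photometric: a (3, y, x) stack is 3 frames, not RGB planes
    tifffile.imwrite(path, frames, photometric="minisblack")
    return path


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_table(df: pd.DataFrame, path: str | Path, config: dict | None = None,
                seed: int | None = None) -> Path:
    """Write a result table as CSV with a provenance comment header.

    Column names are expected to embed their units (e.g.
    ``speed_mm_per_s``); the header records package version, config
    hash, seed and timestamp.
    """
    from . import __version__

    path = Path(path)
    lines = [
        f"# microcirc {__version__}",
        f"# config_hash={config_hash(config or {})}",
        f"# seed={seed}",
        f"# timestamp={datetime.now(timezone.utc).isoformat()}",
    ]
    path.write_text("\n".join(lines) + "\n" + df.to_csv(index=False))
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


# ---------------------------------------------------------------------------
# pipeline dispatch
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """One reproducible pipeline run.

    ``stage`` selects the computation; ``params`` carries stage
    parameters; acquisition metadata lives in ``frame_interval`` (s) and
    ``pixel_size`` (μm/px).  The seed is recorded in every output table.
    """

    stage: str
    inputs: list = field(default_factory=list)
    outdir: str | Path = "."
    frame_interval: float = 1.0
    pixel_size: float | None = None
    seed: int = 0
    params: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        return cls(**doc)

    def as_dict(self) -> dict:
        return {
            "stage": self.stage,
            "inputs": [str(p) for p in self.inputs],
            "outdir": str(self.outdir),
            "frame_interval": self.frame_interval,
            "pixel_size": self.pixel_size,
            "seed": self.seed,
            "params": self.params,
        }


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Dispatch one stage and write its result tables.

    Returns a mapping of artifact names to written paths.  Identical
    config + seed produce identical outputs (modulo the timestamp line).
    """
    stages = {
        "simulate": _stage_simulate,
        "segment": _stage_segment,
        "velocity": _stage_velocity,
        "diameter": _stage_diameter,
        "quality": _stage_quality,
        "decay": _stage_decay,
    }
    if config.stage not in stages:
        raise ValueError(f"unknown stage {config.stage!r}; choose from {sorted(stages)}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        return stages[config.stage](config, outdir)
    except ValueError as exc:
        raise ValueError(f"stage '{config.stage}': {exc}") from exc


def _stage_simulate(config: RunConfig, outdir: Path) -> dict[str, Path]:
    from . import synthetic

    params = dict(config.params)
    generator = params.pop("generator", "kymograph")
    params.setdefault("seed", config.seed)
    out: dict[str, Path] = {}
    if generator == "kymograph":
        stack, truth = synthetic.make_kymograph_movie(synthetic.KymographSimConfig(**params))
        out["stack"] = write_stack(outdir / "kymograph.tif", stack, as_uint16=True)
        out["truth"] = truth.save(outdir / "kymograph.truth.yaml")
    elif generator == "hyperemia":
        stack, truth = synthetic.make_hyperemia_movie(synthetic.HyperemiaSimConfig(**params))
        out["stack"] = write_stack(outdir / "hyperemia.tif", stack, as_uint16=True)
        out["truth"] = truth.save(outdir / "hyperemia.truth.yaml")
    elif generator == "macroscope":
        image, truth = synthetic.make_macroscope_image(**params)
        out["image"] = write_stack(outdir / "macroscope.tif",
                                   image.pixels[None], as_uint16=True)
        out["truth"] = truth.save(outdir / "macroscope.truth.yaml")
    elif generator == "cell_field":
        image, truth = synthetic.make_cell_field(**params)
        out["image"] = write_stack(outdir / "cell_field.tif",
                                   image.pixels[None], as_uint16=True)
        out["truth"] = truth.save(outdir / "cell_field.truth.yaml")
    elif generator == "decay":
        stacks, truth = synthetic.make_decay_movie(synthetic.DecaySimConfig(**params))
        manifest = {"time_points_min": truth.params["time_points_min"], "stacks": []}
        for i, entry in enumerate(stacks):
            rec = {}
            for ch, stk in entry.items():
                p = write_stack(outdir / f"decay_t{i}_{ch}.tif", stk, as_uint16=True)
                rec[ch] = p.name
            manifest["stacks"].append(rec)
        mpath = outdir / "decay_manifest.yaml"
        mpath.write_text(yaml.safe_dump(manifest, sort_keys=True))
        out["manifest"] = mpath
        out["truth"] = truth.save(outdir / "decay.truth.yaml")
    else:
        raise ValueError(f"unknown generator {generator!r}")
    return out


def _require_input(config: RunConfig, n: int = 1) -> list[Path]:
    if len(config.inputs) < n:
        raise ValueError(f"needs {n} input path(s), got {len(config.inputs)}")
    return [Path(p) for p in config.inputs[:n]]


def _stage_segment(config: RunConfig, outdir: Path) -> dict[str, Path]:
    from . import segmentation

    (path,) = _require_input(config)
    stack = read_stack(path, config.frame_interval, config.pixel_size)
    mask, thr = segmentation.otsu_mask(stack,
                                       per_frame=bool(config.params.get("per_frame", False)))
    mask_path = outdir / f"{path.stem}.mask.tif"
    tifffile.imwrite(mask_path, mask.pixels.astype(np.uint8))
    df = pd.DataFrame({"input": [str(path)], "method": [mask.method],
                       "threshold_au": [thr],
                       "vascular_fraction": [mask.pixels.mean()]})
    log = write_table(df, outdir / f"{path.stem}.segment.csv",
                      config.as_dict(), config.seed)
    return {"mask": mask_path, "log": log}


def _stage_velocity(config: RunConfig, outdir: Path) -> dict[str, Path]:
    from . import velocimetry

    (path,) = _require_input(config)
    if config.pixel_size is None:
        raise ValueError("pixel_size (μm/pixel) is required for velocimetry")
    p = config.params
    for key in ("p1", "p2"):
        if key not in p:
            raise ValueError(f"missing point parameter {key!r} (x, y in pixels)")
    stack = read_stack(path, config.frame_interval, config.pixel_size)
    est = velocimetry.estimate_velocity(
        stack, tuple(p["p1"]), tuple(p["p2"]),
        radius=float(p.get("radius", 1.0)),
        max_lag=p.get("max_lag"),
    )
    df = pd.DataFrame({
        "input": [str(path)],
        "speed_mm_per_s": [est.speed],
        "lag_frames": [est.lag],
        "separation_um": [est.separation],
        "peak_correlation": [est.peak_correlation],
        "direction": [est.direction],
    })
    out = {"velocity": write_table(df, outdir / f"{path.stem}.velocity.csv",
                                   config.as_dict(), config.seed)}
    if p.get("write_correlogram", False):
        z1 = velocimetry.zscore_trace(
            velocimetry.extract_point_trace(stack, tuple(p["p1"]),
                                            float(p.get("radius", 1.0))))
        z2 = velocimetry.zscore_trace(
            velocimetry.extract_point_trace(stack, tuple(p["p2"]),
                                            float(p.get("radius", 1.0))))
        corr = velocimetry.unbiased_crosscorrelogram(
            z1, z2, p.get("max_lag") or max(1, stack.n_frames // 4))
        cdf = pd.DataFrame({"lag_frames": corr.lags, "correlation": corr.values})
        out["correlogram"] = write_table(cdf, outdir / f"{path.stem}.correlogram.csv",
                                         config.as_dict(), config.seed)
    return out


def _stage_diameter(config: RunConfig, outdir: Path) -> dict[str, Path]:
    from . import vessel_dynamics

    (path,) = _require_input(config)
    p = config.params
    for key in ("p0", "p1"):
        if key not in p:
            raise ValueError(f"missing line endpoint {key!r} (x, y in pixels)")
    stack = read_stack(path, config.frame_interval, config.pixel_size)
    trace = vessel_dynamics.diameter_timeseries(
        stack, tuple(p["p0"]), tuple(p["p1"]),
        spacing=float(p.get("spacing", 1.0)),
        vessel_label=p.get("vessel_label"),
    )
    onsets = p.get("stimulus_onsets", [])
    artifacts: dict[str, Path] = {}
    if onsets:
        trace = vessel_dynamics.normalize_to_baseline(
            trace, onsets,
            baseline_seconds=float(p.get("baseline_seconds", 2.0)),
            stimulus_duration=float(p.get("stimulus_duration", 5.0)),
        )
        result = vessel_dynamics.hyperemia_metrics(
            trace, post_stimulus_window=float(p.get("post_stimulus_window", 10.0)))
        sdf = pd.DataFrame({
            "stimulus_onset_s": result.stimulus_onsets,
            "peak_percent_change": result.peak_percent_change,
            "time_to_peak_s": result.time_to_peak,
        })
        artifacts["summary"] = write_table(sdf, outdir / f"{path.stem}.hyperemia.csv",
                                           config.as_dict(), config.seed)
    df = pd.DataFrame({
        "time_s": trace.times,
        "diameter_um": trace.diameters,
        "normalized": (trace.normalized if trace.normalized is not None
                       else np.full_like(trace.diameters, np.nan)),
    })
    artifacts["trace"] = write_table(df, outdir / f"{path.stem}.diameter.csv",
                                     config.as_dict(), config.seed)
    return artifacts


def _stage_quality(config: RunConfig, outdir: Path) -> dict[str, Path]:
    from . import segmentation, tracer_metrics

    (path,) = _require_input(config)
    image = read_image(path, config.pixel_size)
    mask, thr = segmentation.otsu_mask(image)
    snr = tracer_metrics.compute_snr(image, mask)
    ent = tracer_metrics.shannon_entropy(image)
    df = pd.DataFrame({"input": [str(path)], "snr": [snr],
                       "entropy_bits": [ent], "otsu_threshold_au": [thr]})
    return {"quality": write_table(df, outdir / f"{path.stem}.quality.csv",
                                   config.as_dict(), config.seed)}


def _stage_decay(config: RunConfig, outdir: Path) -> dict[str, Path]:
    from . import segmentation, tracer_metrics

    (manifest_path,) = _require_input(config)
    manifest = yaml.safe_load(Path(manifest_path).read_text())
    base = Path(manifest_path).parent
    stacks = []
    for rec in manifest["stacks"]:
        stacks.append({ch: read_stack(base / fname, config.frame_interval)
                       for ch, fname in rec.items()})
    time_points = manifest.get("time_points_min")
    reference = int(config.params.get("reference_index", 0))
    ref_channel = config.params.get("reference_channel") or next(iter(stacks[0]))
    mask, _ = segmentation.otsu_mask(stacks[reference][ref_channel])
    mask2d = Mask(mask.pixels.any(axis=0), method=mask.method, threshold=mask.threshold)
    curves = tracer_metrics.decay_curves(stacks, mask2d, reference_index=reference,
                                         time_points=time_points)
    rows = []
    for ch, curve in curves.items():
        for t, raw, norm in zip(curve.time_points, curve.raw_means, curve.normalized):
            rows.append({"channel": ch, "time_min": t, "mean_au": raw,
                         "normalized": norm})
    df = pd.DataFrame(rows)
    return {"decay": write_table(df, outdir / "decay_curves.csv",
                                 config.as_dict(), config.seed)}
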