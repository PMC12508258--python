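"""Image stack I/O, result files, and the end-to-end pipeline driver.

Image stacks are written as multi-page TIFF with a JSON description tag
carrying axes, channel names, timepoints, pixel size and exposures, so a
written stack reads back bit-identically with its metadata. Result tables
are tidy CSV; every run emits a JSON report with the configuration, derived
seeds and a config hash for reproducibility.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import synthetic
from ._utils import derive_seed
from .detection import DetectionParams, calibrate_threshold, detect_particles
from .quantify import IntensityDistribution, counts_per_fov, measure_particles
from .stack import ImageStack

__all__ = [
    "read_image_stack",
    "write_image_stack",
    "write_ground_truth",
    "write_results",
    "PipelineConfig",
    "run_pipeline",
    "DataError",
]


class DataError(RuntimeError):
    """Unreadable or structurally invalid input data."""


# ---------------------------------------------------------------------------
# TIFF stacks
# ---------------------------------------------------------------------------


def write_image_stack(stack: ImageStack, path) -> Path:
    """Write a stack as multi-page TIFF with JSON acquisition metadata."""
    path = Path(path)
    meta = {
        "axes": "TCYX",
        "channel_names": list(stack.channel_names),
        "timepoints_min": list(stack.timepoints_min),
        "pixel_size_nm": stack.pixel_size_nm,
        "exposure_ms": list(stack.exposure_ms),
    }
    tifffile.imwrite(path, stack.data, description=json.dumps(meta))
    return path


def read_image_stack(
    path,
    pixel_size_nm: float | None = None,
    exposure_ms=None,
    channel_names=None,
) -> ImageStack:
    """Read a TIFF/OME-TIFF into the canonical (T, C, Y, X) layout.

    Metadata (pixel size, exposures, channel names, axis order) is taken
    from the JSON description tag written by :func:`write_image_stack`, from
    OME/series axes when present, or from the keyword overrides. A plain
    single-page grayscale file becomes shape ``(1, 1, H, W)``; higher-rank
    files without axis metadata are rejected with a descriptive error.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tf:
            series = tf.series[0]
            data = series.asarray()
            axes = series.axes.upper()
            desc = tf.pages[0].description
    except Exception as exc:  # noqa: BLE001 - normalise into DataError
        raise DataError(f"cannot read TIFF {path}: {exc}") from exc

    meta = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = {}
    if isinstance(meta, dict) and meta.get("axes"):
        axes = str(meta["axes"]).upper()

    if data.ndim == 2:
        arr = data[None, None]
    else:
        axes = axes.replace("S", "C").replace("I", "T")
        if "Q" in axes or len(axes) != data.ndim or not set(axes) <= set("TCZYX"):
            raise DataError(
                f"ambiguous axes {axes!r} for {data.ndim}D data in {path}; "
                "write stacks with write_image_stack or supply axis metadata"
            )
        if "Z" in axes:
            zi = axes.index("Z")
            if data.shape[zi] != 1:
                raise DataError("z-stacks are not supported")
            data = np.take(data, 0, axis=zi)
            axes = axes.replace("Z", "")
        for missing in "TC":
            if missing not in axes:
                data = data[None]
                axes = missing + axes
        order = [axes.index(a) for a in "TCYX"]
        arr = np.transpose(data, order)

    t, c = arr.shape[:2]
    names = channel_names or meta.get("channel_names") or tuple(f"ch{i}" for i in range(c))
    return ImageStack(
        arr,
        channel_names=tuple(names),
        timepoints_min=tuple(meta.get("timepoints_min", [0.0] * t)),
        pixel_size_nm=float(pixel_size_nm or meta.get("pixel_size_nm", 65.0)),
        exposure_ms=tuple(
            exposure_ms
            if exposure_ms is not None
            else meta.get("exposure_ms", [100.0] * c)
        ),
        meta={"source": str(path)},
    )


def write_ground_truth(field_: synthetic.GroundTruthField, path) -> Path:
    """Ground-truth sidecar CSV: one row per simulated particle."""
    path = Path(path)
    field_.to_dataframe().to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# result files
# ---------------------------------------------------------------------------


def particles_to_frame(particles, channels: tuple[str, ...] = ("ch0",)) -> pd.DataFrame:
    """'Result file' analogue: per-particle position, size and intensities."""
    rows = []
    for p in particles:
        row = {
            "id": p.id,
            "x": p.centroid[0],
            "y": p.centroid[1],
            "area_px": p.area_px,
            "border_touching": p.border_touching,
        }
        for ch in channels:
            row[f"integrated_{ch}"] = p.integrated_intensity.get(ch)
            row[f"mean_{ch}"] = p.mean_intensity.get(ch)
        rows.append(row)
    cols = ["id", "x", "y", "area_px", "border_touching"] + [
        f"{kind}_{ch}" for ch in channels for kind in ("integrated", "mean")
    ]
    return pd.DataFrame(rows, columns=cols)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if dataclasses.is_dataclass(o) and not isinstance(o, type):
        return dataclasses.asdict(o)
    raise TypeError(f"not JSON serialisable: {type(o)}")


def write_results(
    tables: dict,
    out_dir,
    summaries: dict | None = None,
    config: dict | None = None,
    seeds: dict | None = None,
) -> dict:
    """Write CSV result tables plus a JSON summary/run log.

    Returns a mapping of logical names to written paths. The run log records
    the configuration, its SHA-256 hash and all seeds, so two runs with the
    same config and seed produce byte-identical outputs.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise DataError(f"cannot create output directory {out}: {exc}") from exc
    written = {}
    for name, table in tables.items():
        p = out / f"{name}.csv"
        table.to_csv(p, index=False, float_format="%.6g")
        written[name] = p
    log: dict = {"summaries": summaries or {}}
    if config is not None:
        blob = json.dumps(config, sort_keys=True, default=_json_default)
        log["config"] = config
        log["config_sha256"] = hashlib.sha256(blob.encode()).hexdigest()
    if seeds is not None:
        log["seeds"] = seeds
    p = out / "report.json"
    p.write_text(json.dumps(log, indent=2, sort_keys=True, default=_json_default))
    written["report"] = p
    return written


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Configuration for the simulate-then-analyse pipeline.

    In ``simulate`` mode the pipeline generates ``n_fovs`` EV fields plus
    ``n_control_fovs`` EV-free controls under one staining chemistry,
    calibrates the detection threshold on the controls, detects and measures
    particles on every FOV, and writes the result tables. In ``analyze``
    mode the image and control paths are read instead.
    """

    out_dir: str = "evquant_out"
    mode: str = "simulate"  # "simulate" | "analyze"
    seed: int = 0
    stain: str = "TSA"
    marker: str = "CD63"
    n_fovs: int = 4
    n_control_fovs: int = 4
    field: synthetic.FieldConfig = dataclasses.field(default_factory=synthetic.FieldConfig)
    optics: synthetic.OpticsCameraConfig = dataclasses.field(
        default_factory=synthetic.OpticsCameraConfig
    )
    detection: DetectionParams = dataclasses.field(default_factory=DetectionParams)
    image_paths: tuple = ()
    control_paths: tuple = ()
    channel: str | int = 0
    write_images: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "analyze"):
            raise ValueError("mode must be 'simulate' or 'analyze'")
        if self.mode == "simulate" and (self.n_fovs < 1 or self.n_control_fovs < 1):
            raise ValueError("simulate mode needs at least one FOV and one control")
        if self.mode == "analyze" and not self.image_paths:
            raise ValueError("analyze mode needs image_paths")

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        kw = dict(raw)
        if "field" in kw:
            kw["field"] = synthetic.FieldConfig(**{
                **kw["field"],
                **(
                    {"fov_shape": tuple(kw["field"]["fov_shape"])}
                    if "fov_shape" in kw["field"]
                    else {}
                ),
                **(
                    {"markers": tuple(synthetic.MarkerModel(**m) for m in kw["field"]["markers"])}
                    if "markers" in kw["field"]
                    else {}
                ),
            })
        if "optics" in kw:
            kw["optics"] = synthetic.OpticsCameraConfig(**kw["optics"])
        if "detection" in kw:
            kw["detection"] = DetectionParams(**kw["detection"])
        return cls(**kw)


_STAIN_FACTORY = {
    "DS": synthetic.ds_default,
    "PSS": synthetic.pss_default,
    "TSA": synthetic.tsa_default,
}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute calibrate -> detect -> quantify and write all outputs.

    Returns the report dict (also written to ``out_dir/report.json``); any
    stage failure is re-raised with the stage name in the message.
    """
    stage = "setup"
    try:
        if config.mode == "simulate":
            stage = "simulate"
            stain = _STAIN_FACTORY[config.stain]()
            fcfg = config.field
            if config.marker not in {m.name for m in fcfg.markers}:
                fcfg = dataclasses.replace(
                    fcfg, markers=(synthetic.MarkerModel(config.marker),)
                )
            fovs, controls, truths = [], [], []
            for k in range(config.n_fovs):
                fld = synthetic.sample_field(fcfg, derive_seed(config.seed, "field", k))
                rates = synthetic.simulate_staining(
                    fld, stain, config.marker, derive_seed(config.seed, "staining", k)
                )
                img = synthetic.render_image(
                    fld, rates, config.optics, derive_seed(config.seed, "render", k)
                )
                fovs.append(img)
                truths.append(fld)
            for k in range(config.n_control_fovs):
                fld = synthetic.control_field(fcfg, derive_seed(config.seed, "control", k))
                rates = synthetic.simulate_staining(
                    fld, stain, None, derive_seed(config.seed, "control", 100 + k),
                    specific=False,
                )
                controls.append(
                    synthetic.render_image(
                        fld, rates, config.optics, derive_seed(config.seed, "control", 200 + k)
                    )
                )
            exposure = config.optics.exposure_ms
        else:
            stage = "load"
            stacks = [read_image_stack(p) for p in config.image_paths]
            fovs = [s.frame(0, config.channel) for s in stacks]
            exposure = stacks[0].exposure_ms[0]
            controls = [
                read_image_stack(p).frame(0, config.channel) for p in config.control_paths
            ]
            truths = []

        stage = "calibrate"
        params = config.detection
        if params.threshold is None:
            if not controls:
                raise DataError("no control images and no explicit threshold")
            thr = calibrate_threshold(controls, params)
            params = dataclasses.replace(params, threshold=thr)
        control_counts = [len(detect_particles(im, params)) for im in controls]

        stage = "detect"
        per_fov = [detect_particles(im, params) for im in fovs]

        stage = "quantify"
        tables = {}
        all_meas = []
        for k, (img, parts) in enumerate(zip(fovs, per_fov)):
            df = measure_particles(parts, img, params)
            df.insert(0, "fov", k)
            all_meas.append(df)
        meas = pd.concat(all_meas, ignore_index=True) if all_meas else pd.DataFrame()
        tables["particles"] = meas
        counts = counts_per_fov(per_fov)
        summary: dict = {
            "threshold": params.threshold,
            "control_counts": control_counts,
            "counts_per_fov": counts,
        }
        if len(meas):
            dist = IntensityDistribution(meas["integrated"].to_numpy())
            summary["intensity"] = dist.summary()
        if config.mode == "simulate" and truths:
            tables["ground_truth"] = pd.concat(
                [t.to_dataframe().assign(fov=k) for k, t in enumerate(truths)],
                ignore_index=True,
            )

        stage = "write"
        cfg_dict = dataclasses.asdict(config)
        seeds = {"pipeline": config.seed}
        written = write_results(
            tables, config.out_dir, summaries=summary, config=cfg_dict, seeds=seeds
        )
        if config.write_images and config.mode == "simulate":
            for k, img in enumerate(fovs):
                write_image_stack(
                    ImageStack(
                        img,
                        channel_names=(config.marker,),
                        pixel_size_nm=config.field.pixel_size_nm,
                        exposure_ms=(exposure,),
                    ),
                    Path(config.out_dir) / f"fov_{k:02d}.tiff",
                )
        summary["written"] = {k: str(v) for k, v in written.items()}
        return summary
    except Exception as exc:
        raise type(exc)(f"[stage: {stage}] {exc}") from exc
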