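"""Experiment configuration, image I/O and pipeline orchestration.

Binds the stages into the acquisition → correction → segmentation →
quantification → analysis flow. Configurations are human-editable YAML or
JSON validated on load; frames travel as multi-page 16-bit unsigned TIFF
with a plain-text CSV sidecar as the source of truth for frame roles (TIFF
tags are advisory only); simulation ground truth is a separate JSON file,
never embedded in pixel data. Every results file is traceable to the
configuration through its hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .errors import ConfigValidationError, MesofluorError
from .frames import ROI, ImageFrame, rois_overlap, validate_roi
from .imgcorr import CalibrationSet
from .pipeline import AnalysisResult, analyze_frames
from .simgen import (
    ExperimentBundle,
    NoiseParams,
    OpticsParams,
    generate_dose_response_experiment,
)

log = logging.getLogger("mesofluor")

KNOWN_CHANNELS = ("dox", "pop")
WELL_ROLES = ("treatment", "control", "blank")

__all__ = [
    "ChannelConfig",
    "WellConfig",
    "ExperimentConfig",
    "ResultsBundle",
    "load_experiment",
    "simulate_to_dir",
    "run_pipeline",
    "write_results",
    "write_frames",
    "read_frames",
]


@dataclass(frozen=True)
class ChannelConfig:
    name: str
    excitation_nm: float
    emission_filter: str
    nd_reference: bool = True


@dataclass(frozen=True)
class WellConfig:
    roi: ROI  # position on the plate canvas, half-open (r0, r1, c0, c1)
    concentration: float
    role: str = "treatment"
    cell_model: str = ""
    background_rois: tuple[ROI, ...] = ()  # in-frame coordinates; () -> fallback


@dataclass
class ExperimentConfig:
    plate_shape: tuple[int, int]
    frame_shape: tuple[int, int]
    channels: list[ChannelConfig]
    wells: dict[str, WellConfig]
    seed: int = 0
    archetype: str = "compact"
    cell_model: str = ""
    bleach_factor: float = 0.9
    optics: OpticsParams = field(default_factory=OpticsParams)
    noise: NoiseParams = field(default_factory=NoiseParams)
    k_sigma: float = 3.0

    def validate(self) -> None:
        if not self.channels:
            raise ConfigValidationError("at least one channel is required")
        for ch in self.channels:
            if ch.name not in KNOWN_CHANNELS:
                raise ConfigValidationError(
                    f"unknown channel name {ch.name!r}; expected one of {KNOWN_CHANNELS}"
                )
        if not self.wells:
            raise ConfigValidationError("at least one well is required")
        items = sorted(self.wells.items())
        for wid, well in items:
            try:
                validate_roi(well.roi, self.plate_shape)
            except ValueError as exc:
                raise ConfigValidationError(f"well {wid}: {exc}") from exc
            if well.concentration < 0:
                raise ConfigValidationError(f"well {wid}: negative concentration")
            if well.role not in WELL_ROLES:
                raise ConfigValidationError(
                    f"well {wid}: unknown role {well.role!r}"
                )
            for roi in well.background_rois:
                try:
                    validate_roi(roi, self.frame_shape)
                except ValueError as exc:
                    raise ConfigValidationError(f"well {wid} background ROI: {exc}") from exc
        for i, (wid_a, a) in enumerate(items):
            for wid_b, b in items[i + 1:]:
                if rois_overlap(a.roi, b.roi):
                    raise ConfigValidationError(
                        f"well ROIs overlap: {wid_a} and {wid_b}"
                    )

    # -- serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "plate_shape": list(self.plate_shape),
            "frame_shape": list(self.frame_shape),
            "seed": self.seed,
            "archetype": self.archetype,
            "cell_model": self.cell_model,
            "bleach_factor": self.bleach_factor,
            "k_sigma": self.k_sigma,
            "channels": [asdict(ch) for ch in self.channels],
            "wells": {
                wid: {
                    "roi": list(w.roi),
                    "concentration": w.concentration,
                    "role": w.role,
                    "cell_model": w.cell_model,
                    "background_rois": [list(r) for r in w.background_rois],
                }
                for wid, w in self.wells.items()
            },
            "optics": {
                "gain": self.optics.gain,
                "leakage_fraction": self.optics.leakage_fraction,
                "dark_level": self.optics.dark_level,
                "nd_contamination": self.optics.nd_contamination,
            },
            "noise": {
                "shot_noise_enabled": self.noise.shot_noise_enabled,
                "read_noise_sd": self.noise.read_noise_sd,
                "relative_noise_frac": self.noise.relative_noise_frac,
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        try:
            channels = [ChannelConfig(**ch) for ch in d["channels"]]
            wells = {
                wid: WellConfig(
                    roi=tuple(w["roi"]),
                    concentration=float(w["concentration"]),
                    role=w.get("role", "treatment"),
                    cell_model=w.get("cell_model", ""),
                    background_rois=tuple(tuple(r) for r in w.get("background_rois", [])),
                )
                for wid, w in d["wells"].items()
            }
            optics = OpticsParams(**d.get("optics", {}))
            noise = NoiseParams(**d.get("noise", {}))
            cfg = cls(
                plate_shape=tuple(d["plate_shape"]),
                frame_shape=tuple(d["frame_shape"]),
                channels=channels,
                wells=wells,
                seed=int(d.get("seed", 0)),
                archetype=d.get("archetype", "compact"),
                cell_model=d.get("cell_model", ""),
                bleach_factor=float(d.get("bleach_factor", 0.9)),
                optics=optics,
                noise=noise,
                k_sigma=float(d.get("k_sigma", 3.0)),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigValidationError(f"malformed configuration: {exc}") from exc
        cfg.validate()
        return cfg

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def treatment_concentrations(self) -> list[float]:
        return sorted(
            w.concentration for w in self.wells.values() if w.role == "treatment"
        )


def load_experiment(config_path, data_dir=None):
    """Load and validate a configuration; optionally index available frames.

    Returns the config alone, or ``(config, frame_index, missing)`` when
    ``data_dir`` is given, where ``missing`` lists every
    (well, channel, timepoint, filter_role) expected but absent on disk.
    """
    path = Path(config_path)
    if not path.exists():
        raise ConfigValidationError(f"config file not found: {path}")
    text = path.read_text()
    d = yaml.safe_load(text) if path.suffix in {".yml", ".yaml"} else json.loads(text)
    config = ExperimentConfig.from_dict(d)
    if data_dir is None:
        return config
    frames, meta = read_frames(Path(data_dir), "frames")
    have = {
        (r.well_id, r.channel, r.timepoint, r.filter_role) for r in frames
    }
    missing = []
    for wid, well in sorted(config.wells.items()):
        for ch in config.channels:
            tps = ("post_activation",) if ch.name == "dox" else (
                "pre_activation", "post_activation",
            )
            for tp in tps:
                for role in ("fluorescence", "nd_reference"):
                    if (wid, ch.name, tp, role) not in have:
                        missing.append((wid, ch.name, tp, role))
    if missing:
        log.warning("missing frames: %s", missing)
    return config, frames, missing


# -- frame I/O -----------------------------------------------------------

def _to_uint16(pixels: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(pixels), 0, 65535).astype(np.uint16)


def write_frames(
    frames: list[ImageFrame],
    out_dir,
    name: str,
    concentrations: dict[str, float] | None = None,
) -> tuple[Path, Path]:
    """Write a frame list as ``<name>.tif`` plus sidecar ``<name>.csv``.

    Pixel values are clipped to [0, 65535] and stored as unsigned 16-bit,
    one page per frame, in sidecar order.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tif_path = out_dir / f"{name}.tif"
    csv_path = out_dir / f"{name}.csv"
    stack = np.stack([_to_uint16(fr.pixels) for fr in frames])
    tifffile.imwrite(tif_path, stack)
    rows = [
        {
            "page": i,
            "well_id": fr.well_id,
            "channel": fr.channel,
            "filter_role": fr.filter_role,
            "timepoint": fr.timepoint,
            "concentration": (concentrations or {}).get(fr.well_id, ""),
        }
        for i, fr in enumerate(frames)
    ]
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    return tif_path, csv_path


def read_frames(data_dir, name: str) -> tuple[list[ImageFrame], pd.DataFrame]:
    """Read a ``<name>.tif`` + ``<name>.csv`` pair back into frames."""
    data_dir = Path(data_dir)
    tif_path = data_dir / f"{name}.tif"
    csv_path = data_dir / f"{name}.csv"
    if not tif_path.exists() or not csv_path.exists():
        raise MesofluorError(f"frame set {name!r} not found under {data_dir}")
    stack = tifffile.imread(tif_path)
    if stack.ndim == 2:
        stack = stack[None]
    meta = pd.read_csv(csv_path, keep_default_na=False)
    frames = [
        ImageFrame(
            pixels=stack[int(row.page)].astype(float),
            channel=row.channel,
            filter_role=row.filter_role,
            timepoint=row.timepoint,
            well_id=str(row.well_id),
        )
        for row in meta.itertuples()
    ]
    return frames, meta


def _calibration_to_frames(cal: CalibrationSet) -> list[ImageFrame]:
    out = list(cal.dark_frames)
    for f, nd in cal.water_well_pairs:
        out.extend([f, nd])
    out.extend(cal.drug_only_frames)
    return out


def _calibration_from_frames(frames: list[ImageFrame]) -> CalibrationSet:
    darks = [f for f in frames if f.filter_role == "dark"]
    by_well: dict[str, dict[str, ImageFrame]] = {}
    for f in frames:
        if f.filter_role in ("fluorescence", "nd_reference"):
            by_well.setdefault(f.well_id, {})[f.filter_role] = f
    pairs = [
        (d["fluorescence"], d["nd_reference"])
        for _, d in sorted(by_well.items())
        if "fluorescence" in d and "nd_reference" in d
    ]
    return CalibrationSet(dark_frames=darks, water_well_pairs=pairs)


# -- simulation to disk --------------------------------------------------

def simulate_to_dir(config: ExperimentConfig, out_dir) -> ExperimentBundle:
    """Simulate the configured experiment and write it in the on-disk layout.

    Writes ``frames.tif/csv``, per-channel ``calibration_<ch>.tif/csv`` and
    the ground truth as ``truth.json`` (keyed by well id, separate from the
    pixel data).
    """
    config.validate()
    out_dir = Path(out_dir)
    bundle = generate_dose_response_experiment(
        config.treatment_concentrations(),
        config.archetype,
        config.optics,
        config.noise,
        config.seed,
        bleach_factor=config.bleach_factor,
        grid_shape=config.frame_shape,
        channels=tuple(ch.name for ch in config.channels),
    )
    conc = bundle.concentration_map()
    write_frames(bundle.all_frames(), out_dir, "frames", concentrations=conc)
    for ch, cal in bundle.calibration.items():
        write_frames(_calibration_to_frames(cal), out_dir, f"calibration_{ch}")
    truth = {
        w.well_id: {
            "role": w.role,
            "concentration": w.concentration,
            "uptake_coefficient": w.truth.uptake_coefficient,
            "media_background": w.truth.media_background,
            "n_cluster_pixels": int(w.truth.cluster_mask.sum()),
            "mean_cluster_thickness": w.truth.mean_cluster_thickness(),
        }
        for w in bundle.wells
    }
    truth["_session"] = {
        "seed": config.seed,
        "leakage_fraction": config.optics.leakage_fraction,
        "bleach_factor": config.bleach_factor,
    }
    (out_dir / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
    return bundle


# -- pipeline orchestration ----------------------------------------------

@dataclass
class ResultsBundle:
    """Everything one pipeline run produced, with provenance."""

    analysis: AnalysisResult
    config_hash: str
    seed: int
    software_version: str = __version__
    input_files: list[str] = field(default_factory=list)

    def analysis_report(self) -> dict:
        a = self.analysis
        return {
            "software_version": self.software_version,
            "config_hash": self.config_hash,
            "seed": self.seed,
            "input_files": self.input_files,
            "leakage_models": {
                ch: m.to_report() for ch, m in a.leakage_models.items()
            },
            "dose_response": {ch: f.to_report() for ch, f in a.dose_fits.items()},
            "fold_changes": a.fold_changes,
            "bleaching": [d.to_report() for d in a.bleaching],
            "wells_below_detection": [list(t) for t in a.missing],
        }


def run_pipeline(config: ExperimentConfig, data_dir) -> ResultsBundle:
    """Execute calibrate → correct → segment → quantify → analyze from disk.

    Deterministic and idempotent for fixed inputs: rerunning on identical
    inputs produces byte-identical tables.
    """
    config.validate()
    data_dir = Path(data_dir)
    input_files = []
    calibration = {}
    for ch in config.channels:
        try:
            cal_frames, _ = read_frames(data_dir, f"calibration_{ch.name}")
        except MesofluorError as exc:
            raise MesofluorError(
                f"stage=calibrate channel={ch.name}: missing calibration frames "
                f"under {data_dir} — run `mesofluor simulate` or point --data at "
                "an acquisition directory"
            ) from exc
        calibration[ch.name] = _calibration_from_frames(cal_frames)
        input_files += [f"calibration_{ch.name}.tif", f"calibration_{ch.name}.csv"]
    frames, _ = read_frames(data_dir, "frames")
    input_files += ["frames.tif", "frames.csv"]

    conc = {wid: w.concentration for wid, w in config.wells.items()}
    rois = None
    explicit = {wid: w.background_rois for wid, w in config.wells.items() if w.background_rois}
    if explicit:
        # per-well ROIs must agree in this layout (one frame per well);
        # use the first well's explicit ROIs for all
        rois = list(next(iter(explicit.values())))
    try:
        analysis = analyze_frames(
            frames, calibration, conc,
            k_sigma=config.k_sigma,
            background_rois=rois,
            roles={wid: w.role for wid, w in config.wells.items()},
            cell_model=config.cell_model,
        )
    except MesofluorError as exc:
        raise MesofluorError(f"stage=analyze: {exc}") from exc
    return ResultsBundle(
        analysis=analysis,
        config_hash=config.config_hash(),
        seed=config.seed,
        input_files=input_files,
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_results(bundle: ResultsBundle, out_dir, *, plots: bool = False) -> dict:
    """Write tables, reports (and optionally plots) plus a checksum manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    df = bundle.analysis.measurements_frame()
    if len(df):
        meas = out_dir / "measurements.csv"
        df.to_csv(meas, index=False)
        written.append(meas)

    report = out_dir / "analysis.json"
    report.write_text(json.dumps(bundle.analysis_report(), indent=1, sort_keys=True))
    written.append(report)

    for ch, model in bundle.analysis.leakage_models.items():
        p = out_dir / f"leakage_model_{ch}.json"
        p.write_text(json.dumps(model.to_report(), indent=1, sort_keys=True))
        written.append(p)

    logp = out_dir / "run.log"
    logp.write_text(
        f"mesofluor {bundle.software_version}\n"
        f"config_hash {bundle.config_hash}\nseed {bundle.seed}\n"
        f"inputs {' '.join(bundle.input_files)}\n"
    )
    written.append(logp)

    if plots and bundle.analysis.dose_fits:
        from . import plots as _plots

        for ch, fit in bundle.analysis.dose_fits.items():
            p = out_dir / f"dose_response_{ch}.png"
            _plots.plot_dose_response(fit, p)
            written.append(p)

    manifest = {
        "config_hash": bundle.config_hash,
        "software_version": bundle.software_version,
        "files": {p.name: _sha256(p) for p in written},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
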