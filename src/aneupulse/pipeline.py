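"""End-to-end orchestration: one declarative config → one analysed run.

A run chains the stages in method order: acquire (generate a synthetic
phantom series or load a stored one) → resample to isotropic voxels → crop →
threshold → mask (bench elliptic scheme or in-vivo polygonal scheme) →
volume time series → pulse extrema → per-pulse amplitudes → summary and
detection verdict → dose block.  Identical config and seed give identical
outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as apio
from . import phantom as ph
from . import preprocess as pre
from . import segment as seg
from . import pulsation as pa
from . import dose as ds

log = logging.getLogger("aneupulse")


@dataclass
class RunConfig:
    """Declarative description of one analysis run.

    Exactly one input source must be set: ``phantom`` (generator parameters)
    or ``input_path`` (+ ``input_format``).  The masking scheme must match
    the mask data provided (``ellipse`` for the bench scheme, ``polygons``
    for the in-vivo scheme).
    """

    phantom: dict | None = None
    input_path: str | None = None
    input_format: str = "dicom_dirs"
    threshold: float | str = "suggest"       # HU value or "suggest"
    seed_point: tuple[int, int, int] | None = None
    crop_box: list[int] | None = None        # [x0,x1,y0,y1,z0,z1], half-open
    mask_scheme: str = "vitro"               # "vitro" | "vivo" | "none"
    ellipse: dict | None = None              # {cx,cy,a,b,init_slice[,slice_range]}
    polygons: list[dict] | None = None       # [{plane, vertices, slab}, ...]
    mask_file: str | None = None
    expected_period: dict = field(default_factory=lambda: {"fixed_hz": 1.5})
    analysis_window: list[float] | None = None  # [t0, t1] seconds
    noise_floor: float = 3.0
    period_tolerance: float = 0.2
    dose: dict | None = None
    outdir: str | None = None
    seed: int = 0

    def validate(self) -> None:
        if (self.phantom is None) == (self.input_path is None):
            raise ValueError("exactly one input source (phantom or input_path) required")
        if self.mask_scheme not in ("vitro", "vivo", "none"):
            raise ValueError(f"unknown mask scheme {self.mask_scheme!r}")
        if self.mask_scheme == "vitro" and self.ellipse is None and self.mask_file is None:
            raise ValueError("bench scheme needs an initial vessel ellipse")
        if self.mask_scheme == "vivo" and self.polygons is None and self.mask_file is None:
            raise ValueError("in-vivo scheme needs polygon masks")
        if self.threshold == "suggest" and self.seed_point is None and self.phantom is None:
            raise ValueError("threshold='suggest' needs a seed_point for loaded series")
        if "fixed_hz" not in self.expected_period and "ecg_csv" not in self.expected_period:
            raise ValueError("expected_period must give fixed_hz or ecg_csv")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        cfg = cls(**json.loads(Path(path).read_text()))
        cfg.validate()
        return cfg


@dataclass
class RunResult:
    series: pa.VolumeTimeSeries
    extrema: list[pa.Extremum]
    events: list[pa.PulseEvent]
    summary: pa.PulsationSummary
    n_complete_cycles: int
    dose: ds.DoseProtocol | None = None
    ground_truth: ph.GroundTruth | None = None
    ecg_alignment: pa.EcgAlignment | None = None
    outputs: dict = field(default_factory=dict)


def _load_mask_file(path: str) -> dict:
    return json.loads(Path(path).read_text())


def _load_ecg_csv(path: str, clock_offset: float = 0.0) -> pa.EcgTrace:
    """Two-column CSV (time_s, r_peak marker); rows with a nonzero marker
    are R-peaks."""
    df = pd.read_csv(path)
    t = df.iloc[:, 0].to_numpy(dtype=float)
    marker = df.iloc[:, 1].to_numpy(dtype=float)
    return pa.EcgTrace(r_peak_times=t[marker != 0], clock_offset=clock_offset)


def run(config: RunConfig) -> RunResult:
    """Execute one configured run end to end."""
    config.validate()

    # --- acquire ----------------------------------------------------------
    gt = None
    if config.phantom is not None:
        pcfg = ph.PhantomConfig(**{**config.phantom, "seed": config.seed})
        log.info("generate: %d-timepoint phantom, ΔV=%.2f mm³",
                 int(pcfg.scan_duration / (pcfg.reconstruction_interval * 1e-3)) + 1,
                 pcfg.amplitude)
        stacks, gt = ph.generate_series(pcfg)
    else:
        log.info("load: %s (%s)", config.input_path, config.input_format)
        manifest = apio.load_series(config.input_path, config.input_format)
        stacks = manifest.stacks
    times = np.array([s.timestamp for s in stacks])

    # --- resample ---------------------------------------------------------
    iso = [pre.resample_isotropic(s) for s in stacks]
    log.info("resample: %s @ %.3g mm isotropic", iso[0].shape, iso[0].spacing)

    # --- threshold (fixed once for the whole series) ------------------------
    if config.threshold == "suggest":
        seed_point = config.seed_point
        if seed_point is None:  # phantom: sac center is the grid center
            seed_point = tuple(n // 2 for n in iso[0].shape)
        thr = seg.suggest_threshold(iso[0], seed_point)
    else:
        thr = float(config.threshold)
    log.info("threshold: %.1f HU", thr)

    binaries = [seg.binarize(v, thr) for v in iso]

    # --- masks ------------------------------------------------------------
    crop_box = pre.CropBox.from_list(config.crop_box) if config.crop_box else None
    track = None
    polys = None
    mask_data = _load_mask_file(config.mask_file) if config.mask_file else {}
    if config.mask_scheme == "vitro":
        e = config.ellipse or mask_data.get("ellipse")
        init = seg.Ellipse(e["cx"], e["cy"], e["a"], e["b"])
        rng = tuple(e["slice_range"]) if "slice_range" in e else None
        track = seg.track_vessel(binaries[0], init, int(e["init_slice"]), rng)
        log.info("vessel track: %d slices, %d flagged", len(track.ellipses),
                 len(track.flagged))
    elif config.mask_scheme == "vivo":
        pdefs = config.polygons or mask_data.get("polygons", [])
        polys = seg.PolyMaskSet(
            [
                seg.PolyMask(
                    plane=p["plane"],
                    vertices=tuple(tuple(v) for v in p["vertices"]),
                    slab=tuple(p["slab"]),
                )
                for p in pdefs
            ]
        )
    segmented = [seg.apply_masks(b, crop=crop_box, track=track, polys=polys)
                 for b in binaries]

    # --- volume series and pulsation ---------------------------------------
    series = pa.volume_series(segmented, times)

    ecg = None
    if "ecg_csv" in config.expected_period:
        ecg = _load_ecg_csv(
            config.expected_period["ecg_csv"],
            config.expected_period.get("clock_offset", 0.0),
        )
        rr = np.diff(ecg.scanner_times)
        if len(rr) == 0:
            raise ValueError("ECG trace has fewer than 2 R-peaks")
        ref_period = float(np.median(rr))
    else:
        ref_period = 1.0 / float(config.expected_period["fixed_hz"])

    analysed = series
    if config.analysis_window is not None:
        analysed = pa.normalize_drift(series, tuple(config.analysis_window))
        series = pa.VolumeTimeSeries(series.times, series.volumes)
        # keep the window's normalized values visible in the full-series output
        norm = np.full(len(series), np.nan)
        sel = (series.times >= config.analysis_window[0]) & (
            series.times <= config.analysis_window[1]
        )
        norm[sel] = analysed.normalized_volumes
        series.normalized_volumes = norm

    extrema = pa.detect_extrema(
        pa.VolumeTimeSeries(analysed.times, analysed.volumes), ref_period
    )
    mode_b = config.mask_scheme == "vivo"
    events = pa.amplitudes_mode_b(extrema) if mode_b else pa.amplitudes_mode_a(extrema)
    n_cycles = len(pa.amplitudes_mode_a(extrema))
    summary = pa.summarize(
        events,
        noise_floor=config.noise_floor,
        reference_period=ref_period,
        period_tolerance=config.period_tolerance,
    )
    log.info("pulsation: %d events, AVP=%.2f mm³, detected=%s",
             summary.n_pulses, summary.avp, summary.detected)

    alignment = pa.align_ecg(extrema, ecg) if ecg is not None else None

    dose_block = ds.DoseProtocol(**config.dose) if config.dose else None

    result = RunResult(
        series=series,
        extrema=extrema,
        events=events,
        summary=summary,
        n_complete_cycles=n_cycles,
        dose=dose_block,
        ground_truth=gt,
        ecg_alignment=alignment,
    )
    if config.outdir:
        result.outputs = apio.save_results(result, config.outdir)
        log.info("results written to %s", config.outdir)
    return result


def generate(config: RunConfig, outdir: str | Path, format: str = "dicom_dirs") -> Path:
    """Generate the configured phantom series and write it to disk with a
    sidecar recording the full configuration and ground-truth event times."""
    if config.phantom is None:
        raise ValueError("config has no phantom block")
    pcfg = ph.PhantomConfig(**{**config.phantom, "seed": config.seed})
    stacks, gt = ph.generate_series(pcfg)
    sidecar = {
        "phantom": pcfg.as_dict(),
        "ground_truth": gt.event_times_dict()
        | {"true_amplitude_mm3": gt.true_amplitude, "true_period_s": gt.true_period},
        "acquisition": {
            "rotation_time_ms": pcfg.rotation_time,
            "scan_time_s": pcfg.scan_duration,
        },
        "seed": config.seed,
    }
    return apio.write_series(stacks, outdir, format=format, sidecar=sidecar)


def sweep(
    base: RunConfig,
    amplitudes: list[float] | None = None,
    pulse_pressures: list[float] | None = None,
    replicates: int = 1,
    seed: int = 0,
) -> tuple[pd.DataFrame, pa.RegressionResult]:
    """Run the bench protocol over a range of programmed pulsations.

    Each run programs one ΔV (directly, or via a pulse pressure through the
    compliance slope), recovers the AVP through the full pipeline, and the
    recovered AVP is regressed against the programmed value — the software
    analogue of sweeping the piston-pump amplitude.
    """
    if (amplitudes is None) == (pulse_pressures is None):
        raise ValueError("give exactly one of amplitudes or pulse_pressures")
    rows = []
    values = amplitudes if amplitudes is not None else pulse_pressures
    for j, val in enumerate(values):
        for rep in range(replicates):
            cfg = RunConfig(**{**base.__dict__})
            cfg.outdir = None
            cfg.phantom = dict(base.phantom or {})
            if amplitudes is not None:
                cfg.phantom["pulsation_amplitude"] = float(val)
            else:
                cfg.phantom["pulsation_amplitude"] = None
                cfg.phantom["pulse_pressure"] = float(val)
            cfg.seed = seed + 1000 * j + rep
            res = run(cfg)
            dv = res.ground_truth.true_amplitude
            rows.append(
                {
                    "programmed_dv_mm3": dv,
                    "pulse_pressure_mmHg": cfg.phantom.get("pulse_pressure"),
                    "replicate": rep,
                    "n_pulses": res.summary.n_pulses,
                    "avp_mm3": res.summary.avp,
                    "sd_mm3": res.summary.sd,
                    "cov_percent": res.summary.cov,
                    "detected": res.summary.detected,
                    "attenuation": res.ground_truth.attenuation,
                }
            )
    df = pd.DataFrame(rows)
    x = df.pulse_pressure_mmHg if pulse_pressures is not None else df.programmed_dv_mm3
    reg = pa.pressure_regression(np.column_stack([x, df.avp_mm3]))
    return df, reg
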