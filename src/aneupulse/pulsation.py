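"""Volume time-series analysis: pulse detection, amplitude, statistics.

The aneurysm sac volume at each timepoint is ``N_w · X_v · Y_v · Z_v`` — the
white-voxel count of the segmented binary volume times the voxel volume.
Pulses are the alternating local maxima (zeniths) and minima (nadirs) of the
sampled volume-versus-time curve; extrema are taken on the raw samples, with
no smoothing, because nadir truncation by coarse temporal sampling is a real
effect the analysis must expose, not hide.

Two per-pulse amplitude definitions are supported:

* mode A (bench): amplitude = zenith − following nadir;
* mode B (in vivo): amplitude = zenith − mean of both adjacent nadirs, which
  cancels the slow apparent-volume drift caused by changing iodine contrast
  concentration — exactly, for any drift linear in time.

Detection requires the average pulsation to clear a noise floor (default
3 mm³, the smallest amplitude unequivocally distinguishable from background
noise on the bench) *and* the estimated period to match the driving period
(pump or heart); apparent pulsation whose period disagrees with the driver
is classified artefactual.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks
from scipy.stats import linregress


@dataclass
class VolumeTimeSeries:
    """(time s, volume mm³) samples, optionally with drift-normalized values."""

    times: np.ndarray
    volumes: np.ndarray
    normalized_volumes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.volumes = np.asarray(self.volumes, dtype=float)
        if self.times.shape != self.volumes.shape:
            raise ValueError("times and volumes must have equal length")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.volumes < 0):
            raise ValueError("volumes must be non-negative")

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class Extremum:
    time: float
    volume: float
    kind: str  # "zenith" | "nadir"
    index: int


@dataclass(frozen=True)
class PulseEvent:
    """One pulse: a zenith and its nadir(s), with the resulting amplitude."""

    zenith: tuple[float, float]          # (time, volume)
    nadirs: tuple[tuple[float, float], ...]
    amplitude: float
    mode: str                            # "A_vitro" | "B_vivo"


@dataclass
class PulsationSummary:
    n_pulses: int
    avp: float                 # mean per-pulse amplitude, mm³
    sd: float                  # sample SD of amplitudes, mm³
    cov: float                 # 100·SD/AVP, percent, full precision
    detected: bool
    period_estimate: float     # median inter-zenith interval, s
    reference_period: float | None
    noise_floor: float = 3.0

    @property
    def cov_rounded(self) -> int | None:
        """CoV to the nearest integer percent, as reported in summaries."""
        return int(round(self.cov)) if np.isfinite(self.cov) else None

    def as_dict(self) -> dict:
        return {
            "n_pulses": self.n_pulses,
            "avp_mm3": None if not np.isfinite(self.avp) else self.avp,
            "sd_mm3": None if not np.isfinite(self.sd) else self.sd,
            "cov_percent": self.cov_rounded,
            "detected": self.detected,
            "period_estimate_s": None
            if not np.isfinite(self.period_estimate)
            else self.period_estimate,
            "reference_period_s": self.reference_period,
            "noise_floor_mm3": self.noise_floor,
        }


def volume_series(binaries, times) -> VolumeTimeSeries:
    """Volumes ``N_w · spacing³`` (mm³) of segmented binary volumes."""
    binaries = list(binaries)
    times = np.asarray(times, dtype=float)
    if len(binaries) != len(times):
        raise ValueError("one timestamp per segmented volume required")
    shapes = {b.shape for b in binaries}
    if len(shapes) > 1:
        raise ValueError(f"segmented grids differ across timepoints: {shapes}")
    vols = np.array([b.volume_mm3 for b in binaries])
    return VolumeTimeSeries(times=times, volumes=vols)


def detect_extrema(series: VolumeTimeSeries, expected_period: float) -> list[Extremum]:
    """Alternating zeniths and nadirs of the sampled curve.

    Local maxima and minima are found with a minimum separation of half the
    expected period between same-type extrema (single-sample spikes closer
    than that to a larger extremum are rejected); alternation is then
    enforced by keeping the more extreme of two consecutive same-type
    extrema.
    """
    t, v = series.times, series.volumes
    if len(t) < 3 or t[-1] - t[0] < expected_period:
        raise ValueError("series must span at least one expected period")
    dt = float(np.median(np.diff(t)))
    distance = max(1, int(np.ceil(0.5 * expected_period / dt)))
    use = series.normalized_volumes if series.normalized_volumes is not None else v
    peaks, _ = find_peaks(use, distance=distance)
    troughs, _ = find_peaks(-use, distance=distance)
    ext = [Extremum(t[i], v[i], "zenith", int(i)) for i in peaks]
    ext += [Extremum(t[i], v[i], "nadir", int(i)) for i in troughs]
    ext.sort(key=lambda e: e.index)
    out: list[Extremum] = []
    for e in ext:
        if out and out[-1].kind == e.kind:
            prev = out[-1]
            better = (
                e.volume > prev.volume if e.kind == "zenith" else e.volume < prev.volume
            )
            if better:
                out[-1] = e
        else:
            out.append(e)
    return out


def amplitudes_mode_a(extrema: list[Extremum]) -> list[PulseEvent]:
    """Bench definition: one event per zenith paired with the nadir that
    follows it; a trailing zenith without a following nadir is excluded."""
    events = []
    for i, e in enumerate(extrema):
        if e.kind != "zenith":
            continue
        nxt = next((x for x in extrema[i + 1:] if x.kind == "nadir"), None)
        if nxt is None:
            continue
        events.append(
            PulseEvent(
                zenith=(e.time, e.volume),
                nadirs=((nxt.time, nxt.volume),),
                amplitude=e.volume - nxt.volume,
                mode="A_vitro",
            )
        )
    return events


def amplitudes_mode_b(extrema: list[Extremum]) -> list[PulseEvent]:
    """In-vivo definition: amplitude = zenith − mean of both adjacent nadirs.

    Boundary zeniths lacking either flanking nadir are excluded.  Exactly
    invariant to any drift linear in time (the symmetric mean cancels it).
    """
    events = []
    for i, e in enumerate(extrema):
        if e.kind != "zenith":
            continue
        before = next((x for x in reversed(extrema[:i]) if x.kind == "nadir"), None)
        after = next((x for x in extrema[i + 1:] if x.kind == "nadir"), None)
        if before is None or after is None:
            continue
        amp = e.volume - (before.volume + after.volume) / 2.0
        events.append(
            PulseEvent(
                zenith=(e.time, e.volume),
                nadirs=((before.time, before.volume), (after.time, after.volume)),
                amplitude=amp,
                mode="B_vivo",
            )
        )
    return events


def normalize_drift(
    series: VolumeTimeSeries, window: tuple[float, float] | None = None
) -> VolumeTimeSeries:
    """Subtract the least-squares line fitted over the analysis window.

    Returns the window's samples with ``normalized_volumes`` set to the
    residual from the fitted line (the in-vivo display normalization: volume
    minus the linear trend of the contrast washout slope).
    """
    t, v = series.times, series.volumes
    if window is not None:
        sel = (t >= window[0]) & (t <= window[1])
        t, v = t[sel], v[sel]
    if len(t) < 3:
        raise ValueError("normalization window must contain at least 3 samples")
    if np.ptp(t) == 0:
        raise ValueError("degenerate window: all timestamps equal")
    slope, intercept = np.polyfit(t, v, 1)
    return VolumeTimeSeries(
        times=t, volumes=v, normalized_volumes=v - (slope * t + intercept)
    )


def summarize(
    events: list[PulseEvent],
    noise_floor: float = 3.0,
    reference_period: float | None = None,
    period_tolerance: float = 0.2,
) -> PulsationSummary:
    """Pulsation statistics and the detection verdict.

    Detection requires AVP ≥ noise floor *and*, when a reference period is
    given, the median inter-zenith interval to agree with it within
    ``period_tolerance`` (fraction).  Zero events → not detected.
    """
    n = len(events)
    if n == 0:
        return PulsationSummary(
            0, np.nan, np.nan, np.nan, False, np.nan, reference_period, noise_floor
        )
    amps = np.array([e.amplitude for e in events])
    avp = float(np.mean(amps))
    sd = float(np.std(amps, ddof=1)) if n > 1 else np.nan
    cov = 100.0 * sd / avp if (n > 1 and avp > 0) else np.nan
    zt = np.array([e.zenith[0] for e in events])
    period = float(np.median(np.diff(np.sort(zt)))) if n > 1 else np.nan
    detected = avp >= noise_floor
    if reference_period is not None:
        detected = bool(
            detected
            and np.isfinite(period)
            and abs(period - reference_period) <= period_tolerance * reference_period
        )
    return PulsationSummary(n, avp, sd, cov, bool(detected), period, reference_period,
                            noise_floor)


@dataclass(frozen=True)
class RegressionResult:
    slope: float        # mm³/mmHg
    intercept: float    # mm³
    r_squared: float
    n_points: int


def pressure_regression(pairs) -> RegressionResult:
    """OLS of volume pulsation (mm³) against pulse pressure (mmHg)."""
    pairs = np.asarray(pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or pairs.shape[0] < 3:
        raise ValueError("need at least 3 (pulse pressure, AVP) pairs")
    pp, avp = pairs[:, 0], pairs[:, 1]
    if np.ptp(pp) == 0:
        raise ValueError("all pulse pressures equal; regression undefined")
    res = linregress(pp, avp)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_points=len(pp),
    )


# ---------------------------------------------------------------------------
# ECG alignment
# ---------------------------------------------------------------------------

@dataclass
class EcgTrace:
    """R-peak times on the monitoring-device clock, plus the offset that
    converts them to the scanner clock (scanner time = peak + offset)."""

    r_peak_times: np.ndarray
    clock_offset: float = 0.0

    def __post_init__(self) -> None:
        self.r_peak_times = np.asarray(self.r_peak_times, dtype=float)
        if len(self.r_peak_times) > 1 and np.any(np.diff(self.r_peak_times) <= 0):
            raise ValueError("R-peak times must be strictly increasing")

    @property
    def scanner_times(self) -> np.ndarray:
        return self.r_peak_times + self.clock_offset


@dataclass
class EcgAlignment:
    pairs: list[tuple[float, float, float]]  # (zenith time, R-peak time, lag)
    unpaired: list[float] = field(default_factory=list)

    @property
    def lags(self) -> np.ndarray:
        return np.array([p[2] for p in self.pairs])

    @property
    def mean_lag(self) -> float:
        return float(np.mean(self.lags)) if self.pairs else np.nan


def align_ecg(extrema: list[Extremum], ecg: EcgTrace) -> EcgAlignment:
    """Pair each zenith with the nearest preceding R-peak.

    On a pulsating volume the zenith follows the upstroke (the R-peak) by
    about a quarter period, so a stable small positive lag across pulses is
    the signature that the apparent pulsation tracks the heart.
    """
    zeniths = [e for e in extrema if e.kind == "zenith"]
    peaks = ecg.scanner_times
    if len(peaks) == 0:
        warnings.warn("empty ECG trace: no zenith could be paired", stacklevel=2)
        return EcgAlignment(pairs=[], unpaired=[z.time for z in zeniths])
    if zeniths:
        z_lo, z_hi = zeniths[0].time, zeniths[-1].time
        if peaks[0] > z_hi or peaks[-1] < z_lo - 2.0:
            raise ValueError("ECG and volume series time ranges are disjoint")
    pairs, unpaired = [], []
    for z in zeniths:
        prior = peaks[peaks <= z.time]
        if len(prior) == 0:
            unpaired.append(z.time)
        else:
            pairs.append((z.time, float(prior[-1]), float(z.time - prior[-1])))
    return EcgAlignment(pairs=pairs, unpaired=unpaired)
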