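"""Beat detection, pulse-width morphology and variability spectral analysis
of finger photoplethysmogram (PPG) recordings.

The variability of the PPG — the beat-to-beat fluctuation of its pulse
amplitude and baseline — carries autonomic and hemodynamic information.  The
spectral features used here are band powers of that variability in three
bands: low frequency (LF, 0.04-0.145 Hz), mid frequency (MF, 0.08-0.145 Hz,
a sub-band of LF) and high frequency (HF, 0.145-0.45 Hz).  Reported features
are the normalized LF power ``lf_nu = LF/(LF+HF)``, the normalized MF power
``mf_nu = MF/(LF+HF)`` and the ratio ``lf_hf = LF/HF``.  The morphological
feature is the pulse width: the duration of a pulse at half of its
trough-to-peak amplitude, normalized by the beat's peak-to-peak interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import interpolate, signal

from .errors import BeatDetectionError

log = logging.getLogger(__name__)

#: (low, high) Hz edges of the LF, MF and HF variability bands.
DEFAULT_BANDS: tuple[tuple[float, float], ...] = (
    (0.04, 0.145),
    (0.08, 0.145),
    (0.145, 0.45),
)

#: Upper edge of the HF band; variability series must resolve up to here.
HF_EDGE_HZ = 0.45


@dataclass(frozen=True)
class PPGRecording:
    """A uniformly sampled PPG waveform."""

    samples: np.ndarray
    fs: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError("recording needs at least 2 samples in a 1-d array")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("recording contains non-finite samples")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.samples.size) / self.fs

    def to_text(self, path) -> None:
        """Write as two-column delimited text (time_s, ppg)."""
        np.savetxt(
            path,
            np.column_stack([self.times(), self.samples]),
            fmt="%.6f",
            delimiter="\t",
            header="time_s\tppg",
            comments="",
        )

    @classmethod
    def from_text(cls, path, fs: float | None = None) -> "PPGRecording":
        """Read two-column (time_s, ppg) text, or one column with ``fs`` given."""
        arr = np.loadtxt(path, skiprows=_count_header_rows(path), ndmin=2)
        if arr.shape[1] >= 2:
            t, x = arr[:, 0], arr[:, 1]
            dt = np.diff(t)
            if dt.size == 0 or not np.allclose(dt, dt[0], rtol=1e-3):
                raise ValueError(f"{path}: time column is not uniformly sampled")
            return cls(x, fs=1.0 / dt[0], start_time=float(t[0]))
        if fs is None:
            raise ValueError(f"{path}: single-column input requires an explicit fs")
        return cls(arr[:, 0], fs=fs)


def _count_header_rows(path) -> int:
    with open(path) as fh:
        first = fh.readline()
    try:
        float(first.split()[0])
        return 0
    except (ValueError, IndexError):
        return 1


@dataclass(frozen=True)
class BeatSeries:
    """Per-beat fiducials extracted from a recording.

    Beat k spans from its onset trough to its systolic peak; ``beat_interval``
    is the peak-to-peak spacing ending at that beat's peak, which also
    normalizes the pulse width.
    """

    trough_time: np.ndarray
    peak_time: np.ndarray
    trough_value: np.ndarray
    peak_value: np.ndarray
    amplitude: np.ndarray
    beat_interval: np.ndarray
    pulse_width_norm: np.ndarray
    n_discarded: int = 0

    def __post_init__(self) -> None:
        n = self.peak_time.size
        for name in ("trough_time", "trough_value", "peak_value", "amplitude",
                     "beat_interval", "pulse_width_norm"):
            if getattr(self, name).size != n:
                raise ValueError(f"fiducial array {name!r} length mismatch")
        if n and (np.any(np.diff(self.peak_time) <= 0) or np.any(self.amplitude <= 0)):
            raise ValueError("beat times must increase and amplitudes be positive")

    def __len__(self) -> int:
        return self.peak_time.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trough_time": self.trough_time,
                "peak_time": self.peak_time,
                "trough_value": self.trough_value,
                "peak_value": self.peak_value,
                "amplitude": self.amplitude,
                "beat_interval": self.beat_interval,
                "pulse_width_norm": self.pulse_width_norm,
            }
        )


@dataclass(frozen=True)
class VariabilitySpectrum:
    """Power spectral density of a beat-to-beat variability series."""

    freqs: np.ndarray
    psd: np.ndarray
    series_kind: str = "amplitude"
    resample_rate: float = 2.0

    def __post_init__(self) -> None:
        if np.any(np.diff(self.freqs) <= 0) or np.any(self.freqs < 0):
            raise ValueError("frequencies must be nonnegative and increasing")
        if np.any(self.psd < 0):
            raise ValueError("power density must be nonnegative")


@dataclass(frozen=True)
class SpectralFeatures:
    """Band powers and normalized spectral features of PPG variability."""

    lf_power: float
    mf_power: float
    hf_power: float
    total_power: float
    lf_nu: float
    mf_nu: float
    lf_hf_ratio: float


def detect_beats(rec: PPGRecording, refractory_s: float = 0.3) -> BeatSeries:
    """Locate one (onset trough, systolic peak) pair per cardiac pulse.

    Peak candidates are picked on a 0.5-10 Hz band-passed copy of the signal
    with an adaptive prominence threshold and the given refractory period;
    fiducials are then refined on the unfiltered waveform.  Beats with
    non-positive trough-to-peak amplitude, or whose normalized pulse width
    falls outside (0, 1], are discarded (counted in ``n_discarded``).

    Raises
    ------
    BeatDetectionError
        If the recording is flat or pulses are buried in noise.
    ValueError
        If the recording is shorter than 10 s or sampled below 50 Hz.
    """
    if rec.duration_s < 10.0:
        raise ValueError("beat detection requires at least 10 s of signal")
    if rec.fs < 50.0:
        raise ValueError("beat detection requires a sampling rate of at least 50 Hz")
    x = rec.samples
    sos = signal.butter(3, [0.5, 10.0], btype="bandpass", fs=rec.fs, output="sos")
    xf = signal.sosfiltfilt(sos, x)

    spread = np.percentile(xf, 95) - np.percentile(xf, 5)
    if spread <= 0 or np.ptp(x) == 0:
        raise BeatDetectionError("no detectable pulses: signal has no oscillation")
    peaks, _ = signal.find_peaks(
        xf, distance=max(int(round(refractory_s * rec.fs)), 1), prominence=0.25 * spread
    )
    if peaks.size < 3:
        raise BeatDetectionError("no detectable pulses: fewer than 3 peak candidates")

    med_gap = float(np.median(np.diff(peaks)))
    half_win = max(int(round(0.25 * med_gap)), 1)
    # refine peaks on the raw waveform
    raw_peaks = np.empty(peaks.size, dtype=int)
    for i, p in enumerate(peaks):
        lo, hi = max(p - half_win, 0), min(p + half_win + 1, x.size)
        raw_peaks[i] = lo + int(np.argmax(x[lo:hi]))
    raw_peaks = np.unique(raw_peaks)
    if raw_peaks.size < 3:
        raise BeatDetectionError("no detectable pulses after peak refinement")

    # onset troughs: minimum of the raw signal between consecutive peaks
    troughs = np.empty(raw_peaks.size - 1, dtype=int)
    for i in range(raw_peaks.size - 1):
        lo, hi = raw_peaks[i], raw_peaks[i + 1]
        troughs[i] = lo + int(np.argmin(x[lo:hi + 1]))

    # quality gate: a pulsatile signal concentrates its variance in the
    # cardiac band; broadband noise leaves only a small fraction there
    band_frac = float(np.var(xf) / np.var(x))
    if band_frac < 0.25:
        raise BeatDetectionError(
            "no detectable pulses: only "
            f"{band_frac:.0%} of signal variance lies in the cardiac band"
        )

    rows = {k: [] for k in ("tt", "pt", "tv", "pv", "amp", "ival", "pwn")}
    discarded = 0
    t0, fs = rec.start_time, rec.fs
    for b in range(1, raw_peaks.size):
        pk = raw_peaks[b]
        tr = troughs[b - 1]
        amp = x[pk] - x[tr]
        interval = (pk - raw_peaks[b - 1]) / fs
        if amp <= 0 or interval <= 0:
            discarded += 1
            continue
        # width window: onset trough to the next trough (or symmetric tail)
        w_hi = troughs[b] + 1 if b < troughs.size + 0 else min(
            pk + (pk - tr) + 1, x.size
        )
        window = x[tr:w_hi]
        try:
            pwn = compute_pulse_width(window, fs, interval)
        except ValueError:
            discarded += 1
            continue
        if not 0 < pwn <= 1:
            discarded += 1
            continue
        rows["tt"].append(t0 + tr / fs)
        rows["pt"].append(t0 + pk / fs)
        rows["tv"].append(x[tr])
        rows["pv"].append(x[pk])
        rows["amp"].append(amp)
        rows["ival"].append(interval)
        rows["pwn"].append(pwn)
    if not rows["pt"]:
        raise BeatDetectionError("no detectable pulses: every candidate beat rejected")
    if discarded:
        log.warning("detect_beats discarded %d candidate beats", discarded)
    return BeatSeries(
        trough_time=np.array(rows["tt"]),
        peak_time=np.array(rows["pt"]),
        trough_value=np.array(rows["tv"]),
        peak_value=np.array(rows["pv"]),
        amplitude=np.array(rows["amp"]),
        beat_interval=np.array(rows["ival"]),
        pulse_width_norm=np.array(rows["pwn"]),
        n_discarded=discarded,
    )


def compute_pulse_width(
    beat_window: np.ndarray, fs: float, beat_interval: float
) -> float:
    """Normalized width of a single pulse at half its trough-to-peak amplitude.

    The window must contain exactly one pulse including its trough and peak.
    The width is the time the signal spends above trough + amplitude/2 around
    the peak, with linear interpolation at the two half-amplitude crossings,
    divided by the beat interval.
    """
    w = np.asarray(beat_window, dtype=float)
    if w.size < 3:
        raise ValueError("beat window too short")
    if not beat_interval > 0:
        raise ValueError("beat interval must be positive")
    trough, peak = float(np.min(w)), float(np.max(w))
    amp = peak - trough
    if amp <= 0:
        raise ValueError("pulse amplitude must be positive")
    half = trough + amp / 2.0
    ipk = int(np.argmax(w))
    below_left = np.nonzero(w[:ipk] < half)[0]
    below_right = np.nonzero(w[ipk:] < half)[0]
    if below_left.size == 0 or below_right.size == 0:
        raise ValueError("window never crosses half amplitude on both sides of the peak")
    j = below_left[-1]  # w[j] < half <= w[j+1]
    t_left = j + (half - w[j]) / (w[j + 1] - w[j])
    k = ipk + below_right[0]  # w[k-1] >= half > w[k]
    t_right = (k - 1) + (w[k - 1] - half) / (w[k - 1] - w[k])
    return float((t_right - t_left) / fs / beat_interval)


def build_variability_series(
    beats: BeatSeries, kind: str = "amplitude", resample_rate: float = 2.0
) -> np.ndarray:
    """Interpolate a per-beat series onto a uniform grid and remove its mean.

    ``kind='amplitude'`` uses the trough-to-peak amplitude of each beat (the
    default variability series); ``kind='baseline'`` uses the trough value.
    Cubic interpolation onto a grid at ``resample_rate`` (Hz), which must
    exceed twice the 0.45 Hz upper band edge.
    """
    if kind not in ("amplitude", "baseline"):
        raise ValueError(f"unknown series kind {kind!r}")
    if not resample_rate > 2 * HF_EDGE_HZ:
        raise ValueError(
            f"resample_rate must exceed {2 * HF_EDGE_HZ} Hz to resolve the HF band"
        )
    if len(beats) < 10:
        raise ValueError(f"need at least 10 beats, got {len(beats)}")
    if kind == "amplitude":
        t, v = beats.peak_time, beats.amplitude
    else:
        t, v = beats.trough_time, beats.trough_value
    spline = interpolate.CubicSpline(t, v)
    grid = np.arange(t[0], t[-1], 1.0 / resample_rate)
    series = spline(grid)
    return series - series.mean()


def estimate_psd(
    series: np.ndarray,
    resample_rate: float = 2.0,
    segment_s: float = 128.0,
    overlap_frac: float = 0.5,
    window: str = "hann",
    detrend: str | bool = "linear",
    series_kind: str = "amplitude",
) -> VariabilitySpectrum:
    """Averaged modified-periodogram (Welch) PSD of a variability series.

    Defaults: 128-s segments, Hann window, 50% overlap, per-segment linear
    detrend — a frequency resolution below 0.01 Hz, enough to separate the
    0.04 Hz band edge within a 10-min recording.  With a rectangular window
    and no detrending the integrated density matches the series variance
    (Parseval) to within integration tolerance.
    """
    series = np.asarray(series, dtype=float)
    nperseg = int(round(segment_s * resample_rate))
    if series.size < nperseg:
        raise ValueError(
            f"series length {series.size} shorter than one {segment_s}-s segment"
        )
    freqs, psd = signal.welch(
        series,
        fs=resample_rate,
        window=window,
        nperseg=nperseg,
        noverlap=int(nperseg * overlap_frac),
        detrend=detrend,
        scaling="density",
    )
    return VariabilitySpectrum(freqs, psd, series_kind, resample_rate)


def _band_power(freqs: np.ndarray, psd: np.ndarray, lo: float, hi: float) -> float:
    """Trapezoidal integral of the PSD over [lo, hi], interpolating edges."""
    f = np.concatenate([[lo], freqs[(freqs > lo) & (freqs < hi)], [hi]])
    p = np.interp(f, freqs, psd)
    return float(np.trapezoid(p, f))


def spectral_features(
    spec: VariabilitySpectrum,
    bands: tuple[tuple[float, float], ...] = DEFAULT_BANDS,
    normalization: str = "lf_hf",
) -> SpectralFeatures:
    """Band powers and normalized features from a variability spectrum.

    ``bands`` are the (low, high) Hz edges of the LF, MF and HF bands.  Under
    the default normalization ``lf_nu = LF/(LF+HF)`` and ``mf_nu =
    MF/(LF+HF)``; ``normalization='total'`` divides by the total power over
    the union of the LF and HF ranges instead.
    """
    (lf_lo, lf_hi), (mf_lo, mf_hi), (hf_lo, hf_hi) = bands
    f, p = spec.freqs, spec.psd
    if f[0] > lf_lo or f[-1] < hf_hi:
        raise ValueError(
            f"spectrum [{f[0]:.3g}, {f[-1]:.3g}] Hz does not cover the "
            f"[{lf_lo}, {hf_hi}] Hz analysis range"
        )
    lf = _band_power(f, p, lf_lo, lf_hi)
    mf = _band_power(f, p, mf_lo, mf_hi)
    hf = _band_power(f, p, hf_lo, hf_hi)
    total = _band_power(f, p, lf_lo, hf_hi)
    if hf == 0:
        raise ValueError("HF band power is zero: LF/HF ratio undefined")
    denom = lf + hf if normalization == "lf_hf" else total
    if normalization not in ("lf_hf", "total"):
        raise ValueError(f"unknown normalization {normalization!r}")
    return SpectralFeatures(
        lf_power=lf,
        mf_power=mf,
        hf_power=hf,
        total_power=total,
        lf_nu=lf / denom,
        mf_nu=mf / denom,
        lf_hf_ratio=lf / hf,
    )


def extract_ppg_features(
    rec: PPGRecording,
    bands: tuple[tuple[float, float], ...] = DEFAULT_BANDS,
    resample_rate: float = 2.0,
    segment_s: float = 128.0,
    overlap_frac: float = 0.5,
    series_kind: str = "amplitude",
    normalization: str = "lf_hf",
    refractory_s: float = 0.3,
) -> dict[str, float]:
    """End-to-end extraction of the four PPG features from a recording.

    Returns a dict with ``lf_nu``, ``mf_nu``, ``lf_hf`` (from the variability
    spectrum of the per-beat series) and ``pw`` (the median normalized pulse
    width over all detected beats).
    """
    beats = detect_beats(rec, refractory_s=refractory_s)
    series = build_variability_series(beats, kind=series_kind, resample_rate=resample_rate)
    seg = min(segment_s, series.size / resample_rate)
    spec = estimate_psd(
        series, resample_rate, segment_s=seg, series_kind=series_kind,
        overlap_frac=overlap_frac,
    )
    feats = spectral_features(spec, bands=bands, normalization=normalization)
    return {
        "lf_nu": feats.lf_nu,
        "mf_nu": feats.mf_nu,
        "lf_hf": feats.lf_hf_ratio,
        "pw": float(np.median(beats.pulse_width_norm)),
    }
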