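"""Synthetic PPG waveforms and synthetic hemodynamic cohorts.

The study conditions emulated here are an intensive-care cohort of 48
post-cardiac-surgery patients: ~10-minute finger PPG recordings sampled at
200 Hz, and routine measurements with cohort moments HR 84 bpm, MAP 78 mmHg,
CVP 14.5 mmHg, CO 5.7 L/min and SVR 926 dyn.s.cm^-5 (means; spreads taken
from the reported standard errors at N=48).  The generators provide full
ground truth — pulse widths, modulation depths, and a sparse linear model
from transformed features to the target — so every downstream stage (beat
detection, spectral analysis, stepwise selection, nested cross-validation)
can be tested against known answers.

The PPG generator renders a train of symmetric unimodal pulses (no dicrotic
notch) whose per-beat peak amplitude is modulated by low-frequency sinusoids,
on top of sinusoidal baseline wander and white Gaussian noise.  The cohort
generator draws strictly positive base features, expands them with the
squared/cubed/log transforms, and forms the target as a sparse weighted sum
of transformed features plus Gaussian noise; systemic vascular resistance
always satisfies SVR = 80*(MAP-CVP)/CO exactly, by construction.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import features as ft
from .errors import ConfigurationError
from .ppg_features import PPGRecording, compute_pulse_width

PULSE_SHAPES = ("gaussian", "triangular", "rectangular")

_GAUSS_FWHM = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass(frozen=True)
class SynthPPGConfig:
    """Parameters of a synthetic PPG recording.

    ``pulse_width_frac`` is the target normalized pulse width: the realized
    width of each pulse at half its trough-to-peak amplitude divided by the
    beat interval.  ``am_components`` are (frequency Hz, relative depth)
    amplitude-modulation terms applied to the per-beat peak amplitude as
    ``1 + sum(depth_k * sin(2 pi f_k t))``; ``baseline_components`` are
    (frequency Hz, amplitude) additive baseline-wander sinusoids.
    """

    duration_s: float = 600.0
    fs: float = 200.0
    heart_rate_bpm: float = 84.0
    pulse_shape: str = "gaussian"
    pulse_width_frac: float = 0.35
    am_components: tuple[tuple[float, float], ...] = ((0.10, 0.08), (0.30, 0.06))
    baseline_components: tuple[tuple[float, float], ...] = ((0.25, 0.03),)
    noise_sd: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.duration_s > 0:
            raise ConfigurationError(f"duration_s must be positive, got {self.duration_s}")
        if not self.fs >= 50:
            raise ConfigurationError(f"fs must be at least 50 Hz, got {self.fs}")
        if not self.heart_rate_bpm > 0:
            raise ConfigurationError(
                f"heart_rate_bpm must be positive, got {self.heart_rate_bpm}"
            )
        if self.pulse_shape not in PULSE_SHAPES:
            raise ConfigurationError(
                f"pulse_shape must be one of {PULSE_SHAPES}, got {self.pulse_shape!r}"
            )
        if not 0 < self.pulse_width_frac < 1:
            raise ConfigurationError(
                f"pulse_width_frac must lie in (0, 1), got {self.pulse_width_frac}"
            )
        for f, _ in tuple(self.am_components) + tuple(self.baseline_components):
            if not 0 < f < self.fs / 2:
                raise ConfigurationError(
                    f"am_components/baseline_components: frequency {f} Hz outside (0, fs/2)"
                )
        if self.noise_sd < 0:
            raise ConfigurationError(f"noise_sd must be nonnegative, got {self.noise_sd}")


def _render_template(shape: str, param: float, offsets: np.ndarray) -> np.ndarray:
    """Unit-height pulse template evaluated at time offsets (beat interval = 1)."""
    if shape == "gaussian":
        return np.exp(-0.5 * (offsets / param) ** 2)
    if shape == "triangular":
        return np.clip(1.0 - np.abs(offsets) / (param / 2.0), 0.0, None)
    # rectangular
    return (np.abs(offsets) <= param / 2.0).astype(float)


def _realized_width(shape: str, param: float) -> float:
    """Half-amplitude width of one pulse in a periodic unit-interval train."""
    t = np.linspace(-0.5, 1.5, 8001)
    w = sum(_render_template(shape, param, t - c) for c in (-1.0, 0.0, 1.0, 2.0))
    mid = w[(t >= -0.5) & (t <= 0.5)]
    tm = t[(t >= -0.5) & (t <= 0.5)]
    return compute_pulse_width(mid, fs=1.0 / (tm[1] - tm[0]), beat_interval=1.0)


@functools.lru_cache(maxsize=128)
def _calibrate_shape_param(shape: str, width_frac: float) -> float:
    """Shape parameter whose rendered periodic train has the target width.

    For isolated pulses the closed forms apply (Gaussian FWHM =
    2*sqrt(2 ln 2)*sigma; triangle half-height chord = base/2; rectangle
    width = duration).  For wide pulses the tails of neighbouring beats raise
    the inter-beat trough and shrink the realized half-amplitude width, so
    the parameter is refined by bisection on the rendered waveform.
    """
    from scipy.optimize import brentq

    naive = {
        "gaussian": width_frac / _GAUSS_FWHM,
        "triangular": 2.0 * width_frac,
        "rectangular": width_frac,
    }[shape]
    if shape == "rectangular":
        return naive
    err = _realized_width(shape, naive) - width_frac
    if abs(err) < 1e-4:
        return naive
    return float(
        brentq(lambda p: _realized_width(shape, p) - width_frac, 0.5 * naive, 2.0 * naive,
               xtol=1e-6)
    )


def generate_ppg(config: SynthPPGConfig) -> PPGRecording:
    """Render a synthetic PPG recording from its configuration.

    The waveform is a periodic pulse train at the configured heart rate with
    per-beat amplitude modulation, sinusoidal baseline wander and additive
    white Gaussian noise; the same seed and configuration always yield
    bit-identical samples.
    """
    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration_s * config.fs))
    t = np.arange(n) / config.fs
    period = 60.0 / config.heart_rate_bpm
    param = _calibrate_shape_param(config.pulse_shape, config.pulse_width_frac) * period

    # support half-width of one pulse, in samples
    if config.pulse_shape == "gaussian":
        support = 6.0 * param
    elif config.pulse_shape == "triangular":
        support = 0.5 * param
    else:
        support = 0.5 * param + 2.0 / config.fs
    x = np.zeros(n)
    # ghost beats beyond both edges keep the train periodic at the borders
    k_lo = int(math.floor((-support) / period)) - 1
    k_hi = int(math.ceil((config.duration_s + support) / period)) + 1
    for k in range(k_lo, k_hi):
        c = (k + 0.5) * period
        amp = 1.0 + sum(
            depth * math.sin(2.0 * math.pi * f * c) for f, depth in config.am_components
        )
        lo = max(int(math.ceil((c - support) * config.fs)), 0)
        hi = min(int(math.floor((c + support) * config.fs)) + 1, n)
        if lo >= hi:
            continue
        x[lo:hi] += amp * _render_template(
            config.pulse_shape, param, t[lo:hi] - c
        )
    for f, a in config.baseline_components:
        x += a * np.sin(2.0 * math.pi * f * t)
    if config.noise_sd > 0:
        x += config.noise_sd * rng.standard_normal(n)
    return PPGRecording(x, fs=config.fs)


#: Default per-subject feature distributions: (mean, s.d.) pairs.  Vitals use
#: the cohort moments (s.d. = reported standard error * sqrt(48)); the PPG
#: feature moments are not reported for the original cohort and are set to
#: plausible values for ICU patients.
DEFAULT_FEATURE_STATS: dict[str, tuple[float, float]] = {
    "lf_nu": (0.55, 0.15),
    "mf_nu": (0.30, 0.10),
    "lf_hf": (1.50, 0.80),  # used only when spectral_consistency is off
    "hr": (84.0, 2.0 * math.sqrt(48)),
    "map": (78.0, 3.0 * math.sqrt(48)),
    "cvp": (14.5, 0.7 * math.sqrt(48)),
    "pw": (0.35, 0.08),
}

_TARGET_MEANS = {"CO": 5.7, "SVR": 926.0}
_DEFAULT_PLANTED = {
    # CO model: log(lf_nu) and log(pw); SVR model: log(lf_hf).  Weights sized
    # so the planted signal explains roughly a quarter of the target variance,
    # matching the held-out correlations (~0.5) seen in the original cohort.
    "CO": (((22, 28), (-1.5, -2.2)), 1.2),
    "SVR": (((24,), (200.0,)), 215.0),
}


@dataclass(frozen=True)
class SynthCohortConfig:
    """Parameters of a synthetic hemodynamic cohort.

    The target column (CO in L/min or SVR in dyn.s.cm^-5) is generated as
    ``intercept + sum(w_j * phi_j) + N(0, noise_sd^2)`` where ``phi_j`` are
    the transformed features at ``true_feature_indices``.  When
    ``true_intercept`` is None it is calibrated (deterministically) so the
    expected target equals the cohort mean (5.7 L/min or 926 dyn.s.cm^-5).
    With ``spectral_consistency`` (default) the LF/HF ratio is derived from
    the normalized LF power as ``lf_nu / (1 - lf_nu)`` — the relation that
    holds whenever both come from one spectrum — instead of being drawn
    independently.
    """

    n_subjects: int = 48
    feature_stats: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_FEATURE_STATS)
    )
    true_feature_indices: tuple[int, ...] | None = None
    true_weights: tuple[float, ...] | None = None
    true_intercept: float | None = None
    noise_sd: float | None = None
    target: str = "CO"
    spectral_consistency: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target not in _TARGET_MEANS:
            raise ConfigurationError(f"target must be 'CO' or 'SVR', got {self.target!r}")
        (idx, w), nsd = _DEFAULT_PLANTED[self.target]
        if self.true_feature_indices is None:
            object.__setattr__(self, "true_feature_indices", idx)
            object.__setattr__(self, "true_weights", w)
        elif self.true_weights is None:
            raise ConfigurationError("true_weights: required when indices are given")
        if self.noise_sd is None:
            object.__setattr__(self, "noise_sd", nsd)
        object.__setattr__(
            self, "true_feature_indices", tuple(self.true_feature_indices)
        )
        object.__setattr__(self, "true_weights", tuple(self.true_weights))
        bad = [j for j in self.true_feature_indices if not 1 <= j <= ft.N_FEATURES]
        if bad:
            raise ConfigurationError(f"true_feature_indices outside 1..28: {bad}")
        if len(self.true_weights) != len(self.true_feature_indices):
            raise ConfigurationError(
                "true_weights: need one weight per planted feature index"
            )
        if self.noise_sd < 0:
            raise ConfigurationError(f"noise_sd must be nonnegative, got {self.noise_sd}")
        if self.n_subjects < 3 + len(self.true_feature_indices):
            raise ConfigurationError(
                f"n_subjects must be at least 3 + number of planted features "
                f"({3 + len(self.true_feature_indices)}), got {self.n_subjects}"
            )
        for name in ("lf_nu", "mf_nu", "hr", "map", "cvp", "pw"):
            if name not in self.feature_stats:
                raise ConfigurationError(f"feature_stats: missing entry for {name!r}")


@dataclass(frozen=True)
class GroundTruth:
    """The generating model of a synthetic cohort."""

    target: str
    feature_indices: tuple[int, ...]
    weights: tuple[float, ...]
    intercept: float
    noise_sd: float

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "target": self.target,
                    "feature_indices": list(self.feature_indices),
                    "feature_formulas": [ft.feature_formula(j) for j in self.feature_indices],
                    "weights": [float(w) for w in self.weights],
                    "intercept": float(self.intercept),
                    "noise_sd": float(self.noise_sd),
                },
                fh,
                sort_keys=False,
            )

    @classmethod
    def from_yaml(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(
            d["target"],
            tuple(d["feature_indices"]),
            tuple(d["weights"]),
            d["intercept"],
            d["noise_sd"],
        )


@dataclass(frozen=True)
class SynthCohort:
    """A generated cohort table plus its generating model."""

    table: pd.DataFrame
    ground_truth: GroundTruth

    def feature_table(self) -> pd.DataFrame:
        """The 28-column transformed feature table with targets attached."""
        return ft.build_feature_table(self.table)


def _draw_base_features(
    rng: np.random.Generator, stats: Mapping[str, tuple[float, float]], consistent: bool
) -> dict[str, float]:
    """One subject's base features; truncated so logs and ratios are defined."""

    def positive(name, lo=1e-6, hi=math.inf):
        m, s = stats[name]
        for _ in range(1000):
            v = rng.normal(m, s)
            if lo < v < hi:
                return v
        raise RuntimeError(f"could not draw a valid value for {name}")

    # MF band is a sub-band of LF: draw the pair jointly until mf_nu < lf_nu
    for _ in range(1000):
        lf_nu = positive("lf_nu", hi=0.95)
        mf_nu = positive("mf_nu")
        if mf_nu < lf_nu:
            break
    else:
        raise RuntimeError("could not draw a valid (lf_nu, mf_nu) pair")
    row = {
        "lf_nu": lf_nu,
        "mf_nu": mf_nu,
        "lf_hf": lf_nu / (1.0 - lf_nu) if consistent else positive("lf_hf"),
        "hr": positive("hr"),
        "map": positive("map"),
        "cvp": positive("cvp"),
        "pw": positive("pw", hi=0.95),
    }
    row["map_over_hr"] = row["map"] / row["hr"]
    return row


@functools.lru_cache(maxsize=32)
def _calibrated_intercept(
    target: str,
    indices: tuple[int, ...],
    weights: tuple[float, ...],
    stats_key: tuple,
    consistent: bool,
) -> float:
    """Intercept giving the target its cohort mean, from a fixed reference draw."""
    stats = dict(stats_key)
    rng = np.random.default_rng(202_301)  # fixed: the calibration is a constant
    phi_means = np.zeros(len(indices))
    n_ref = 4000
    for _ in range(n_ref):
        row = _draw_base_features(rng, stats, consistent)
        phi = ft.transform_features(
            {k: row[k] for k in ft.BASE_FEATURE_NAMES}
        )
        phi_means += phi[[j - 1 for j in indices]]
    phi_means /= n_ref
    return float(_TARGET_MEANS[target] - np.dot(weights, phi_means))


def generate_cohort(config: SynthCohortConfig) -> SynthCohort:
    """Draw a synthetic cohort with a known sparse feature-to-target model.

    Base features are drawn independently per subject (truncated to remain
    strictly positive); the target is the planted linear model in transformed
    features plus Gaussian noise; the complementary hemodynamic column is
    completed through SVR = 80*(MAP-CVP)/CO, back-solving CO when the target
    is SVR.  Rows violating positivity (CO <= 0, MAP <= CVP, target <= 0)
    are redrawn.
    """
    rng = np.random.default_rng(config.seed)
    stats_key = tuple(sorted((k, tuple(v)) for k, v in config.feature_stats.items()))
    intercept = (
        config.true_intercept
        if config.true_intercept is not None
        else _calibrated_intercept(
            config.target,
            config.true_feature_indices,
            config.true_weights,
            stats_key,
            config.spectral_consistency,
        )
    )
    sel = [j - 1 for j in config.true_feature_indices]
    w = np.asarray(config.true_weights, dtype=float)

    rows = []
    for i in range(config.n_subjects):
        for _ in range(1000):
            base = _draw_base_features(rng, config.feature_stats, config.spectral_consistency)
            if base["map"] <= base["cvp"]:
                continue
            phi = ft.transform_features({k: base[k] for k in ft.BASE_FEATURE_NAMES})
            y = intercept + float(phi[sel] @ w) + rng.normal(0.0, config.noise_sd)
            if y <= 0:
                continue
            if config.target == "CO":
                co = y
                svr = ft.compute_svr(base["map"], base["cvp"], co)
            else:
                co = 80.0 * (base["map"] - base["cvp"]) / y
                if co <= 0:
                    continue
                # re-derive so the stored column satisfies the resistance
                # identity bit-exactly (differs from y by at most 1 ulp)
                svr = ft.compute_svr(base["map"], base["cvp"], co)
            rows.append(
                {
                    "subject_id": f"S{i + 1:03d}",
                    "HR": base["hr"],
                    "MAP": base["map"],
                    "CVP": base["cvp"],
                    "CO": co,
                    "SVR": svr,
                    "lf_nu": base["lf_nu"],
                    "mf_nu": base["mf_nu"],
                    "lf_hf": base["lf_hf"],
                    "hr": base["hr"],
                    "map": base["map"],
                    "map_over_hr": base["map_over_hr"],
                    "pw": base["pw"],
                }
            )
            break
        else:
            raise RuntimeError("cohort row rejection sampling failed to converge")
    table = pd.DataFrame(rows)
    truth = GroundTruth(
        target=config.target,
        feature_indices=config.true_feature_indices,
        weights=config.true_weights,
        intercept=intercept,
        noise_sd=config.noise_sd,
    )
    return SynthCohort(table, truth)


def ppg_config_for_subject(
    base: Mapping[str, float],
    duration_s: float = 600.0,
    fs: float = 200.0,
    modulation_power: float = 0.01,
    noise_sd: float = 0.005,
    seed: int = 0,
) -> SynthPPGConfig:
    """A per-subject PPG configuration realizing the subject's base features.

    Three amplitude-modulation tones are placed at 0.06 Hz (LF outside MF),
    0.10 Hz (inside MF) and 0.30 Hz (HF) with depths chosen so the
    amplitude-series band powers reproduce the subject's ``lf_nu`` and
    ``mf_nu`` (and hence ``lf_hf = lf_nu/(1-lf_nu)``); the pulse width and
    heart rate are taken directly.  ``modulation_power`` sets the total
    (LF+HF) variance of the relative amplitude modulation.
    """
    lf = base["lf_nu"] * modulation_power
    mf = base["mf_nu"] * modulation_power
    hf = (1.0 - base["lf_nu"]) * modulation_power
    if mf > lf:
        raise ConfigurationError("mf_nu: MF power cannot exceed LF power")
    depths = [math.sqrt(2.0 * p) for p in (lf - mf, mf, hf)]
    return SynthPPGConfig(
        duration_s=duration_s,
        fs=fs,
        heart_rate_bpm=base["hr"],
        pulse_width_frac=float(base["pw"]),
        am_components=((0.06, depths[0]), (0.10, depths[1]), (0.30, depths[2])),
        noise_sd=noise_sd,
        seed=seed,
    )
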