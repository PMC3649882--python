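"""Bland-Altman agreement statistics, percentage error, and report tables.

Agreement between an estimator and the gold standard is summarized by the
per-subject differences d_i = estimated_i - measured_i: their mean (the
bias), their sample standard deviation, the precision 1.96*s.d., the limits
of agreement bias +/- precision, the Pearson correlation of measured with
estimated, and the percentage error 100 * precision / mean of the measured
values.  Reporting conventions: cardiac output to two decimals, vascular
resistance to the nearest integer, percentage error to the nearest percent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: 97.5th-percentile normal quantile used for the limits of agreement.
LOA_FACTOR = 1.96


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (the convention used in printed reports)."""
    scale = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * scale + 0.5) / scale, x)


@dataclass(frozen=True)
class AgreementStats:
    """Bland-Altman summary of estimated against measured values."""

    bias: float
    sd: float
    precision: float
    loa_low: float
    loa_high: float
    r: float
    percentage_error: float
    n: int


def bland_altman(measured, estimated) -> AgreementStats:
    """Bland-Altman statistics of paired measured/estimated values.

    Differences are taken as estimated - measured; the standard deviation
    uses the n-1 denominator.  The correlation is reported as NaN (flagged
    downstream) when either input has zero variance; the percentage error is
    NaN when the measured mean is not positive.
    """
    measured = np.asarray(measured, dtype=float)
    estimated = np.asarray(estimated, dtype=float)
    if measured.shape != estimated.shape or measured.ndim != 1:
        raise ValueError("measured and estimated must be equal-length 1-d arrays")
    n = measured.size
    if n < 2:
        raise ValueError(f"need at least 2 paired values, got {n}")
    d = estimated - measured
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    precision = LOA_FACTOR * sd
    if measured.std() == 0 or estimated.std() == 0:
        r = float("nan")
    else:
        r = float(stats.pearsonr(measured, estimated).statistic)
    mean_meas = float(measured.mean())
    pe = percentage_error(precision, mean_meas) if mean_meas > 0 else float("nan")
    return AgreementStats(
        bias=bias,
        sd=sd,
        precision=precision,
        loa_low=bias - precision,
        loa_high=bias + precision,
        r=r,
        percentage_error=pe,
        n=n,
    )


def percentage_error(precision: float, mean_of_measured: float) -> float:
    """Percentage error: 100 * precision / mean of the measured values.

    The mean must be positive.  The value is returned unrounded; reports
    round it to the nearest integer percent.
    """
    if not mean_of_measured > 0:
        raise ValueError(f"mean of measured values must be positive, got {mean_of_measured}")
    return 100.0 * precision / mean_of_measured


def report_table(results: dict[str, AgreementStats], target: str = "CO") -> pd.DataFrame:
    """One agreement row per feature pool, with the printed rounding rules.

    ``results`` maps a pool description to its :class:`AgreementStats`; row
    order follows the input order.  Cardiac-output rows round bias/s.d. to
    two decimals, resistance rows to the nearest integer; the percentage
    error always rounds to the nearest percent, and an undefined correlation
    is flagged.
    """
    if not results:
        raise ValueError("report_table needs at least one result")
    nd = 2 if target == "CO" else 0
    rows = []
    for label, s in results.items():
        rows.append(
            {
                "feature_pool": label,
                "r": "undefined" if math.isnan(s.r) else f"{s.r:.2f}",
                "bias": round_half_away(s.bias, nd),
                "sd": round_half_away(s.sd, nd),
                "precision": round_half_away(s.precision, nd),
                "pct_error": int(round_half_away(s.percentage_error))
                if not math.isnan(s.percentage_error)
                else "undefined",
                "n": s.n,
            }
        )
    return pd.DataFrame(rows)


def render_report(table: pd.DataFrame, target: str = "CO") -> str:
    """Plain-text rendering of a report table."""
    unit = "L/min" if target == "CO" else "dyn.s.cm^-5"
    header = f"Agreement report — target {target} ({unit})"
    return header + "\n" + table.to_string(index=False) + "\n"


def bland_altman_plot(measured, estimated, path, target: str = "CO") -> None:
    """Bland-Altman plot: per-subject mean vs difference with bias/limit lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    s = bland_altman(measured, estimated)
    measured = np.asarray(measured, dtype=float)
    estimated = np.asarray(estimated, dtype=float)
    unit = "L/min" if target == "CO" else "dyn.s.cm$^{-5}$"
    fig, ax = plt.subplots(figsize=(6, 4.5))
    ax.scatter((measured + estimated) / 2, estimated - measured, s=18, color="k")
    ax.axhline(s.bias, color="b", lw=1.5)
    for y in (s.loa_low, s.loa_high):
        ax.axhline(y, color="r", ls="--", lw=1.2)
    ax.set_xlabel(f"Mean of measured and estimated {target} ({unit})")
    ax.set_ylabel(f"Estimated − measured {target} ({unit})")
    ax.set_title(
        f"Bias {s.bias:.2f}, limits {s.loa_low:.2f} to {s.loa_high:.2f} {unit}"
    )
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
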