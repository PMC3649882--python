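"""Base hemodynamic features, nonlinear feature expansion, and feature pools.

Seven base features describe each subject: three variability spectral features
of the finger photoplethysmogram (normalized low-frequency power ``lf_nu``,
normalized mid-frequency power ``mf_nu``, and the low- to high-frequency power
ratio ``lf_hf``), the morphological pulse width ``pw``, and three routine
cardiovascular measurements (heart rate ``hr``, mean arterial pressure ``map``,
and their ratio ``map_over_hr``).  Each base feature x is expanded with x^2,
x^3 and log(x), giving 28 candidate regressors referenced by a fixed index:

==============  ===  =====  =====  ========
feature          x    x^2    x^3    log(x)
==============  ===  =====  =====  ========
lf_nu            1     8     15      22
mf_nu            2     9     16      23
lf_hf            3    10     17      24
hr               4    11     18      25
map              5    12     19      26
map_over_hr      6    13     20      27
pw               7    14     21      28
==============  ===  =====  =====  ========

Systemic vascular resistance is derived from routine pressures and cardiac
output as SVR = 80 * (MAP - CVP) / CO, in dyn.s.cm^-5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError

#: Base feature names, in index order (linear indices 1..7).
BASE_FEATURE_NAMES: tuple[str, ...] = (
    "lf_nu",
    "mf_nu",
    "lf_hf",
    "hr",
    "map",
    "map_over_hr",
    "pw",
)

#: Transform names, in block order (blocks of 7 indices each).
TRANSFORM_NAMES: tuple[str, ...] = ("x", "x^2", "x^3", "log(x)")

N_BASE = len(BASE_FEATURE_NAMES)
N_FEATURES = N_BASE * len(TRANSFORM_NAMES)

#: Known feature pools: named subsets of the 28 indices.
POOL_NAMES: tuple[str, ...] = (
    "all",
    "only_ppg",
    "only_pw",
    "exclude_ppgv",
    "only_linear",
)

_NON_PPG = frozenset({4, 5, 6, 11, 12, 13, 18, 19, 20, 25, 26, 27})
_PPGV = frozenset({1, 2, 3, 8, 9, 10, 15, 16, 17, 22, 23, 24})
_ALL = frozenset(range(1, N_FEATURES + 1))


def feature_index(base_name: str, transform: str = "x") -> int:
    """Return the 1-based index of a base feature under a given transform."""
    b = BASE_FEATURE_NAMES.index(base_name)
    t = TRANSFORM_NAMES.index(transform)
    return t * N_BASE + b + 1


def feature_formula(index: int) -> str:
    """Human-readable formula for a feature index, e.g. 28 -> ``log(pw)``."""
    if not 1 <= index <= N_FEATURES:
        raise ValueError(f"feature index {index} outside 1..{N_FEATURES}")
    t, b = divmod(index - 1, N_BASE)
    name = BASE_FEATURE_NAMES[b]
    return {
        "x": name,
        "x^2": f"{name}^2",
        "x^3": f"{name}^3",
        "log(x)": f"log({name})",
    }[TRANSFORM_NAMES[t]]


def index_map() -> dict[int, str]:
    """Machine-readable map of every feature index to its formula string."""
    return {j: feature_formula(j) for j in range(1, N_FEATURES + 1)}


def column_name(index: int) -> str:
    """Canonical table column name for a feature index (``f01`` .. ``f28``)."""
    return f"f{index:02d}"


FEATURE_COLUMNS: tuple[str, ...] = tuple(
    column_name(j) for j in range(1, N_FEATURES + 1)
)


def compute_svr(map_mmhg, cvp_mmhg, co_lpm):
    """Systemic vascular resistance, 80*(MAP-CVP)/CO, in dyn.s.cm^-5.

    Accepts scalars or arrays; cardiac output must be strictly positive.
    """
    co = np.asarray(co_lpm, dtype=float)
    if np.any(co <= 0):
        raise ValueError("cardiac output must be > 0 to compute SVR")
    out = 80.0 * (np.asarray(map_mmhg, dtype=float) - np.asarray(cvp_mmhg, dtype=float)) / co
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class BaseFeatures:
    """The seven per-subject base features; all must be strictly positive."""

    lf_nu: float
    mf_nu: float
    lf_hf: float
    hr: float
    map: float
    map_over_hr: float
    pw: float

    def __post_init__(self) -> None:
        for name in BASE_FEATURE_NAMES:
            v = getattr(self, name)
            if not (v > 0 and math.isfinite(v)):
                raise ValueError(
                    f"base feature {name!r} must be strictly positive and finite, got {v}"
                )
        if not math.isclose(self.map_over_hr, self.map / self.hr, rel_tol=1e-9):
            raise ValueError("map_over_hr must equal map/hr exactly")

    @classmethod
    def from_measurements(
        cls, *, lf_nu: float, mf_nu: float, lf_hf: float, hr: float, map: float, pw: float
    ) -> "BaseFeatures":
        return cls(lf_nu, mf_nu, lf_hf, hr, map, map / hr, pw)

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in BASE_FEATURE_NAMES], dtype=float)


def transform_features(base, log_base: float | None = None) -> np.ndarray:
    """Expand the 7 base features to the 28-vector ordered by feature index.

    Parameters
    ----------
    base
        A :class:`BaseFeatures`, a mapping of base-feature name to value, or a
        length-7 array in index order.
    log_base
        Base of the logarithm transform; ``None`` means natural log.

    Returns
    -------
    numpy.ndarray of shape (28,), position j-1 holding feature index j.
    """
    if isinstance(base, BaseFeatures):
        x = base.as_array()
    elif isinstance(base, Mapping):
        x = np.array([base[n] for n in BASE_FEATURE_NAMES], dtype=float)
    else:
        x = np.asarray(base, dtype=float)
        if x.shape != (N_BASE,):
            raise ValueError(f"expected {N_BASE} base features, got shape {x.shape}")
    for name, v in zip(BASE_FEATURE_NAMES, x):
        if not v > 0:
            raise ValueError(f"base feature {name!r} must be > 0 for log transform, got {v}")
    logs = np.log(x) if log_base is None else np.log(x) / np.log(log_base)
    return np.concatenate([x, x**2, x**3, logs])


@dataclass(frozen=True)
class FeaturePool:
    """A named subset of the 28 feature indices used to seed stepwise search."""

    name: str
    indices: frozenset[int]

    def __post_init__(self) -> None:
        bad = [j for j in self.indices if not 1 <= j <= N_FEATURES]
        if bad:
            raise ValueError(f"pool indices outside 1..{N_FEATURES}: {bad}")

    def sorted(self) -> tuple[int, ...]:
        return tuple(sorted(self.indices))


def make_pool(name: str) -> FeaturePool:
    """Return one of the named feature pools.

    ``all`` is every index; ``only_ppg`` removes the heart-rate and
    pressure-derived indices; ``exclude_ppgv`` removes the spectral
    variability indices; ``only_linear`` keeps the untransformed features;
    ``only_pw`` keeps pulse width and its transforms.
    """
    sets = {
        "all": _ALL,
        "only_ppg": _ALL - _NON_PPG,
        "exclude_ppgv": _ALL - _PPGV,
        "only_linear": frozenset(range(1, N_BASE + 1)),
        "only_pw": frozenset({7, 14, 21, 28}),
    }
    if name not in sets:
        raise ConfigurationError(
            f"pool: unknown pool name {name!r}; known pools: {', '.join(POOL_NAMES)}"
        )
    return FeaturePool(name, sets[name])


def build_feature_table(
    base_df: pd.DataFrame, log_base: float | None = None
) -> pd.DataFrame:
    """Expand a per-subject base-feature table to the 28 indexed columns.

    ``base_df`` must contain the seven base feature columns (``map_over_hr``
    is computed from ``map``/``hr`` if absent).  ``subject_id``, ``CO``,
    ``SVR``, ``CVP`` columns are carried through when present.

    Returns a DataFrame with columns ``subject_id`` (if present), ``f01`` ..
    ``f28``, and any carried targets.
    """
    df = base_df.copy()
    if "map_over_hr" not in df.columns:
        df["map_over_hr"] = df["map"] / df["hr"]
    missing = [n for n in BASE_FEATURE_NAMES if n not in df.columns]
    if missing:
        raise ValueError(f"base feature columns missing from table: {missing}")
    x = df[list(BASE_FEATURE_NAMES)].to_numpy(dtype=float)
    if np.any(x <= 0):
        raise ValueError("all base features must be strictly positive")
    logs = np.log(x) if log_base is None else np.log(x) / np.log(log_base)
    mat = np.hstack([x, x**2, x**3, logs])
    out = pd.DataFrame(mat, columns=list(FEATURE_COLUMNS), index=df.index)
    carried = [c for c in ("subject_id", "CO", "SVR") if c in df.columns]
    for c in reversed(carried):
        out.insert(0, c, df[c])
    return out


def feature_matrix(table: pd.DataFrame) -> np.ndarray:
    """Return the (n_subjects, 28) array of transformed features from a table."""
    return table[list(FEATURE_COLUMNS)].to_numpy(dtype=float)


def pool_columns(pool: FeaturePool | Iterable[int]) -> list[str]:
    indices = pool.sorted() if isinstance(pool, FeaturePool) else sorted(pool)
    return [column_name(j) for j in indices]
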