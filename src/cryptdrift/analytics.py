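"""Closed-form predictions of the one-dimensional stochastic conveyor belt.

With division rate k_d pushing cells up and relocation rate k_r letting them
re-enter the niche from above, the probability that a clone started at row x
is retained long-term falls off as a Gaussian of the starting position,

    P(x) / P(0) = exp(-x^2 / (2 sigma^2)),   sigma^2 = k_r / k_d,

so the half-width of the competitive zone is sigma = sqrt(k_r/k_d) rows.
Counting cells whose row has at least a 5% normalized retention probability
(about 2 sigma of the positional fluctuations) gives the effective stem cell
number

    N_s = N_g * (1 + 2 * sqrt(k_r/k_d)),

with N_g cells per row. These are the analytic surfaces the 2D lattice
simulation is validated against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError
from .lattice import CryptGeometry, KineticParams

__all__ = [
    "RetentionProfile",
    "StemCellEstimate",
    "FixationScaling",
    "retention_profile",
    "effective_stem_cell_number",
    "effective_rows",
    "fixation_time_scaling",
]


@dataclass(frozen=True)
class RetentionProfile:
    """Normalized long-term retention probability per starting row."""

    sigma2: float
    rows: np.ndarray
    probabilities: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"row": self.rows, "retention": self.probabilities})


@dataclass(frozen=True)
class StemCellEstimate:
    """Effective stem cell number N_s and the matching effective row count."""

    n_g: int
    ratio: float
    n_s: float
    n_s_rounded: int
    n_rows_effective: int
    threshold: float = 0.05


def retention_profile(ratio: float, rows) -> RetentionProfile:
    """Normalized Gaussian retention profile exp(-x^2/(2 sigma^2)) with
    sigma^2 = ratio; row 0 is 1 by construction. ratio=0 collapses the
    profile onto row 0 (deterministic conveyor belt)."""
    if ratio < 0:
        raise ConfigurationError(f"ratio must be >= 0, got {ratio}")
    rows = np.asarray(rows, dtype=float)
    if ratio == 0:
        probs = np.where(rows == 0, 1.0, 0.0)
    else:
        probs = np.exp(-(rows**2) / (2.0 * ratio))
    return RetentionProfile(sigma2=float(ratio), rows=rows, probabilities=probs)


def effective_stem_cell_number(n_g: int, ratio: float, threshold: float = 0.05) -> StemCellEstimate:
    """N_s = N_g (1 + 2 sqrt(ratio)), reported raw and rounded."""
    if n_g < 1:
        raise ConfigurationError(f"n_g must be >= 1, got {n_g}")
    if ratio < 0:
        raise ConfigurationError(f"ratio must be >= 0, got {ratio}")
    n_s = n_g * (1.0 + 2.0 * np.sqrt(ratio))
    return StemCellEstimate(
        n_g=int(n_g),
        ratio=float(ratio),
        n_s=float(n_s),
        n_s_rounded=int(round(n_s)),
        n_rows_effective=effective_rows(ratio, threshold),
        threshold=threshold,
    )


def effective_rows(ratio: float, threshold: float = 0.05) -> int:
    """Number of consecutive rows from the base whose normalized retention
    stays at or above ``threshold``."""
    if not 0 < threshold < 1:
        raise ConfigurationError(f"threshold must be in (0, 1), got {threshold}")
    if ratio < 0:
        raise ConfigurationError(f"ratio must be >= 0, got {ratio}")
    if ratio == 0:
        return 1
    x_max = np.sqrt(-2.0 * ratio * np.log(threshold))
    return int(np.floor(x_max)) + 1


@dataclass(frozen=True)
class FixationScaling:
    """Mean monoclonal-conversion times versus sqrt(k_r/k_d), with the
    linear regression documenting the close-to-linear scaling."""

    table: pd.DataFrame  # columns: ratio, mean_time_days, n
    slope: float
    intercept: float
    r_squared: float

    def summary(self) -> str:
        return (
            f"mean conversion time ~ {self.intercept:.2f} + {self.slope:.2f} * sqrt(ratio) days"
            f" (R^2 = {self.r_squared:.3f})"
        )


def fixation_time_scaling(
    ratios,
    params: KineticParams | None = None,
    n_reps: int = 100,
    rng=None,
    geometry: CryptGeometry | None = None,
    horizon: float = 3000.0,
) -> FixationScaling:
    """Mean time for the Lgr5+ zone to become monoclonal at each ratio,
    from simulation, with a linear fit of mean time against sqrt(ratio).

    ``params`` supplies the division rate (default 1.4/day); k_r is set per
    ratio. Crypts not fixed by ``horizon`` days are excluded (and counted in
    the ``n`` column).
    """
    from .experiments import run_monoclonal_conversion_times

    ratios = [float(r) for r in np.atleast_1d(np.asarray(ratios, dtype=float))]
    if any(r < 0 for r in ratios):
        raise ConfigurationError("all ratios must be >= 0")
    if n_reps < 1:
        raise ConfigurationError("n_reps must be >= 1")
    k_d = params.k_d if params is not None else 1.4
    geometry = geometry or CryptGeometry()
    rng = np.random.default_rng(rng)
    records = []
    for ratio in ratios:
        times = run_monoclonal_conversion_times(
            KineticParams.from_ratio(ratio, k_d), geometry, n_reps, rng, horizon=horizon
        )
        finite = times[np.isfinite(times)]
        records.append(
            {"ratio": ratio, "mean_time_days": float(finite.mean()), "n": int(finite.size)}
        )
    table = pd.DataFrame(records)
    if len(table) >= 2:
        fit = stats.linregress(np.sqrt(table["ratio"]), table["mean_time_days"])
        slope, intercept, r2 = float(fit.slope), float(fit.intercept), float(fit.rvalue**2)
    else:
        slope, intercept, r2 = float("nan"), float(table["mean_time_days"].iloc[0]), float("nan")
    return FixationScaling(table=table, slope=slope, intercept=intercept, r_squared=r2)
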