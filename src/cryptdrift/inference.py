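"""Inference of the relocation-to-division ratio k_r/k_d and of k_d.

The late-time clone retention probability from starting row x follows
p(x) = p0 * exp(-x^2 / (2 sigma^2)) with sigma^2 = k_r/k_d. We fit (p0,
sigma^2) by maximizing the binomial likelihood of the per-row retained
counts; fitting the amplitude p0 jointly avoids dividing the data by a noisy
row-0 estimate (normalized curves are produced only for display).
Uncertainty comes from a nonparametric bootstrap over clones (percentile
intervals). The division rate k_d only enters the short-term dynamics and is
recovered by a simulation-based grid search with the ratio held fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .analytics import effective_stem_cell_number
from .errors import ConfigurationError, UnidentifiableFitError
from .lattice import CryptGeometry, KineticParams

__all__ = [
    "RetentionCounts",
    "RatioFit",
    "KdFit",
    "fit_ratio_longterm",
    "fit_kd_shortterm",
    "predict_retention",
]

_LOG_S2_BOUNDS = (-12.0, 8.0)
_LOG_P0_BOUNDS = (-30.0, 0.0)


@dataclass(frozen=True)
class RetentionCounts:
    """Retained/total clone counts per starting row at one observation time."""

    rows: np.ndarray
    n_clones: np.ndarray
    n_retained: np.ndarray
    time_days: float | None = None

    def __post_init__(self):
        rows = np.asarray(self.rows, dtype=int)
        n = np.asarray(self.n_clones, dtype=int)
        k = np.asarray(self.n_retained, dtype=int)
        if not (rows.shape == n.shape == k.shape):
            raise ConfigurationError("rows, n_clones, n_retained must have equal length")
        if (k < 0).any() or (k > n).any():
            raise ConfigurationError("need 0 <= n_retained <= n_clones per row")
        object.__setattr__(self, "rows", rows)
        object.__setattr__(self, "n_clones", n)
        object.__setattr__(self, "n_retained", k)

    @classmethod
    def from_observations(cls, observations: pd.DataFrame, time: float | None = None) -> "RetentionCounts":
        """Aggregate a clone observation table (see experiments module) at a
        single observation time."""
        obs = observations
        if time is None:
            times = obs["time_days"].unique()
            if len(times) != 1:
                raise ConfigurationError(
                    f"observations span times {sorted(times)}; pass `time` explicitly"
                )
            time = float(times[0])
        sub = obs[obs["time_days"] == time]
        g = sub.groupby("start_row")["retained"].agg(["size", "sum"])
        return cls(
            rows=g.index.to_numpy(),
            n_clones=g["size"].to_numpy(),
            n_retained=g["sum"].to_numpy().astype(int),
            time_days=time,
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "RetentionCounts":
        """From an aggregated table with columns start_row, n_clones,
        n_retained (and optionally time_days)."""
        t = None
        if "time_days" in frame:
            times = frame["time_days"].unique()
            if len(times) > 1:
                raise ConfigurationError("aggregated counts must be at a single time")
            t = float(times[0]) if len(times) else None
        return cls(
            rows=frame["start_row"].to_numpy(),
            n_clones=frame["n_clones"].to_numpy(),
            n_retained=frame["n_retained"].to_numpy(),
            time_days=t,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "start_row": self.rows,
                "time_days": self.time_days,
                "n_clones": self.n_clones,
                "n_retained": self.n_retained,
            }
        )


@dataclass(frozen=True)
class RatioFit:
    """Maximum-likelihood Gaussian retention fit with bootstrap uncertainty."""

    sigma2: float
    p0: float
    n_s: float
    n_s_rounded: int
    n_g: int
    ci_low: float
    ci_high: float
    n_boot: int
    loss: float  # negative log-likelihood at the optimum
    seed: int | None
    at_boundary: bool
    bootstrap_sigma2: np.ndarray = field(repr=False)
    bootstrap_p0: np.ndarray = field(repr=False)

    @property
    def ratio(self) -> float:
        return self.sigma2

    def summary(self) -> str:
        flag = " (sigma^2 at zero boundary)" if self.at_boundary else ""
        return (
            f"k_r/k_d = {self.sigma2:.3g} (95% CI {self.ci_low:.3g}-{self.ci_high:.3g}, "
            f"{self.n_boot} bootstrap resamples){flag}; "
            f"N_s = {self.n_s:.2f} ~ {self.n_s_rounded} at N_g = {self.n_g}"
        )


@dataclass(frozen=True)
class KdFit:
    """Grid-search estimate of the division rate from short-term retention."""

    k_d: float
    loss: float
    grid: np.ndarray
    losses: np.ndarray
    seed: int | None

    def summary(self) -> str:
        return f"k_d = {self.k_d:.3g}/day (squared-error loss {self.loss:.4g})"


def _neg_loglik_and_grad(theta, x, n, k):
    log_p0, log_s2 = theta
    p0 = np.exp(log_p0)
    s2 = np.exp(log_s2)
    p = p0 * np.exp(-(x**2) / (2.0 * s2))
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    nll = -np.sum(k * np.log(p) + (n - k) * np.log1p(-p))
    dl_dp = k / p - (n - k) / (1.0 - p)
    g_logp0 = -np.sum(dl_dp * p)
    g_logs2 = -np.sum(dl_dp * p * x**2 / (2.0 * s2))
    return nll, np.array([g_logp0, g_logs2])


def _fit_counts(x, n, k, x0):
    res = minimize(
        _neg_loglik_and_grad,
        x0,
        args=(x, n, k),
        jac=True,
        method="L-BFGS-B",
        bounds=[_LOG_P0_BOUNDS, _LOG_S2_BOUNDS],
    )
    return res.x, float(res.fun)


def _initial_theta(x, n, k):
    with np.errstate(divide="ignore"):
        frac = np.where(n > 0, k / np.maximum(n, 1), 0.0)
    p0_init = float(np.clip(frac[x == 0][0] if (x == 0).any() else frac.max(), 1e-3, 1.0))
    pos = (x > 0) & (frac > 0)
    if pos.any():
        # log(frac/p0) = -a x^2 with a = 1/(2 s2): least squares through origin
        y = np.log(frac[pos] / p0_init)
        a = -np.sum(x[pos] ** 2 * y) / np.sum(x[pos] ** 4)
        s2 = float(np.clip(1.0 / (2.0 * a), 1e-4, 1e3)) if a > 0 else 1.0
    else:
        s2 = 0.01
    return np.array([np.log(p0_init), np.log(s2)])


def fit_ratio_longterm(
    counts,
    n_boot: int = 1000,
    rng=None,
    n_g: int | None = None,
    geometry: CryptGeometry | None = None,
    groups: np.ndarray | None = None,
) -> RatioFit:
    """Fit sigma^2 = k_r/k_d (and the amplitude p0) to late-time retention
    counts by binomial maximum likelihood.

    ``counts`` is a :class:`RetentionCounts`, an aggregated table, or a clone
    observation table at a single time. The 95% CI is a percentile bootstrap
    over clones (``n_boot`` resamples); pass per-clone ``groups`` (e.g. mouse
    ids, one per clone in row-major expansion order) to resample whole groups
    instead.
    """
    if isinstance(counts, pd.DataFrame):
        if {"n_clones", "n_retained"}.issubset(counts.columns):
            counts = RetentionCounts.from_frame(counts)
        else:
            counts = RetentionCounts.from_observations(counts)
    used = counts.n_clones > 0
    x = counts.rows[used].astype(float)
    n = counts.n_clones[used]
    k = counts.n_retained[used]
    if x.size < 2:
        raise ConfigurationError("need counts at >= 2 distinct start rows")
    if not (x == 0).any():
        raise ConfigurationError("row 0 must be observed to anchor the profile")
    if k.sum() == 0:
        raise UnidentifiableFitError("no clone was retained at any row; sigma^2 unidentifiable")

    if k[x > 0].sum() == 0:
        # zero retention everywhere beyond row 0: the MLE sits on the
        # sigma^2 = 0 boundary with p0 = k0/n0
        p0 = float(k[x == 0].sum() / n[x == 0].sum())
        theta_hat = np.array([np.log(max(p0, 1e-12)), _LOG_S2_BOUNDS[0]])
        loss = float(_neg_loglik_and_grad(theta_hat, x, n, k)[0])
        sigma2, at_boundary = 0.0, True
    else:
        theta0 = _initial_theta(x, n, k)
        theta_hat, loss = _fit_counts(x, n, k, theta0)
        sigma2 = float(np.exp(theta_hat[1]))
        p0 = float(np.exp(theta_hat[0]))
        at_boundary = bool(theta_hat[1] <= _LOG_S2_BOUNDS[0] + 1e-6)
        if at_boundary:
            sigma2 = 0.0

    # clone-level (or group-level) nonparametric bootstrap
    rng_ = np.random.default_rng(rng)
    seed = int(rng) if isinstance(rng, (int, np.integer)) else None
    clone_rows = np.repeat(np.arange(x.size), n)  # index into x per clone
    clone_outcome = np.zeros(clone_rows.size, dtype=np.int64)
    pos = 0
    for j in range(x.size):
        clone_outcome[pos : pos + k[j]] = 1
        pos += n[j]
    boot_s2 = np.empty(n_boot)
    boot_p0 = np.empty(n_boot)
    n_total = clone_rows.size
    if groups is not None:
        groups = np.asarray(groups)
        if groups.shape[0] != n_total:
            raise ConfigurationError("groups must give one group id per clone")
        uniq = np.unique(groups)
    for b in range(n_boot):
        if groups is None:
            idx = rng_.integers(0, n_total, size=n_total)
        else:
            chosen = rng_.choice(uniq, size=uniq.size, replace=True)
            idx = np.concatenate([np.flatnonzero(groups == g) for g in chosen])
        nb = np.bincount(clone_rows[idx], minlength=x.size)
        kb = np.bincount(clone_rows[idx], weights=clone_outcome[idx], minlength=x.size).astype(int)
        use = nb > 0
        if kb.sum() == 0 or use.sum() < 2 or not use[np.argmin(x)]:
            boot_s2[b] = 0.0
            boot_p0[b] = kb.sum() / max(nb.sum(), 1)
            continue
        tb, _ = _fit_counts(x[use], nb[use], kb[use], theta_hat)
        boot_s2[b] = np.exp(tb[1])
        boot_p0[b] = np.exp(tb[0])
    ci_low, ci_high = (
        (float(np.percentile(boot_s2, 2.5)), float(np.percentile(boot_s2, 97.5)))
        if n_boot > 0
        else (float("nan"), float("nan"))
    )

    n_g = n_g if n_g is not None else (geometry or CryptGeometry()).cells_per_row
    est = effective_stem_cell_number(n_g, sigma2)
    return RatioFit(
        sigma2=sigma2,
        p0=p0,
        n_s=est.n_s,
        n_s_rounded=est.n_s_rounded,
        n_g=n_g,
        ci_low=ci_low,
        ci_high=ci_high,
        n_boot=n_boot,
        loss=loss,
        seed=seed,
        at_boundary=at_boundary,
        bootstrap_sigma2=boot_s2,
        bootstrap_p0=boot_p0,
    )


def fit_kd_shortterm(
    observations: pd.DataFrame,
    ratio: float,
    kd_grid,
    n_sim_per_grid: int = 200,
    rng=None,
    geometry: CryptGeometry | None = None,
) -> KdFit:
    """Grid search for k_d against short-term per-row retention trajectories.

    For each candidate k_d (with k_r = ratio * k_d) the same number of clones
    per starting row is simulated with common random numbers, and the summed
    squared error between observed and simulated retained fractions over all
    (start_row, time) cells is the loss."""
    from .experiments import run_lineage_tracing

    if ratio < 0:
        raise ConfigurationError("ratio must be >= 0")
    times = np.sort(observations["time_days"].unique())
    if times.size < 2:
        raise UnidentifiableFitError(
            "k_d sets the time scale; need >= 2 observation times to constrain it"
        )
    geometry = geometry or CryptGeometry()
    kd_grid = np.asarray(sorted(float(v) for v in np.atleast_1d(kd_grid)))
    if (kd_grid <= 0).any():
        raise ConfigurationError("all k_d candidates must be > 0")
    obs_frac = (
        observations.groupby(["start_row", "time_days"])["retained"].mean().rename("obs")
    )
    start_rows = np.sort(observations["start_row"].unique())
    rng_ = np.random.default_rng(rng)
    seed = int(rng) if isinstance(rng, (int, np.integer)) else None
    base_seed = int(rng_.integers(0, 2**31 - 1))
    losses = np.empty(kd_grid.size)
    for i, kd in enumerate(kd_grid):
        sim = run_lineage_tracing(
            KineticParams.from_ratio(ratio, kd),
            geometry,
            start_rows,
            n_sim_per_grid,
            times,
            rng=np.random.default_rng(base_seed),  # common random numbers
            condition="grid",
        )
        sim_frac = sim.groupby(["start_row", "time_days"])["retained"].mean().rename("sim")
        joined = pd.concat([obs_frac, sim_frac], axis=1).dropna()
        losses[i] = float(((joined["obs"] - joined["sim"]) ** 2).sum())
    best = int(np.argmin(losses))
    return KdFit(
        k_d=float(kd_grid[best]),
        loss=float(losses[best]),
        grid=kd_grid,
        losses=losses,
        seed=seed,
    )


def predict_retention(fit: RatioFit, rows, time: float | None = None) -> pd.DataFrame:
    """Normalized retention prediction per row with the 95% bootstrap band.

    The late-time Gaussian law does not depend on time; ``time`` is carried
    through for labelling only. Row 0 is 1 by construction and the band is
    the 2.5-97.5 percentile envelope of the bootstrap replicate curves."""
    rows = np.asarray(np.atleast_1d(rows), dtype=float)
    s2 = max(fit.sigma2, 1e-12)
    central = np.exp(-(rows**2) / (2.0 * s2))
    boot = np.clip(fit.bootstrap_sigma2, 1e-12, None)
    curves = np.exp(-(rows[None, :] ** 2) / (2.0 * boot[:, None]))
    lo = np.minimum(np.percentile(curves, 2.5, axis=0), central)
    hi = np.maximum(np.percentile(curves, 97.5, axis=0), central)
    out = pd.DataFrame(
        {"row": rows.astype(int), "retention": central, "ci_low": lo, "ci_high": hi}
    )
    if time is not None:
        out.insert(1, "time_days", time)
    return out
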