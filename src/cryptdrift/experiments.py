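"""Virtual lineage-tracing, monoclonal-drift, fragmentation and ablation
experiments run on top of the lattice simulator.

Each induced clone occupies its own independent crypt (one labelled cell per
crypt, as with low-dose tamoxifen induction). A clone is *retained* at an
observation time when it still has at least one cell in the Lgr5+ zone; it is
present in the *centre* (rows 0-1) or *border* (rows 2-3) compartments
according to where its cells sit. Monoclonality is judged over the Lgr5+
zone. Fragmentation means the rows occupied by a clone are non-contiguous —
two fragments separated by at least one row holding none of its cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels
from ._kernels import VACANT
from .errors import ConfigurationError, EstimationError, SimulationError
from .lattice import CryptGeometry, CryptState, KineticParams

__all__ = [
    "OBSERVATION_COLUMNS",
    "CloneObservation",
    "MonoclonalitySeries",
    "AblationTrajectory",
    "run_lineage_tracing",
    "compartment_transition_summary",
    "run_monoclonal_drift",
    "run_monoclonal_conversion_times",
    "is_fragmented",
    "run_fragmentation_assay",
    "FragmentationResult",
    "ablate",
    "run_ablation_recovery",
]

#: Delimited-text schema for clone observation tables.
OBSERVATION_COLUMNS = [
    "clone_id",
    "condition",
    "start_row",
    "time_days",
    "retained",
    "in_centre",
    "in_border",
    "n_cells",
    "fragmented",
]


@dataclass(frozen=True)
class CloneObservation:
    """One clone's occupancy summary at one observation time."""

    clone_id: int
    condition: str
    start_row: int
    time_days: float
    retained: bool
    in_centre: bool
    in_border: bool
    cells_per_row: np.ndarray

    @property
    def n_cells(self) -> int:
        return int(self.cells_per_row.sum())


@dataclass(frozen=True)
class MonoclonalitySeries:
    """Fraction of crypts whose Lgr5+ zone is monoclonal at each time."""

    times: np.ndarray
    fraction_monoclonal: np.ndarray
    n_crypts: int
    per_crypt: np.ndarray  # (n_crypts, n_times) 0/1 matrix

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_days": self.times,
                "fraction_monoclonal": self.fraction_monoclonal,
                "n_crypts": self.n_crypts,
            }
        )


@dataclass(frozen=True)
class AblationTrajectory:
    """Recovery of the ablated stem-cell zone: per-crypt lowest occupied row
    and per-row occupancy over time."""

    times: np.ndarray
    lowest_row: np.ndarray  # (n_crypts, n_times)
    occupancy: np.ndarray  # (n_crypts, n_times, n_rows)

    @property
    def mean_lowest_row(self) -> np.ndarray:
        return self.lowest_row.mean(axis=0)

    def recovery_fraction(self, row: int) -> np.ndarray:
        """Fraction of crypts with at least one cell at or below ``row``."""
        return (self.lowest_row <= row).mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        n_crypts, n_times = self.lowest_row.shape
        return pd.DataFrame(
            {
                "crypt_id": np.repeat(np.arange(n_crypts), n_times),
                "time_days": np.tile(self.times, n_crypts),
                "lowest_row": self.lowest_row.ravel(),
            }
        )


def _child_seeds(rng, n: int) -> np.ndarray:
    """Per-crypt seeds for the compiled kernels (kept below 2**31)."""
    rng = np.random.default_rng(rng)
    return rng.integers(0, 2**31 - 1, size=n, dtype=np.int64)


def _prepare_times(record_times) -> np.ndarray:
    times = np.asarray(sorted(float(t) for t in np.atleast_1d(record_times)), dtype=float)
    if times.size and times[0] < 0:
        raise ConfigurationError("record times must be >= 0")
    return times


def _counts_to_observations(
    counts: np.ndarray,
    start_rows: np.ndarray,
    times: np.ndarray,
    geometry: CryptGeometry,
    condition: str,
) -> pd.DataFrame:
    """Vectorize kernel output (n_clones, n_times, n_rows) into the long
    observation table."""
    n, n_times, n_rows = counts.shape
    c_lo, c_hi = geometry.centre_rows
    b_lo, b_hi = geometry.border_rows
    g_lo, g_hi = geometry.lgr5_rows
    retained = counts[:, :, g_lo : g_hi + 1].sum(axis=2) > 0
    in_centre = counts[:, :, c_lo : c_hi + 1].sum(axis=2) > 0
    in_border = counts[:, :, b_lo : b_hi + 1].sum(axis=2) > 0
    n_cells = counts.sum(axis=2)
    occupied = counts > 0
    n_occ_rows = occupied.sum(axis=2)
    first = np.argmax(occupied, axis=2)
    last = n_rows - 1 - np.argmax(occupied[:, :, ::-1], axis=2)
    span = np.where(n_occ_rows > 0, last - first + 1, 0)
    fragmented = (n_occ_rows > 0) & (n_occ_rows < span)
    df = pd.DataFrame(
        {
            "clone_id": np.repeat(np.arange(n), n_times),
            "condition": condition,
            "start_row": np.repeat(start_rows, n_times),
            "time_days": np.tile(times, n),
            "retained": retained.ravel(),
            "in_centre": in_centre.ravel(),
            "in_border": in_border.ravel(),
            "n_cells": n_cells.ravel(),
            "fragmented": fragmented.ravel(),
        }
    )
    for r in range(n_rows):
        df[f"cells_row{r}"] = counts[:, :, r].ravel()
    return df


def run_lineage_tracing(
    params: KineticParams,
    geometry: CryptGeometry,
    start_rows,
    n_clones_per_row: int,
    record_times,
    rng=None,
    condition: str = "custom",
) -> pd.DataFrame:
    """Trace ``n_clones_per_row`` single-cell clones induced at t=0 at each
    of ``start_rows``, each in its own crypt, scoring occupancy at every
    record time. Returns the long observation table (one row per clone per
    time; extras ``cells_row*`` hold per-row clone cell counts)."""
    start_rows = np.asarray(np.atleast_1d(start_rows), dtype=np.int64)
    if start_rows.size and (start_rows.min() < 0 or start_rows.max() >= geometry.n_rows):
        raise ConfigurationError(
            f"start rows {start_rows.tolist()} outside lattice of {geometry.n_rows} rows"
        )
    if n_clones_per_row < 0:
        raise ConfigurationError("n_clones_per_row must be >= 0")
    times = _prepare_times(record_times)
    all_starts = np.repeat(start_rows, n_clones_per_row)
    return trace_clones(params, geometry, all_starts, times, rng, condition)


def trace_clones(
    params: KineticParams,
    geometry: CryptGeometry,
    start_rows,
    record_times,
    rng=None,
    condition: str = "custom",
) -> pd.DataFrame:
    """Like :func:`run_lineage_tracing` but with one explicit starting row
    per clone (used by the synthetic study generator)."""
    start_rows = np.asarray(np.atleast_1d(start_rows), dtype=np.int64)
    times = _prepare_times(record_times)
    rng = np.random.default_rng(rng)
    if start_rows.size == 0:
        df = pd.DataFrame(columns=OBSERVATION_COLUMNS)
        for r in range(geometry.n_rows):
            df[f"cells_row{r}"] = pd.Series(dtype=np.int64)
        return df
    if start_rows.min() < 0 or start_rows.max() >= geometry.n_rows:
        raise ConfigurationError("start rows outside lattice")
    start_cols = rng.integers(0, geometry.cells_per_row, size=start_rows.size).astype(np.int64)
    seeds = _child_seeds(rng, start_rows.size)
    pos_times = times[times > 0]
    counts = np.zeros((start_rows.size, times.size, geometry.n_rows), dtype=np.int64)
    if pos_times.size:
        kcounts = _kernels.lineage_batch(
            geometry.n_rows,
            geometry.cells_per_row,
            start_rows,
            start_cols,
            pos_times,
            params.k_d,
            params.k_r,
            seeds,
        )
        counts[:, times > 0, :] = kcounts
    if (times == 0).any():
        j0 = int(np.where(times == 0)[0][0])
        counts[np.arange(start_rows.size), j0, start_rows] = 1
    return _counts_to_observations(counts, start_rows, times, geometry, condition)


def compartment_transition_summary(
    observations: pd.DataFrame, geometry: CryptGeometry | None = None
) -> pd.DataFrame:
    """Per condition, start compartment and time: probability that a clone is
    present in the centre, present in the border only, or lost from the
    Lgr5+ zone (the three sum to 1)."""
    from .errors import EmptyInputError

    if observations is None or len(observations) == 0:
        raise EmptyInputError("no clone observations to summarize")
    geometry = geometry or CryptGeometry()
    c_lo, c_hi = geometry.centre_rows
    b_lo, b_hi = geometry.border_rows
    obs = observations.copy()
    start = obs["start_row"].to_numpy()
    compartment = np.where(
        (start >= c_lo) & (start <= c_hi),
        "centre",
        np.where((start >= b_lo) & (start <= b_hi), "border", "other"),
    )
    obs["start_compartment"] = compartment
    obs["p_centre"] = obs["in_centre"].astype(float)
    obs["p_border_only"] = (obs["in_border"] & ~obs["in_centre"]).astype(float)
    obs["p_lost"] = (~obs["retained"]).astype(float)
    grouped = (
        obs.groupby(["condition", "start_compartment", "time_days"], observed=True)
        .agg(
            p_centre=("p_centre", "mean"),
            p_border_only=("p_border_only", "mean"),
            p_lost=("p_lost", "mean"),
            n=("p_lost", "size"),
        )
        .reset_index()
    )
    return grouped


def run_monoclonal_drift(
    params: KineticParams,
    geometry: CryptGeometry,
    n_crypts: int,
    record_times,
    rng=None,
    monoclonal_band=None,
) -> MonoclonalitySeries:
    """Initialize ``n_crypts`` crypts with every cell a distinct lineage and
    report the fraction whose ``monoclonal_band`` (default: Lgr5+ zone) is
    occupied by a single lineage at each record time."""
    if n_crypts < 1:
        raise ConfigurationError("n_crypts must be >= 1")
    band = tuple(monoclonal_band) if monoclonal_band is not None else geometry.lgr5_rows
    if not (0 <= band[0] <= band[1] < geometry.n_rows):
        raise ConfigurationError(f"monoclonal band {band} outside lattice")
    times = _prepare_times(record_times)
    seeds = _child_seeds(rng, n_crypts)
    pos_times = times[times > 0]
    mono = np.zeros((n_crypts, times.size), dtype=np.uint8)
    if pos_times.size:
        kmono = _kernels.monoclonal_batch(
            geometry.n_rows,
            geometry.cells_per_row,
            band[0],
            band[1],
            pos_times,
            params.k_d,
            params.k_r,
            seeds,
        )
        mono[:, times > 0] = kmono
    if (times == 0).any():
        # all-distinct start: monoclonal at t=0 only for a single-site band
        j0 = int(np.where(times == 0)[0][0])
        single = (band[0] == band[1]) and geometry.cells_per_row == 1
        mono[:, j0] = 1 if single else 0
    return MonoclonalitySeries(
        times=times,
        fraction_monoclonal=mono.mean(axis=0),
        n_crypts=n_crypts,
        per_crypt=mono,
    )


def run_monoclonal_conversion_times(
    params: KineticParams,
    geometry: CryptGeometry,
    n_reps: int,
    rng=None,
    horizon: float = 3000.0,
    monoclonal_band=None,
) -> np.ndarray:
    """First time each of ``n_reps`` all-distinct crypts becomes monoclonal
    over the band (NaN when not reached within ``horizon`` days)."""
    if n_reps < 1:
        raise ConfigurationError("n_reps must be >= 1")
    band = tuple(monoclonal_band) if monoclonal_band is not None else geometry.lgr5_rows
    seeds = _child_seeds(rng, n_reps)
    return _kernels.conversion_time_batch(
        geometry.n_rows,
        geometry.cells_per_row,
        band[0],
        band[1],
        params.k_d,
        params.k_r,
        seeds,
        horizon,
    )


def is_fragmented(state: CryptState, clone_label: int, geometry: CryptGeometry | None = None) -> bool:
    """True when the set of rows occupied by ``clone_label`` is
    non-contiguous (an empty row strictly between two occupied rows).
    A pure function of the snapshot."""
    counts = state.row_counts(clone_label)
    occupied = np.flatnonzero(counts)
    if occupied.size == 0:
        raise SimulationError(f"clone {clone_label} has no cells in this state")
    return bool(occupied.size < occupied[-1] - occupied[0] + 1)


@dataclass(frozen=True)
class FragmentationResult:
    probability: float
    n_fragmented: int
    n_eligible: int  # surviving clones with >= 2 cells
    n_clones: int


def run_fragmentation_assay(
    params: KineticParams,
    geometry: CryptGeometry,
    n_clones: int,
    t: float,
    rng=None,
) -> FragmentationResult:
    """Induce ``n_clones`` single-cell clones uniformly over the Lgr5+ rows
    and score fragmentation at time ``t`` among surviving clones with at
    least two cells."""
    if n_clones < 1:
        raise EstimationError("fragmentation probability undefined for n_clones = 0")
    if not t > 0:
        raise ConfigurationError("t must be > 0")
    rng = np.random.default_rng(rng)
    g_lo, g_hi = geometry.lgr5_rows
    start_rows = rng.integers(g_lo, g_hi + 1, size=n_clones).astype(np.int64)
    obs = trace_clones(params, geometry, start_rows, [t], rng, condition="fragmentation")
    eligible = obs[obs["n_cells"] >= 2]
    if len(eligible) == 0:
        raise EstimationError("no surviving multi-cell clones; probability undefined")
    n_frag = int(eligible["fragmented"].sum())
    return FragmentationResult(
        probability=n_frag / len(eligible),
        n_fragmented=n_frag,
        n_eligible=len(eligible),
        n_clones=n_clones,
    )


def ablate(state: CryptState, rows) -> CryptState:
    """Vacate all sites in the inclusive row band ``rows`` (in place),
    switching the state to ablation mode. An empty band is a no-op. The mode
    reverts to homeostasis automatically once the lattice refills."""
    if rows is None or (hasattr(rows, "__len__") and len(rows) == 0):
        return state
    lo, hi = int(rows[0]), int(rows[1])
    if not (0 <= lo <= hi < state.geometry.n_rows):
        raise ConfigurationError(f"ablation band {rows} outside lattice")
    state.grid[lo : hi + 1, :] = VACANT
    return state


def run_ablation_recovery(
    params: KineticParams,
    geometry: CryptGeometry,
    n_crypts: int,
    record_times,
    rng=None,
) -> AblationTrajectory:
    """Ablate the Lgr5+ zone of ``n_crypts`` crypts at t=0 and follow the
    vacancy-filling recovery, recording per-row occupancy (and hence the
    lowest occupied row) at each record time."""
    if n_crypts < 1:
        raise ConfigurationError("n_crypts must be >= 1")
    times = _prepare_times(record_times)
    g_lo, g_hi = geometry.lgr5_rows
    seeds = _child_seeds(rng, n_crypts)
    pos_times = times[times > 0]
    occ = np.zeros((n_crypts, times.size, geometry.n_rows), dtype=np.int64)
    if pos_times.size:
        kocc = _kernels.ablation_batch(
            geometry.n_rows,
            geometry.cells_per_row,
            g_lo,
            g_hi,
            pos_times,
            params.k_d,
            params.k_r,
            seeds,
        )
        occ[:, times > 0, :] = kocc
    if (times == 0).any():
        j0 = int(np.where(times == 0)[0][0])
        occ[:, j0, :] = geometry.cells_per_row
        occ[:, j0, g_lo : g_hi + 1] = 0
    occupied = occ > 0
    lowest = np.where(
        occupied.any(axis=2), np.argmax(occupied, axis=2), geometry.n_rows - 1
    )
    return AblationTrajectory(times=times, lowest_row=lowest, occupancy=occ)
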