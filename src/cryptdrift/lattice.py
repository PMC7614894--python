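"""Crypt geometry, kinetic rates, lattice state and the exact simulator.

The crypt is modelled as a cylindrical lattice of cell positions: ``n_rows``
rows of ``cells_per_row`` cells, row 0 at the crypt base, columns cyclic.
Two per-cell Poisson processes drive the dynamics:

* division at rate ``k_d`` per cell per day — the label is duplicated and one
  daughter is inserted at a random neighbour (left/right/above), pushing the
  column above the insertion point up by one row (anterograde conveyor-belt
  displacement, with absorbing loss at the top);
* relocation at rate ``k_r`` per cell per day — the cell swaps places with a
  random lattice neighbour, which is the source of retrograde (downward)
  movement.

``simulate`` runs the exact continuous-time dynamics (Gillespie direct
method) and optionally records every event; the batch experiments in
:mod:`cryptdrift.experiments` use compiled kernels built on the same step
functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from . import _kernels
from ._kernels import VACANT
from .errors import ConfigurationError, SimulationError

__all__ = [
    "VACANT",
    "CryptGeometry",
    "KineticParams",
    "CryptState",
    "EventRecord",
    "PRESETS",
    "preset",
    "build_homeostatic_state",
    "total_event_rate",
    "apply_division",
    "apply_relocation",
    "simulate",
    "snapshots_to_frame",
    "events_to_frame",
]

RowBand = tuple[int, int]


def _check_band(band: Sequence[int], name: str) -> RowBand:
    if len(band) != 2 or band[0] > band[1] or band[0] < 0:
        raise ConfigurationError(f"{name} must be an inclusive (lo, hi) row band, got {band!r}")
    return (int(band[0]), int(band[1]))


@dataclass(frozen=True)
class CryptGeometry:
    """Lattice shape and the row-band definitions of the stem-cell zone.

    Rows 0..1 are the niche centre and rows 2..3 the border by default,
    together forming the Lgr5+ zone; the lattice extends to ``n_rows`` so
    displaced clones can transiently re-enter from above.
    """

    n_rows: int = 8
    cells_per_row: int = 5
    lgr5_rows: RowBand = (0, 3)
    centre_rows: RowBand = (0, 1)
    border_rows: RowBand = (2, 3)

    def __post_init__(self):
        lgr5 = _check_band(self.lgr5_rows, "lgr5_rows")
        centre = _check_band(self.centre_rows, "centre_rows")
        border = _check_band(self.border_rows, "border_rows")
        object.__setattr__(self, "lgr5_rows", lgr5)
        object.__setattr__(self, "centre_rows", centre)
        object.__setattr__(self, "border_rows", border)
        if self.cells_per_row < 2:
            raise ConfigurationError(f"cells_per_row must be >= 2, got {self.cells_per_row}")
        if self.n_rows <= lgr5[1]:
            raise ConfigurationError(
                f"n_rows ({self.n_rows}) must exceed the top Lgr5+ row ({lgr5[1]})"
            )
        centre_set = set(range(centre[0], centre[1] + 1))
        border_set = set(range(border[0], border[1] + 1))
        lgr5_set = set(range(lgr5[0], lgr5[1] + 1))
        if centre_set & border_set:
            raise ConfigurationError("centre_rows and border_rows must be disjoint")
        if centre_set | border_set != lgr5_set:
            raise ConfigurationError("centre_rows and border_rows must tile lgr5_rows")

    @property
    def n_sites(self) -> int:
        return self.n_rows * self.cells_per_row

    def band_rows(self, band: RowBand) -> range:
        return range(band[0], band[1] + 1)


@dataclass(frozen=True)
class KineticParams:
    """Per-cell division (k_d) and relocation (k_r) rates, in 1/day.

    The long-term clone dynamics depend only on the dimensionless ratio
    k_r/k_d; k_d sets the overall time scale.
    """

    k_d: float
    k_r: float

    def __post_init__(self):
        if not self.k_d > 0:
            raise ConfigurationError(f"k_d must be > 0, got {self.k_d}")
        if self.k_r < 0:
            raise ConfigurationError(f"k_r must be >= 0, got {self.k_r}")

    @property
    def ratio(self) -> float:
        return self.k_r / self.k_d

    @classmethod
    def from_ratio(cls, ratio: float, k_d: float = 1.4) -> "KineticParams":
        if ratio < 0:
            raise ConfigurationError(f"ratio must be >= 0, got {ratio}")
        return cls(k_d=k_d, k_r=ratio * k_d)


#: Fitted study conditions: small intestine, large intestine, and the small
#: intestine under porcupine-inhibitor (LGK974) treatment, which lowers k_r
#: while leaving the division rate essentially unchanged.
PRESETS: dict[str, KineticParams] = {
    "SI": KineticParams.from_ratio(2.0, 1.4),
    "LI": KineticParams.from_ratio(0.25, 1.4),
    "SI_LGK974": KineticParams.from_ratio(0.4, 1.4),
}


def preset(name: str) -> KineticParams:
    try:
        return PRESETS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown preset {name!r}; expected one of {sorted(PRESETS)}"
        ) from None


@dataclass
class EventRecord:
    time: float
    kind: Literal["division", "relocation"]
    site: tuple[int, int]
    target: tuple[int, int]


class CryptState:
    """Occupancy of the crypt lattice at one instant.

    ``grid[row, col]`` holds a non-negative lineage label, or ``VACANT`` (-1)
    in ablation mode. The state is in homeostasis mode when every site is
    occupied; it reverts to homeostasis automatically once vacancies refill.
    """

    __slots__ = ("grid", "geometry", "time")

    def __init__(self, grid: np.ndarray, geometry: CryptGeometry, time: float = 0.0):
        grid = np.asarray(grid, dtype=np.int64)
        if grid.shape != (geometry.n_rows, geometry.cells_per_row):
            raise ConfigurationError(
                f"grid shape {grid.shape} does not match geometry "
                f"({geometry.n_rows}, {geometry.cells_per_row})"
            )
        if (grid < VACANT).any():
            raise ConfigurationError("labels must be non-negative integers (or VACANT)")
        self.grid = grid
        self.geometry = geometry
        self.time = float(time)

    @property
    def mode(self) -> str:
        return "homeostasis" if self.n_occupied == self.geometry.n_sites else "ablation"

    @property
    def n_occupied(self) -> int:
        return int((self.grid != VACANT).sum())

    def labels(self) -> np.ndarray:
        """Distinct labels currently on the lattice."""
        occ = self.grid[self.grid != VACANT]
        return np.unique(occ)

    def row_counts(self, label: int) -> np.ndarray:
        """Number of cells of ``label`` in each row."""
        return (self.grid == label).sum(axis=1)

    def is_monoclonal(self, band: RowBand | None = None) -> bool:
        """True when all sites in ``band`` (default: the Lgr5+ zone) are
        occupied by a single lineage."""
        lo, hi = band if band is not None else self.geometry.lgr5_rows
        sub = self.grid[lo : hi + 1]
        return bool((sub != VACANT).all() and (sub == sub.flat[0]).all())

    def copy(self) -> "CryptState":
        return CryptState(self.grid.copy(), self.geometry, self.time)

    def to_frame(self) -> pd.DataFrame:
        rows, cols = np.divmod(np.arange(self.geometry.n_sites), self.geometry.cells_per_row)
        return pd.DataFrame(
            {
                "time": self.time,
                "row": rows,
                "column": cols,
                "label": self.grid.ravel(),
            }
        )


def build_homeostatic_state(
    geometry: CryptGeometry,
    labelling: Literal["all-distinct", "single-label"] = "all-distinct",
) -> CryptState:
    """Full lattice at t=0: every site its own lineage (``all-distinct``,
    used for monoclonal-drift experiments) or one shared label 0
    (``single-label``, the background for clone induction)."""
    shape = (geometry.n_rows, geometry.cells_per_row)
    if labelling == "all-distinct":
        grid = np.arange(geometry.n_sites, dtype=np.int64).reshape(shape)
    elif labelling == "single-label":
        grid = np.zeros(shape, dtype=np.int64)
    else:
        raise ConfigurationError(f"unknown labelling {labelling!r}")
    return CryptState(grid, geometry)


def total_event_rate(state: CryptState, params: KineticParams) -> float:
    """Total Gillespie rate: n_occupied x (k_d + k_r), per day."""
    return state.n_occupied * (params.k_d + params.k_r)


def _require_occupied(state: CryptState, site: tuple[int, int]) -> None:
    row, col = site
    if not (0 <= row < state.geometry.n_rows and 0 <= col < state.geometry.cells_per_row):
        raise SimulationError(f"site {site} outside the lattice")
    if state.grid[row, col] == VACANT:
        raise SimulationError(f"site {site} is vacant")


def apply_division(
    state: CryptState, site: tuple[int, int], rng: np.random.Generator
) -> CryptState:
    """Divide the cell at ``site`` in place (random daughter placement among
    left/right/above, with column push-up). Returns the same state object."""
    _require_occupied(state, site)
    _kernels._division_at(state.grid, site[0], site[1], int(rng.integers(3)))
    return state


def apply_relocation(
    state: CryptState, site: tuple[int, int], rng: np.random.Generator
) -> CryptState:
    """Swap the cell at ``site`` with a uniformly chosen lattice neighbour,
    in place. Returns the same state object."""
    _require_occupied(state, site)
    n_nb = _kernels._n_reloc_neighbours(state.geometry.n_rows, site[0])
    _kernels._relocation_at(state.grid, site[0], site[1], int(rng.integers(n_nb)))
    return state


def simulate(
    state: CryptState,
    params: KineticParams,
    duration: float,
    record_times: Iterable[float] | None = None,
    rng: np.random.Generator | int | None = None,
    log_events: bool = False,
) -> tuple[list[tuple[float, CryptState]], list[EventRecord]]:
    """Exact event-driven simulation from ``state`` for ``duration`` days.

    Waiting times are exponential with the total occupied-cell rate; the
    event cell is uniform over occupied sites and the kind is chosen in
    proportion to k_d and k_r. Snapshots (copies) are taken at
    ``record_times`` (default: only at ``duration``). The input state is not
    modified. Returns (snapshots, event_log); the log is empty unless
    ``log_events``.
    """
    if duration < 0:
        raise ConfigurationError(f"duration must be >= 0, got {duration}")
    rng = np.random.default_rng(rng)
    if record_times is None:
        record_times = [duration]
    record_times = sorted(float(t) for t in record_times)
    if record_times and (record_times[0] < 0 or record_times[-1] > duration):
        raise ConfigurationError("record_times must lie within [0, duration]")

    geom = state.geometry
    n_rows, n_cols = geom.n_rows, geom.cells_per_row
    work = state.copy()
    t = work.time
    t0 = t
    snapshots: list[tuple[float, CryptState]] = []
    events: list[EventRecord] = []
    p_div = params.k_d / (params.k_d + params.k_r)

    rec_iter = iter(record_times)
    next_rec = next(rec_iter, None)
    n_occ = work.n_occupied
    t_final = t0 + duration
    while True:
        rate = n_occ * (params.k_d + params.k_r)
        if rate == 0:
            break
        dt = rng.exponential(1.0 / rate)
        if t + dt >= t_final:
            break
        t += dt
        # snapshot times strictly before the event time
        while next_rec is not None and t0 + next_rec < t:
            snap = work.copy()
            snap.time = t0 + next_rec
            snapshots.append((t0 + next_rec, snap))
            next_rec = next(rec_iter, None)
        # choose an occupied site uniformly
        while True:
            idx = int(rng.integers(n_rows * n_cols))
            row, col = divmod(idx, n_cols)
            if work.grid[row, col] != VACANT:
                break
        if rng.random() < p_div:
            exited, nr, nc = _kernels._division_at(work.grid, row, col, int(rng.integers(3)))
            if exited == VACANT:
                n_occ += 1
            if log_events:
                events.append(EventRecord(t, "division", (row, col), (int(nr), int(nc))))
        else:
            n_nb = _kernels._n_reloc_neighbours(n_rows, row)
            nr, nc = _kernels._relocation_at(work.grid, row, col, int(rng.integers(n_nb)))
            if log_events:
                events.append(EventRecord(t, "relocation", (row, col), (int(nr), int(nc))))
    # flush remaining snapshots at their nominal times
    while next_rec is not None:
        snap = work.copy()
        snap.time = t0 + next_rec
        snapshots.append((t0 + next_rec, snap))
        next_rec = next(rec_iter, None)
    return snapshots, events


def snapshots_to_frame(snapshots: Sequence[tuple[float, CryptState]]) -> pd.DataFrame:
    """Long-format table of snapshots: time, row, column, label."""
    if not snapshots:
        return pd.DataFrame(columns=["time", "row", "column", "label"])
    return pd.concat([s.to_frame() for _, s in snapshots], ignore_index=True)


def events_to_frame(events: Sequence[EventRecord]) -> pd.DataFrame:
    """Event log as a table: time, kind, site_row, site_col, target_row, target_col."""
    return pd.DataFrame(
        {
            "time": [e.time for e in events],
            "kind": [e.kind for e in events],
            "site_row": [e.site[0] for e in events],
            "site_col": [e.site[1] for e in events],
            "target_row": [e.target[0] for e in events],
            "target_col": [e.target[1] for e in events],
        }
    )
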