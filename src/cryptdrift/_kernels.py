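"""Numba kernels for the crypt lattice dynamics.

The lattice is an ``(n_rows, cells_per_row)`` int64 array; row 0 is the crypt
base, columns are cyclic (cylinder). Entries are non-negative lineage labels,
or ``VACANT`` (-1) after ablation. All mechanics live in the two step
functions below; the batch kernels and the Python-level event loop both call
them, so there is a single source of truth for how division and relocation
rearrange cells.

Division at (row, col): the label is duplicated, one daughter stays in place
and the other is inserted at a uniformly chosen neighbour among
{left, right, directly above}. Insertion pushes the occupied run of the target
column upward; the push is absorbed by the first vacancy above (ablation
mode), otherwise the top-row cell exits the lattice. An insertion above the
top row means the daughter exits immediately.

Relocation at (row, col): contents are swapped with a uniformly chosen
existing lattice neighbour (left, right, up, down; row 0 has no down, the top
row no up). Swapping with a vacancy moves the cell into it.
"""

import numpy as np
from numba import njit

VACANT = -1


@njit(cache=True)
def _division_at(lat, row, col, choice):
    """Apply a division with daughter-placement ``choice`` (0=left, 1=right,
    2=above). Returns (exited_label, target_row, target_col); exited_label is
    VACANT when no cell left the lattice (a vacancy absorbed the push)."""
    n_rows, n_cols = lat.shape
    label = lat[row, col]
    if choice == 0:
        nr, nc = row, (col - 1) % n_cols
    elif choice == 1:
        nr, nc = row, (col + 1) % n_cols
    else:
        nr, nc = row + 1, col
    if nr >= n_rows:
        # daughter placed above the top row: duplicated then immediately lost
        return label, nr, nc
    vac = -1
    for r in range(nr, n_rows):
        if lat[r, nc] == VACANT:
            vac = r
            break
    if vac == -1:
        exited = lat[n_rows - 1, nc]
        for r in range(n_rows - 1, nr, -1):
            lat[r, nc] = lat[r - 1, nc]
        lat[nr, nc] = label
        return exited, nr, nc
    for r in range(vac, nr, -1):
        lat[r, nc] = lat[r - 1, nc]
    lat[nr, nc] = label
    return VACANT, nr, nc


@njit(cache=True)
def _n_reloc_neighbours(n_rows, row):
    n = 2
    if row > 0:
        n += 1
    if row < n_rows - 1:
        n += 1
    return n


@njit(cache=True)
def _relocation_at(lat, row, col, choice):
    """Swap (row, col) with its ``choice``-th neighbour. Choices 0/1 are
    left/right; 2 is up where it exists, otherwise down; 3 is down.
    Returns (target_row, target_col)."""
    n_rows, n_cols = lat.shape
    if choice == 0:
        nr, nc = row, (col - 1) % n_cols
    elif choice == 1:
        nr, nc = row, (col + 1) % n_cols
    elif choice == 2:
        if row < n_rows - 1:
            nr, nc = row + 1, col
        else:
            nr, nc = row - 1, col
    else:
        nr, nc = row - 1, col
    tmp = lat[row, col]
    lat[row, col] = lat[nr, nc]
    lat[nr, nc] = tmp
    return nr, nc


@njit(cache=True)
def _advance_full(lat, kd, kr, t, t_end, label, n_label):
    """Advance a full (homeostatic) lattice to t_end with exact Gillespie
    dynamics, optionally tracking the cell count of one lineage ``label``
    (pass label=-1 to disable tracking). Returns (t_end, n_label); stops
    early once the tracked lineage is extinct (the lattice is then stale but
    the lineage count is zero forever after)."""
    n_rows, n_cols = lat.shape
    n_sites = n_rows * n_cols
    total = n_sites * (kd + kr)
    pdiv = kd / (kd + kr)
    while True:
        if label >= 0 and n_label == 0:
            return t_end, 0
        dt = np.random.exponential(1.0 / total)
        if t + dt >= t_end:
            return t_end, n_label
        t = t + dt
        idx = np.random.randint(n_sites)
        row = idx // n_cols
        col = idx - row * n_cols
        if np.random.random() < pdiv:
            lab = lat[row, col]
            exited, _, _ = _division_at(lat, row, col, np.random.randint(3))
            if label >= 0:
                if lab == label:
                    n_label += 1
                if exited == label:
                    n_label -= 1
        else:
            _relocation_at(
                lat, row, col, np.random.randint(_n_reloc_neighbours(n_rows, row))
            )


@njit(cache=True)
def _advance_vacant(lat, kd, kr, t, t_end, n_occ):
    """Advance a lattice that may contain vacancies (ablation mode).
    Per-cell rates apply to occupied sites only. Returns (t_end, n_occ)."""
    n_rows, n_cols = lat.shape
    n_sites = n_rows * n_cols
    pdiv = kd / (kd + kr)
    while n_occ > 0:
        total = n_occ * (kd + kr)
        dt = np.random.exponential(1.0 / total)
        if t + dt >= t_end:
            return t_end, n_occ
        t = t + dt
        while True:
            idx = np.random.randint(n_sites)
            row = idx // n_cols
            col = idx - row * n_cols
            if lat[row, col] != VACANT:
                break
        if np.random.random() < pdiv:
            exited, _, _ = _division_at(lat, row, col, np.random.randint(3))
            if exited == VACANT:
                n_occ += 1
        else:
            _relocation_at(
                lat, row, col, np.random.randint(_n_reloc_neighbours(n_rows, row))
            )
    return t_end, n_occ


@njit(cache=True)
def _band_monoclonal(lat, lo, hi):
    first = lat[lo, 0]
    for r in range(lo, hi + 1):
        for c in range(lat.shape[1]):
            if lat[r, c] != first:
                return False
    return True


@njit(cache=True)
def lineage_batch(n_rows, n_cols, start_rows, start_cols, record_times, kd, kr, seeds):
    """Simulate one labelled clone per independent crypt.

    Each clone i starts as a single cell with label 1 at
    (start_rows[i], start_cols[i]) on a label-0 background. Returns an
    (n, n_times, n_rows) array of per-row clone cell counts at the record
    times (all zero from the first record time after extinction onward)."""
    n = start_rows.shape[0]
    n_times = record_times.shape[0]
    counts = np.zeros((n, n_times, n_rows), dtype=np.int64)
    for i in range(n):
        np.random.seed(seeds[i])
        lat = np.zeros((n_rows, n_cols), dtype=np.int64)
        lat[start_rows[i], start_cols[i]] = 1
        t = 0.0
        n_lab = 1
        for j in range(n_times):
            t, n_lab = _advance_full(lat, kd, kr, t, record_times[j], 1, n_lab)
            if n_lab == 0:
                break
            for r in range(n_rows):
                cnt = 0
                for c in range(n_cols):
                    if lat[r, c] == 1:
                        cnt += 1
                counts[i, j, r] = cnt
    return counts


@njit(cache=True)
def monoclonal_batch(n_rows, n_cols, band_lo, band_hi, record_times, kd, kr, seeds):
    """All-distinct initial labelling; returns an (n, n_times) uint8 matrix of
    whether rows band_lo..band_hi share a single label at each record time."""
    n = seeds.shape[0]
    n_times = record_times.shape[0]
    mono = np.zeros((n, n_times), dtype=np.uint8)
    for i in range(n):
        np.random.seed(seeds[i])
        lat = np.arange(n_rows * n_cols, dtype=np.int64).reshape(n_rows, n_cols)
        t = 0.0
        for j in range(n_times):
            t, _ = _advance_full(lat, kd, kr, t, record_times[j], -1, 0)
            if _band_monoclonal(lat, band_lo, band_hi):
                mono[i, j] = 1
    return mono


@njit(cache=True)
def conversion_time_batch(n_rows, n_cols, band_lo, band_hi, kd, kr, seeds, horizon):
    """First time at which rows band_lo..band_hi become monoclonal, starting
    from all-distinct labels; NaN if not reached before ``horizon`` days."""
    n = seeds.shape[0]
    out = np.empty(n, dtype=np.float64)
    n_sites = n_rows * n_cols
    pdiv = kd / (kd + kr)
    total = n_sites * (kd + kr)
    for i in range(n):
        np.random.seed(seeds[i])
        lat = np.arange(n_sites, dtype=np.int64).reshape(n_rows, n_cols)
        t = 0.0
        out[i] = np.nan
        while True:
            t += np.random.exponential(1.0 / total)
            if t >= horizon:
                break
            idx = np.random.randint(n_sites)
            row = idx // n_cols
            col = idx - row * n_cols
            touched_band = False
            if np.random.random() < pdiv:
                _division_at(lat, row, col, np.random.randint(3))
                touched_band = row <= band_hi
            else:
                _relocation_at(
                    lat, row, col, np.random.randint(_n_reloc_neighbours(n_rows, row))
                )
                touched_band = row <= band_hi + 1
            if touched_band and _band_monoclonal(lat, band_lo, band_hi):
                out[i] = t
                break
    return out


@njit(cache=True)
def ablation_batch(n_rows, n_cols, ablate_lo, ablate_hi, record_times, kd, kr, seeds):
    """Ablate rows ablate_lo..ablate_hi at t=0 and let the vacancy-filling
    dynamics run. Returns an (n, n_times, n_rows) array of per-row occupied
    cell counts at the record times."""
    n = seeds.shape[0]
    n_times = record_times.shape[0]
    occ = np.zeros((n, n_times, n_rows), dtype=np.int64)
    n_ablated = (ablate_hi - ablate_lo + 1) * n_cols
    for i in range(n):
        np.random.seed(seeds[i])
        lat = np.zeros((n_rows, n_cols), dtype=np.int64)
        for r in range(ablate_lo, ablate_hi + 1):
            for c in range(n_cols):
                lat[r, c] = VACANT
        n_occ = n_rows * n_cols - n_ablated
        t = 0.0
        for j in range(n_times):
            t, n_occ = _advance_vacant(lat, kd, kr, t, record_times[j], n_occ)
            for r in range(n_rows):
                cnt = 0
                for c in range(n_cols):
                    if lat[r, c] != VACANT:
                        cnt += 1
                occ[i, j, r] = cnt
    return occ
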