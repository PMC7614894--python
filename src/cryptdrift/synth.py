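"""Synthetic study-like datasets emulating the intravital lineage-tracing
design: single-cell induction at known rows, a long-term arm observed at ~48 h
and 8 weeks, a short-term arm observed daily on days 1-4, cross-sectional
whole-mount monoclonality counts at weeks 1-8, and ablation-recovery scoring.

Clones are allocated uniformly to mice; sampling noise is binomial by
construction (each clone is one Bernoulli trajectory of the simulator). By
default there are no mouse effects; an optional log-normal per-mouse jitter
on k_d stresses grouped resampling in the inference module.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .experiments import trace_clones, run_monoclonal_drift, run_ablation_recovery
from .lattice import CryptGeometry, KineticParams, preset

__all__ = ["StudyArm", "StudyDesign", "StudyBundle", "allocate_start_rows", "generate_study"]

#: Qualitative Lgr5-expression gradient used by the "lgr5-graded" weighting:
#: rows 0-1 high, rows 2-3 intermediate.
DEFAULT_GRADED_WEIGHTS = (0.3, 0.3, 0.2, 0.2)


@dataclass(frozen=True)
class StudyArm:
    """One experimental condition with its sample sizes."""

    condition: str
    params: KineticParams
    n_clones_long: int = 267
    n_mice_long: int = 6
    n_clones_short: int = 305
    n_mice_short: int = 9
    #: whole-mount crypt counts per monoclonality time point
    n_crypts_monoclonal: tuple[int, ...] = (444, 375, 218, 152, 151)
    n_mice_monoclonal: int = 3
    n_crypts_ablation: int = 100
    n_mice_ablation: int = 3
    start_row_weighting: str = "uniform"  # or "lgr5-graded"


def _default_arms() -> tuple[StudyArm, ...]:
    return (
        StudyArm(
            condition="SI",
            params=preset("SI"),
            n_clones_long=267,
            n_mice_long=6,
            n_clones_short=305,
            n_mice_short=9,
            n_crypts_monoclonal=(444, 375, 218, 152, 151),
        ),
        StudyArm(
            condition="LI",
            params=preset("LI"),
            n_clones_long=294,
            n_mice_long=6,
            n_clones_short=311,
            n_mice_short=5,
            n_crypts_monoclonal=(304, 465, 236, 164, 531),
        ),
    )


@dataclass(frozen=True)
class StudyDesign:
    """Arms, observation schedules and sample sizes of the emulated study."""

    arms: tuple[StudyArm, ...] = field(default_factory=_default_arms)
    geometry: CryptGeometry = field(default_factory=CryptGeometry)
    long_term_times: tuple[float, ...] = (2.0, 56.0)
    short_term_times: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0)
    monoclonality_times: tuple[float, ...] = (7.0, 14.0, 28.0, 42.0, 56.0)
    ablation_times: tuple[float, ...] = (1.0, 2.0, 4.0, 7.0, 15.0)
    mouse_kd_cv: float = 0.0  # log-normal CV of an optional per-mouse k_d jitter
    seed: int | None = None

    def __post_init__(self):
        if not self.arms:
            raise ConfigurationError("design needs at least one arm")
        for arm in self.arms:
            if arm.n_clones_long < 1 or arm.n_clones_short < 1:
                raise ConfigurationError(f"arm {arm.condition}: n_clones must be >= 1")
            if len(arm.n_crypts_monoclonal) != len(self.monoclonality_times):
                raise ConfigurationError(
                    f"arm {arm.condition}: one crypt count per monoclonality time"
                )
        for times in (
            self.long_term_times,
            self.short_term_times,
            self.monoclonality_times,
            self.ablation_times,
        ):
            if list(times) != sorted(times):
                raise ConfigurationError("observation times must be sorted ascending")


@dataclass(frozen=True)
class StudyBundle:
    long_term: pd.DataFrame
    short_term: pd.DataFrame
    monoclonality: pd.DataFrame
    ablation: pd.DataFrame
    manifest: dict


def allocate_start_rows(
    n_clones: int,
    geometry: CryptGeometry,
    weighting: str = "uniform",
    rng=None,
    graded_weights=DEFAULT_GRADED_WEIGHTS,
) -> np.ndarray:
    """Starting row per induced clone, drawn over the Lgr5+ rows either
    uniformly or weighted by the qualitative Lgr5-expression gradient."""
    rng = np.random.default_rng(rng)
    lo, hi = geometry.lgr5_rows
    rows = np.arange(lo, hi + 1)
    if n_clones == 0:
        return np.empty(0, dtype=np.int64)
    if weighting == "uniform":
        p = None
    elif weighting == "lgr5-graded":
        w = np.asarray(graded_weights, dtype=float)
        if w.size != rows.size:
            raise ConfigurationError(
                f"graded weights length {w.size} != {rows.size} Lgr5+ rows"
            )
        p = w / w.sum()
    else:
        raise ConfigurationError(f"unknown weighting {weighting!r}")
    return rng.choice(rows, size=n_clones, p=p).astype(np.int64)


def _mouse_params(arm: StudyArm, n_mice: int, cv: float, rng) -> list[KineticParams]:
    if cv <= 0:
        return [arm.params] * n_mice
    sigma = np.sqrt(np.log1p(cv**2))
    factors = rng.lognormal(mean=-(sigma**2) / 2, sigma=sigma, size=n_mice)
    return [
        KineticParams(k_d=arm.params.k_d * f, k_r=arm.params.k_r * f) for f in factors
    ]


def _tracing_table(arm, n_clones, n_mice, times, design, rng, assay) -> pd.DataFrame:
    geometry = design.geometry
    mouse_of = rng.integers(0, n_mice, size=n_clones)
    rows = allocate_start_rows(n_clones, geometry, arm.start_row_weighting, rng)
    per_mouse = _mouse_params(arm, n_mice, design.mouse_kd_cv, rng)
    frames = []
    offset = 0
    for m in range(n_mice):
        sel = mouse_of == m
        if not sel.any():
            continue
        obs = trace_clones(
            per_mouse[m], geometry, rows[sel], times, rng, condition=arm.condition
        )
        obs["clone_id"] = obs["clone_id"] + offset
        obs["mouse_id"] = f"{arm.condition}_{assay}_m{m}"
        offset += int(sel.sum())
        frames.append(obs)
    out = pd.concat(frames, ignore_index=True)
    out["assay"] = assay
    return out


def generate_study(design: StudyDesign, rng=None) -> StudyBundle:
    """Simulate the full study design: one table per assay plus a manifest
    recording seeds and generating parameters. Deterministic for a given
    design and seed."""
    if not isinstance(design, StudyDesign):
        raise ConfigurationError("design must be a StudyDesign")
    if rng is None:
        rng = design.seed
    seed_note = int(rng) if isinstance(rng, (int, np.integer)) else None
    rng = np.random.default_rng(rng)
    geometry = design.geometry

    long_frames, short_frames, mono_frames, abl_frames = [], [], [], []
    for arm in design.arms:
        long_frames.append(
            _tracing_table(
                arm, arm.n_clones_long, arm.n_mice_long, design.long_term_times,
                design, rng, assay="long_term",
            )
        )
        short_frames.append(
            _tracing_table(
                arm, arm.n_clones_short, arm.n_mice_short, design.short_term_times,
                design, rng, assay="short_term",
            )
        )
        # cross-sectional whole mounts: independent crypts at each time
        for t, n_crypts in zip(design.monoclonality_times, arm.n_crypts_monoclonal):
            series = run_monoclonal_drift(arm.params, geometry, n_crypts, [t], rng)
            mono_frames.append(
                pd.DataFrame(
                    {
                        "condition": arm.condition,
                        "time_days": t,
                        "crypt_id": np.arange(n_crypts),
                        "mouse_id": [
                            f"{arm.condition}_mono_t{t:g}_m{m}"
                            for m in rng.integers(0, arm.n_mice_monoclonal, size=n_crypts)
                        ],
                        "monoclonal": series.per_crypt[:, 0].astype(bool),
                    }
                )
            )
        traj = run_ablation_recovery(
            arm.params, geometry, arm.n_crypts_ablation, design.ablation_times, rng
        )
        abl = traj.to_frame()
        abl.insert(0, "condition", arm.condition)
        mouse_of = rng.integers(0, arm.n_mice_ablation, size=arm.n_crypts_ablation)
        abl["mouse_id"] = [
            f"{arm.condition}_abl_m{m}" for m in mouse_of[abl["crypt_id"]]
        ]
        c_lo, c_hi = geometry.centre_rows
        b_lo, b_hi = geometry.border_rows
        centre_occ = traj.occupancy[:, :, c_lo : c_hi + 1].sum(axis=2) > 0
        border_occ = traj.occupancy[:, :, b_lo : b_hi + 1].sum(axis=2) > 0
        abl["centre_recovered"] = centre_occ.ravel()
        abl["border_recovered"] = border_occ.ravel()
        abl_frames.append(abl)

    long_term = pd.concat(long_frames, ignore_index=True)
    short_term = pd.concat(short_frames, ignore_index=True)
    monoclonality = pd.concat(mono_frames, ignore_index=True)
    ablation = pd.concat(abl_frames, ignore_index=True)
    manifest = {
        "seed": seed_note,
        "geometry": dataclasses.asdict(geometry),
        "arms": [
            {
                "condition": a.condition,
                "k_d": a.params.k_d,
                "k_r": a.params.k_r,
                "ratio": a.params.ratio,
                "n_clones_long": a.n_clones_long,
                "n_clones_short": a.n_clones_short,
            }
            for a in design.arms
        ],
        "tables": {
            "long_term": len(long_term),
            "short_term": len(short_term),
            "monoclonality": len(monoclonality),
            "ablation": len(ablation),
        },
    }
    return StudyBundle(long_term, short_term, monoclonality, ablation, manifest)
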