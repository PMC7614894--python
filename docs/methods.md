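# Methods

## Model

A crypt is abstracted as a cylinder of cell positions: `n_rows` rows of
`cells_per_row` cells, row 0 at the base, cyclic columns. The hemispheric
crypt bottom is approximated by the cylinder's closed bottom row (row 0 has
no downward neighbour); because equal-height bands of a hemisphere have
equal area, a constant number of cells per row is a reasonable rendering of
the observed near-constant Lgr5⁺ cell counts per position. The Lgr5⁺ zone is
rows 0–3, split into centre (rows 0–1) and border (rows 2–3); the default
lattice extends to 8 rows — twice the Lgr5⁺ zone — so displaced clones can
transiently re-enter from above. A sensitivity check in the test suite
doubles `n_rows` and finds 8-week niche retention unchanged within
Monte-Carlo error.

Dynamics are two per-cell Poisson clocks, identical for every occupied site:

* **Division, rate `k_d`** (default 1.4/day, the measured proliferation rate
  of crypt-base cells). The lineage label is duplicated; one daughter stays
  in place, the other is inserted at a uniformly chosen neighbour among
  {left, right, directly above}. Insertion pushes the occupied run of the
  target column up one row; a cell pushed past the top row leaves the
  system (absorbing loss toward the villus/lumen). An insertion above the
  top row means the daughter itself is lost. This realization produces both
  the net upward flux ("conveyor belt") and lateral neutral competition
  within rows.
* **Relocation, rate `k_r`**. The cell swaps places with a uniformly chosen
  existing lattice neighbour (left, right, up, down; row 0 has no down
  neighbour, the top row no up neighbour). Downward swaps are the model's
  retrograde movement. `k_r` is the single knob through which Wnt enters
  the model; there are no explicit Paneth cells, gradients or mechanics.

Simulation is an exact continuous-time Gillespie direct method: waiting
times are exponential in `n_occupied × (k_d + k_r)`, the event cell is
uniform over occupied sites and the kind proportional to the two rates.
There is no time-discretization parameter. All times are days; rows are
0-based from the crypt base.

In ablation mode, sites can be vacant: a division daughter entering a vacant
site fills it without push-up (a vacancy above the insertion point likewise
absorbs the push), and a relocation with a vacant neighbour moves the cell
into the vacancy. The state returns to homeostasis automatically once the
lattice refills. These vacancy rules are this package's realization;
alternatives (e.g. biased migration into vacancies) would accelerate
recovery uniformly and not change the SI/LI contrast, which is driven by
`k_r`.

## Analytic surfaces

Treating a cell's row as a continuous coordinate, relocation contributes
symmetric diffusion and the divisions below a cell an upward drift whose
gradient is `k_d` (each division inserts exactly one daughter into exactly
one column, so a column at row `x` receives insertions at rate `k_d` per row
below). Long-term clone persistence then decays as a Gaussian of the
starting position, `P(x)/P(0) = exp(-x²/(2σ²))` with `σ² = k_r/k_d` — the
convention adopted exactly here, as it is pinned by the anchor values it
must reproduce (ratio 2 → 19 effective cells, ratio 0.25 → 10, two effective
LI rows). Profiles are normalized to row 0. Counting rows whose normalized
retention is at least 5% (≈2σ of positional fluctuations) gives
`N_s = N_g (1 + 2√(k_r/k_d))`, reported raw and rounded.

**Known property of the lattice realization.** For the uniform 4-neighbour
exchange rule, only about half of relocation events move a cell vertically,
so the realized vertical diffusion coefficient is ≈`k_r/2`, not `k_r`; at
small ratios lattice discreteness and the multi-cell structure of clones
inflate apparent spread in the opposite direction. The net effect, measured
by the acceptance tests: refitting simulated 8-week retention recovers the
generating ratio well at 0.25 and 0.4 but underestimates it at 2 (≈1.1–1.3
instead of 2, i.e. the simulated SI profile is narrower than the ideal
Gaussian). A vertical-only exchange rule removes the SI bias but introduces
a comparable LI bias; no uniform local-exchange rule examined satisfies
`σ² = k_r/k_d` across the whole ratio range. The 4-neighbour rule is kept
as the reference realization because it is the most literal rendering of
"exchange of neighbouring cells within or between adjacent rows".

A second, related property: with every cell dividing at 1.4/day, lateral
division-driven replacement fixes a simulated crypt's Lgr5⁺ zone in ~8–16
days (median), so essentially all simulated crypts are monoclonal by six
weeks and the asymptotic absolute retention of border-derived clones is
1–2%. Reported experimental values (~30% SI monoclonality at six weeks,
~15% absolute border-clone retention at eight weeks) imply a ~3–4× slower
neutral-drift clock; since per-crypt fixation probabilities must sum to 1,
no neutral-competition realization at these rates can reproduce the 15%
absolute figure at fixation. The contrast structure (LI converts faster
than SI; conversion time grows close to linearly in `√(k_r/k_d)`; SI
fragments clones more and regenerates faster) is reproduced throughout.
Quantities tied to the absolute drift clock are therefore reported as
computed, without rescaling.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| `k_d` | division rate per cell | 1.4 /day | sets the overall time scale |
| `k_r` | relocation rate per cell | preset | `k_r/k_d`: SI 2, LI 0.25, SI_LGK974 0.4 |
| `n_rows` | simulated rows | 8 | 2× the Lgr5⁺ zone |
| `cells_per_row` | `N_g` | 5 | measured cells per row |
| `lgr5_rows` | stem-cell zone | (0, 3) | centre (0,1) + border (2,3) |
| retention threshold | "effective" cutoff | 0.05 | per-row normalized retention |

## Inference

`fit_ratio_longterm` maximizes the binomial likelihood of per-row retained
counts under `p(x) = p0·exp(-x²/(2σ²))`, optimizing `(log p0, log σ²)` with
L-BFGS-B and analytic gradients. The amplitude `p0` is a free parameter:
fitting it jointly avoids dividing the data by a noisy row-0 estimate
(normalization to row 0 is applied only for display/prediction). The
σ² ≥ 0 boundary is handled by optimizing `log σ²` with a boundary flag; a
profile with zero retention beyond row 0 is placed on the boundary
explicitly. Uncertainty is a nonparametric bootstrap over clones (default
1000 resamples, percentile 95% intervals, seeded); mouse-level clustering is
ignored by default, with a grouped bootstrap available via `groups=`. Only
the ratio is identifiable from a late-time profile; `fit_kd_shortterm`
recovers `k_d` from day 1–4 retention trajectories by grid search with the
ratio held fixed, simulating every candidate with common random numbers and
minimizing summed squared error over (row, time) cells.

`predict_retention` returns the normalized central curve with the
2.5–97.5 percentile envelope of the bootstrap replicate curves. In the
well-specified regime (counts drawn from the binomial Gaussian model
itself) the band covers the generating profile at every row in ≥90% of
replicates (checked at 300 clones/row, 200 resamples, 60 replicates).

## Synthetic data

`generate_study` emulates the intravital study design: a long-term arm
observed at 2 and 56 days (defaults: SI 267 clones / 6 mice, LI 294 / 6), a
short-term arm observed daily on days 1–4 (SI 305 / 9 mice, LI 311 / 5),
cross-sectional whole-mount monoclonality counts at weeks 1–8 with per-time
crypt counts matching the study tables, and ablation-recovery scoring at
days 1–15. Clones are allocated to mice uniformly; starting rows are
uniform over the Lgr5⁺ rows by default (the induced-row distribution is not
known; an Lgr5-expression-graded weighting — rows 0–1 high, 2–3
intermediate — is available in config). Sampling noise is binomial by
construction; mouse effects are absent by default, with an optional
log-normal per-mouse jitter on `k_d` (configurable CV) to stress grouped
resampling. What the generator does **not** emulate: imaging artefacts,
Lgr5-GFP patchiness, confetti colour multiplicity, or observation
conditioning (clones are classified by their induction row at t=0, not by
their position at the first imaging session). Tests passing on these data
therefore demonstrate correctness of the pipeline under the model's own
assumptions, not fidelity to every feature of real intravital data.

## Numerical choices

* Exact event-driven simulation; compiled (numba) batch kernels for the
  ensemble experiments share the single-event step functions with the
  Python-level `simulate()`, which additionally records an event log.
* Per-crypt RNG streams are spawned from the user seed; identical seed and
  configuration give byte-identical outputs (asserted for the CLI).
* Lineage-tracing kernels stop a crypt's simulation once the traced clone
  is extinct (its observables are then constant).
* Monoclonality is judged over the Lgr5⁺ zone (rows 0–3). Judging over the
  whole lattice delays conversion only by the short upper-lattice flush
  time. Conversion time is the first time the band is monoclonal.
* Fragmentation is scored along the row axis only: a clone is fragmented
  when its occupied rows are non-contiguous. Within-row (lateral) splits
  are not counted. The probability is reported among surviving clones with
  at least two cells.
* "Lost" means no clone cell within rows 0–3; retained = centre-present or
  border-present.
* Desk-scale experiment sizes used by the tests and the acceptance script:
  2,000 clones per row for retention round trips, 500 crypts for
  monoclonality, 250–300 crypts for ablation, 300 replicates per ratio for
  fixation-time scaling, 10,000 clones for fragmentation contrasts.

## Limitations

* The two quantitative gaps of the reference realization described above
  (effective vertical diffusion ≈`k_r/2`; fast absolute drift clock) are
  intrinsic to the uniform-rate, local-exchange lattice rendering, not to
  the analytic theory. Applications that depend on the absolute fixation
  time scale should treat `k_d` as an effective, fittable clock rather than
  the literal cell-cycle rate.
* No villus dynamics, differentiation states, Paneth-cell agents or
  Lgr5-expression dynamics; Lgr5⁺ status is purely positional.
* The hemispheric crypt base is approximated by a closed bottom row.
* Bootstrap intervals are percentile intervals; no Bayesian posterior is
  provided, and `(k_d, k_r)` cannot be fit jointly from late-time data
  (only the ratio enters the asymptotic profile).
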