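# cryptdrift

Stochastic conveyor-belt dynamics of intestinal crypt stem cells: an exact
lattice simulator, closed-form clone-retention analytics, virtual
lineage-tracing experiments, and inference of the relocation-to-division
rate ratio from clone-tracing tables.

## The problem

Intestinal epithelium renews from stem cells at the base of crypts. Cells
carrying the stem-cell marker Lgr5 occupy roughly the lowest four cell rows
(~5 cells per row); division pressure from below continuously displaces
cells upward toward the gut lumen (*anterograde* movement, the "conveyor
belt"), while active, Wnt-dependent cell rearrangement can move cells back
down toward the niche base (*retrograde* movement). Whether a cell acts as a
long-term *effective* stem cell is then not a fixed identity but a question
of position and movement: cells away from the base persist only if
retrograde movement returns them before they are flushed away. The small
intestine (SI) shows substantial retrograde movement; the large intestine
(LI) almost none — with measurable consequences for effective stem cell
numbers, monoclonal conversion of crypts, and regeneration after ablation
of the Lgr5⁺ compartment.

`cryptdrift` implements the biophysical model of this competition for
modellers and quantitative biologists analysing clonal lineage-tracing
data.

## The model

A crypt is a cylindrical lattice of cell positions (default 8 rows × 5
cells, row 0 at the base; columns are cyclic). Two Poisson processes act on
every cell, simulated exactly (Gillespie direct method):

* **division** at rate `k_d` per cell per day: the lineage label is
  duplicated, one daughter takes a uniformly chosen neighbouring position
  (left, right, or directly above) and pushes the occupied column above the
  insertion point up one row; cells pushed past the top row are lost;
* **relocation** at rate `k_r` per cell per day: the cell exchanges places
  with a uniformly chosen lattice neighbour (left, right, up, down), the
  source of retrograde movement.

The one-dimensional theory of this *stochastic conveyor belt* predicts that
the probability that a clone induced at row `x` persists long-term in the
niche falls off as a Gaussian of its starting position,

```
P(x) / P(0) = exp(-x² / (2σ²)),        σ² = k_r / k_d,
```

so the number of effective stem cells is

```
N_s ≈ N_g (1 + 2 √(k_r/k_d)),
```

with `N_g` cells per row. With the fitted study conditions — `k_r/k_d = 2`
(SI), `0.25` (LI), `0.4` (SI under the porcupine/Wnt-secretion inhibitor
LGK974), all at `k_d = 1.4/day` — this gives ≈19 effective stem cells per SI
crypt and ≈10 per LI crypt, the LI competitive zone reaching only the first
two rows. These conditions ship as the presets `"SI"`, `"LI"` and
`"SI_LGK974"`.

On top of the simulator the package reproduces the study designs in silico:
single-cell clone induction with retention/centre/border scoring
(`run_lineage_tracing`), monoclonal drift from all-distinct labelling
(`run_monoclonal_drift`), clone fragmentation (`run_fragmentation_assay`),
Lgr5⁺-zone ablation and recovery (`run_ablation_recovery`), and a
synthetic-study generator with realistic arm sizes and per-mouse grouping
(`generate_study`). `fit_ratio_longterm` estimates `σ² = k_r/k_d` from
retention-by-row counts by binomial maximum likelihood with a clone-level
bootstrap CI; `fit_kd_shortterm` recovers the division rate from short-term
retention trajectories by a simulation-based grid search.

## Worked example

```python
import numpy as np
import cryptdrift as cd

geom = cd.CryptGeometry()                 # 8 rows x 5 cells, Lgr5+ zone rows 0-3
si = cd.preset("SI")                      # k_d = 1.4/day, k_r/k_d = 2

# closed-form effective stem cell number
est = cd.effective_stem_cell_number(geom.cells_per_row, si.ratio)
print(est.n_s, est.n_s_rounded)           # 19.14 19

# virtual 8-week lineage tracing, 2000 clones per starting row
rng = np.random.default_rng(1)
obs = cd.run_lineage_tracing(si, geom, [0, 1, 2, 3], 2000, [56.0], rng, "SI")
fit = cd.fit_ratio_longterm(obs, n_boot=1000, rng=rng)
print(fit.summary())
```

The same analyses are available from the shell; `cryptdrift reproduce`
runs all of them end to end. Output excerpt (seed 7):

```
SI: k_r/k_d=2 -> N_s=19.14 ~ 19 effective stem cells (4 effective rows)
LI: k_r/k_d=0.25 -> N_s=10.00 ~ 10 effective stem cells (2 effective rows)

SI recovery: true ratio 2 -> k_r/k_d = 1.13 (95% CI 0.932-1.34, 1000 bootstrap resamples); N_s = 15.61 ~ 16 at N_g = 5
LI recovery: true ratio 0.25 -> k_r/k_d = 0.312 (95% CI 0.258-0.372, 1000 bootstrap resamples); N_s = 10.58 ~ 11 at N_g = 5

SI clone fragmentation probability at day 7: 29.7% (192 multi-cell clones)
LI clone fragmentation probability at day 7: 16.5% (158 multi-cell clones)

SI ablation recovery, mean lowest occupied row — d1: 2.33, d2: 1.24, d4: 0.17, d7: 0.00, d15: 0.00
LI ablation recovery, mean lowest occupied row — d1: 3.60, d2: 3.28, d4: 2.75, d7: 1.98, d15: 0.50
```

The first two lines are the closed-form anchors (19 and 10 effective stem
cells). The recovery lines perform the full round trip — simulate 8-week
retention on the 2D lattice, refit the Gaussian law — and show that the LI
and LGK974 ratios are recovered well, while the SI estimate is biased low;
the effective positional diffusion of the reference lattice realization is
about half `k_r`, a documented property of this realization (see
`docs/methods.md`). The remaining lines show the qualitative contrasts the
model predicts between SI and LI: more clone fragmentation and much faster
niche regeneration where retrograde movement is strong.

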