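# Model and methods

`agroecosim` couples three compartments on an `n x n` lattice of 1-ha cells
wrapped on a torus: a stochastic soil-quality landscape, an intra-annual
pest / natural-enemy lattice dynamical system, and an annual
profit-maximising land-use decision model. The package's purpose is to
quantify conservation biocontrol — the regulation of a crop pest by a
natural enemy sustained in non-crop habitat (NCH) — as a private benefit
(profit gain `Δπ`) and a public benefit (pesticide reduction `ΔTFI`)
relative to a paired counterfactual without predation.

## Soil-quality landscapes

Each cell carries a potential yield `Q(x) ∈ [Q_min, Q_max]` (defaults 0 and
12 t/ha, a realistic range for temperate cereals). Maps are generated in
two steps:

1. **Values.** `n²` draws from a normal distribution with mode `q_bar` and
   s.d. `s_q`, truncated to `[Q_min, Q_max]` (via `scipy.stats.truncnorm`,
   inverse-CDF sampling, seed-reproducible).
2. **Arrangement.** The values are permuted in space according to the Gibbs
   measure `P(X = Q) ∝ exp(f·S(Q))`, where the fragmentation statistic is

   `S(Q) = (C/4) Σ_{x, y∈V(x)} |Q(x) − Q(y)|`

   summed over ordered four-neighbour pairs on the torus (each adjacency
   counted twice), with `C = 10`. We read the statistic's constant as
   `C/4`; since `C` only rescales `f`, this convention is what makes the
   study levels `f ∈ {−1, 0, 1}` meaningful, and it is fixed throughout.
   Positive `f` favours fragmented maps, negative `f` aggregated maps.

The Gibbs measure is sampled by Metropolis–Hastings over uniformly chosen
cell-pair swaps (which preserves the drawn multiset exactly), accepting a
swap with probability `min(1, exp(f·ΔS))`. `ΔS` is computed locally from
the two swapped cells' neighbourhoods and is tested to equal full
recomputation, including adjacent-swap and `n = 2` wrap cases. The default
chain length is `100·n²` proposals; the default lattice side is `n = 25`
(625 ha). Both are declared package choices — the dynamics are
parameterised to be robust to `n` (below), and chain-length sensitivity only
affects how sharply the arrangement approaches the Gibbs measure.

## Pest and enemy dynamics

Densities `P` (pest, in units of `Q`) and `N` (enemy, fraction of its NCH
carrying capacity) obey, in continuous time `τ` (years):

```
P' = D_P L[P] + g_P(τ, x, P) − α P N − φ(x) P
N' = D_N L[N] + g_N(x, N)     + α P N − φ(x) N
```

with the five-point periodic discrete Laplacian `L` (`dx = 1/n`). Pest
growth is zero during the first half-year (post-harvest) and logistic with
rate `r_P` and carrying capacity `Q(x)` on cultivated cells during the
second half; it is zero on NCH. The enemy dies at rate `1/γ` (default
`γ = 1/2` y) on crops and grows logistically (rate `r_N = ln 2`, capacity 1)
on NCH. Predation is Lotka–Volterra with a one-to-one conversion factor
`α`; enemy gains from predation are additive and not capped at the NCH
carrying capacity. Pesticide mortality `φ ∈ {0, ρ, 2ρ}` applies to both
species on treated crops over the whole year `[t, t+1)`; the model does not
specify a within-year treatment window, and the whole-year reading is the
simplest — alternatives would only rescale the effective `ρ` levels.

Diffusion coefficients are specified as `D = c/n²` with `c ∈ {0.1, 1}`, so
the discrete mixing rate `D/dx² = c` is independent of the lattice side;
homogeneous-landscape outcomes are verified to be insensitive to doubling
`n`.

**Integration.** Fixed-step explicit RK4 with substeps aligned exactly on
the half-year breakpoints where the growth term switches; the active growth
branch is chosen per segment, so no step straddles the discontinuity. The
step is `dt = min(0.5 / ceil(0.5·(4·max(D)/dx² + r_max)), 10⁻²)` years,
which enforces the explicit diffusion stability condition `D·dt/dx² ≤ 1/4`
and resolves the fastest reaction rate `r_max` (including `2ρ`). A fixed
step with exact event alignment is reproducible where adaptive solvers are
awkward on a discontinuous right-hand side; agreement with a tight-tolerance
adaptive oracle on a 3×3 instance is better than 10⁻⁴ in max norm, and the
single-cell logistic closed form is matched to 10⁻⁶. States are never
clipped; negativity or non-finiteness raises a diagnostic error. Cells with
`Q = 0` are zero-growth (the logistic limit), avoiding division by zero.

## Economic decisions

Every year each cell picks one of four options — NCH, untreated crop,
moderately treated crop (TFI 3, mortality `ρ`), highly treated crop (TFI 6,
mortality `2ρ`) — by maximising anticipated profit. The forecast pest
density `P~` solves the *local* growth dynamics only (no diffusion, no
predation), starting from the observed density; it has a closed form
(half-year exponential decay under `φ`, then a logistic-with-harvesting
solution). For treated options we include the mortality `−φP~` in the
forecast: the farmer controls and knows their own spraying, and without
this term treatment could never raise anticipated profit and would never be
chosen, contradicting the observed use of pesticide in the full design. A
strict mode without the term (`anticipate_pesticide=False`) is available.

Anticipated damage is `L~ = min(1, P~/Q)` (`L = 1` at `Q = 0`; the cap
covers transient diffusion overshoot above `Q`). The fertiliser dose
maximises the Mitscherlich–Baule profit and has the closed form
`ϕ* = max(0, −(1/c2)·ln(λϕ / (p·c1·c2·Q·(1−L~))))`, verified against a
brute-force grid search. Crop profit is
`p·Y − λϕ·ϕ − λφ·TFI − ν − C_{NCH→C}·1[converted]` with
`Y = Q(1 − c1·e^{−c2·ϕ})(1 − L)`; NCH returns `s_NCH` minus `C_{C→NCH}` on
conversion (conversion costs are asymmetric, `C_{C→NCH} > C_{NCH→C}`).
Ties are broken by keeping the previous option, then by lower TFI (with
NCH ordered before the crop options). Realised profit at harvest reuses the
decision-time fertiliser dose but the realised end-of-year pest density for
damage — fertiliser is not re-optimised ex post.

Reference parameter values: `p = 150` €/t, `λϕ = 1.62` €/kg, `λφ = 33` € per
TFI unit-dose, `ν = 110` €/ha/y, `s_NCH = 300` €/ha/y, `C_{C→NCH} = 219.4`,
`C_{NCH→C} = 27.4` €/ha, `c1 = 0.38`, `c2 = 0.015` ha/kg. Where a parameter
is a study axis rather than a constant (e.g. `ρ`, `α`, `r_P`), the scalar
default is the middle level (`ρ = ln 10²`, `α = 5/6`); sweeps always set
them explicitly.

## Simulation protocol and indicators

The year-0 allocation is greenfield: profit maximisation at zero pest with
no conversion costs (the model needs an initial landscape and this is the
economically consistent choice). The enemy starts at 1 on the initial NCH
cells, 0 elsewhere. Three pest-free burn-in years let land use and the
enemy distribution settle; at the end of the burn-in the pest is introduced
on **every** cell at `0.2·Q(x)` (NCH cells then act as growth sinks), so the
first post-introduction decision sees that density. The model then runs
`T = 10` further years.

Indicators average over the `T` post-introduction years and all cells:
mean profit `π` (€/ha/y) and mean TFI (unit-doses/ha/y). Biocontrol is
`Δπ = π − π₀` and `ΔTFI = TFI₀ − TFI` against the paired `α = 0` run on the
identical map and parameters (positive = benefit); pairing is enforced — a
mismatch in map or any non-predation parameter raises an error. Given the
map, the whole simulation is deterministic.

## Factorial design and analyses

The reference factorial varies `q_bar ∈ Q_max·{0.3, 0.5, 0.7}`,
`s_q ∈ Q_max·{0.05, 0.1, 0.3}`, `f ∈ {−1, 0, 1}` (27 agronomic contexts),
`c_P, c_N ∈ {0.1, 1}`, `r_P ∈ {ln 4, ln 10², ln 10⁴}`,
`α ∈ {0, 1/3, 5/6, 4/3}` (48 ecological contexts) and
`ρ ∈ {ln 4, ln 10², ln 10⁴}` — 3888 contexts, and with 8 maps per agronomic
context 31 104 runs. Map seeds derive deterministically from the master
seed and the (agronomic context, repetition) pair only, so baselines pair
exactly.

Analyses on the resulting table:

- **Marginal means** of `Δπ` and `ΔTFI` per level of each parameter,
  averaged over all other parameters, with arrows (differences against the
  lowest level).
- **Significance classification**: a run's effect is significant when
  `|Δπ|` exceeds 5% of the mean profit over all `α > 0` runs (analogously
  for TFI; the reference set is configurable). Shares per dimension, the
  positive-quadrant share among significant runs, and Pearson correlations
  on the upper (`ΔTFI > 0`) and lower (`ΔTFI < 0`) branches are reported.
- **Modal windows**: most frequent parameter values inside an outcome
  window (ties reported as sets, empty windows explicitly empty).
- **Stepwise interaction regression** of `Δπ` and `100·ΔTFI` on the eight
  parameters (natural scales, no standardisation) and all two-way products:
  forward–backward selection by F-tests on the change in residual sum of
  squares, entry p-value 0.05 and removal p-value 0.10 (the common defaults
  of this selection procedure; no hierarchy constraint). Aliased terms
  cannot improve the fit and are never selected. Note that unadjusted
  forward selection over 36 candidates retains some term on a pure-noise
  response in most realisations; what is controlled (and tested) is the
  per-term false-inclusion rate, which stays near the nominal entry level.

## Scaled-down experiment

The full 31 104-run design takes hours on one CPU. The package therefore
declares a scaled experiment used by its acceptance checks: `n = 15`, 2
maps per agronomic context, and levels `q_bar` (all 3), `s_q = 0.1·Q_max`,
`f` (all 3), `c_P ∈ {0.1, 1}`, `c_N = 0.1`, `r_P ∈ {ln 4, ln 10²}`,
`α ∈ {0, 4/3}`, `ρ ∈ {ln 4, ln 10²}` — 144 contexts, 288 runs, about three
minutes. The choice keeps all three levels of the axes whose marginal
direction is analysed (`q_bar`, `f`), spans the extremes of pest mobility
and the lower pest-growth and pesticide-efficiency range, and uses the
strongest predation level so the paired effects are informative rather than
dominated by near-zero contrasts. Because it conditions on high `α` and
drops the weak-predation levels, its *magnitudes* (mean `Δπ`, quadrant
shares, R²) are expected to exceed the full design's, and only the
qualitative structure is asserted: a majority of significant runs in the
win-win quadrant, a positive `Δπ`–`ΔTFI` correlation on the upper branch,
and marginal arrows positive in `f` and negative in `q_bar` on both
dimensions.

## What the generator does and does not emulate

The landscape model controls the value distribution and spatial
auto-correlation of potential yields but is neutral in every other respect:
no roads, field shapes, farm ownership structure, or correlated weather.
The ecological model has no stochastic demography, no within-cell
structure, no pesticide decay, and a single pest–enemy pair with
non-specific pesticide mortality. The economic model has constant prices,
a single representative crop, and purely local myopic decisions. Passing
tests therefore demonstrate the internal consistency of this stylised
feedback system and the direction of its comparative statics — not
predictions for any particular real landscape.

## Known limitations

- The Metropolis chain length trades arrangement quality for time; at
  `f = ±1` the chain is far from exhausting the Gibbs measure's tails at
  the default length, which matters only to the sharpness of the
  fragmentation contrast.
- Anticipated and realised damage use end-of-year densities; pests that
  damage cumulatively over the season are outside the damage model.
- The stepwise procedure is a selection heuristic; retained-term sets on
  noisy responses are seed-dependent near the thresholds.
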