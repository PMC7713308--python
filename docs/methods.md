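# Methods

This note documents the models, numerical choices and limitations of
`arstrack`, in the spirit of the methods documentation of packages such
as msprime or statsmodels. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## 1. Argos preprocessing

Fixes carry one of seven Argos quality classes (3, 2, 1, 0, A, B, Z).
All classes are retained, including the invalid-grade Z: quality enters
only through the measurement model's class-specific error scales.
Malformed rows (unknown class token, unparseable timestamp, coordinates
out of range) are rejected with their line numbers recorded — never
silently dropped.

Segmentation splits a tag's record wherever the interval between
consecutive received fixes *strictly exceeds* 48 h (a gap of exactly
48.0 h does not split) and removes segments with fewer than 20 fixes.
Gaps are measured between received fixes regardless of class, because
all classes are retained upstream. Duplicate timestamps are allowed
(satellite passes can double-report); the sort is stable. All
timestamps are normalised to UTC.

## 2. The switching state-space model

### Process model

Per segment, on a regular grid of `dt = 3 h` anchored at the first fix:

    x_t − x_{t−1} = γ_{b_t} (x_{t−1} − x_{t−2}) + ε_t,  ε_t ~ N(0, Σ),

a first-difference correlated random walk in lon/lat degrees with
state-specific move persistence γ and shared 2×2 process covariance Σ.
`b_t ∈ {transit, ARS}` follows a two-state Markov chain with transition
matrix A. Working in degrees rather than a projection follows standard
practice for this model family; the caveat is mild anisotropy (1° of
longitude shrinks with latitude), which is absorbed by Σ's off-diagonal
and differing diagonal entries over the mid-latitude study domain.

Identifiability: the states are label-switchable, so the constraint
γ_transit > γ_ars is enforced throughout (transit = faster, straighter
movement) and asserted over every retained draw.

Σ is shared between behavioural states (the states differ through γ);
a config switch could make it state-specific, but the default keeps the
difference in persistence only.

### Measurement model

A fix at irregular time `t_i` ties to its flanking regular states with
interpolation weight `j_i = (t_i − t_k)/dt ∈ [0, 1)`:

    y_i = (1 − j_i) x_k + j_i x_{k+1} + e_i,

with `e_i` independent Student-t per coordinate, scale and degrees of
freedom fixed per Argos class (not estimated — standard practice for
this model family). The default error table follows published Argos
calibration studies, from ~0.3 km (class 3) to ~15 km (class Z) with
heavier tails for worse classes; it is configuration, not a constant.
A fix landing exactly on the last grid time has single-state
attribution (j = 0).

### Sampler

Blocked Gibbs, all conditionals exact:

* **t-mixture weights.** Each t error is a scale mixture of normals:
  `w ~ Gamma((ν+1)/2, (ν + r²/σ²)/2)` per observation coordinate, making
  every other update conditionally Gaussian.
* **Locations.** Given (b, γ, Σ, w), each `x_t` has a Gaussian full
  conditional assembled from the (at most three) process equations and
  the observations touching it. Sites `t mod 3` are conditionally
  independent, so the update is an exact vectorised sweep over three
  colour classes. The first two states carry a weak Gaussian anchor
  (sd 3°, centred on the interpolated observations) so the boundary is
  proper.
* **States.** `b_t` has an exact two-point conditional (one process
  likelihood term plus the two chain factors); even/odd sites are
  conditionally independent. Three sweeps run per iteration — they are
  cheap and materially improve mixing of the state sequence and switch
  probabilities.
* **Persistence.** The conditional for γ_s is normal (the process
  equation is linear in γ) truncated to the ordering constraint:
  γ_transit on (γ_ars, 1), then γ_ars on (0, γ_transit), sampled by
  inverse CDF with a final clamp into the open interval (the inverse
  CDF loses precision in extreme tails).
* **Σ.** Inverse-Wishart (prior ν₀ = 4, S₀ = 10⁻⁶ I).
* **Switch probabilities.** Beta(1 + n_stay, 1 + n_switch) per row.

Hierarchical mode pools (γ, Σ, A) across all segments with per-segment
latent paths; non-hierarchical mode fits each segment separately.

### Plan and diagnostics

The full regimen is the default `McmcPlan`: 2 chains, 80,000 burn-in,
30,000 post-burn-in samples thinned by 30 → 2000 retained draws
(`retained = n_chains × floor(post/thin)` always). Tests and desk runs
use reduced plans; the plan is configuration.

Convergence: Gelman–Rubin shrink factor per scalar parameter, clipped
below at 1 — the classical estimate falls below 1 by (n−1)/n when the
between-chain variance is ~0, so identical chains report exactly 1 —
plus an initial-positive-sequence ESS and lag autocorrelations. A
shrink factor above 1.1 flags non-convergence in the report (and the
pipeline's exit status); it never aborts silently. With a single chain
the shrink factor is reported as undefined.

### Summaries

Per grid time: posterior mean lon/lat with 2.5/97.5% quantile
intervals; `mean_b`; `p_ars = mean_b − 1`; `mode_state = ARS` iff
`mean_b > 1.5` (a tie at exactly 1.5 is assigned transit). The retained
joint draws (locations and discrete states, with chain/draw indices)
feed the multiple-imputation procedure.

## 3. Occupancy and track metrics

* Great-circle distances: haversine with R = 6371 km.
* Distance per whale sums consecutive 3-h state locations *within*
  segments only; mean speed divides by the within-segment elapsed hours
  (3 h × step count). Track duration spans first to last transmission
  including gaps. A single-location series has zero distance and its
  speed flagged undefined.
* Occupancy: each state location contributes dt/24 day to its
  half-open cell `[lon₀, lon₀+c) × [lat₀, lat₀+c)` (anchored at integer
  degrees; the anchoring is a declared convention), scaled by
  `duration_w / max duration`. The grid total equals
  Σ_w weight_w × located-days_w to machine precision, and is invariant
  to cell refinement.
* Region residence counts distinct UTC calendar days with at least one
  state location inside the mask. The GSACUS preset is lat ≤ −30° and
  lon ≥ 125°E.

## 4. Seascape extraction

Nearest-cell, nearest-time-slice sampling (bilinear optional).
Variability covariates (`sst_sd`, `ssha_sd`) are the SD over the set of
cells whose centres fall in a square window of configurable area
(default 100 km²) centred on the location, implemented as a uniform
filter with the window size fixed at the domain's mean latitude;
population SD (ddof = 0), so a sub-cell window yields 0 rather than
NaN. Rasters should therefore be finer than ~0.09° for the default
window to be meaningful. Lagged covariates average the field over the
window ending at the location's timestamp: chlorophyll *a* over the
prior 30 d at the whale's cell; wind speed over the prior 7 d at a
*nominated fixed point location* (required configuration — it
represents the coastal wind driving the upwelling), not at the whale.
Transforms are applied exactly once here — log(chla), log10(ssha_sd),
log of positive depth — and recorded in the extraction metadata, so the
habitat model sees final covariates. Locations outside the raster or
with lag windows preceding the raster start become missing rows,
counted and dropped listwise before modelling.

Collinearity: pairs with |Pearson ρ| ≥ 0.8 are resolved first — within
a recognised scale/lag family the 100-km² and 30-day variants are kept;
otherwise the later-listed variable is dropped — then variables with
VIF ≥ 3 are removed one at a time (highest first). Constant columns
have undefined VIF and are dropped with a reason.

## 5. Habitat model and multiple imputation

Binomial (logit) GAM of the most probable discrete state (ARS = 1) on
cubic B-spline smooths (default basis size k = 10, penalty weight
α = 1 per smooth — α = 1 keeps the smooth Wald test near its nominal
5% size in null simulations while still regularising), fitted with
statsmodels `GLMGam`. The per-whale random intercept of the original
mixed-model formulation is implemented as fixed per-whale intercepts:
with ≤ 13 whales and thousands of rows the adjustment is equivalent,
and no penalized-GAM implementation with true random effects exists in
the scientific Python stack. Smooth significance is a Wald-type
chi-square on the spline coefficients; the reported adjusted R² is a
deviance-based analogue. A `linear=True` mode forces all terms linear
(plain penalised → ordinary logistic regression), used as an oracle
cross-check in the tests. All-ARS or all-transit responses raise a
degenerate-fit error; rank-deficient designs raise naming the columns.

Uncertainty propagation: the model is first fitted to posterior-mean
locations, then refitted `n_iter` times (default 100, half the draws
from each retained chain — the source description is ambiguous between
100 total and 100 per chain; 100 total refits is the resolution here),
each time on one joint posterior draw's locations and drawn discrete
states with covariates freshly extracted at the drawn positions. A
covariate's resilience to location uncertainty is the count of refits
with p < 0.05. Any single refit failure is logged and counted as
non-significant; the loop never aborts.

**Interpretation caveat.** Behavioural states are spatially and
temporally clustered, so *any* spatially smooth field shows inflated
significance in this procedure (pseudo-replication); the test-suite
null calibration therefore uses white (cell- and slice-independent)
fields, which is what a "pure-noise covariate" means. Significance
counts for smooth real-world fields measure resilience to location
uncertainty, not causal association.

## 6. The synthetic world

The generator emulates the observation process of the 2015 Bonney
Upwelling deployment: ~13 whales tagged January–March, fixes as a
Poisson process with mean interval 2.3 h, explicit (deterministic)
multi-day transmission gaps, an Argos class mix dominated by A/B with
6% Z, and class-specific t errors from the table above. Movement truth
is the same switching CRW as the model, with defaults γ = (0.8, 0.2),
Σ = 1.6·10⁻³ I deg² (stationary transit speed ≈ 2.5 km/h, matching the
published per-whale mean speeds of ~2–4 km/h) and stay probabilities
0.95 (mean dwell 2.5 d; recovery experiments use 0.97, ≈ 4 d, for
well-separated dwells). Observations are linear interpolations of the
true path at their times — mirroring the measurement mapping — plus
class error.

Seascape rasters are smooth Gaussian random fields with realistic
ranges (SST ~ 10–22 °C with a latitudinal gradient, log-normal
chlorophyll, negative-down depth with derived slope/rugosity/aspect);
they contain no ocean physics (no advection or upwelling dynamics). An
optional SST *link* overwrites visited cells (nearest-cell/nearest-
slice, the same convention as extraction) so true-ARS visits carry
values inside a band (default 14–17 °C) with probability 0.85 and
transit visits values outside it — a positive control for the habitat
stage that avoids complete separation. Setting the smoothing scales to
zero yields white fields for calibration nulls.

A green test on this world establishes that the pipeline recovers known
parameters and calibrates correctly under its own model assumptions; it
does not establish robustness to real-Argos pathologies the generator
omits (satellite-pass clustering of fixes, duty-cycling, location-class
drift, non-stationary behaviour).

## 7. Known limitations

* Decoding accuracy of the discrete states is bounded by the
  information in the data: with the default Argos error mix, exact
  forward–backward decoding *given the true path and parameters*
  already misclassifies ~10–15% of steps at 4-day dwells, and posterior
  decoding from noisy fixes sits a few points below that ceiling.
* The sampler is single-machine, pure numpy; full-regimen runs
  (80k + 30k iterations) on many segments take hours, not minutes.
* No continuous-time move-persistence variant; the model is the
  two-state discrete switch. No turn-angle rotation parameter (an
  extension point present in some formulations).
* Dive data, photo-identification and genetic clustering are out of
  scope; only the small ancestry threshold rule (≥ 98% pygmy → pure
  pygmy, ≤ 12% → pure Antarctic, inclusive boundaries) is implemented.
* Priors for γ (uniform with ordering), Σ and switch rows (Beta(1,1))
  are weakly informative defaults; sensitivity analysis is left to the
  user.
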