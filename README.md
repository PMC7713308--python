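# arstrack

Movement-ecology analysis of satellite-tagged whales: from raw Argos
fixes to behavioural states, occupancy maps, and behaviour–seascape
association models.

`arstrack` reimplements, as a tested and reusable Python pipeline, the
telemetry analysis used to study pygmy blue whales (*Balaenoptera
musculus brevicauda*) foraging in the Great Southern Australian Coastal
Upwelling System (GSACUS): track preprocessing, a Bayesian two-state
switching correlated-random-walk state-space model, area-restricted-
search (ARS) probability and occupancy mapping, and a binomial additive
model of behaviour against seascape covariates with multiple-imputation
propagation of location/state uncertainty. A synthetic-data module
generates Argos-like tracks from a known switching random walk, so every
stage can be validated against ground truth without any raw tag data.

It is written for movement ecologists and biologging analysts who work
with Argos platform data and want a single pipeline from delimited
location files and gridded environment rasters to behavioural maps and
habitat inference.

## The model

Raw Argos fixes arrive irregularly (on average every 2.3 h for these
tags) in seven quality classes (3, 2, 1, 0, A, B, Z). All classes are
retained; tracks are split into segments at transmission gaps exceeding
48 h, and segments with fewer than 20 fixes are discarded.

The switching state-space model estimates latent locations `x_t` on a
regular 3-h grid together with a discrete behavioural state
`b_t ∈ {1, 2}` (1 = transit, 2 = ARS):

    x_t − x_{t−1} = γ_{b_t} (x_{t−1} − x_{t−2}) + ε_t,   ε_t ~ N(0, Σ)

with state-specific move persistence γ (identifiability constraint
γ_transit > γ_ars), shared process covariance Σ, and `b_t` a two-state
Markov chain. Each fix is tied to its two flanking regular states by a
linear interpolation weight and perturbed by class-specific Student-t
measurement error. Inference is blocked Gibbs sampling (t errors as
scale mixtures of normals, exact vectorised location updates in three
interleaved colour classes); the hierarchical mode shares (γ, Σ, switch
probabilities) across whales. The probability of ARS at each time is
`p_ars = mean(b_t) − 1` over retained draws.

Downstream, occupancy is the number of days per 0.5° × 0.5° cell
weighted by deployment duration relative to the longest deployment;
habitat association is a binomial (logit) GAM of the most probable
discrete state on smooths of SST, SST variability, depth, wind speed,
SSHa, SSHa variability and lagged chlorophyll *a*, screened for
collinearity (|ρ| ≥ 0.8, VIF ≥ 3), with a per-whale intercept. Location
and state uncertainty is propagated by refitting the model on repeated
joint posterior draws and counting significant refits.

## Worked example

```python
import numpy as np
from arstrack import (SimConfig, simulate_tracks, McmcPlan, ModelSpec,
                      fit_hssm)
from arstrack.argos_io import segment_all

cfg = SimConfig(n_whales=3, n_steps=500, seed=11,
                switch_prob=np.array([[0.97, 0.03], [0.03, 0.97]]))
obs, truth = simulate_tracks(cfg)          # Argos-like fixes + ground truth
segments = segment_all(obs)                # 48-h gap split, ≥20-fix filter
plan = McmcPlan(n_chains=2, burn_in=2000, post_burn_in=3000, thin=3, seed=12)
series, draws, report = fit_hssm(segments, ModelSpec(), plan)

g = draws.gamma
print("gamma_transit mean %.3f, 95%% CI %s" % (
    g[:, 0].mean(), np.round(np.quantile(g[:, 0], [.025, .975]), 3)))
print("gamma_ars     mean %.3f, 95%% CI %s" % (
    g[:, 1].mean(), np.round(np.quantile(g[:, 1], [.025, .975]), 3)))
```

prints (truth γ = (0.8, 0.2)):

```
gamma_transit mean 0.831, 95% CI [0.785 0.876]
gamma_ars     mean 0.208, 95% CI [0.08  0.317]
```

i.e. both persistence parameters are recovered with 95% credible
intervals covering the simulation truth, and `series[0].data` then holds
the 3-h location estimates with `p_ars` and the decoded `mode_state` for
mapping or habitat modelling. The same objects feed
`arstrack.occupancy`, `arstrack.seascape.extract` and
`arstrack.habitat.imputation_significance`.

A command-line interface wraps the library:

```sh
arstrack simulate --n-whales 3 --n-steps 400 --seed 1 --out obs.csv
arstrack segment obs.csv --gap-hours 48 --min-obs 20 --out segments.csv
arstrack report --config config.yaml --seed 1
```

## Acceptance script

`scripts/acceptance.py` exercises the whole pipeline from scratch: it
simulates a tagged deployment with linked seascape rasters, runs
segmentation, the state-space model (reduced MCMC plan), metrics,
occupancy, covariate extraction, the collinearity screen, the additive
model and the imputation-significance loop, and writes its JSON output
to the path given:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

Intermediate artifacts (state series, occupancy grid, smooth curves,
manifest) land under `scratch/`.
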