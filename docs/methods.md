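# Methods

This note documents the models and procedures implemented in `dipsdm`, the
assumptions behind them, the defaults that matter, and what the synthetic
test bed does and does not establish.

## The presence–background model

We model habitat suitability as a Gibbs distribution over landscape cells:
`P(x) = exp(η(x))/Z` with `η = Σ β_j f_j(x)` and `Z` summed over a set of
background (pseudo-absence) cells. Coefficients minimize the penalized
point-process objective

    L(β) = −mean_presence η + log Z(β) + Σ_j λ_j |β_j|.

This is the standard maximum-entropy SDM formulation: the minimizer is the
distribution of maximum entropy subject to the fitted feature expectations
matching the presence sample within the slack set by the lasso penalties.

**Features.** Linear, quadratic, pairwise-product, and hinge classes.
Hinges place forward and reverse ramps at `n_hinge_knots` equally spaced
interior knots of each covariate's background range (default 10; the
desk-scale pipeline uses 4 — hinge-heavy models are insensitive to the
exact knot count because neighbouring hinges are nearly collinear and the
lasso selects among them). All features are rescaled to [0, 1] using
background bounds; prediction clamps covariates to the training range
before feature evaluation, the conventional guard against extrapolation
when projecting to future climates.

**Penalties.** `λ_j = rm · s(class, n) · sd(f_j|bg) / √n` with `n` the
presence count. The per-class scalars `s` are the sample-size-interpolated
defaults of the mainstream implementations and ship as
`data/regularization_defaults.json` so they can be inspected or overridden.
The regularization multiplier `rm` is the tuned hyperparameter.

**Optimization.** Cyclic coordinate descent. Each coordinate takes a
Newton step on the smooth part (gradient `E_P[f_j] − mean_pres f_j`,
curvature `Var_P[f_j]`), soft-thresholds against `λ_j`, and halves the step
until the exact objective does not increase, so the objective is
monotonically nonincreasing across sweeps. Convergence is declared when
the largest coefficient change in a sweep falls below `convergence_tol`
(default 1e-5) or the objective decrement stalls below 1e-10 relative; a
model that exhausts `max_iterations` is returned with `converged=False`
and a warning. With an (effectively) zero penalty a separable problem has
no finite optimum — the iteration cap exists for exactly that case, and a
strictly positive `rm` is required by construction. Features with zero
background variance are dropped before fitting.

**Output scale.** `raw` sums to 1 over the training background. `cloglog`
is `1 − exp(−e^H · raw)` with `H` the entropy of the fitted distribution, a
monotone rescaling interpretable as probability of presence; whether a
given historical analysis used cloglog or logistic output rarely matters
for threshold-based results because both are monotone in `raw`. Cloglog is
the default here, and the synthetic truth uses the same inverse-cloglog
link so that model recovery of the truth is attainable in-family.

## Background extent and pseudo-absences

Pseudo-absences are cell centres sampled uniformly from the annulus
`exclusion < d ≤ buffer` around the presences, where `d` is distance to
the nearest presence (cell-centre geometry; Euclidean on planar
landscapes, haversine on geographic ones). The 10 km exclusion prevents a
cell from contributing both a presence and a pseudo-absence. If the
annulus holds fewer cells than requested, sampling falls back to
with-replacement draws.

The buffer is tuned per species: for each buffer in an ascending grid, a
default-settings model (LQPH, rm = 1) is scored by block cross-validated
AUC against that buffer's 1000 pseudo-absences; `AUC(d) = Vm·d/(K+d)` is
fitted by least squares; and the smallest buffer whose observed AUC
reaches the fitted asymptote `Vm` is selected. A noiseless saturating
curve approaches `Vm` strictly from below, so only noise produces
crossings; when none occurs the best-AUC buffer is selected. A flat curve
degenerates to `Vm` = the common value and `K → 0`, and selection falls to
the smallest buffer. Block partitioning is used during extent tuning for
all species regardless of sample size, to keep this computationally heavy
stage uniform.

## Cross-validation, selection and gates

Species with more than 25 presences use 'block' partitioning: presences
are split at their median x, then each half at its own median y, giving
four geographic bins whose counts differ by at most one (ties broken by
index); background points inherit the same boundaries, and each fold's
models are built and evaluated with fold-local background. Species with
≤ 25 presences use leave-one-presence-out folds with the full background.

The tuning grid crosses the five feature-class menus with 19 multipliers:
the ratio-0.75 geometric progression `0.75^1..0.75^8` plus `1.0, 1.5, …,
6.0` — the only composition of the two stated sequences totalling 19.
Candidates are ranked by mean cross-validated omission rate at the lowest
presence threshold (the minimum training-presence score, with strict `<`
so training omission is exactly 0 by definition), ties broken by mean test
AUC, then by grid order. Fold metrics are aggregated by unweighted means.
The winner is refit on all presences and the full background.

The final report evaluates the refit model on all presences and background:
AUC, the maxSSS threshold (candidate thresholds are the unique pooled
scores; sensitivity counts presences ≥ τ, specificity counts background
< τ, ties resolve to the smallest τ), TSS = sens + spec − 1, and omission
at maxSSS. Gates reject a species when AUC < 0.75, TSS < 0.45 or
OR(maxSSS) > 0.25, each strict. The cross-validated omission rate of the
selected candidate is carried alongside. Which data the post-selection
gates should use is a genuinely open design point; evaluating the refit
model on its training data is the permissive convention adopted here and
flagged as such.

## Land-cover correction and change analytics

Projections are binarized at the maxSSS threshold and corrected post hoc:
cells whose land-cover class is reclassified 'unsuitable' are set to 0.
The correction is idempotent, is applied with the same static contemporary
map to every scenario of a species, and never adds area. Applying land
cover after modelling (instead of as a covariate) avoids mis-learning
species–habitat associations from occurrence records that predate recent
land-cover change.

Change classification between two corrected binary maps is the exact
partition (1,0)→loss, (1,1)→stable, (0,1)→gain, (0,0)→never. Gain assumes
full dispersal; a `no_dispersal` switch reclassifies gains as never for
sensitivity analysis. Stable cells are the species' in-situ climate
macrorefugia; stacking them across species gives a richness surface whose
overlap with the protected-area mask is tabulated per richness level, with
the protected proportion suppressed below 50 km² to avoid arbitrarily
high ratios from tiny denominators.

Elevation profiles count suitable cells in half-open 50 m bins (cells
below sea level clamp to the lowest bin) and are scaled by the species'
maximum current-scenario bin count, so the current profile peaks at
exactly 1; species profiles are averaged binwise, including all-zero
profiles of species with no suitable cells in a scenario. Areas are cell
sums: `dx·dy` on planar grids, the spherical-band formula
`R²Δλ(sin φ₂ − sin φ₁)` on geographic grids (the projection used for area
accounting in the source analyses is not stated; the spherical convention
is a documented assumption), rounded to the nearest km².

## Summary statistics

Per species: `reduced% = 100(A_noLCC − A_LCC)/A_noLCC` and loss/gain
percentages relative to the current corrected area (national and
within-PA denominators respectively); gains can exceed 100% for species
with small current ranges. Species with zero corrected current area are
flagged and excluded from aggregates. Medians and IQRs use the
linear-interpolation percentile convention (for n = 19 the median is the
10th order statistic, convention-independent). Scenario contrasts are
paired t-tests over species, two-sided by default with a one-sided option.
The packaged 19-species reference table reproduces the published aggregate
medians of all eight loss/gain columns and all four paired mean
differences exactly; its two LCC-reduction medians are known not to be
recoverable from the printed per-species values (they were evidently
computed on unrounded values upstream) and are not asserted.

## The synthetic test bed

`synthetic_data` generates what the analysis assumes and nothing more:

* **Environmental fields** are standardized smoothed white noise
  (Gaussian-filtered, σ = 6 cells), giving smooth spatially autocorrelated
  layers; a designated pair can be built with a prescribed
  cross-correlation to exercise collinearity pruning. Soil layers mix
  three latent fields plus idiosyncratic noise so a PCA is meaningful. The
  DEM is negatively correlated with the temperature-like layer (lapse-rate
  analogue). Cells default to 4 km, so a 64×64 grid spans 256 km and the
  kilometre-scale rules (10 km thinning/exclusion, 20–200 km buffers) are
  geometrically meaningful at desk scale.
* **Species truth** is inverse-cloglog of a linear/quadratic predictor on
  standardized layers, intercept calibrated by bisection to a target
  landscape prevalence (default 0.15). The default test species is a
  cool-climate specialist (quadratic optimum on the temperature-like
  layer, secondary dependence on a second climate layer and the first soil
  component) whose true-surface AUC against uniform background is ~0.92 —
  chosen to emulate the discrimination of well-performing accepted models;
  with a much weaker effect size no model, including the truth, could meet
  the recovery bar, so this is a property of the study conditions rather
  than a tunable.
* **Sampling** is presence-only with optional spatial bias and
  within-cell jitter; **land cover** grows as argmax-of-smooth-fields
  blobs with a chosen number of unsuitable classes; **protected areas**
  are smooth-field quantile blobs; **future climates** are per-layer
  shift/scale of the current layers plus independent smooth GCM noise,
  averaged per scenario (defaults: +0.8 and +1.6 landscape-s.d. warming
  for the moderate and strong scenarios, five GCMs, noise s.d. 0.1).

What passing tests show: the estimator recovers a truth inside its model
family under realistic presence-only sampling; the selection, gating,
masking, change, and aggregation arithmetic are exact; and the qualitative
upward elevation shift emerges from the mechanism rather than being coded
in. What they do not show: robustness to niche truncation, georeferencing
error, non-stationary sampling bias, model misspecification against real
climate surfaces, or any claim about real species — real-data results
additionally depend on inputs this package deliberately does not download.

## Numerical choices and degenerate inputs

* Thinning is randomized-restart greedy (delete one member of the closest
  violating pair at random; default 20 restarts, best kept), deterministic
  under seed; exhaustive enumeration confirms it attains the maximum
  retained set on small inputs.
* Collinearity pruning drops the non-protected variable with the largest
  mean |r| among currently violating pairs; a keep-list pair violating the
  threshold is an error naming the pair.
* Soil layers are standardized before PCA (units are incommensurate);
  constant layers are an error. PC loadings are reused verbatim when
  projecting other scenarios.
* Bisection for the species intercept runs 200 halvings on [−30, 30],
  giving prevalence to well below 1e-6.
* maxSSS ties resolve to the smallest threshold; omission uses strict `<`;
  presence at the threshold counts as predicted present.
* Michaelis–Menten fitting bounds `Vm ∈ (0, 1]`, falls back to the initial
  guess if the least-squares engine fails, and short-circuits flat curves.
* Desk-scale problem sizes (64×64 cells, 1000/2000 background points,
  reduced 7-value rm grid, 4 hinge knots, 10-buffer grid) are the
  package's default synthetic study conditions; every rule is
  size-agnostic and the full 199-buffer, 95-candidate, 10,000-background
  configuration is the documented default of the corresponding functions.

## Known limitations

* No reprojection between coordinate systems; inputs must be
  co-registered (land cover may be majority-resampled externally).
* The original Java MaxEnt's threshold and categorical feature classes are
  not implemented (unused by the five supported menus).
* AICc-based model selection is deliberately out of scope (omission-rate
  selection with spatial cross-validation is the implemented rule).
* Protected areas are consumed as pre-rasterized masks; no polygon I/O.
* The jackknife path refits one model per held-out presence per candidate
  and is therefore expensive for n close to 25.
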