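# Methods

This note records the models implemented by `wmfractal`, the defaults
and why they were chosen, what the synthetic data does and does not
emulate, and the numerical decisions a maintainer would want written
down.

## Subject-level pipeline

A white-matter probability volume (NIfTI, values in [0, 1]) passes
through:

1. **Isotropic resampling** (default 1.0 mm, linear interpolation).
   Box counting and thinning assume cubic cells; clinical T1 grids are
   often mildly anisotropic (e.g. 0.9 × 0.9 × 1.0 mm). Linear
   interpolation preserves the 0.5 level set better than
   nearest-neighbour; binarization happens after resampling. Whether to
   resample at all is configurable (`PipelineConfig.resample`).
2. **Thresholding** at p ≥ 0.5. The tie (p exactly 0.5) counts as WM so
   plateaus behave deterministically.
3. **Thinning** to the skeleton with Lee's 6-subiteration medial-axis
   algorithm (26-connected foreground, 6-connected background), which
   deletes simple boundary voxels in a deterministic direction order and
   therefore preserves the number of 26-connected components and the
   Euler number while leaving no solid 2×2×2 block. One boundary case is
   handled on top of the library routine: a topologically trivial
   component (a large solid ball erodes to nothing under simple-point
   deletion) is restored as its single deepest voxel — the
   distance-transform argmax, which is the correct zero-length skeleton
   and keeps component counts invariant.
4. **Surface extraction**: WM voxels with a background (or out-of-grid)
   face-neighbour. Face adjacency (6-connectivity) is the strictest
   boundary definition and the default; 18 and 26 are available.
5. **Hemisphere split**: the left–right axis is read from the affine
   (the voxel axis with the largest world-x component); the split plane
   is the sagittal plane with minimal foreground intersection within the
   central 20% of that axis (avoiding degenerate edge planes), ties
   resolved toward the centre. The whole-brain skeleton/surface/general
   sets are computed first and then masked per hemisphere — a hemisphere
   skeleton is a restriction, not a re-thinning, so voxels never move
   when the split changes.

## Box counting and the FD regression

`N(r)` is the number of occupied cells of an `r × r × r` lattice; the
dimension is minus the OLS slope of `log N` on `log r` over a selected
window. Implementation is an exact block reduction (pad to a multiple of
r, reshape, any()); a brute-force cell scan serves as the test oracle.

**Scale ladder.** The default ("auto") ladder is a *divisor chain* of
the largest grid dimension: scales that each divide the next, with the
largest equal to the dimension itself (27 → 1, 3, 9, 27; 64 → powers of
two). Two properties motivated this over the more common
powers-of-two-with-padding ladder:

* aligned lattices eliminate partial boxes at the grid boundary, the
  dominant small-grid bias — on the level-3 Menger sponge the chain
  ladder recovers FD = 2.7268 exactly, while a powers-of-two ladder on
  the same 27³ grid is biased to ≈ 2.49;
* nested lattices make `N(r)` provably non-increasing in `r` (with
  arbitrary ladders box counts can locally increase; 1-D
  counterexample: voxels {2, 3} give N(2) = 1 < N(3) = 2).

Dimensions with fewer than four chain divisors (primes) fall back to
powers of two up to the dimension.

**Offset averaging** (`n_offsets`): counts can optionally be averaged
over deterministic diagonal lattice offsets. The default is the single
zero offset — bit-reproducible, and empirically less biased on aligned
phantoms than offset means.

**Window selection** (`select_scaling_range`): among contiguous windows
of at least `min_points` scales (default 4), the one maximizing R² wins;
ties go to the wider window, then the smaller minimum scale. A floor of
R² ≥ 0.98 rejects degenerate, non-power-law inputs instead of reporting
a meaningless slope. Both knobs are configurable and echoed into output
(QC columns carry the fitted window and R² per measure) so results are
auditable.

A perfectly flat curve (all counts equal) is reported with R² = 1 and
FD = 0 — the correct dimension of a point-like set. Fitted dimensions
outside [0, 3.1] raise rather than clamp.

**Finite-size behaviour of smooth sets.** A digitized ball shows two
asymptotic regimes: fine scales track the digitized volume and coarse
scales saturate to the embedding dimension, with O(r/R) surface
corrections in between. At desk-scale grids (≤128³) no ≥4-point window
is free of those corrections (best ≈ 2.88 for the volume of a 128³
ball); with `min_points=3` the selector finds the exactly saturated
coarse window and reports 3.0. Tests on smooth phantoms therefore use
the 3-point minimum; fractal phantoms are unaffected.

## Cohort statistics

Each of the nine FD outcomes is modelled as

    FD_ij = β0 + β_age · age_ij + γ_{group(i)} + b_{gender(i)} + ε_ij,
    b_g ~ N(0, σ_g²),  ε ~ N(0, σ²)

fitted by REML (`statsmodels` MixedLM). Group contrasts are tested two
ways: a marginal F-test on the group coefficients with `n − p`
denominator degrees of freedom, and all-pairs Tukey HSD on the
model-adjusted group means (evaluated at the covariate grand means)
using the studentized-range distribution with the same residual df.
A sensitivity variant adds ALSFRS-R as a fixed covariate on the patient
subset.

Numerical decisions:

* At the FD scale (responses ≈ 2.5, SDs ≈ 0.02) the REML objective is
  badly conditioned and optimizers can hit singular matrices. Models are
  fitted on an internally standardized response and covariates and the
  coefficients transformed back — an exactly scale-equivariant
  reparameterization, verified against OLS at the variance boundary.
* A two-level gender random effect routinely lands on the zero-variance
  boundary. Boundary fits are reported, not treated as errors; if every
  optimizer fails outright the boundary (OLS) solution is used and
  flagged (`converged=False`).
* Outlier screening uses the fixed-effects design: externally
  studentized residual > 3 or leverage > 3p/n, remove-and-refit once.
  On clean simulated cohorts the false-flag rate is below 1% of
  subjects.

Spearman correlations between each FD outcome and a clinical measure
are computed complete-case with Benjamini–Hochberg FDR flags across the
nine outcome tests (per clinical measure). Kruskal–Wallis compares FD
across El Escorial strata (diagnostic certainty 1–4) with
Bonferroni-corrected pairwise Mann–Whitney tests. Disease progression
rate is (48 − ALSFRS-R) / duration in months — functional decline from
the full score per month — and duration and rate are natural-log
transformed before use as approximately normal covariates.

## Synthetic data: what it emulates, what it does not

**Phantoms** provide exact ground truth for the estimator: the Menger
sponge (dimension log 20 / log 3), fractal percolation with subdivision
2 and retention p (dimension 3 + log₂ p, generated conditional on
survival with retries logged), solid blocks/planes/lines (3/2/1), tori
(for topology checks) and a branching-tube "WM tree" with left/right
asymmetry for end-to-end plumbing. The probability-map wrapper places
foreground near 0.9 and background near 0.1 with bounded smoothed noise,
so thresholding at 0.5 recovers ≥ 99% of the phantom by construction.

**Cohorts** are drawn from the generating model the mixed model assumes:
per-group FD means and SDs for all nine outcomes, group-dependent age
distributions, per-group gender imbalance, a shared linear age effect
(default −0.0005 FD/yr, the magnitude used throughout the simulation
examples), a cohort-level gender intercept (default SD 0.005, a quarter
of the typical within-group FD SD), log-normal disease duration matched
to group medians and quartiles, per-group El Escorial proportions, and
an ALSFRS-R score coupled to whole-brain skeleton FD through a Gaussian
copula targeting a rank correlation (default 0.431) with the
Spearman-to-Pearson conversion 2·sin(πρ/6). Reference parameter values
live in `wmfractal/constants.py` (version 1).

Two properties of the generator worth knowing:

* the gender intercept is one draw per cohort, so realized group means
  carry a random O(σ_g) offset that does not average out with n — mean
  recovery is therefore checked with that component disabled;
* clipping ALSFRS-R to [0, 48] creates ties at the ceiling for
  high-scoring groups and mildly attenuates the realized rank coupling.

What passing tests on this data do **not** show: robustness to
segmentation error, partial-volume effects, bias fields, registration
error, or real anatomical variability. The phantoms are geometrically
clean; clinical WM maps are not. Conclusions about real cohorts require
real images.

## Simulation sizes

The shipped tests and the acceptance script use: 50-seed phantom suites
for the thinning contract and box-count oracle; 30 seeds per retention
value (0.6, 0.8) at 64³ for fractal percolation; 500 replicate cohorts
(n = 97, five groups) for type-I error, family-wise error and age-slope
recovery; 200 replicate two-group cohorts (n = 20/20) for power. These
sizes put Monte-Carlo error well inside each check's tolerance while
keeping a full run at about a minute on one CPU.

The power simulation generates its two groups from the whole-brain
skeleton FD parameters (2.469 ± 0.020 vs 2.501 ± 0.024) with a common
age distribution (57.9 ± 12.7) and gender mix: the quantity of interest
is the detectability of that FD separation at n = 20/20 under the
fitted model, not the additional (and separately simulated) age–group
confounding of the calibration suite, which uses the full group-specific
demographics.

## Known limitations

* The hemisphere split is a single sagittal plane; anatomically curved
  midlines (falx crossings) are not modelled.
* The skeleton restored for fully-eroded components is a point, which
  under-represents the medial surface of plate-like components.
* Tukey p-values use the residual-df approximation rather than
  Satterthwaite/Kenward–Roger corrections; with a two-level random
  effect near the boundary this is close to exact and simulation-checked
  (FWER ≤ 0.06 at nominal 0.05).
* `select_scaling_range` maximizes R², which on smooth (non-fractal)
  sets legitimately locks onto saturated regimes; the reported window
  and R² should always be inspected alongside the FD value.
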