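# Methods

This note documents the models and procedures irakit implements, the
choices made where the methodology left room, and what the synthetic
scenarios do and do not establish.

## Data model and preprocessing

The universal exchange type is an annual table: strictly consecutive
calendar years by named variables, no gaps (inputs with missing cells
are rejected rather than imputed — the intended application series are
complete, and silent imputation would contaminate the shift detectors).
LPUC (landings per unit of capacity) divides each taxon's summed annual
landings (kg) by the fleets' summed gross tonnage (GT); GT is the
capacity surrogate because engine-power declarations are unreliable in
the fisheries this targets. Anomaly standardization uses the sample
standard deviation (n − 1); the choice affects the fourth decimal of
anomalies at these series lengths.

Redundant stressor variables are screened by empirical distance
correlation (double-centered pairwise-distance matrices; dCor =
dCov/√(dVarₓ·dVar_y)), a dependence measure that also catches non-linear
duplication. The screen is a greedy pass in column order with a default
cut-off of 0.9; both are configurable because no canonical value exists
— the retained set is ordinarily data-given and should be reviewed, not
automated away.

Traffic-light matrices bin each variable's raw values by its own
empirical 20/40/60/80 percentiles (linear interpolation), ties going to
the lowest admissible quintile, rows ordered by PC1 loading.

## Ordination

PCA is an eigendecomposition of the covariance — by default the
correlation — matrix of column-centered data. Correlation PCA is the
default because the blocks mix units (kg/GT against °C, psu, pH);
covariance PCA of such a table would let the largest-variance unit
dominate. Explained fractions are eigenvalue/trace over all components.
Because eigenvector signs are arbitrary, components are oriented so the
largest-magnitude loading is positive (ties broken by variable-name
order); every downstream threshold and landscape coordinate is thereby
reproducible.

## Shift detectors

**CONISS.** Agglomerative clustering restricted to temporally adjacent
merges; the merge cost is the Ward increment nᵢnⱼ/(nᵢ+nⱼ)·‖x̄ᵢ−x̄ⱼ‖².
The pipeline standardizes rows first. Cutting the tree into k blocks
splits recursively from the root, always splitting the component whose
root merge is most expensive; with monotone heights this equals undoing
the k − 1 most expensive merges, and it remains well defined when
CONISS increments are non-monotone. k defaults to 2 and is a user
decision (in practice read off the dendrogram), so the validation
studies pass the true regime count.

**Breakpoints.** Dynamic programming minimizes the total RSS of
constant-mean segments subject to a minimum segment length of
floor(0.15·n) years (15% trimming, the conventional default). The
number of breaks m minimizes BIC(m) = n·log(RSS_m/n) + (2m+1)·log n —
2m + 1 parameters: m boundaries, m + 1 means, variance profiled out.
RSS is floored at 10⁻¹²·TSS so exact piecewise-constant fits do not
send the log to −∞; ties then resolve to the smallest m. Confidence
intervals per breakpoint collect the years whose boundary shift (others
fixed) raises RSS by less than the χ²₁ 95% increment at σ̂² = RSS/n. The
sup-F statistic max_t (RSS₀−RSS_t)/(RSS_t/(n−2)) is tested by
permutation (series shuffled, default 199 draws) rather than by
asymptotic response-surface approximations: exact under exchangeability,
at the price of a granular p-value.

**STARS.** The base sequential-t-test algorithm: regime-scale variance
σ²_L averages the sample variance of all consecutive L-year windows;
the critical difference is t_crit(p, 2L−2)·√(2σ²_L/L); a year beyond
the current regime mean ± diff opens a confirmation window of up to L
years in which normalized exceedances are accumulated — any
non-positive running sum rejects the candidate, otherwise the shift is
accepted and its RSI is the final sum divided by L·σ_L. Two stated
choices: candidate-window values never update the old regime's mean,
and the current regime's mean is recomputed over *all* its years as the
regime grows (no L-year cap). Outlier down-weighting and red-noise
prewhitening variants are out of scope. Defaults L = 15, p = 0.05. All
detectors report threshold years as the last year of the old regime;
STARS's native shift year (first year of the new regime) is also kept.

## GAM and threshold GAM

The smooth is a penalized cubic B-spline (P-spline): uniform knots over
the training x-range, second-difference coefficient penalty, smoothing
parameter chosen by minimizing GCV = n·RSS/(n − edf)² over a fixed
49-point log-spaced grid (10⁻⁷..10⁹), with near-ties resolved toward
the smoother fit. Uniform (rather than quantile) knots make the penalty
null space exactly the linear functions, so noise-free linear data is
reproduced with edf → 2. The basis dimension defaults to 5 per smooth:
with ~52 years split into branches, anything larger saturates. The
generalized-eigenvalue factorization makes the whole λ-sweep a single
matrix product, which matters because the cross-validation below refits
the smooth ~10⁵ times. Predictions beyond the training range continue
linearly with the boundary slope — cubic polynomial extrapolation is
unstable in leave-one-out folds, and the linear rule matches the
attractor-extension convention below. A zero-span x (possible in
degenerate branches) falls back to the mean model with edf 1.

A TGAM splits the years at a threshold year θ into two fully
independent branches (separate intercepts and smooths — the two
response curves share nothing). Candidate thresholds are 50 evenly
spaced whole years between the 0.2 and 0.8 quantiles of the year range
(de-duplicated after rounding); θ minimizes the combined
GCV = n·(RSS₁+RSS₂)/(n − edf₁ − edf₂)², ties to the earliest year.

Model classes are compared by the genuine cross-validatory squared
prediction error (gCV): for each held-out year the *entire* procedure —
threshold search and smoothing selection included — is refit on the
remaining years and the held-out response predicted by the branch its
year side implies. This charges the TGAM for estimating the threshold,
not only the smooths. A cheaper fixed-θ variant exists but is never the
default. Folds whose refit fails fall back to the global fit and are
flagged. The comparison runs at stressor lags 0–2.

Sequential detection is two-stage, as the single-threshold TGAM cannot
see a second shift: stage 1 keeps the full-series TGAM only if its gCV
beats the GAM's; stage 2 repeats the contest on the window from the
year after the first threshold to the penultimate year. The final year
is excluded by default because a trailing year may belong to a state
not yet established (configurable); the same year is excluded from
regime assignment in the resilience stage but still exported.

## Resilience and the stability landscape

The branches of the accepted TGAM stages are the attractors: regime 1
from stage 1's first branch, regimes 2 and 3 from stage 2's branches,
each evaluated densely over its regime's observed stressor range and
extended linearly with the end slopes (the extensions are a geometric
convention, not a fitted claim). Tipping points bound each regime on
the side(s) facing its neighbors — the middle regime of a three-regime
system on both sides, so three regimes carry four points F1..F4. For a
side toward increasing stressor the coordinate is max over the regime's
years of (x_y + vComp_y) (mirrored with min/− for decreasing): the
smallest value guaranteeing every year's Res_y = hComp_y − vComp_y ≥ 0,
with equality for the binding year. hComp uses the nearest of the
regime's tipping points; vComp the vertical distance to the attractor
(or its extension). Res is normalized by its observed maximum; the x
and y axes are both PC1 scores, i.e. already commensurate, so no
re-scaling enters the sum.

One theoretical repulsion "year" per fold pair — at the midpoint
stressor coordinate of the pair, midway between the two attractors,
its resilience computed by the same rule with the nearer tipping point
and nearer attractor — prevents the interpolation from drawing
spurious high-resilience corridors between basins. The landscape is
piecewise-linear (Delaunay) interpolation of rRes onto a 100 × 100
grid over the point set's bounding box; cells outside the convex hull
are missing, and the surface reproduces the input values exactly at
the input points. A caveat: when a fold is *vertical* (the adjacent
regimes share their stressor range, as in the bundled scenario's
second fold), the fold pair's tipping points sit at opposite extremes
and the midpoint rule places the repulsion state mid-basin; its
resilience is then low relative to the surrounding basin altitude but
not necessarily below the binding years' zero.

## Synthetic scenarios

The generator draws a latent stressor (trend + step changes + Gaussian
noise), maps it through regime-specific branch functions switching at
known threshold years to a latent system score (plus Gaussian noise),
and observes each variable as loading × latent + idiosyncratic Gaussian
noise. Noise is i.i.d. Gaussian throughout — the simplest testable
choice; real series carry autocorrelation and heavier tails, so the
recovery rates below are upper bounds on real-data performance, and
passing tests establish correctness of the machinery, not field
validity.

The bundled discontinuous scenario spans 1966–2017 with 12 + 12
variables, threshold years 1991 and 2002, and a stressor staircase
(+0.8 after 1975, +1.2 after 1988, +1.0 after 1999, −1.0 after 2008).
Three constraints shaped it, all consequences of making every stated
recovery property hold simultaneously:

- *Step-dominated forcing, flat outer branches.* Any deterministic
  within-regime drift (trend × branch slope) breaks exact noise-free
  recovery: with zero noise the BIC's n·log(RSS) term diverges and the
  segment-mean DP always splits structured drift. Hence no trend term,
  and only the middle branch is sloped (+0.5 per stressor unit) — its
  two stressor-level blocks are shorter than the 15% minimum segment
  length, which is exactly what keeps the DP from splitting them.
- *Hysteresis at both folds.* The first regime's late years share the
  second regime's stressor level, and the third regime revisits both of
  the second regime's levels. Without such overlap a threshold in the
  year domain is not identifiable from the (x, y) relation: any split
  severing only non-overlapping levels is costless and the estimated
  threshold wanders. The overlap is also what makes the system–stressor
  relation genuinely non-functional, i.e. discontinuous.
- *A linear null.* The continuous counterpart keeps the observation
  model but responds through a single linear branch, with forcing steps
  bracketing the threshold-candidate window so that every candidate
  split severs the long middle stressor level. A linear truth keeps the
  single smooth unbiased at every smoothing level, so the gCV contest
  isolates the threshold model's extra variance; curved truths let the
  two branches reduce local smoothing bias and genuinely tighten the
  contest.

Validation at the study conditions (100 seeds, latent and idiosyncratic
noise 0.3, tolerance ±1 year, both true thresholds required): CONISS
99/100, breakpoints 100/100, STARS 100/100, sequential TGAM 93/100;
gCV prefers the TGAM on the discontinuous scenario in 99/100 runs and
the GAM on the continuous scenario in 91/100. The last figure sits near
the intrinsic null power of the comparison at n = 52: on single-smooth
data the two models' leave-one-out errors differ only through the
threshold model's excess variance, a signal of the same order as its
sampling noise. In the noise-free limit all four detectors recover
{1991, 2002} exactly.

## Numerical conventions

Threshold years everywhere mean the last year of the old regime. Exact
GCV ties prefer smoother fits (within smooths) and earlier years
(within threshold searches). The breakpoint RSS floor is 10⁻¹²·TSS.
Spline boundary knots are pinned to the exact data extremes against
rounding. CSV readers parse floats round-trip-exactly so that writers
mirror readers bit for bit. All randomness flows from explicit integer
seeds; pipeline reruns with the same config and seed are byte-identical.

## Known limitations

Gaussian-identity responses only; at most two sequential thresholds; no
red-noise or outlier-robust STARS variants; no heteroskedasticity-robust
breakpoint inference; the permutation sup-F assumes exchangeability,
which autocorrelated residuals violate; repulsion-state placement
degrades to mid-basin for vertical folds (above); and the synthetic
scenarios' i.i.d. noise understates the difficulty of real series.
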