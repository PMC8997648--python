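# Methods

This note documents the models, defaults and design choices behind
`ferment-screen`, and what the synthetic test surface does and does not
establish about real fermentations.

## Screening design

The default design is a regular 3^(7−2) fractional factorial (243 runs)
over the seven formulation factors. Five basic columns form a full
3-level factorial; the last two are GF(3) linear combinations of basic
columns,

    x6 = (x1 + x2 + x3) mod 3
    x7 = (x1 + 2·x2 + x4) mod 3

applied on {0,1,2} codes and shifted to {−1,0,+1}. These generators are
fixed and recorded in the design metadata so the confounding pattern is
reproducible. Every column is balanced (81 runs per level) and the
generated columns are orthogonal to the basic ones. Because the
interaction predictors are *products* of the −1/0/+1 codes rather than
GF(3) sums, the full 36-column second-order model matrix on this
fraction happens to be full rank, so all 21 two-way interactions are
estimable (with reduced efficiency); the fitting code nevertheless
detects rank deficiency on arbitrary designs and proceeds on a maximal
independent column subset, reporting the dropped (aliased) columns.

Run order is shuffled by a seed (default 20220325) and labels S1…S243
are assigned after shuffling; the *set* of runs is seed-independent.
Coding is piecewise linear through the three anchors, so decode(−1/0/+1)
reproduces the physical level table exactly even if a midpoint is
off-centre, and encode is its exact inverse.

## Growth model

The secondary model follows the gamma concept: μ = μ_ref · ∏ γᵢ, each
γᵢ ∈ [0,1], equal to 1 at that factor's optimum and 0 at/beyond its
cardinal limit, multiplied without an interaction correction (no Le Marc
ξ term): the screening layer, not the fine structure of the
growth/no-growth boundary, is the object of study here, and the
simulator is exercised mostly inside the growth region.

| term | form | defaults |
|---|---|---|
| temperature | ((T − T_min)/(T_opt − T_min))², suboptimal branch | T_min = 2 °C, T_opt = 28 °C |
| pH | (pH−pH_min)(pH_max−pH) / ((pH_opt−pH_min)(pH_max−pH_opt)) | 3.4 / 6.3 / 9.2 |
| NaCl | linear in a_w between a_w,min and a_w,opt; a_w from %WPS via the quadratic brine relation 1 − 5.2471·10⁻³·W − 1.2206·10⁻⁴·W² | a_w,min = 0.928, a_w,opt = 0.997 |
| smoke | (1 − P/MIC)^n | MIC = 55 ppm phenol, n = 2 |
| CO₂ | 1 − C/C_max | C_max = 120 % equilibrium headspace |
| nitrite | 1 − N/MIC | MIC = 600 ppm |

with μ_ref = 0.7 h⁻¹ at the joint optimum. These values are a
*calibration by qualitative anchors*, not a fit to any strain or
software: they were chosen once so that (i) growth occurs across the
whole 10–25 °C screening range, (ii) liquid smoke is the strongest
single inhibitor, followed by temperature and then salt, with pH, CO₂
and nitrite minor over their screening ranges, and (iii) complete
suppression of growth occurs only where low temperature combines with
near-MIC smoke (at 10 °C the no-growth region starts near 34 ppm with
the other factors at their centre levels). All parameters live in a
plain dataclass serialisable to JSON and can be replaced wholesale.

The primary model is a logistic in cell numbers with a discrete lag:

    N(t) = N_max / (1 + ((N_max − N₀)/N₀) · e^(−μ·max(t−lag, 0)))

run from N₀ = 10⁵ to N_max = 10⁹ CFU/g (5 → 9 log). The lag comes from
the relative lag time via lag = RLT·ln2/μ — RLT counted as doublings of
adaptation work — isolated in one function (`lag_from_rlt`) so the
convention can be swapped. A Baranyi-type primary model would shift the
shoulder shape slightly but not the threshold-crossing times at the
tolerances used here (one time step). pH is constant within a run; no
acidification dynamics, microbial competition, or spoilage-metabolite
formation is modelled.

## Responses and censoring

t_crit is the first time the simulated curve reaches 8.9 log CFU/g,
linearly interpolated between grid points (curves are smooth at the
default Δt = 0.5 h; the interpolation error is far below one step). The
default horizon is 2000 h; runs that never cross within the horizon —
either μ = 0 or too slow — are flagged no-growth and their t_crit is
censored (NaN). Censored runs are excluded from the t_crit regression
and their count is reported; μ_max is defined (possibly 0) for every
run and uses all 243 observations. Under the defaults 29 of 243 runs
are censored, all in the cold/high-smoke corner.

## Regression and elimination

Fits are ordinary least squares on the **coded** predictors, the
standard scale for standardized-effect reporting, with classical
standard errors and two-sided t tests on the residual degrees of
freedom. Adjusted R² uses the usual small-sample correction and is
floored at 0 (a model no better than the mean reports 0). Two-way
interactions are included by default — they carry real signal here (the
temperature-by-smoke interaction is among the largest effects) — with a
flag to drop them.

Backward elimination removes, one at a time with a refit after each
removal, the removable term with the largest p-value above α = 0.05,
under *weak heredity*: a linear term cannot leave while its quadratic or
any interaction involving its factor is retained. The procedure is
deterministic and idempotent. Two calibration facts, both verified by
simulation in the test suite: a truly inactive quadratic or interaction
term survives elimination ≈5 % of the time, matching α; but the
*overall* retained fraction under a pure-noise response is ≈11 %, not
5 %, because heredity keeps insignificant linear parents alongside
whichever higher-order false positives survive. Exact interpolation
(zero residual variance) leaves the t tests undefined; p-values are then
reported as NaN and such terms are treated as removable.

## Desirability

Individual desirability is the two-sided-clipped linear ramp between
y_unfav (d = 0) and y_fav (d = 1); one formula serves both orientations
through the sign of y_fav − y_unfav. Default anchors are the min/max of
the *fitted model's predictions over the design points*, not of the raw
simulated responses, so censored runs cannot distort the scale. Profiles
sweep one factor over the coded range with the others held at the centre
(coded 0) by default — the usual one-factor-at-a-time profiler reading —
and both the held values and the anchors are overridable. An overall
desirability (geometric mean, with any zero component vetoing) is
provided for combining responses.

## Synthetic ground truth

`synthetic` generates (a) response tables y = quadratic(codes) + N(0,σ²)
with arbitrary known coefficients, (b) a "study-like" sparse truth whose
signs and ranking (dominant negative smoke, positive temperature,
negative salt, a temperature-by-smoke interaction) match the qualitative
outcome of the simulation pipeline — magnitudes are free fixture
choices — and (c) delayed-logistic growth curves whose threshold
crossings are known in closed form. Everything is seeded and exactly
reproducible.

What passing tests show: the design algebra, the least-squares engine
(cross-checked against an independent normal-equations solver), interval
coverage and elimination type-I behaviour under the Gaussian error model,
and the internal consistency of simulator, extraction and regression.
What they do not show: that the growth-model defaults describe any
particular strain or product — real validation requires challenge tests;
the synthetic noise is homoscedastic Gaussian, whereas deterministic-
simulator residuals are structured lack-of-fit; and the desirability
anchors are model-range conventions, not sensory or regulatory limits.

## Problem sizes

The statistical calibration checks use 500 replicates of the 243-run
design for interval coverage and null-term retention, 120 replicates for
the pure-noise retention rate, 50 random small designs for the
least-squares oracle, and 100 kinetic parameter draws for crossing-time
accuracy; the full simulation pipeline runs all 243 conditions at
Δt = 0.5 h over 2000 h. The complete suite runs in well under a minute
on one CPU.
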