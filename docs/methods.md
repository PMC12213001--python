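# Methods

## Trajectory model

A trajectory is an ordered sequence of planar vertices `(x_i, y_i)` in
metres with strictly increasing timestamps `t_i` in seconds.  Field traces
digitized at constant spatial resolution usually lack native timestamps; in
that case a uniform frame interval `τ` (default 1 s per vertex) is
assigned, which makes the directional-change rate proportional to the
turning angle per vertex.  Coordinates are treated as planar metric
throughout — the paths of interest span tens of metres, where geodesic
effects are irrelevant.

Duplicate consecutive vertices (zero-length steps, a common digitization
artefact) are removed before any analysis because the turning angle is
undefined at zero displacement; the number dropped is recorded in the
trajectory metadata.  Turning angles are signed and computed as
`atan2(cross, dot)` of consecutive displacement vectors, which is stable
near 0 and π; the value −π is mapped to +π so angles lie in (−π, π].

### Rediscretization

`rediscretize(path, R)` resamples a polyline at constant arc-length spacing
`R`, interpolating coordinates and timestamps linearly in arc length and
discarding (never extrapolating) the terminal remainder shorter than `R`.
Consequences: the resampled length never exceeds the input length and
differs from it by less than `R`; when input segment lengths are
commensurate with `R` (the natural situation for paths digitized at the
same resolution), sample points land exactly on the polyline's corners and
every output chord has length exactly `R`.  An alternative convention steps
by chord length (circle–polyline intersection); it was not used because it
cuts corners, so the resampled length can drift from the measured path
length by more than `R` on tortuous paths.

## Movement indices

Six statistics summarize each path.  `L`, `D`, `TS = D/L`, `DC` and `SDDC`
are computed on the cleaned input path; `S2` and `TE` on the path
rediscretized at the digitization resolution `R` (default 0.05 m), because
both are functionals of the turning-angle distribution of a *constant-step*
walk and must not conflate step-length variation with turning behaviour.
`L` and `D` are never computed on resampled paths, which would shorten
them.

* `S2 = 2·[p((1+c)/(1−c) + b²)]^(−1/2)` (rad·m^(−1/2)), with `p` the mean
  step length, `b` the CV of step length (0 after rediscretization) and `c`
  the mean cosine of turning angles.
* `TE = c/(1−c)`, dimensionless and scale-free, monotone in `c`.
* `DC_i = |θ_i| (degrees) / (t_{i+1} − t_i)` at each interior vertex; `DC`
  is the mean and `SDDC` the sample (ddof = 1) standard deviation.  The
  "angular change between two points over their time difference" is
  implemented with the consecutive-step convention — the angle between
  successive displacement vectors over the forward time difference — the
  standard definition of this index; an all-pairs variant would be
  quadratic in path length and measure something else.

Degenerate cases are flagged rather than silently capped: a perfectly
straight path (`c → 1`) reports `S2 = 0` (the formula's limit) with a
limit-case flag and `TE = ∞` with an infinity flag, preserving the
interpretation that larger `TE` means straighter.  `SDDC` is flagged
missing when only one directional-change sample exists.  Mildly negative
`c` (anti-persistent walks) would give small negative `TE`; the value is
floored at 0, the index's sinuous extreme.

Dimensional behaviour, used as test invariants: scaling coordinates by
`k > 0` leaves `TS` and `TE` unchanged, scales `L` and `D` by `k`, and
scales `S2` by `k^(−1/2)`.

## Group comparisons

One-way fixed-effects ANOVA with the classical decomposition
`SS_total = SS_between + SS_within` and `F = MS_between/MS_within`;
p-values from the F distribution.  Pairwise location contrasts use the
Tukey–Kramer studentized-range statistic
`q = |m_i − m_j| / sqrt(MS_w (1/n_i + 1/n_j)/2)` with adjusted p-values
from the studentized-range distribution with `(k, n − k)` parameters.  The
compact letter display uses the insert-and-absorb algorithm: each group
joins every existing letter set it is compatible with, otherwise opens a
new set seeded with all earlier compatible groups; sets contained in others
are then absorbed.  The result is deterministic given the sorted group
order, and groups share a letter exactly when their adjusted p ≥ α.

Comparisons are run both by location (4 groups) and by mobility phenotype
(residents vs dispersers, 2 groups).  Sexes are pooled by default (sex
enters the GLMs instead); missing values are deleted listwise per variable,
since the assay sample sizes differ (48 tracked / 152 measured / 56
enzyme-assayed).

The collinearity screen computes pairwise Pearson correlations on complete
cases and iteratively removes the variable with the largest mean |r| among
pairs exceeding the threshold (default |r| > 0.7, a common collinearity
rule; the threshold is configurable because no single value is canonical)
until no pair exceeds it, with ties broken by variable name.  Note an
inherent property of any such screen: an isolated cluster of
inter-correlated variables retains exactly one representative — it cannot
vanish entirely.  With the default generator the four body-size proxies
(INTOC, PRONOL, PRONOW, ELYT) collapse to one representative and the
functionally distinct covariates (STER, FEMU, PGI, PYRU) always survive.

## GLM layer

Each movement index is regressed on location (LOC), sex (SEX), sternite
and femur lengths (STER, FEMU) and enzyme activities in milliunit/ml (PGI,
PYRU), plus the interactions LOC:SEX, SEX:FEMU, SEX:STER, LOC:FEMU,
LOC:STER, LOC:PGI, LOC:PYRU.  Families: Gaussian/identity for every index
except `TE`, which uses Poisson/log.  `TE` is continuous, so the Poisson
deviance and IRLS are applied in their quasi-likelihood form to the
non-negative real response, and the log-likelihood (hence AIC) uses the
continuous factorial extension `Γ(y+1)`; this reproduces the intended
family without discretizing the response.

Categorical terms use sum-to-zero contrasts — a prerequisite for
interpretable type-3 tests.  Fitting is by IRLS (deviance-converged,
relative tolerance 1e−8, ≤ 100 iterations) via statsmodels; the
Gaussian/identity case is exact ordinary least squares.  Rank-deficient
designs raise an error naming the aliased terms.

**AIC convention.**  `AIC = −2·loglik + 2·p`, with the Gaussian
log-likelihood in profile (ML) form `−n/2·(log(2π·deviance/n) + 1)` and the
error variance counted in `p`.  This matches R's `AIC()`/`step()`
convention (verified against R in the test suite) rather than the
statsmodels GLM attribute, which omits the scale parameter and uses a
non-ML scale estimate.

**Backward selection** repeatedly deletes the single droppable term whose
removal most decreases AIC and stops when no deletion decreases it.  By
default marginality is enforced — a main effect becomes droppable only when
it no longer appears in any retained interaction.  Published stepwise
tables sometimes retain an interaction without its main effect, so a
compatibility switch (`enforce_marginality=False`, CLI `--no-marginality`)
allows the freer deletions.  Ties (ΔAIC within 1e−8) keep the term — the
larger model wins — and candidate ties break by term name, making the
search deterministic.

**Type-3 tests** compare the final model with and without each term's
design columns, all other columns retained.  Gaussian models use an F test
on the deviance difference; Poisson models a likelihood-ratio chi-square.
Significance bands: `***` < 0.001, `**` < 0.01, `*` < 0.05, `•` < 0.1.

**Explained deviance.**  `D² = (null deviance − deviance)/null deviance`;
`adjusted D² = 1 − [(n−1)/(n−p)]·(1−D²)` with `p` the number of mean
parameters including the intercept, giving a deviance percentage comparable
across families.

## Synthetic study generator

`simulate_cohort` emulates the field campaign: per location, beetles are
tracked until a 35-minute cap (2100 s), a random abandonment event
(exponential stop hazard — the beetle hides or is washed away), or a pause
reaching the 10-minute motionless cutoff (600 s); the censoring reason is
recorded and trajectories never fall below 4 vertices.  Attempts fail
independently with probability 2/14 (emulating 14 assayed, 12 completing
per population) until 12 complete walks exist.  Specimen tables hold 38
morphometric records per location, the first 14 of which carry enzyme
assays and the first 12 the trajectory links — so the modelling subset has
complete covariates, as in the motivating design (48/152/56 records).

The walk model is a constant-step correlated random walk: steps of `p` =
0.05 m at a constant 0.02 m/s, with i.i.d. turning angles.  The default
angle family is wrapped normal because its mean cosine has the closed form
`c = exp(−σ²/2)`, giving analytic oracles for `S2` and `TE` (`von Mises`,
with `c = I₁(κ)/I₀(κ)`, is available).  Pauses are time gaps with zero
displacement, so directional-change denominators lengthen across them.
Finished walks are rediscretized at 5 cm to emulate digitization.  The
0.02 m/s speed is an order-of-magnitude placeholder for a small
ground-dwelling beetle, exposed in the configuration and not presented as a
measured value.

The default ("invasion-gradient") scenario separates phenotypes behaviourally and
morphologically: residents POC (σ = 1.0 rad) and PELIS (0.85) versus
dispersers ISB (0.45) and VST (0.40); FEMU/STER and PGI increase along the
invasion timeline POC < PELIS < ISB ≈ VST (a 0–6% shift in trait means,
about 1–2 within-group SDs between the extremes), while PYRU decreases;
residents also pause more.  A shared latent body-size factor (SD 0.09 mm)
loads on INTOC/PRONOL/PRONOW/ELYT with trait noise SD 0.04 mm, making the
size proxies inter-correlated near r ≈ 0.8 so the collinearity screen has
realistic structure to act on.  Ground truth (per-location `c`, expected
`S2`/`TE`, censoring log) is returned alongside the data for
parameter-recovery tests.

What the generator does **not** emulate: terrain and wind effects,
inter-individual variation in speed within a location, behavioural
state-switching beyond pause/move, digitization noise on coordinates, and
any real morphometric covariance beyond the single size factor.  Passing
tests therefore demonstrate that the estimators and the inference chain
recover known structure of this idealized process — not that the field
estimates themselves are reproduced.

## Problem sizes and numerical choices

Closed-form recovery tests use 10,000-step walks (Monte-Carlo standard
errors ≈ 0.002–0.01 on `c`); selection-recovery uses 200 replicates at
n = 200; null calibration uses 2,000 simulated datasets; the end-to-end
phenotype-ordering check uses 100 simulated cohorts of 48 trajectories.
These sizes keep Monte-Carlo error well inside the asserted margins while
the full suite runs in well under a minute of compute.

Floating tolerances: rediscretization targets are generated by integer
multiples of `R` with an epsilon guard against overshooting the final arc
length; interpolated timestamps that collide across zero-length pauses are
nudged by ≤ 1e−9 s to preserve strict monotonicity; `c ≥ 1 − 1e−12`
triggers the straight-path limit flags.  Report tables round to 6
significant digits; trajectory data files are written at full precision so
they round-trip exactly.
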