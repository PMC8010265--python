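# Methods

## The measurement problem

Comparing drought responses across cultivars from field trials confounds
genotype with water regime. The dry-down protocol removes the confound: pots
are watered to container capacity, sealed at the base, and then weighed daily
while watering is withheld, so the balance itself is the flux meter. Two
derived variables put every pot on a common scale:

* **FTSW** (fraction of transpirable soil water),
  `(w_d − w_last) / (w_first − w_last)`, anchored at 1 at container capacity
  and 0 when transpirable water is exhausted. Per-pot normalization makes
  trials of different lengths commensurate.
* **NTR** (normalized transpiration rate): the drought pot's daily water loss
  divided by the mean loss of its well-watered controls (the transpiration
  ratio TR), then divided by the well-watered baseline, the mean TR of days 3
  and 5. NTR ≈ 1 while water is ample, by construction.

The quantity of interest is **FTSWc**, the breakpoint of a plateau
regression of NTR on FTSW: NTR stays on a plateau above FTSWc and declines
linearly below it, reaching 0 in dry soil. FTSWc is read as the soil-water
level at which stomata begin to close: a low threshold means transpiration is
sustained into drier soil (an advantage in short droughts), a high threshold
means early water saving (an advantage in long droughts).

## Pipeline conventions

* **TR is a ratio of daily water losses**, not of pot weights. A weight
  ratio hovers near the ratio of pot masses (≈1 regardless of stress) and
  cannot equal 1 under well-watered conditions on the NTR scale; the loss
  ratio is the reading under which the days-3/5 normalization makes sense.
  `tr_mode="weight_ratio"` implements the literal weight ratio for
  comparison.
* **Evaporation correction**: the mean daily loss of the bare pots is
  subtracted from every planted pot's loss, floored at 0, symmetrically for
  drought and control pots, so the TR ratio stays unbiased.
* **Control pairing**: a drought pot is compared against the average of all
  irrigated replicates of the same cultivar in the same experiment —
  variance-minimizing, and the natural choice when no explicit pairing is
  recorded.
* **Rewatered controls** are weighed before rewatering; since the previous
  evening's state was a full pot, their daily loss is `w_1 − w_d`.
* **FTSW pairing** (`ftsw_pairing`): a day's loss accumulates over the whole
  interval between weighings, so by default it is attributed to the *daily
  mean* soil water, the midpoint of the bounding weighings. Pairing with the
  opening or closing weighing instead shifts the apparent breakpoint up or
  down by up to half a day's drawdown (~0.05 FTSW under default demand).
* **Exhaustion day** (`exclude_exhaustion_day`, default on): the day on
  which a pot's FTSW first reaches 0 is logged and dropped — its loss
  measures the water that remained, not the demand the response curve
  describes, and including this censored point biases breakpoints upward
  for fast-draining pots.
* FTSW is computed from raw (uncorrected) weights, clamped to [0, 1]; days
  after transpiration ceases are kept (zero NTR at zero FTSW is
  informative). Day indexing is 1-based from the first post-saturation
  weighing.

## Curve fitting

**Plateau regression.** `ntr = plateau · min(1, ftsw/c)` by default: the
declining limb passes through the origin, matching a decline that reaches 0
in dry soil. `free_slope=True` relaxes to an unconstrained continuous
two-segment line; `fix_plateau` pins the plateau (e.g. at 1). For fixed `c`
the remaining parameters are linear, so the SSE is profiled over a `c` grid
(0.02–0.95, step 0.005), ties resolved to the smaller `c`, followed by
bounded local refinement between the neighbouring grid values, accepted only
when it strictly improves the SSE — the fit therefore never does worse than
an exhaustive grid search, which `grid_breakpoint_oracle` provides as an
independent cross-check. Uncertainty comes from a seeded percentile
bootstrap over response points (500 draws by default); the interval is
widened if needed to contain the point estimate. Error taxonomy: data with
no point below the best-fit breakpoint raise a no-breakpoint error (decline
unobserved); fewer than two points at/above it emit an all-declining
warning.

**Logistic curve.** `NTR = 1/(1 + A·exp(B·FTSW))` is fitted by multi-start
nonlinear least squares (a ln-linearized start plus a fixed 3×3 fallback
grid over A ∈ {10, 50, 200}, B ∈ {−5, −15, −30}); 95% CIs are asymptotic
(t, n−2 df). A fit where no start converges is returned flagged, never
silently replaced. Two cultivars' curves are called "distinct" when either
coefficient's 95% CIs are disjoint.

**Decade trend.** Mean FTSWc per release decade (missing thresholds
excluded, never imputed), then OLS on a linear spline with one knot at 1965:
`a + b·Time + c·max(0, Time − 5)` with `Time = (decade − 1915)/10`, so `b`
and `b + c` are slopes per decade before and after the knot; the knot falls
midway between the 1960 and 1970 design points, so either knot coding fits
identical piecewise shapes. SE of `b + c` comes from the coefficient
covariance; inference is two-sided t with n−3 df. Decade means are
unweighted by default (each decade is one observation of the trend), with a
count-weighted option. A degenerate flat series reports r² = 0 rather than
the 0/0 float residue.

## The synthetic trial

The generator emulates the replicated two-treatment glasshouse design:
per cultivar, `n_reps` drought and `n_reps` irrigated pots, plus `n_bare`
plant-free evaporation pots, weighed daily for `n_days`. Ground truth
(threshold, plateau, demand) is attached to every dataset, so the full
pipeline can be scored on parameter recovery.

Defaults describe a 4 L pot trial sized to the published design: 14–19 day
trials (default 19), 2 technical replicates, 10 bare pots, ~5 kg saturated
pot weight with 1200 g transpirable water, 10 g/day bare-soil evaporation,
and 120 g/day unstressed transpiration demand — which dries a pot in roughly
10–14 days, matching the reported ~10 days to the end of transpiration on
the NTR scale. Weighing noise is observation noise only (the water balance
is tracked exactly): default s.d. 4.2 g per weighing, i.e. ≈0.05 s.d. on the
NTR scale under default demand, a realistic balance-plus-handling error for
multi-kilogram pots. Growth defaults to 0 g/day (pot-weight analyses do not
correct for biomass gain); a nonzero value injects the corresponding
confound deliberately. An optional hook scales daily demand by
`vpd(day)/mean(vpd)` when a weather table is supplied.

**Within-day integration.** Each day is integrated in closed form: the pot
drains at the constant unstressed rate while above the threshold, then
switches to exponential decay (transpiration proportional to remaining
water, evaporation as a constant offset), with the pool absorbed at 0. A
one-step explicit-Euler variant (`integration="euler"`, rate held at its
start-of-day value) is kept because every reported loss then equals a rate
the response function printed, which makes worked examples transparent —
but it overshoots the decline whenever the daily drawdown (~0.11 FTSW at
default demand) is comparable to the threshold, misplacing low thresholds
by up to ~0.1; it is not the default for that reason.

Measured under the defaults (fixed seeds, reproduced by the test suite and
`scripts/acceptance.py`): noiseless end-to-end recovery of FTSWc is within
0.02 of truth for every cultivar (max ≈ 0.016 across a 0.10–0.50 threshold
sweep), and with default weighing noise the mean absolute error over 50
cultivars is ≈ 0.01 with bias below 0.01.

What the generator does *not* emulate: soil hydraulics (retention curves,
conductivity), root architecture, canopy energy balance, day-to-day demand
fluctuations (unless a weather table is supplied), plant death dynamics, or
block/table effects of the glasshouse layout. Passing recovery tests
therefore show that the estimator chain is consistent with its own
measurement model at realistic noise — not that real pots obey a sharp
two-segment response.

## Reference panel

The packaged table transcribes the published 80-cultivar white clover panel
(decade of release 1920–2010, country, leaf size, drought/irrigated total
dry weights, FTSWc). 21 cultivars have no threshold ("/" in the source);
they are excluded from all FTSWc statistics and never imputed. The file is
pinned by a SHA-256 digest. Where the source's narrative and its table
disagree (FTSWc range 0.11–0.50 vs table extremes 0.12/0.52; drought
dry-weight maximum 23.32 vs 23.33 g; Kotare 0.44 vs 0.42; leaf-size counts
53 medium/26 large vs 52/27 in the table rows), the tabulated values are
authoritative.

On this panel the published decade means behind the original spline fit are
not recoverable from the table (e.g. the table's 1960 mean is 0.30, not the
0.38 the narrative reports), so the trend's published magnitudes are not
reproduction targets; the package asserts the qualitative structure — a
significant rise (b > 0) to the mid-1960s and a significant fall
(b + c < 0) after — which the table-derived fit shows
(b ≈ +0.029/decade, b + c ≈ −0.025/decade, r² ≈ 0.67).

## Numerical notes and limitations

* Saturation vapor pressure uses the Tetens-type constant 0.6108 kPa;
  humidity is accepted in percent only, and a series that looks fractional
  warns rather than converting.
* All summary statistics are computed at full precision and rounded
  half-to-even to 2 decimals only at presentation; ranking ties break
  alphabetically and are visible in the output.
* Replicates are pooled per cultivar before fitting (per-replicate fits can
  be had by filtering the points table); the two experiments are combined by
  pooling response points, which per-pot FTSW normalization makes
  commensurate.
* The bootstrap interval for FTSWc is a percentile interval over points
  resampled with replacement; with strongly clustered designs (few distinct
  FTSW levels) it can be optimistic.
* Thresholds below the daily FTSW drawdown of the trial (~0.1 under default
  demand) sit at the resolution limit of daily weighing; estimates there
  lean on the day-averaging convention and carry the largest bias (~0.015).
* No mixed-effects pooling across cultivars, no Bayesian breakpoint model,
  no leaf-area normalization, and no growth correction — matching the
  analysis the package reproduces.
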