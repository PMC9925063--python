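# Methods

This note documents the models and procedures implemented in
`coralkrige`, the defaults chosen where the method leaves room, and what
the synthetic-data experiments do and do not demonstrate.

## Grid and geometry

All stages share one raster convention: the global 0.05° × 0.05°
lat-lon grid (7200 × 3600 cells), origin at (−180°, −90°), half-open
cells `[edge, edge + 0.05)`, cell centers at `edge + 0.025`. A
coordinate exactly on an edge belongs to the cell above/right of it; a
small (1e-9 cell) nudge absorbs float noise at edges. All distances —
report snapping, variogram lags, kriging systems — are great-circle
(haversine) kilometres on a sphere of radius 6371 km. Planar degree
distances would distort neighborhoods across latitudes and at the
antimeridian; one shared metric keeps the variogram and the kriging
system consistent.

## Report quality control

A report enters the database only with latitude, longitude, year,
severity code and source present. Severity uses the ordinal scale
−1 (unknown), 0 (<1 %), 1 (1–10 %), 2 (10–50 %), 3 (>50 %). The
published class ranges overlap at their edges; we fix the boundaries as
exactly 1 % → mild, exactly 10 % → mild, exactly 50 % → moderate. A
missing severity is infilled from percent bleached through that mapping;
when both are present and disagree, the explicit code wins and the
conflict is logged. Unknown severity (−1) is a distinct code throughout
(some plotting conventions merge −1 and 1; the analysis never does).

Reports whose cell is not on the reef raster snap to the nearest reef
cell center; ties break to the lowest (row, column). Unlike
unconditional nearest-reef assignment, a configurable cap (default
50 km) rejects reports as unlocatable beyond it — gross coordinate
errors should not silently relocate across a basin. Snapping is
idempotent and its distance is logged per report.

## Degree Heating Weeks

The DHW implementation fixes the standard operational definition, since
results depend on it:

* monthly climatological means over a baseline (default: the first ten
  complete calendar years of the supplied series, or all complete years
  if fewer); MMM = the maximum of the twelve;
* HotSpot(t) = max(0, SST(t) − MMM), °C;
* DHW(t) = (1/7) · Σ over the trailing 84 days of HotSpots ≥ 1 °C,
  °C·weeks.

The operational satellite product's climatology recentering is not
reproduced; the baseline is a plain monthly mean. Leading partial
windows (the first 83 days) are evaluated over the available days by
default so short series remain usable; `mask_partial=True` blanks them.
Annual maxima use calendar years with no hemisphere-season adjustment —
a documented limitation for austral-summer events spanning New Year,
which can split one event across two annual maxima.

## Pseudo-absences

Cells with annual maximum DHW strictly below the threshold become
value-0 indicator observations; the zero threshold demands DHW exactly
zero all year. The default threshold is 0.5 °C·weeks, with 0, 0.25 and
1.0 supported by `threshold_sensitivity`, which re-interpolates a
region-year per threshold and reports the mean/median probability at
report cells. When a cell qualifies as both presence and pseudo-absence
(severe reports in a thermally quiet year), presence wins by default —
the source text is ambiguous on this point, so the precedence is an
explicit, switchable choice (`presence_precedence`); with it off, the
thermal criterion overrides the reports.

## Variogram estimation and automatic fitting

The empirical indicator semivariogram is the method-of-moments
estimator over great-circle lag bins: 15 equal-width bins to a cutoff
of one third of the maximum pairwise distance by default (both
configurable). Empty bins are flagged, not interpolated. For binary
data with presence fraction p the theoretical sill is p(1−p) ≤ 0.25.

Model fitting minimizes Σ w_j (γ̂_j − γ(h_j))² with weights
w_j = N(h_j)/h_j², the default of the automatic-fitting lineage this
follows (alternatives: N(h), equal). Optimization is bounded
derivative-free local search (Nelder–Mead) from automatic initials
(nugget = min γ̂; partial sill = mean upper-half γ̂ − nugget;
range = 0.1 × max lag), with one restart from user-supplied initials
when given — the manual-oversight pathway for fits that fail from
automatic starts. Parameters are constrained non-negative.

Nine families are supported: Spherical, Exponential, Gaussian, Matérn,
Stein's Matérn, Circular, bounded Linear, Bessel and Pentaspherical
(the source names nine while counting eight; all nine named are
implemented). The Matérn smoothness κ is selected over a discrete grid
(0.3–10) rather than optimized continuously, mirroring common automatic
fitters and avoiding a poorly conditioned joint search. `autofit`
returns the converged fit with the smallest weighted RSS; ties — which
occur exactly, e.g. Matérn κ = 0.5 versus Exponential — break to family
list order, with "tie" meaning RSS differences below 1e-9 of the data
scale so float noise cannot override the documented order.

## Ordinary indicator kriging

Per target, the solver builds the (n+1) augmented system from model
semivariances with a Lagrange multiplier enforcing Σλ = 1, over the
`n_max` nearest observations (default 100; `None` gives the global
solve, which the test oracles use). Raw estimates may leave [0, 1] —
they are clamped for use as probabilities, with the raw value and a
clamped flag retained. Kriging variance λ·γ₀ + μ is reported per cell.
Duplicate observation locations make the system singular; the pipeline
prevents them by collapsing to one observation per cell (presence
precedence), and the solver refuses them by name rather than jittering.

## Regions, sufficiency and fallback

Kriging runs per region-year in four ocean basins; default boundaries
are configurable lon/lat rectangles (Caribbean, East Pacific, Indian,
Pacific as catch-all) assigned first-match so that the regions always
partition the reef mask. The source gives no numeric data-sufficiency
rule; ours requires ≥ 5 presence cells, ≥ 5 pseudo-absence cells and
≥ 3 non-empty lag bins (all configurable). Anything less — or a
variogram that fails even from manual initials — produces the fallback
map: 1.0 at presence cells, 0.0 at every other region cell, flagged
`fallback` in the per-region provenance. Years with no reports at all
still produce (all-zero) maps. Combining fragments is a strict union:
a missing region yields NaN probabilities flagged `no-data`, never
silent zeros.

## Analysis layer

* Welch two-sample t-tests, two-sided, with Welch–Satterthwaite degrees
  of freedom; implemented directly and cross-checked against
  `scipy.stats.ttest_ind(equal_var=False)` in the tests. Both-samples
  zero variance (below 1e-20, absorbing float noise in sums of
  identical values) is an error.
* Probability bins ≤10 %, >10–33 %, >33–50 %, >50–66 %, >66–90 %, >90 %
  are upper-inclusive, matching the printed range notation (0.90 falls
  in >66–90 %); the source does not state closure, so this is fixed
  here. The DHW-by-bin table pools cell-years over a period and flags a
  bin whose mean differs from every other occupied bin by Welch tests at
  p < 0.01. No multiple-testing correction is applied by default,
  matching the exploratory framing; a Bonferroni switch exists.
* Extent uses "at least once in the period" semantics at the likely
  (>66 %) and very likely (>90 %) thresholds.
* Trends are OLS slopes of annual subset means (not pooled cell-years —
  the per-year distributions motivate the subset-mean formulation) of
  annual-max DHW on calendar year, for all cells and for cells above
  each probability threshold in that year.

## Synthetic worlds

The generator emulates the statistical structure of the real inputs
with everything derived deterministically from (seed, parameters):

* **Reefs**: four Gaussian clusters of 50 unique cells (σ = 1.2°), one
  per region.
* **SST**: latitude-dependent mean (29 °C − 0.08 °C/deg·|lat|),
  seasonal sinusoid (amplitude 1.5 °C, hemisphere-phased), linear
  warming trend 0.2 °C/decade (a realistic recent tropical rate), AR(1)
  daily noise (ρ = 0.8, σ = 0.3 °C — enough sub-1 °C HotSpot flicker to
  make the 0 vs 0.25/0.5/1.0 threshold comparison meaningful), and
  Gaussian-in-space-and-time heatwaves (peak 1.5–3.5 °C, 40–90 days,
  radius 100–250 km, probability 0.7 per region per modelled year,
  centered in the local warm season). Three event-free baseline years
  precede five modelled years.
* **Truth**: bleached ~ Bernoulli(expit(−4 + 1·annualMaxDHW)) per
  cell-year — the simplest monotone link consistent with the observed
  DHW–probability gradient; 50 % bleaching odds at 4 °C·weeks, the
  operational Bleaching Alert Level 1.
* **Observation**: per-region survey effort (Caribbean 0.5, Indian and
  Pacific 0.3, East Pacific 0.2, emulating Caribbean-heavy reporting),
  percent-bleached drawn conditional on truth and mapped through the
  severity scale, 2 % false reports, 5 % unknown-severity (−1) reports,
  and 10 % coordinate errors of 0.08–0.3° to exercise snapping.

What passing synthetic tests shows: the solvers are correct against
independent oracles; the pipeline recovers known spatial structure
(truth-ranking AUC, report-cell contrast, DHW gradient across bins)
under a realistic observation process. What it does not show: fidelity
to real reef geography, real ENSO-driven event structure, severity
misclassification patterns of human observers, or the behaviour of the
method on the real decades-long record.

## Numerical choices and degenerate inputs

* Kriging solves use a symmetric dense solver; non-finite solutions are
  reported as singular systems, and failed target cells are masked and
  logged rather than aborting the region.
* Variogram fits bound the range to [1e-6, 100] × max lag; fits
  reported non-converged are excluded from selection unless nothing
  converges, which triggers the fallback pathway.
* `percent_to_severity` rejects values outside [0, 100]; SST series must
  be daily, gap-free and within (−5, 45) °C or they are refused with an
  instruction to fill or trim.
* Problem sizes in the tests and the acceptance script (200-cell worlds,
  five modelled years, ten seeds) are chosen so the full reconstruction
  and its replications run comfortably on a single CPU while leaving
  every region-year large enough to exercise both the kriged and the
  fallback pathways.

## Known limitations

* Calendar-year annual maxima split austral-summer events.
* Rectangle region boundaries only approximate published basin
  boundaries; both region layers (four kriging basins, analysis
  regions) are configuration, not geography.
* The fallback map is a coarse prior (certain presence, certain absence
  elsewhere) and dominates sparse early years; extent statistics pool
  kriged and fallback years without reweighting.
* Anisotropy, REML/ML variogram estimation, cross-validated model
  choice, and sequential indicator simulation are out of scope.
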