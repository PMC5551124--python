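# Methods

## Problem and model

The package designs a supplement to an existing air-pollution monitoring
network: given `n_current` monitors, `n_subject` residences and
`n_candidate` feasible spots for new monitors, place `n_new` new sites so
that the combined network represents the spatial variability of long-term
(annual-average) concentrations across residences. The underlying model
assumption is the standard land-use-regression (LUR) one: annual averages
are largely determined by a small set of geographic covariates, so
locations that are similar in those covariates experience similar
concentrations. Clusters in covariate space therefore partition the city
into exposure regimes, and the ratio of monitors to residences per cluster
measures how well each regime is monitored.

The pipeline is deliberately modular; every stage reads and writes plain
CSV, so users with real monitoring data and covariates can enter at any
stage.

## Completeness QC

Hourly values → daily means → annual mean, with eligibility criteria:

| rule | default | note |
|---|---|---|
| hours per valid day | ≥ 18 of 24 (75%) | threshold configurable |
| months with ≥ 1 daily average | ≥ 10 | |
| missing days | ≤ 91 (25% of the year) | |
| consecutive missing days | < 45 (strict) | runs evaluated within the calendar year only |

The annual mean is the unweighted mean of valid daily averages (two-stage
averaging, so an over-sampled day cannot dominate) and is reported for
ineligible sites too, flagged. The first two thresholds are stated in the
literature both as strict and non-strict inequalities; the percentages
they are glossed with (75%, ≥10 of 12) fix the readings used here, and
both are exposed as parameters.

## Geographic covariates

Two metric families: proximity (distance in metres to the nearest source
geometry — point, or nearest point on a segment) and density (count of
point sources, clipped segment length, or land-use area percentage within
a circular buffer). Before modelling:

* proximities are truncated at a cap (1 km default; 2 km intended for
  large physical features like coastline or rivers, carried per variable
  in `VariableMeta.truncation_cap`) and natural-log transformed with a
  +1 m offset, `log(min(d, cap) + 1)`, so a zero distance maps to 0 and
  the covariate saturates beyond plausible influence range;
* variables with < 10% distinct values across locations are dropped, and
  land-use area variables whose maximum share never reaches 10% are
  dropped. These are implemented as two independent rules (the
  alternative — a conjunction — would almost never fire, since area-share
  variables are continuous and rarely fail the distinct-value rule); the
  exclusion report states which rule fired per variable;
* remaining variables are z-scaled with mean/SD computed jointly over all
  three roles, because clustering operates on the pooled set; sample SD
  (n−1) is the default, with the statistics retained so new locations can
  be projected onto the same scale.

## Land use regression

Forward selection from a null model: each step fits OLS for every
remaining candidate alongside the already-selected set, requires the
added coefficient's t-test p < `entry_alpha` (0.05 default; for a single
added variable this is equivalent to the F-test of the R² change), and
takes the qualifying candidate with the largest R². The entered variable
is then checked against VIF ≤ 10 (variable regressed on the other
selected ones) and pairwise |r| ≤ 0.7 with each selected variable; a
violator is removed and permanently barred, which prevents
add/remove cycling. Selection stops at `max_vars` (5) or when no
candidate qualifies.

LOOCV R² = 1 − MSE/var(y) with var using denominator n (configurable);
the score can be negative when held-out predictions are worse than the
mean. Standardized effects are reported as coefficient × (p90 − p10) of
the covariate, with percentiles by linear interpolation (the method is
recorded on the model object).

## Clustering and DiD

k-means (Lloyd) runs in the scaled space of the selected covariates over
all locations. Each restart draws K distinct data rows as initial
centers from one seeded generator; iterations stop when the assignment is
stable. An empty cluster is reseeded at the point farthest from its
assigned center, which cannot increase the objective. The restart with
minimum total SSW wins; the per-iteration SSW history is exposed and is
non-increasing, and the whole search is bit-reproducible given the seed.
The full-city-scale default is 1000 restarts; the pipeline default is smaller
(50) because the synthetic problems it ships with are far smaller than a
full city.

DiD(k) = 100 × (1 − (1/J) Σⱼ ΣₖSSWⱼₖ/SSEⱼ) is evaluated per k on two
characteristic sets — LUR predictions (J = 1) and the selected covariates
(J = J_sel) — clustering always being done on the covariates alone. This
normalisation (each characteristic's SSW ratio normalised by its own SSE
before averaging) is the only reading under which DiD(1) = 0 and
DiD → 100 as clusters shrink to singletons. `suggest_k` proposes the
smallest k ≥ 2 whose forward gains stay below a threshold (default 1
percentage point) over a 3-step lookahead on *both* curves; the last k of
the curve cannot confirm a plateau and triggers a fallback warning. The
suggestion is advisory — plateau choice is partly judgement, so the
pipeline accepts a fixed k.

## Allocation

Iterated greedy argmin of the per-cluster current/subject proportion,
with three rules that the shipped printed count tables pin down exactly:

* a placed site increments the cluster's current count before the next
  comparison (otherwise the repeated recomputation of the proportion
  would never change anything);
* clusters with zero remaining candidates are excluded from the argmin,
  whatever their proportion;
* proportions are compared unrounded; the ×10⁴, one/two-decimal form is
  display only.

Ties default to lowest cluster label; a seeded random tie-break is
available, and both shipped applications give identical final counts
under either rule. The concrete candidate within the chosen cluster is a
uniform seeded draw without replacement.

## Stability

100 replicates (default) keep 90% of locations, rerun `kmeans_best`, and
score the Hubert–Arabie adjusted Rand index against the full-data
partition *restricted to the retained locations* — the only well-defined
pairing of the two partitions. Replicate seeds derive from the master
seed. Summary bands: ≥ 0.90 excellent, ≥ 0.80 good, ≥ 0.65 moderate.
The adjusted Rand computation itself is delegated to scikit-learn; the
test suite checks it against an exhaustive pair-counting implementation
on every set partition of up to 8 items.

## Synthetic city generator

Emulates the data regime the design targets: currents on a jittered grid
(even administrative coverage), subjects in a handful of Gaussian blobs
(clumped residential districts — the allocation step is only interesting
when roles differ spatially), candidates uniform. Sources are random line
segments (major roads) and points (bus stops, construction sites);
covariates are the proximity and buffer-density variables derived from
them plus pure-noise columns. Concentration is
`intercept + Σ β·(recoded covariate) + N(0, noise_sd)` — i.i.d. noise,
no spatial autocorrelation term, matching the LUR model's own assumption
of independent residuals.

Defaults: 37 / 31,097 / 412 locations per role on a 25 km × 25 km extent;
250 road segments, 2000 bus stops, 300 construction points — densities
chosen so typical nearest-source distances fall well inside the 1 km
truncation cap (median distance to a major road of a few hundred metres,
the dense-city regime); intercept 30 µg/m³, noise SD 1.5 µg/m³, ten noise
covariates. What the generator does **not** emulate: spatially correlated
residuals, temporally structured hourly pollution (hourly series are
i.i.d. lognormal about a site mean), real road topology, or
covariate-covariate dependence beyond what shared geometry induces. Tests
passing on these cities therefore demonstrate the correctness of the
algorithms under the model's own assumptions, not predictive performance
on real monitoring data.

## Problem sizes in tests and the acceptance script

The shipped tests and `scripts/acceptance.py` run on scaled-down
instances chosen to exercise every code path at interactive speed: 6 km
synthetic cities with a few hundred to two thousand subjects (source
counts scaled to keep the same per-km² density as the full-scale
defaults), k_max 6–12, 8–50 k-means restarts, 100 selection-recovery
replicates, 400 null-entry replicates, 25 stability replicates. The
generator's full-scale defaults are used once in the acceptance script to
verify the full-scale location count. Full-scale clustering (31,546
locations × 1000 restarts × 50 k values) is intended for real analyses.

## Known limitations

* k-means with random-row initialisation can return local optima; the
  multi-restart minimum mitigates but does not eliminate this, which is
  exactly what the stability module quantifies.
* The allocation criterion uses counts only — no spatial spacing,
  population weighting, or distance-to-existing-monitor constraints.
* Proximity recoding fixes log base e and offset 1 m; other conventions
  change coefficient scales but not selection order.
* No geodetic support: coordinates are planar metres.
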