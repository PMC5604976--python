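# Methods

## The problem

Species distribution models (SDMs) map environmental predictors to the
probability of a species occurring. They implicitly assume the species is
at equilibrium with its environment — that every suitable place has had an
equal chance of being reached. A spreading invader violates this
assumption badly: during the *space-infilling* stage its distribution is
patchy and strongly spatially autocorrelated, governed as much by where
propagules can get to as by where they can survive. Models that ignore
this either over-predict (flagging suitable but unreachable areas) or
launder dispersal limitation into spurious environmental effects.

`hpvsdm` addresses this with **historical proximity variables (HPVs)**:
predictor rasters that encode the state of the invasion at a fixed time
lag before the response data. An HPV is characterized by

* **information capacity** — what it encodes: presence of past sites in a
  cell (`P`, low), their count (`C`, moderate), or the distance from each
  cell to the nearest past site (`D`, high);
* **minimal recentness** — the shortest lag between response and source
  distribution (5, 10 or 25 years here);
* **number of time periods** included.

The four capacity choices {P, C, D, CD} crossed with the six period
subsets {5}, {10}, {25}, {10+5}, {25+10}, {25+10+5} give 24 predictor-set
variants, plus a no-HPV control.

## Grid and proximity transforms

The analysis grid is an unprojected lon/lat grid (EPSG:4326) with 1/120°
cells (~1 km at mid-latitudes), row 0 at the northern edge, half-open
cells. Counts are tallies of site points per cell; presence is count > 0;
distance is the great-circle (haversine, sphere radius 6 371 008.8 m)
distance from each **cell center** to the nearest site. Distances are
computed exactly via a k-d tree on the unit sphere: chord distance is
monotone in arc distance, so the chord-nearest site is the arc-nearest,
and the chord is converted back to an arc length. Test oracles are
exhaustive all-pairs scans on ≤40×40 grids (agreement < 1e-6 m).

Dated occurrences carry an onset year (earliest known existence) and a
census year (field verification). Sites closer than 500 m are
single-linkage merged into one population (earliest onset, centroid
location). Onsets known only to a decade are coarsened to the mid-decade
year (1970s → 1975). The period-p subset keeps records with
`onset_year ≤ response_year − p`; subsets are therefore nested, and the
derived distance layers are pointwise ordered (older subset ⇒ larger
distances), which the tests assert.

## Model fitting and evaluation

The response is presence (response-snapshot occurrences) versus 1000
pseudoabsences drawn uniformly without replacement from mask cell centers
that hold no presence; with the printed design of 628 presences this gives
1628 cases. Presence cells are excluded from the pseudoabsence pool to
avoid label noise; the count contract is unaffected.

Seven algorithms are fitted per variant behind one scorer interface
(case → probability): random forest (RF), gradient boosting (GBM), a
single classification tree (CTA), a small feed-forward network (ANN,
lbfgs-trained — robust at these sample sizes), an adaptive hinge-basis
logistic regression standing in for MARS, a linear discriminant on the
same hinge basis standing in for FDA, and a surface range envelope (SRE)
that predicts presence iff every predictor lies inside the presence
quantile envelope `[q_α, q_1−α]` (α = 0.025 by default; predictions are
binary by construction). The algorithms are treated as interchangeable
black boxes whose evaluation score is the object of study, so functional
stand-ins with the same model families are appropriate.

Evaluation uses a stratified 80/20 calibration/evaluation split repeated 3
times (the split fractions are configurable; nothing in the factorial
design depends on them). Two scores are computed on the held-out cases:

* **TSS** = sensitivity + specificity − 1, maximized over the threshold
  grid {0, 0.001, …, 1} (smallest threshold wins ties). TSS < 0.4 is
  moderate at best, 0.4–0.6 good, above 0.6 very good.
* **ROC AUC** via the rank (Mann–Whitney) formulation with averaged ties;
  the curve-based computation is an independent oracle in the tests.

Single models with held-out TSS ≥ 0.7 (the gate) become ensemble members.
Six ensemble statistics are built per repetition: mean; TSS-proportional
weighted mean; pointwise median; committee averaging (mean of member
predictions binarized at each member's TSS-optimal threshold); and the
lower/upper bounds of the normal-approximation confidence interval of the
member mean, mean ∓ 1.96·sd/√m clipped to [0, 1]. The CI construction is
a design choice — the interval form is standard, and the exact variant
used by legacy ensemble toolkits is not documented. Models that fail to
converge are flagged and excluded from ensembles.

## Meta-model: what drives model quality

All evaluations are melted into a long table with five attributes per row
— algorithm, capacity code, minimal recentness, number of periods, and
single/ensemble group — and the TSS z-scored within the single and
ensemble groups (`tss_std`). A shadow-feature procedure then classifies
each attribute:

1. per iteration, append a permuted shadow copy of every attribute
   (categoricals one-hot encoded, columns of one attribute permuted
   jointly); shadows are padded to at least five so the max-shadow
   reference is stable for small attribute sets;
2. fit a bagged ensemble of regression trees (explicit bootstrap, 100
   trees by default) and compute each feature's **out-of-bag permutation
   importance** per tree — the increase in OOB squared error when the
   feature's column is permuted. The Z-score is the mean over trees
   divided by the sd over trees. OOB permutation importance is essential:
   impurity-based importance is always positive and nearly constant
   across trees, which inflates Z-scores of null attributes;
3. an attribute scores a *hit* when its Z (max over its one-hot columns)
   beats every shadow's Z; after `max_iter` = 100 iterations the hit count
   is tested two-sided against Binomial(100, ½) at p = 0.01: significantly
   many hits → **Confirmed**, significantly few → **Rejected**, otherwise
   **Tentative** (never forced).

The ranking by mean Z over iterations is the variable-importance table.
On replicated synthetic runs with a panel spanning weak (SRE) to strong
(RF, GBM) learners, the algorithm attribute dominates, and the number of
periods ranks last — the qualitative structure expected when algorithm
choice matters far more than predictor-set details.

## Projection scenarios

Because HPVs carry an explicit time lag, substituting them turns one
fitted model into several maps: the **current** map (project the training
stack); the **forecast** at (present + minimal recentness) (recompute
every proximity layer from the *current* sites); the **potential range**
(set distance layers to a constant fill, 0 m by default, and
presence/count to saturating constants — the probability of final space
infilling); the **emergence map** (forecast − current) and the
**unsaturation map** (potential − current). Identity substitution is
bit-exact by construction; difference maps are plain cell-wise
subtractions with nodata propagation. Iterated forecasting is possible by
thresholding a projection into pseudo-sites (cell centers above the
TSS-optimal threshold), with the caveat that the environmental layers age
as the horizon grows.

## The synthetic-data generator

No occurrence data are distributed, so a simulator stands in for the
field study. It emulates:

* an environmental stack of 8 spatially autocorrelated layers (white
  noise smoothed with a Gaussian kernel of 15 cells, z-scored) on a
  200×200 grid of 1/120° cells near 52° N;
* a true suitability surface, logistic in a linear combination of the
  first six layers (weights 0.6, −0.5, 0.4, 0.35, −0.3, 0.25; intercept
  −4.2). The intercept is strongly negative so suitable habitat is sparse
  and patchy — the regime of a dispersal-limited invader far from
  equilibrium;
* a dispersal-limited invasion: 5 foci seeded in 1980 in top-quintile
  cells; each extant site emits 3 propagule events per year, traveling an
  Exponential(2 km) distance or, with probability 0.01, a Uniform(0,
  100 km) jump, in a uniform direction; the target cell establishes with
  probability equal to its suitability; events leaving the grid are lost
  (absorbing boundary); sites persist by default (the modelled species'
  populations outlive the longest lag considered);
* a census snapshot in 2007 producing dated records, with onsets before
  1997 coarsened to mid-decade years (decennial dating noise), and a 2012
  response snapshot.

The suitability parameters were chosen once so the census analogue holds
on the order of a hundred sites and the response analogue a few hundred
(matching the scale of the motivating survey data; medians ~120 and ~250
over 10 seeds, with wide natural variation). All stages are deterministic
given their seeds.

What the simulator does *not* emulate: observation error and uneven survey
effort, population extinction dynamics (persistence defaults to 1),
seed-bank or age structure, anthropogenic transport corridors, and any
real geography. Consequently, passing tests demonstrate that the pipeline
recovers dispersal-driven structure *when it is present and cleanly
observed* — not that it would do so at real-data noise levels. Absolute
TSS values on synthetic data run high (~0.9): with establishment tied to
suitability, a sparse invasion forces a sparse suitable area, so even the
no-HPV control discriminates presences from random background well. The
replicated experiments therefore assert *orderings* — distance HPVs above
the control, more recent above less recent, distance above presence
encoding — not absolute levels.

## Numerical and scale choices

* Threshold grid step 0.001 with smallest-argmax tie-break: deterministic
  and fine enough for evaluation sets of a few hundred cases.
* Nodata propagates through every raster operation; model matrices drop
  nodata rows with logged counts.
* Replicated experiments use 10 replicate invasions, the RF/GBM/SRE
  panel, 3 split repetitions and 1000 pseudoabsences — a few minutes on
  one core, while leaving clear medians. The planted-signal meta-model
  trials use n = 500 rows, 100 iterations, 50 trees per iteration.
* One master seed spawns named substreams per stage (simulate /
  pseudoabsences / splits / fit / meta), so stages re-run independently
  and reproducibly; all derived seeds stay below 2³¹.

## Known limitations

* MARS/FDA are fixed-knot hinge-basis approximations (knots at the 25/50/75%
  quantiles), not adaptive forward/backward basis selection.
* The SRE envelope ignores predictor correlations (axis-aligned box).
* Great-circle distances assume a spherical Earth; at 1 km cells the
  ellipsoidal correction is irrelevant.
* The shadow-feature test inherits the usual caveat of importance testing
  on a fixed dataset: an attribute that is correlated with the response
  *in the sample*, however accidentally, is genuinely informative in-sample
  and may emerge Tentative rather than Rejected.
* `ensemble` and `project` CLI commands refit deterministically from the
  seed rather than loading a serialized model store.
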