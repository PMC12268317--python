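# Methods

This note records the models, parameter choices and numerical decisions
behind `rtbridge`, and what the synthetic study does and does not
emulate.

## Retention time indexing

RTIs are strictly two-anchor linear: for an ordered system pair, the
anchors are the minimum and maximum RT of the calibrants detected on
*both* systems, recomputed per pair because each lab detects a
different subset of the shared panel. A calibrant seen on only one side
never anchors either side. The scale is 0–1000; the earliest and latest
shared calibrants map to exactly 0 and 1000, and the index is invariant
under any affine change of one system's time axis (a·RT+b, a>0).
Suspects may index outside [0, 1000]; they are flagged, not clipped.
Anchor ties are resolved by value, not by compound: two calibrants
sharing the minimum RT give the same anchor. No multi-point or
piecewise index scheme is offered.

## Pair projection (GAM)

The source→target map is a univariate penalized cubic regression
spline: a B-spline basis of dimension k = 6 (intercept plus five basis
columns, the statsmodels `BSplines` basis spanning the full RTI domain
[0, 1000]) with an integrated-squared-second-derivative penalty. The
penalized least-squares problem is solved in closed form on a fixed
grid of 40 log-spaced smoothing parameters (1e−4 … 1e9) and the
smoothing parameter is chosen by generalized cross-validation,
GCV(λ) = n·RSS/(n − edf)². A fixed grid keeps every one of the ~1300
pair fits deterministic and fast; the grid is wide enough that the
optimum is interior in practice.

Decisions where the design was open:

- **No monotonicity constraint** on the smooth; `ProjectionModel.
  is_monotone()` can flag non-monotone fits but nothing is enforced.
- **No extrapolation**: evaluation is allowed on exactly [0, 1000]
  (boundaries included); suspects outside the source calibration range
  are excluded with reason `out_of_range`. Suspects out of range on the
  *target* side are evaluated but flagged, with a switch
  (`include_out_of_range_targets=False`) to exclude them too.
- **Pre-model baseline** is the raw index transfer: residual =
  observed target RTI − source RTI on the same evaluation set.
- **min_shared = 8** calibrants per pair: a 6-dimensional basis needs
  more points than coefficients with headroom; pairs below the
  threshold are skipped and logged, never silently fitted.
- Direction matters: the smooth minimizes residuals toward the target
  axis, so both orders of every pair are fitted and reported; the suite
  asserts the two directions are independent fits, never that they
  agree.

## Similarity and clustering

Correlations use all compounds (calibrants and suspects) detected by
both systems: Pearson on raw RTs, Spearman with average ranks for ties.
Entries with fewer than 3 shared compounds or zero variance are missing
and logged. Clustering is agglomerative with average linkage on the
distance 1 − coefficient (the transform is this package's decision);
systems enter in lexical id order so ties resolve deterministically,
and an all-identical matrix short-circuits to lexical leaf order.
Missing entries are imputed to the column mean before clustering, with
a warning.

## Peak spacing

Normalized RT = 1000 · RT / run_time — plain division by program
length, no dead-time subtraction. Spread is the sample (n−1) standard
deviation, and the cumulative curve is the empirical CDF at each
observed value. An RT above the program length is a validation error.

## Prediction arm

Descriptor cleaning runs four rules in order: (1) drop descriptors
missing for more than 15 compounds (exactly 15 is kept); (2) drop
compounds with any remaining missing value; (3) drop near-zero-variance
descriptors (most/second-most frequent value ratio ≥ 19 together with
unique fraction ≤ 10%, plus all constant columns); (4) iteratively drop
from each pair with |r| > 0.7 the member with the larger mean absolute
correlation, ties keeping the earlier column. Every drop is logged by
rule.

The learner is an xgboost regression-tree ensemble
(`tree_method="hist"`, single thread, seeded). The default
hyperparameter grid is depth {3, 5, 7} × learning rate {0.05, 0.1,
0.3} × rounds {100, 300} × subsample 0.8, scored by mean RMSE over
five-times repeated two-fold cross-validation with identical splits for
every grid point, then refit on all data. `FAST_GRID` (one point:
depth 4, rate 0.1, 150 rounds) exists for repeated small fits such as
per-system local models and multi-seed experiments.

Predicted RTs are transferred to a target system's RTI scale by fitting
the same penalized-spline machinery on predicted calibrant RT →
observed calibrant RTI (this package's reading of the calibration step;
a two-anchor linear alternative is available via `linear=True`).
Suspects whose predicted RT falls outside the calibrants' predicted-RT
range are excluded as out of range. The calibrant-only local variant
trains the same learner directly on one system's calibrant RTIs
(minimum 10). External training compounds are disjoint from the study
panel by construction, and the suite asserts it.

Real-structure descriptors (`compute_descriptors`) use RDKit:
standardization (largest fragment, normalization, charge neutralization)
followed by the full 2D descriptor set and 3D shape descriptors from a
single ETKDG conformer embedded with a fixed seed. Unparseable SMILES
yield an all-missing row and a log entry, never an exception.

## Synthetic study

Each compound carries a one-dimensional latent elution coordinate
u ~ U(0.02, 0.98) — a log-hydrophobicity surrogate. This is
deliberately statistical, not mechanistic: one latent dimension plus
monotone system warps reproduces every phenomenon the analysis
interrogates (program nonlinearity, additive-dependent shifts,
detection dropout) without modelling gradient-elution theory.

A system's warp comes from its gradient program through the elution
progress g(t) = (1−η)·(φ(t)−φ(0))/(φ(T)−φ(0)) + η·t/T with η = 0.05,
inverted piecewise-linearly and offset by the dead time
(max(0.5 min, 2% of run)). Consequences, by construction: a single
linear gradient gives an affine warp; mid-run isocratic segments and
gradient-speed changes make pairs of systems *nonlinearly* related in
RTI space (start offsets and overall scale are absorbed by the index);
a terminal plateau at maximum organic fraction ends elution in a short
washout just past the plateau start, compressing late eluters and
keeping the maximum normalized RT well below the run end.

Default study conditions: 20 systems, 41 calibrants + 45 suspects, run
times U(15, 54) min, random programs combining (by coin flips) an
initial hold (3–20% of run), a two-slope gradient with optional mid-run
isocratic segment (5–20%), and a terminal plateau (10–40%); 25% of
systems use an ammonium-salt additive, the rest formic acid; 40% of
compounds are ionizable (even acid/base split, pKa U(3.6, 8.1)).
Ionizables shift in latent space on ammonium systems by ±delta_ion
(default 0.08; bases later, acids earlier) so the shift composes
naturally with each warp. Measurement noise defaults to 10 index units
on the RTI scale (`noise_rti=10`), realized per system as minutes
scaled by that system's elution span; a fixed minute-scale
`noise_sd` is available instead. Detection dropout is independent
Bernoulli per compound×system with a per-system rate drawn from
U(rate−0.2, rate+0.2) around the configured mean (0.25), which spreads
detected calibrant counts from the low teens to the high thirties.
One global seed fans out to fixed per-component streams
(`SeedSequence([seed, stream])`).

Synthetic descriptors are noisy monotone transforms of u plus pure
noise columns, with optional planted defects (constant, duplicated,
missing-polluted) for exercising the cleaning rules. One informative
column encodes acid/base character: it is the structural handle through
which a model trained on one additive class can learn the pH-dependent
shift — without it, training-system additive class could not matter,
which real descriptors (ionizable-group counts, charge descriptors)
plainly allow.

What the generator does **not** emulate: peak widths and co-elution,
column-chemistry effects beyond the additive mechanism, temperature
and flow programs, detector-dependent sensitivity, or any real
structure–retention relationship. Tests passing on this study show the
pipeline's statistical machinery behaves correctly under the stated
generative assumptions; they do not certify accuracy on any particular
laboratory dataset.

## Statistical comparison

Error summaries report RMSE, MAD (mean absolute deviation), the 95th
percentile of absolute deviations (linear interpolation between order
statistics) and, when predicted/observed vectors are supplied, the
squared Pearson correlation. RMSE ≥ MAD always (Jensen) and the suite
asserts it on random vectors.

The F-test takes F = MSE_larger/MSE_smaller with degrees of freedom
equal to the residual counts — residuals are prediction errors, not
deviations from a fitted mean, so no degree is lost — and a two-sided
p = 2·min(tail probabilities) capped at 1. Both-zero MSEs give p = 1 by
convention; exactly one zero MSE gives the degenerate p = 0 limit. No
multiple-testing correction is applied. Pair verdicts are computed on
the suspects for which both routes produced an RTI, require at least 3
such compounds, and are invariant under label swap except for the
verdict name.

## Problem sizes

The shipped suite and acceptance script run desk-scale versions of the
analysis: the default 20-system study for all-pairs projection (380
ordered pairs), 100 simulated pairs for the noise-band check, 10⁴
replicates for the F-test null calibration, 20-seed sweeps at 6–8
systems with the single-point hyperparameter grid for the prediction
effect-direction checks, and an 8-system run for the byte-identical
rerun check. These sizes are the package's chosen defaults for quick,
reproducible verification; every knob scales up through
`SimulationConfig` and `RunConfig`.
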