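# Methods

## Data model

A layered network holds an ordered list of layers, an ordered list of
entities, an ordered grid of N time-point labels shared by all layers, and
one value vector of length N per (layer, entity) present. Entities may
appear on any subset of layers. Missing values are NaN in memory and the
token `NA` on disk; they are never coerced to zero, because "no
measurement" and "zero signal" are distinct states (the colormap draws both
grey, but statistics drop only the former). Time points are labels with an
implied uniform order — the analyses use only adjacency and count, so a
grid in days and one in half-hours are handled identically.

The TSV dialect has three sections (`#LAYERS`, `#VALUES` with the time
labels on the header row, `#EDGES` with intra-layer rows when the two layer
fields agree), plus a JSON twin that stores the entity order explicitly.
Value rows are written entity-major so that first-appearance order
reconstructs the entity list and read∘write is the identity. Floats are
written with `repr`, i.e. shortest round-tripping decimal, which makes the
identity exact at full stored precision.

## Color encoding

Linear interpolation between two RGB endpoints over the layer's own
[min, max], computed over all entities and time points of that layer.
Per-layer anchoring is deliberate: layers measure incomparable quantities,
and a shared scale would make cross-layer color comparison look meaningful
when it is not. Exact zero is detected with an absolute tolerance of 1e-12;
values outside the layer range by more than a relative 1e-9 raise, since
that can only mean the caller is using stale stats. Orientation (which
endpoint is yellow) is a flag rather than a constant because published
figure conventions disagree; reversing the gradient and negating the values
commute, which is the property tests pin down. A constant layer maps
everything to the low endpoint. The colorblind-safe preset uses the
Okabe–Ito blue (0,114,178) / orange (230,159,0) pair. Score bins 0–10 map
linearly white → red with integer rounding.

## Distance-geometry clustering

Classical MDS (Torgerson scaling) on the per-time-point scalar distance
D_ij = |v_i(t) − v_j(t)|: B = −½·J·D²·J, eigendecomposition of the
symmetrized B, top three eigenpairs with negative eigenvalues truncated to
zero, coordinates V·√λ padded to three columns when n ≤ 3. Truncation
rather than an error on non-Euclidean input keeps the function usable for
arbitrary user-supplied metrics; for the scalar metric the truncation is
inactive because a 1-D configuration always embeds exactly, which is the
acceptance surface (distance recovery ≤ 1e-8 relative, not coordinate
equality). Determinism: eigenpairs sorted by descending eigenvalue, each
axis's sign fixed so its largest-magnitude coordinate is positive. Entities
with a missing value at t are excluded from the embedding and listed.

Change detection between consecutive time points uses |Δv| per entity with
both values present; the top-k list includes all ties at the cutoff (a tie
is information, not an artifact to break arbitrarily), with a deterministic
(−delta, entity-name) sort. Default k = 1 per layer.

## Correlation significance

Both routes are two-sided with df = n − 2, where n counts pairwise-complete
time points (pairs with n < 3 are skipped and logged). The Pearson rule
inverts the product-moment critical-value relation exactly,
r_crit = t_crit/√(t_crit²+df), instead of embedding a printed lookup table;
at df = 1, α = 0.05 this gives 0.99692…, i.e. the familiar three-decimal
0.997. The Spearman route computes average-rank correlation and
t = r√(n−2)/√(1−r²) with a Student-t p-value; |r| = 1 maps to p = 0 by
convention, and no tie correction is applied beyond average ranks. The two
routes agree at the boundary: r just below r_crit(n, α) has p > α and just
above has p < α (a tested invariant).

When a layer has no missing values the pair loop collapses to one matrix
correlation call per layer (`numpy.corrcoef` / `scipy.stats.spearmanr` on
the value matrix), which is what makes hundred-seed recovery runs cheap;
with missing values it falls back to per-pair pairwise-complete
computation. Constant vectors make correlation undefined, so they raise
(`ConstantVectorError`) in the scalar API and are skipped-and-counted in
the bulk API rather than silently scored 0.

Recurrence = significance on ≥ min_layers (default 2) layers. Per-layer
signs are retained and a `consistent_sign` flag computed; the positive/
negative filter keeps only pairs whose every counted record has that sign.
No multiple-testing correction is applied by default — these are screening
statistics over non-independent samples and are documented as such — but a
per-layer Benjamini–Hochberg option exists behind a flag.

Alphas are restricted to {0.10, 0.05, 0.02, 0.01} by default, with an
`alpha_free` escape hatch: fidelity to the offered menu by default, utility
on demand.

## Similarity scoring

The average scheme is the plain mean of non-missing values. The Wilson
scheme needs Bernoulli ratings from continuous values; how to threshold is
genuinely open, so it is an explicit parameter: a time point is a positive
rating iff its value strictly exceeds `positive_threshold` (default 0).
The default suits penetrance-style non-negative data where any nonzero
value means the phenotype is present; for signed data the caller should set
a meaningful threshold. The interval's ± is resolved to the minus branch
(it is a lower bound), z defaults to the α = 0.05 Gaussian quantile
(1.95996…), and p̂ = 0 returns exactly 0. The known failure mode is
documented by a test: a layer whose values are uniformly low but nonzero
saturates to p̂ = 1 everywhere, so the Wilson scheme ranks "true signal
within a layer" and must not be compared across layers.

Binning: floor(10·(raw − min)/(max − min)) clamped to [0, 10], computed
against the layer's own raw-score range; a degenerate range (all scores
equal) maps to bin 0. Floor, not round, so ties at bin edges are
deterministic; equal raw scores always get equal bins and colors.

## Synthetic generator

Trajectories are piecewise-linear plants plus i.i.d. Gaussian noise;
penetrance-style layers are clipped at zero. Non-planted entities sit at a
per-(layer, entity) uniform baseline. Planted structures:

* **Correlated pairs** share a monotone latent ramp (0 → amplitude); the
  partner is mirrored for negative plants. The noise weight starts at the
  layer noise level and is halved until the realized sample |r| reaches the
  pair's target, so a planted pair always clears the threshold it was
  planted for — the plant is a guarantee, not a tendency.
* **Step changes** add a constant from a given time index onward; the jump
  lands between index−1 and index.
* **Latent signals** are flat near zero until an onset index, then ramp to
  the amplitude — the "late-onset phenotype" pattern.
* **Rare layers** zero out a seeded random fraction of non-planted
  entities.

One random interaction topology is drawn and replicated on every layer,
matching designs where the same physical network is displayed per
measurement type. All draws come from one `numpy` Generator seeded by the
spec, so identical seeds give byte-identical files; plants live in the spec
and are therefore seed-independent.

Preset conditions: `esc_core` is 4 named layers × 3 time points
(day1/3/5), 30 entities, noise SD 0.05 against amplitude 10, two planted
recurrent pairs (one positive, one negative, target |r| = 0.999 — above
the 0.997 three-point threshold) and one step change of magnitude 8.
The 30-entity default is a realistic core-regulatory-network size; the
noise level is chosen so that three-point correlations are detectable at
all, which any n = 3 design requires. `mitotic_screen` is the seven named
phenotype layers × 90 half-hour points over 45 h, 1067 entities by
default (its published full-set size; tests use smaller counts purely as a
matter of runtime proportion, via the `n_entities` override),
penetrance-scaled (amplitude 1, baselines 0.02–0.25, clip at zero), with
the grape layer 70% sparse, one three-layer planted pair (target r = 0.6,
comfortably above r_crit(90, 0.05) ≈ 0.207), one mid-course step and one
late-onset latent signal. `n_time_points=50` gives a one-cell-cycle
window with the same 45 h span.

## Snapshot rendering

The contract is the draw manifest — positions, hex colors, sizes, edges,
cross-layer highlights — a pure function of (network, time point, options);
the PNG/SVG is a faithful projection of it, and tests compare manifests,
never pixels. Positions come from the distance-geometry embedding (first
two axes) when requested, else a fixed grid; entities without a usable
value at t are parked on a side strip. The top-change highlight at time t
covers the interval arriving at t (leaving it, for the first point).
2-D small multiples replace a 3-D stacked scene deliberately: the analytic
outputs are the contract and the renderer stays headless and testable.

## Problem sizes in the validation suite

Acceptance-style checks run at: 100 random point sets of up to 50 points
for distance recovery; 10,000 simulated Gaussian pairs per n ∈ {3, 10, 50}
for type-I calibration (3-standard-error band); 100 generator seeds of the
esc_core preset for planted-structure recovery (criterion ≥ 95 of 100).
These sizes make the Monte-Carlo bands tight relative to the effects
checked while keeping the whole suite in tens of seconds.

## Known limitations

* The correlation p-values treat time points as independent samples, which
  they are not; results are a first screen, and the package does not try to
  repair the statistics (dependence-aware measures are out of scope).
* The Wilson scheme's threshold convention is a declared default, not a
  universal rule; signed or baseline-shifted data need a caller-chosen
  threshold.
* The generator's Gaussian, piecewise-linear world lacks autocorrelated
  noise, batch effects and heteroscedasticity; passing recovery tests shows
  the pipeline is correct under its stated model, not that real screens are
  this clean.
* Classical MDS is one realization of "coordinates from a distance
  matrix"; other distance-geometry variants would differ in coordinates
  while agreeing in recovered distances, which is why distances are the
  only asserted quantity.
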