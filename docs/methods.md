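# Methods

This note records the models, parameter choices, numerical conventions and
known limitations of `ambytc`, in the order data flows through the
pipeline.

## Synthetic study generator

The generator emulates a two-species larval brain expression study: two
species (a paedomorphic axolotl line and a metamorphic tiger salamander
line), arrays at 42/56/70/84 dph with three replicate RNA pools per
species × day, qPCR extending to 28–98 dph, and ~11–20 probe pairs per
probe-set.  Every generator is a deterministic function of an explicit
integer seed; no global random state is used.

**Expression truth.**  Each gene's log2 trajectory is a quadratic of day,
parameterized on the interval-centred scale and stored uncentred.  Planted
classes are realized as:

* flat — b₁ = b₂ = 0;
* LU/LD — |b₁| set so the endpoint-to-endpoint change equals the effect
  size, b₂ = 0;
* QV/QC — curvature such that the vertex-to-endpoint depth equals the
  effect size, vertex uniform in the middle half of the interval;
* monotone quadratics (QLVU/QLCU/QLVD/QLCD) — curvature amplitude
  0.75 × effect with the vertex placed 1.5–1.8 half-ranges outside the
  interval.  The vertex margin matters: closer placements make the fitted
  vertex wander inside the interval under noise (misread as transient),
  while weaker curvature is indistinguishable from a line.  With these
  choices every class is identifiable at effects ≥ 4 × noise SD.

Before emitting, the generator classifies its own planted coefficients
with the same sign/vertex rule the analysis uses and asserts agreement, so
truth tables and classifier semantics cannot drift apart.  Baselines b₀
are uniform on 6–12 log2 units (intensities ~64–4096); species offsets are
added as constants (tiger-higher with probability 0.84 by default,
mirroring the asymmetry this design is meant to detect); a configurable
fraction of genes draws an independent profile in the second species
(species × time interaction).

**Noise model.**  Homoscedastic Gaussian on the log2 scale — the model the
downstream regressions assume.  The array literature for this chip
reports no noise or effect-size magnitudes, so the defaults are
calibration choices of this package: noise SD 0.25 log2 units and planted
effect 1.5 log2 units (~2.8-fold over the sampled range), which put
planted genes at 6σ — comfortably detectable with 12 observations but far
from trivial.  Residual variance about the planted trajectory converges to
the nominal noise variance (checked at n = 10⁴ within 5 %).

**Probe level.**  PM = 2^(target + affinity) + background, with per-probe
affinities N(0, 0.5) in log2 and additive optical background
N(50, 10) truncated positive; MM carries 0.3 × the specific signal plus
its own background draw, so probe-sets at background level have symmetric
PM/MM discrimination scores and are called absent.  Probe length is fixed
at 25 nt.  Only the relative PM/MM behaviour matters for the detection
surface; no scanner artifacts, spatial effects or 3′ degradation gradients
are simulated, so QC statistics on these data exercise the code paths but
cannot certify behaviour on physically degraded chips.

**Ortholog alignments.**  Probes are tiled along a source contig with
random 0–7 nt spacers; the partner sequence starts as a copy and receives
planted substitutions, single-base deletions (gap in the partner),
insertions (gap column in the source) and optionally a restricted
alignment span leaving probes uncovered.  The truth mismatch counts are
computed by a direct per-column walk, independent of the projection module
they test.

**qPCR.**  Ct = intercept − log2(template·2^expr)/log2(E) + noise, with a
gene-specific assay intercept shared across species and per gene × species
efficiencies E ∈ (1, 2].  A reference gene with flat, species-equal
expression is always included; plates are blocked by day with both
species present and two template-free control wells.  Note that with a
single cross-species calibrator, species-unequal efficiencies displace
the two species' ratio scales even for identical expression — exact
noiseless recovery therefore holds within the calibrator species, or
across species when the assay efficiencies are equal.

**Growth.**  SVL = species quadratic of day + N(0, 2 mm), 30 individuals
per species × day.  Defaults plant a larger, early-fast, decelerating
tiger salamander against a slowly accelerating axolotl, so the default
study realizes the fully species-distinct growth pattern (all six model
terms significant, R² ≈ 0.96).

## Preprocessing

**Normexp background correction.**  Per array, X = S + B with
S ~ Exp(1/θ), B ~ N(μ, σ²).  Parameters are estimated by method of
moments — θ = (m₃/2)^⅓ from the third central moment, σ² = var − θ²,
μ = mean − θ — which is simpler than the full MLE and adequate at fixture
scale; when the moment system is infeasible (non-positive skewness or
variance deficit, e.g. a constant array) the correction falls back to
subtracting (min − ε).  The posterior mean E[S | X = x] is evaluated with
the log-scale normal pdf/cdf ratio for stability; it is strictly positive
and increasing in x.  A property worth knowing: on data whose intensity
distribution is signal-dominated, the fitted θ absorbs the signal scale
and the nonlinear correction compresses log-ratios at low-to-mid
intensities — the familiar RMA fold-change attenuation.  The transformer
therefore exposes `background=` and `normalize=` switches; exact
round-trip and offset-recovery guarantees are stated for the pipeline with
background correction off, and the full default pipeline is verified to
preserve direction and most of the planted magnitude.

**Quantile normalization.**  Columns are mapped onto the mean of the
sorted columns; ties within a column receive the mean of the normalized
values their positions span, so sorted column vectors agree bitwise on
ties-free input.  Quantile normalization assumes most genes are unchanged
between arrays: offsets planted on a large fraction of genes, or on genes
at the extremes of the intensity distribution, are partially absorbed by
construction.

**Median polish.**  Alternating row/column median sweeps with effect
medians folded into the overall term; the summary per array is
overall + column effect.  Convergence is declared when the residuals
change by < 1e-12 between sweeps, with a cap of 1000 sweeps: even-sized
blocks approach their fixed point geometrically but can need more than
the textbook handful of iterations, and the cap is set so residual row
and column medians are ≤ 1e-9 on random blocks.  Single-probe blocks pass
through unchanged.

**Detection calls.**  Discrimination scores (PM − MM)/(PM + MM) tested
against τ = 0.015 by a one-sided Wilcoxon signed-rank test (zsplit zero
handling); present < 0.04 ≤ marginal < 0.06 ≤ absent.  Absent filtering
drops probe-sets absent on strictly more than 75 % of the arrays of the
matrix at hand, and is meant for the species-specific matrices; filtering
precedes all DEG screens.

**Three matrices.**  The pipeline produces species-specific matrices for
the within-species screens and a global matrix for the direct comparison;
`rma` is a pure function of its input (byte-identical on repeated calls,
equivariant under array reordering).

## Within-species screen

Quadratic OLS on centred days for numerical conditioning, coefficients
reported back on the raw-day scale.  The two-tier structure: the overall
F p-value (against intercept-only) feeds BH FDR at q = 0.05 and decides
*whether* a gene changes; coefficient t-tests at α₁ = 0.05 decide *how*
(profile shape).  Classification:

* screen failed → flat;
* b₂ not significant → LU/LD by the sign of the mean slope over the
  sampled interval, b₁ + b₂(t_lo + t_hi) — the raw-day b₁ alone is
  contaminated by the discarded curvature term and can carry the wrong
  sign;
* b₂ significant → vertex t* = −b₁/(2b₂): strictly inside the interval →
  QV (valley) / QC (peak); outside → monotone quadratic by direction
  (mean slope) and curvature sign.  The open interval is deliberate: a
  vertex on the boundary produces a monotone shape over the data.
* screen passed but neither coefficient individually significant (rare by
  construction): the coefficient with the larger |t| drives the shape,
  with a warning.

The fold filter computes per-day replicate-mean log2 values and passes a
gene when 2^|mean(day) − mean(42 dph)| ≥ 1.5 at any later day —
direction-agnostic, replicate means rather than pooled medians.  A gene is
a DEG iff FDR-rejected, fold-passing and non-flat.  The realized
false-discovery proportion among screen rejections averages ~0.04–0.05
under the default study conditions (q = 0.05 with ~90 % null genes).

Degenerate inputs: zero-variance responses are flagged, given overall
p = 1 and classified flat; exact (noiseless) fits get zero p-values on
non-zero coefficients so the noiseless limit classifies exactly.

## Cross-species comparison

The species-dummy design (intercept, S, T, ST, T², ST² on centred days)
is fit by the same vectorised OLS engine.  Backward selection follows the
"eliminate non-significant terms from significant models" reading: a full
model whose overall F p-value exceeds α returns the intercept-only null
outright — without this gate roughly one pure-noise gene in five retains
a spurious term (five terms at α = 0.05), which would be indistinguishable
from real species signal downstream.  Elimination then drops the least
significant removable term with p > α and refits; marginality freezes S
while any S×time interaction remains and T^k while T^(k+1) or ST^k
remains, while interactions themselves are freely removable (so an
ST²-only truth retains S, T and T² but sheds ST).  The intercept is never
removed.

Retention requires all four criteria; R² is evaluated on the full model —
a design choice where full versus reduced is genuinely open, resolved in
favour of the model the overall p-value tests.  The interspecies fold uses observed per-day
replicate means, not fitted values.  Swapping the dummy flips the signs of
S/ST/ST² and leaves the retained set unchanged.  Per retained gene the
screen reports which species is higher, and at which days — "higher at
all days" only when every day mean agrees in sign.

Heatmap computation: rows standardized to mean 0, sample SD 1 (ddof = 1;
constant rows become zeros with a warning), column distances |1 − r| over
genes, average-linkage agglomeration via scipy with its deterministic
lowest-index tie-break, leaf order and a Newick serialization with merge
heights as branch lengths.

## qPCR, enrichment, growth

Efficiencies come from OLS of Ct on log10(amount) over ≥ 3 dilution points
spanning ≥ 2 orders of magnitude; E = 10^(−1/slope), and a non-negative
slope is an error (no amplification).  Pfaffl ratios use
ΔCt = Ct(calibrator) − Ct(sample) per assay, calibrated to the mean
axolotl 28 dph Ct and normalized to the reference gene on the same pool;
with both efficiencies equal to 2 the ratio reduces to the classical
2^−ΔΔCt (identity holds to 1e-12).  Ratios are computed per replicate
pool, log2-transformed, and modelled by the cubic species-dummy GLM with
the same backward selection; "species-distinct profiles" means any
species term survives.  Reference-gene invariance is checked by a one-way
F-test across species × day cells — a failure warns rather than errors,
since a drifting reference biases ratios but does not invalidate the
arithmetic.

EASE scores are the hypergeometric upper tail with one observed list hit
removed (L ≤ 1 scores 1), which is conservative relative to the plain
Fisher tail for every L ≥ 1.  Enrichment keeps terms with ≥ 2 hits and
EASE p ≤ 0.05 against the annotated background (size 3728 by default, the
chip's human-orthologous complement); terms with identical hit sets are
collapsed to the smallest-background representative — a deterministic
stand-in for manual redundancy pruning; GO-graph-aware reduction is out of
scope.  Under random gene lists the scores are super-uniform.

The growth model is the quadratic species-dummy design fit to SVL records,
reporting per-term significance and R².

## Numerical engine

All per-gene fits share one vectorised OLS routine (normal equations with
a condition-number guard, t/F tails from scipy): the design matrix is
common across genes, so thousands of fits are a single matrix product.
statsmodels serves as the independent cross-check oracle in the test
suite, never as the implementation.  Noiseless fits (residual MSE below
1e-20) switch to exact inference (p = 0 for coefficients above 1e-8, else
1); zero-variance responses are flagged degenerate.  BH FDR is the
step-up procedure with monotone adjusted p-values, validated against a
brute-force oracle and statsmodels.

## Scale of the shipped analyses

The test suite and the acceptance script run at fixture scale — hundreds
to a few thousand genes per study, chosen as the smallest sizes at which
the stochastic properties (FDR control, recovery rates, clustering
separation) are stable across seeds.  All simulations derive from
explicit seeds and complete in well under a minute each.

## Known limitations

* The generator's noise is homoscedastic Gaussian in log2; real chips show
  intensity-dependent variance and spatial artifacts, so passing tests
  demonstrate correctness of the algorithms, not robustness to every
  physical failure mode.
* Normexp method-of-moments estimation is crude on signal-dominated
  distributions (see the attenuation note above); a full MLE normexp was
  not needed at fixture scale.
* The probe compatibility filter consumes precomputed pairwise alignments
  (paired gapped FASTA); it does not run an aligner, infer orthologs, or
  chain multi-HSP alignments — one best local alignment per pair, with the
  conservative uncovered-counts-as-mismatch rule.
* Cross-species Pfaffl ratios with species-specific efficiencies share a
  single calibrator; the induced scale displacement between species is a
  property of the design, not removed by the package.
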