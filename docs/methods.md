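# Methods

## Model and estimation

The neutral community model (NCM) used here is Sloan's continuous
approximation of neutral theory for microbial taxa. Each animal's rumen
community at one sampling day is treated as a local community of roughly
*N* individuals (here: mapped reads) connected to a shared metacommunity by
immigration. At stationarity the local relative abundance *x* of a taxon
with metacommunity abundance *p* follows Beta(*Nm·p*, *Nm·(1−p)*): large
*Nm* means immigration dominates drift and local abundances track the
metacommunity tightly; small *Nm* means drift dominates and abundances are
dispersed. A taxon is detected when *x* exceeds the detection limit
*d* = 1/*N* (one read), so its expected occurrence frequency across animals
is the Beta upper tail above *d*.

Per group-timepoint slice the package computes:

- *p_i*: pooled raw counts of SGB *i* over the slice's animals, divided by
  the slice total. SGBs with zero counts in the slice carry no abundance
  information and are dropped from the fit set (recorded in `dropped`).
- *F_i*: fraction of animals with count ≥ 1. The ≥ 1 rule is the minimal
  defensible detection threshold on raw counts. SGBs with *F_i* = 1 are
  retained — the model predicts *F̂* < 1, so full occupancy can signal
  positive selection.
- *N*: arithmetic mean of per-sample totals; *d* = 1/*N*, held fixed while
  fitting.
- *Nm*: minimizer of Σ(*F_i* − *F̂_i*)², found by Levenberg–Marquardt on
  log(*Nm*) (positivity implicit, well-conditioned scale) from four starts
  log *Nm* ∈ {2, 4, 6, 8}, best SSE kept; a bounded scalar search is the
  fallback if every LM start fails. Observations are unbinned (one residual
  per SGB).
- R²: 1 − SS_res/SS_tot, not clamped; a negative value (model worse than
  the mean frequency) is reported with a warning, and R² is undefined (NaN,
  with warning) when all observed frequencies are equal.

## Selection partitioning

The 95% band around each predicted frequency is the Wilson score interval
with point value *F̂_i* and *n* = number of animals in the slice (the
observed frequency is a proportion over animals; the Wilson form remains
sensible near 0 and 1 where most SGBs sit). Classification uses strict
inequalities — *F_i* above the upper bound is "above" (positive selection),
below the lower bound "below" (negative selection), anything else,
including exact ties, "neutral".

Two numerical details matter at the edges. In exact arithmetic the Wilson
upper bound equals 1 exactly when *F̂* = 1 (and the lower bound 0 at
*F̂* = 0), but in double precision it lands one ulp inside; bounds within
1e-12 of the edge are snapped to it so fully occupied, fully predicted taxa
compare as ties rather than exceedances. Second, with *n* = 10 animals the
partition rule is intrinsically aggressive near saturation: a taxon with
true *F̂* ∈ (≈0.8, 1) is observed at *F* = 1 with probability *F̂*ⁿ and is
then always "above", because the Wilson upper bound is strictly below 1 for
any *F̂* < 1. Under pure neutrality this places roughly 15–25% of taxa in
the "above" partition (depending on where the abundance distribution puts
its mass relative to *d*); users should read partition proportions as
relative, between-group evidence rather than absolute selection rates.

## Bootstrap and pooling

Uncertainty in *Nm* and R² is estimated by resampling animals (columns)
with replacement, B = 1000 by default, recomputing *p*, *F*, *N*, *d* from
each resample and refitting (replicates warm-start from the point
estimate). Replicates with fewer than `min_sgb` fittable SGBs or failed
convergence are dropped and counted; an undefined R² on a replicate drops
only the R² stream. More than 20% failures flags the result unreliable.
CIs are percentile (2.5/97.5), SE is the replicate standard deviation.
Because resampling 10 animals with replacement leaves ~6.3 distinct
animals, occupancy in a resample is more extreme than in the original
slice and replicate *Nm* values sit systematically above the point
estimate; the percentile CI therefore reflects resampling variability
around a shifted center and should not be read as bias-corrected.

Per-group pooling across sampling days uses DerSimonian–Laird
random-effects meta-analysis: weights 1/*v_k*, Q-statistic heterogeneity,
τ² = max(0, (Q − (K−1)) / (Σw − Σw²/Σw)), random-effects weights
1/(*v_k* + τ²), normal-theory 95% CI. DL is the classical closed-form
estimator; iterative alternatives (REML, Paule–Mandel) are out of scope and
the method tag records the choice. *Nm* is pooled on the natural-log scale
(variance = variance of log replicates) and exponentiated for reporting;
R² is pooled on the linear scale with the reported CI clipped at 1.

## Compositional statistics

CLR uses log base 2 — per sample, log₂(count + pseudocount) centered by the
sample mean — so a between-group difference of mean CLR values is directly
a log2 fold change. The pseudocount defaults to 1 (configurable; 0 is
allowed on zero-free matrices, where the transform is exactly
scale-invariant). Aitchison distance is the Euclidean distance between CLR
sample vectors. `clr_log2fc` reports per-feature mean CLR differences
(group2 − group1, reference = lexicographically first level unless given)
with stratified percentile-bootstrap 95% CIs resampling samples within
group; `block_by_animal=True` resamples whole animals instead, respecting
the repeated-measures design. The reported interval is widened, if needed,
to include the point estimate.

## CBM architecture profiling

Architecture strings are split on `+` and `|`; `-` is split only when every
fragment looks like a complete domain token (letters + family digits,
optional `_subfamily`), since hyphens also appear inside annotation labels.
Tokens are classified by prefix: `CBM*` → CBM; `GH/PL/CE/AA` + family
number → catalytic (GT is excluded by default as non-degradative,
toggleable); anything else → other. A "CBM-associated catalytic enzyme
structure" is a protein carrying ≥ 1 CBM and ≥ 1 catalytic domain, counted
once per protein regardless of order — the conservative reading of a
per-genome bar count; an adjacency-pair count (CBM token directly next to a
catalytic token) is reported alongside for the stricter reading. Tandem
runs are maximal stretches of consecutive CBM tokens (default min length 2).
Group comparisons report median and IQR of per-genome structure counts,
fold-difference of medians and a two-sided Mann–Whitney U test; counts are
not normalized by genome completeness.

## Synthetic-data generator

The generator emulates the motivating study design: 2 feed-efficiency
groups × 4 sampling days × 10 animals (5 forage-fed, 5 grain-fed per
group), animals persisting across days. Metacommunity abundances are
lognormal(0, σ = 2) normalized — a long-tailed SGB profile; per animal and
SGB, local relative abundance is an independent Beta(*Nm·p*, *Nm·(1−p)*)
draw renormalized within the animal (the fitted model treats SGBs
independently, so exact multivariate neutrality is not required); library
size is Poisson(depth_mean = 1e5, the middle of the realistic 1e4–1e6
range) and reads are multinomial. Default group *Nm* values (1.1e5 HFE /
1.35e5 LFE) match the scale reported for real rumen metatranscriptomes.
Selection is injected by construction: positively selected taxa are drawn
from the bottom abundance tercile and forced present in every animal;
negatively selected taxa are drawn from mid-abundance taxa (capped so that
zeroing them moves any sample depth by well under 1%) and zeroed in a
random ≥ 60% majority of animals. Injected taxa are concentrated in a
designated genus so genus-level summaries are testable. All randomness
flows through one seeded `numpy.random.Generator`.

What the generator does **not** emulate: taxon-taxon correlations,
overdispersion beyond the Beta law, diet effects on composition (diet
labels are design metadata only), day-to-day autocorrelation within an
animal beyond the shared metacommunity, and chimeric/contaminant SGBs.
Passing tests therefore demonstrate correctness of the estimation machinery
under the model's own assumptions plus read sampling — not robustness to
every feature of real data.

## Known limitations

- **Upward bias of fitted Nm under read sampling.** The model detects a
  taxon when *x* > *d*; sequencing detects it with probability
  ≈ 1 − e^(−*x*/*d*). This smoothing inflates detection of rare taxa
  relative to the hard threshold, and the fit absorbs it by raising *Nm*:
  in recovery simulations (2000 SGBs, 10 animals, 1e5 reads) the median
  fitted/true ratio is ≈ 1.19 at *Nm* = 1e3, ≈ 1.36 at 1e4 and ≈ 1.20 at
  1e5; estimating *p* from pooled counts (errors-in-variables) contributes
  part of this. Fitting model-consistent data (hard-threshold detection,
  true *p*) recovers *Nm* within a few percent, isolating the cause.
  Between-group comparisons at a common depth are ordered correctly
  (ordered-recovery simulations succeed), but absolute *Nm* values should
  be read with this bias in mind.
- **Percentile bootstrap CIs do not correct that bias** (see above); under
  the generator they often exclude the true *Nm* even when the fit is
  working as designed.
- The partition rule's behavior near full occupancy (see Selection
  partitioning) means "above" fractions are non-zero under pure
  neutrality at small animal counts.

## Problem sizes used in checks

End-to-end statistical checks run at reduced but representative sizes
chosen for single-CPU runtimes: recovery and neutral-coverage grids at
2000 SGBs × 10 animals × 20 seeds; selection detection at 2000 SGBs ×
10 seeds; bootstrap coverage at 500 SGBs with B = 200 over 25 slices;
ordered-group studies at 600 SGBs with B = 40 over 10 seeds; CBM fuzzing
at 10,000 random architectures.
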