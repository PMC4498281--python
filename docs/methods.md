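# Methods

This note documents the models, parameters and design decisions behind the
package, the way the synthetic data emulate the real study design, and what
the passing tests do and do not establish.

## Study design and data model

The target experiment is a five-point time course — germinated seeds at
radicle protrusion (0 h control) and after 2, 12, 24 and 72 h of incubation
in 10 µM ABA — with three biological replicates per time point, measured on
expression arrays and RMA-normalized to a log2 scale. The package consumes
that normalized matrix; normalization itself, probe summarization and any
array-level modeling are out of scope.

All values below 4 are raised to 4 before analysis ("floor transform"),
because near that level array signal is dominated by background and
fold changes computed against it are noise. Flooring is idempotent and is
applied after the (synthetic) noise, matching the position of the transform
in the real workflow — downstream of normalization, upstream of contrasts.

## Synthetic data generator

The generator plants the structure the analysis is supposed to find:

- **Classes.** `ER_up`/`ER_down`: a step of ±`amplitude_log2` completed at
  the first treated time point (2 h) and held; `LR_up`/`LR_down`: a ramp
  ±amplitude · log(1+t)/log(1+t_max) (log-time interpolation produces the
  gradual monotone profiles that remain distinguishable from the step at a
  0.97 correlation resolution); `flat`: baseline only.
- **Noise model.** Each gene draws a profile jitter (SD `shape_jitter_sd`,
  default 0.02) once, shared across replicates — it represents gene
  identity and sets the within-class correlation below 1 with a single
  knob. Replicate noise (SD `noise_sd_log2`, default 0.25) is i.i.d. per
  observation. The real arrays' noise level is unknown; these defaults are
  calibration knobs chosen to give realistic within-class correlations
  (median within-block r ≈ 0.99 on replicate means), not estimates.
- **Defaults.** 600 genes; baseline 7.0 log2; amplitude 4.0 log2; floor
  4.0; class fractions ER_up 0.25, ER_down 0.15, LR_up 0.15, LR_down 0.10,
  flat 0.35. The fractions were chosen once so that the responsive blocks
  are large enough for the 100-hub cut to fall inside the largest block
  while a substantial flat background exercises the DEG gate's
  specificity. Planted sets: `regulon` (40 % of ER_up), `lea` (25 % of
  ER_up), `tf` (30 % of LR_up) — nested in responsive blocks the way the
  real regulon/LEA/TF lists concentrate in network regions.

With the default baseline (7.0) and amplitude (4.0), down-regulated
classes hit the floor (7 − 4 = 3 → 4), so their realized effect size is
−3 log2 rather than −4 — exactly as a floored array matrix would behave.
They still clear the |log2FC| ≥ 2 gate. Tests asserting the *exact*
amplitude therefore use a baseline clear of the floor (9.0).

What the generator does **not** emulate: probe-level effects, intensity-
dependent variance, correlated noise between genes outside the planted
blocks, partially overlapping or leaky modules, and the long tail of small
effect sizes in real data. Passing recovery tests therefore show the
pipeline is correct and well-calibrated under its own assumptions, not
that real arrays would yield equally clean networks.

## Replicate screening

The PCA overview reports the variance spectrum of gene-centered data
(how much PC1 explains, etc.). Outlier flagging itself deliberately does
not use per-component scores: the leading components separate time
points, so a global score rule flags entire (correct) time groups, and
even group-centered scores are heteroscedastic — flooring clips
replicate noise on strongly down-regulated genes in treated samples,
and PC1 weights exactly those genes, making the control group's PC
spread systematically larger.

Instead, each sample's replicate deviation is the Euclidean distance to
the per-gene median of its time-point group, computed over genes whose
values stay strictly above the floor in every sample (removing the
clip-induced heteroscedasticity at its source). The group median keeps a
gross outlier from dragging its replicate mates over the threshold. A
sample is flagged when the robust z (median/MAD over all samples) of its
deviation exceeds 3. A replicate shifted globally by as little as
0.5 log2 units is flagged; coherent groups and zero-variance data are
not. The rule is this package's operationalization — the original
workflow reports an outlier replicate without stating its test.

## DEG calling

Per gene, a one-way fixed-effects model over the time-point groups:
log2FC(t) = x̄(t) − x̄(0); t statistic on the pooled residual variance of
all groups, df = n − k; two-sided p. With exactly two groups this reduces
to the classic pooled t test (tested to 1e-10). Thresholds are inclusive
(|log2FC| ≥ 2.0 on the log2 scale, P ≤ 0.01) and no across-gene
multiplicity correction is applied at this stage, matching the reference
workflow's stated rule; the fold-change threshold is a config knob because
"fold change of 2.0 on a log2 scale" admits two readings (we take the
parenthetical as binding: a log2 difference of 2, i.e. 4-fold).

An optional moderated variant shrinks the per-gene variance toward the
median variance with 4 pseudo-degrees of freedom (fixed-prior shrinkage).
It is off by default: the plain model is transparent, exact under
normality (type-I error at P ≤ 0.01 verified within the 99 % binomial
interval on 20,000 null genes), and sufficient at three replicates with
the large planted effects.

Zero pooled variance (constant gene) yields p = 1 at zero fold change and
p = 0 otherwise, with a logged warning.

## Network

Pearson correlations are computed by default on per-time-point
replicate-mean profiles (five points). A 0.97 cutoff on replicate-level
vectors would be far sparser — replicate noise attenuates r — and the
reference analysis reports a dense, fully connected network, so replicate
means are the default and `all_samples` is retained for sensitivity
analysis. "Above a threshold" is implemented strictly (r > 0.97); signed
r is the default (`positive` mode) with an `absolute` mode available,
since published single-component networks containing both rising and
falling genes leave sign handling underdetermined. Zero-variance genes
are excluded with a warning. Degree is the only centrality; the top-100
cut breaks ties by gene id so the hub list is deterministic.

On synthetic defaults the four responsive blocks are four near-cliques:
the network has four components, not one. A single connected component in
real data reflects correlation structure (e.g. genes bridging patterns)
that the generator deliberately does not plant.

## SOM and regions

Gene profiles are standardized per gene (mean 0, SD 1 over time points;
zero-variance profiles map to the zero vector). A 2 × 3 rectangular
Kohonen map is trained online: best-matching unit by Euclidean distance,
Gaussian neighborhood on the grid, learning rate 0.5 → 0.01 and radius
1.5 → 0.25 decaying linearly over 200 epochs. The codebook is initialized
by seeded farthest-point sampling of input vectors, and for maps of ≤ 8
units the seeds are arranged so similar vectors occupy adjacent units
(exact minimization over permutations) — this avoids collapsed clusters
when cluster count equals unit count. Presentation order is drawn from
the same seeded generator, so the processing order is part of the seed
contract: identical seed, identical codebook.

A geometric caveat established while validating the trainer: six z-scored
patterns that span only two dimensions of profile space necessarily lie
on a circle, and a 2 × 3 sheet tiling a hollow ring starves its middle
unit — no trainer parameters avoid it. Six-pattern recovery at purity 1.0
requires patterns spreading over a genuine two-parameter family, which is
how the test toy is built (step × ramp × transient-pulse mixtures). On
the pipeline's actual input (network genes, four planted classes, six
units) bin-vs-class purity is 1.0 across seeds.

The SOM is trained on the network genes (the DEGs), as in the reference
workflow: flat genes never reach it. Region labels: per bin, earliness
E = |x̄(2 h) − x̄(0 h)| / (max − min) of the bin's mean member profile
(computed from the expression matrix; E is scale-invariant). E ≥ 0.5 →
ER, else LR; zero dynamic range → none. On the (0, 2, 12, 24, 72) h grid
the pure step gives E = 1 and the log ramp E = log 3 / log 73 ≈ 0.256,
so the 0.5 cut separates them with a wide margin. The published region
boundary was drawn visually; this rule is our operationalization.

## Enrichment

All over-representation uses the one-sided hypergeometric upper tail
P(X ≥ k) (scipy's log-space implementation; verified against exact
integer enumeration to < 1e-10 for every parameter combination with
N ≤ 60). ORA tests every category with ≥ 1 selected member against the
whole-matrix universe (GeneTrail convention; configurable), applies
Bonferroni across tested categories (α = 0.05) and reports both
observed/expected and expected/observed ratios — published figure legends
use the two directions interchangeably, so both are emitted with explicit
labels. Hub enrichment takes the network nodes as universe and the hubs
as selection, at P < 0.01 without multiplicity correction by default
(few sets are tested there); Bonferroni is available. The exact test
behind the published hub-enrichment claim is unstated; hypergeometric is
the canonical choice and is documented as ours. Semantic-similarity
pruning of redundant categories is replaced by an optional rule that
drops categories whose member list is a subset of a strictly more
significant category (off by default).

## Pipeline and determinism

`run_pipeline` executes floor → QC → contrasts → DEG → correlation →
network → degrees/hubs/components → SOM → regions → overlays → enrichment
→ exports, aborting with the stage name on failure. One master seed fans
out to per-stage seeds via `numpy.random.SeedSequence(seed).generate_state(2)`
(synthetic, SOM), each reduced mod 2³¹. All writers sort their output;
the JSON run report excludes volatile fields (timings are logged, and the
output directory is not echoed), so identical config + seed gives
byte-identical files anywhere.

## Problem sizes

The shipped study conditions are 600 genes × 15 samples for structural
analyses (giving ~390-node networks, comparable in density to the real
~1000-node network) and 20,000 genes for the null/type-I simulation —
the real array's gene count at the one stage where scale matters
statistically. The hypergeometric validation enumerates every universe up
to N = 60 exactly.

## Known limitations

- The DEG model assumes equal variance across time-point groups per gene.
- The hard 0.97 threshold makes the network topology sensitive to the
  correlation basis; only degree centrality is computed.
- SOM bin identity (which unit gets which pattern) is seed-dependent;
  only the pattern content and the derived ER/LR labels are stable.
- The ER/LR rule reduces each bin to one earliness number; bins mixing
  early and late members (not planted here, possible in real data) would
  be labeled by their average behavior.
- Real-data reproduction requires the deposited arrays and a pinned
  normalization stack, and is out of scope by design.
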