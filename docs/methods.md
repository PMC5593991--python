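# Methods

This note documents the statistical models implemented in `dimorph`,
the choices made where the procedures admit more than one reasonable
reading, and what the synthetic-data generator does and does not
emulate.

## Differential-expression screen

### Preprocessing

Arrays are quantile normalized: every column is mapped onto the row-wise
mean of the sorted columns, with an average-tie rule, preserving
within-column ranks.  Main-experiment and replication arrays were
hybridized and scanned separately, so normalization is applied per
batch.  The low-signal filter keeps probes whose intensity exceeds the
per-array background quantile (default 0.10) in at least a fraction
(default 0.5) of the arrays; both thresholds are exposed because the
source procedure names the step but not its parameters.  The filter log
records probe counts in/out so the screen's accounting is auditable.

### Technical covariate

Single-channel array studies of this size routinely show a first
principal component dominated by hybridization/scanner batch rather than
biology.  PC1 scores are the first right-singular-vector projection of
the probe-centred main-experiment matrix (sign fixed so the first
sample's score is non-negative).  The replication batch receives no PC1
term: the covariate is defined on, and only meaningful for, the 16
original arrays.

### Per-probe models and moderation

Two treatment-coded OLS models are fitted per probe on log₂ values —
`Sex + Diet + Stress` (A) and `PC1 + Sex + Diet + Stress` (B) — with
reference levels Sex = F, Diet = CTRL, Stress = none, so coefficients
read M vs F, LPD vs CTRL, swim vs none.  Empirical-Bayes moderation
follows the standard microarray treatment: (d₀, s₀²) are estimated by
matching the first two moments of log s² against the log
scaled-inverse-χ² distribution (digamma/trigamma inversion, Newton
iterations); s̃² = (d₀s₀² + d·s²)/(d₀ + d); moderated t is referred to a
t distribution on d₀ + d df (capped at the pooled df).  If the observed
spread of log s² does not exceed its sampling noise, d₀ is reported
infinite and every probe gets s̃² = s₀².  The B-statistic (log posterior
odds of differential expression) uses a prior DE proportion p_de = 0.01
— a conventional default; only the ranking it induces is consumed — and
a prior coefficient variance estimated from the top tail of the
moderated t-statistics (the estimate is clipped to coefficient-scale
standard deviations in [0.1, 4]).  The implementation is verified to
machine precision against the reference empirical-Bayes implementation
in the test suite.

### Consensus and replication validation

Candidates are the intersection of the top-K probes of models A and B,
ranked by descending B for the stress coefficient with deterministic
tie-breaks (p ascending, then probe id).  The screen targets the acute
stress response, so the stress coefficient is the default ranking
coefficient; any other coefficient can be named.  A candidate is
validated when the replication fit — the same moderated machinery run on
the replication batch with a `Diet + Stress` design (all replication
animals are male) — gives p < α_rep (default 0.1) with the same log₂
fold-change sign as the main model-B estimate; sign 0 matches nothing.
Under the null this passes about α_rep/2 of candidates (p below 0.1,
times a 1/2 chance of sign agreement).  Replication p-values come from
the replication fit's own moderation rather than ordinary t, for
consistent treatment of the two batches.  One consequence worth knowing:
because a probe's true variance is shared between batches, moderation
couples the two fits — probes selected for extreme moderated t in the
main batch are mildly enriched for small moderated replication p (the
conditional pass rate runs ≈ 0.125 rather than 0.10 at the simulator's
variance prior), so the null validated fraction sits 1–2 points above
α_rep/2.  Ordinary replication t-tests would be exactly calibrated
conditionally but were not adopted, to keep the two batches under the
same moderated treatment.

## Consensus peaks

Support is counted base-wise with a boundary sweep (O(total intervals ·
log) per contig): the consensus rule reads "m samples simultaneously
overlap", taken in its strictest form — every base of a consensus region
is covered by calls from at least m distinct samples.  Overlap
thresholds are 1 bp both for support and for input exclusion; a
candidate intersecting any input-control interval by ≥ 1 bp is reported
in the `excluded` set rather than silently dropped.  Coordinates are
0-based half-open throughout.  Adjacent runs separated by sub-threshold
gaps are not merged by default (`merge_gap = 0`), since no gap parameter
is part of the rule; raising m never adds consensus bases, and m = 1
reproduces the merged union minus input overlaps.  An alternative
seed-peak/reciprocal-overlap reading of "overlapping calls" exists; the
base-wise reading was chosen because it is parameter-free and
order-independent.

## CpG methylation

Percent methylation is analysed on the raw percent scale (the scale on
which results are displayed and effects stated); values are clamped to
[0, 100] at generation only — no logit transform, since all assays here
sit at low-to-moderate methylation where the percent scale is
near-linear.  Each assay is fitted with

    pct ~ Sex + Diet + Sex:Diet + CpG  +  (1 | animal)

by REML (statsmodels MixedLM, default optimizer; the random intercept
induces compound symmetry across an animal's CpGs).  CpG enters as a
fixed effect by default and can be dropped.  Term F-tests are Wald
contrasts on the fixed effects with containment denominator df:
between-animal terms on n_animals − 4 df, the CpG term on
N − n_animals − (n_CpG − 1) df.  Satterthwaite df would be an
alternative; containment was chosen because it is deterministic,
closed-form, and exact for the balanced designs generated here (the
between-animal F-tests then equal the two-way ANOVA on per-animal CpG
means, which the tests verify).  With a single CpG the two variance
components are not separately identifiable and the fit reduces to the
factorial GLM on per-animal values, flagged `singular`.  Post-hoc
contrasts are within-sex LPD − CTRL differences of model cell means with
Bonferroni correction over the declared contrasts.  Retrotransposon
assays (B1, IAP) are checked with the shared factorial GLM on per-animal
means.

## qPCR

ΔCt normalizes each target against the arithmetic mean of the two
housekeeping Cts — the geometric mean of expression, the standard
multi-reference-gene practice; the source names two reference genes but
not the aggregation rule.  Fold change is 2^−(ΔCt − reference mean ΔCt)
per gene within each brain region; the reference group defaults to the
control-diet animals of the region, which makes control marginal means
hover near (not exactly at) 1, matching how such tables are reported.
The exact baseline used in the original tables is not recoverable and is
not asserted.  Statistics run on the fold-change scale by default
(matching the reported marginal means), with a `log2` option; analysis
on log₂ fold changes is algebraically identical to analysis on negated,
reference-centred ΔCt, which the tests confirm numerically.  The
pipeline is invariant to a global Ct offset.  No amplification-efficiency
correction is applied.

## Shared statistics

"Generalized linear model (normal, identity)" is ordinary least squares
with Wald/F tests — exactly that model family, with no IRLS machinery.
Designs use sum-to-zero coding, so each term's coefficient-block F-test
is the Type-III-style test matching estimated-marginal-mean semantics in
unbalanced data.  EMMs are model predictions averaged over the other
factors with pooled residual SE; in balanced designs they equal raw
cell/marginal means.

Newman-Keuls orders the cell means and tests the span-r pair with
q = diff / √(MSE/n_h) against the studentized-range quantile
q(α, r, df_error), computed numerically from the range distribution
(`scipy.stats.studentized_range`); published q tables are used only as
test oracles.  Pairs enclosed by a non-significant span are blocked
without testing.  Unequal cell sizes use the harmonic mean of the two
cells compared.  Interaction-cell comparisons use the pooled residual
error term.

The repeated-measures ANOVA is the classic split-plot decomposition:
between-group effects tested against subjects-within-groups, the within
factor and its interaction against the within-subject residual.  No
sphericity correction is applied (uncorrected df are what such growth
curves conventionally report); with one within level the analysis
reduces to the between-groups GLM.  A 58-subject, 4-group, 7-time-point
layout yields the structural df (3, 54), (6, 324) and (18, 324).

## Synthetic-data generator

All generators are pure functions of configuration plus a seed (one
`numpy` Generator per call, no global state) and emit truth tables
sufficient to score recovery downstream.

**Expression.** 16 main arrays (2 per Sex × Diet × Stress cell, each the
average of a 2-animal pool, which halves the biological variance) plus 8
male-only replication arrays.  Probe baselines are N(8, 1.5²) log₂
units; per-probe technical variances follow a scaled inverse-χ² law with
d₀ = 4 and s₀² = 0.04 (residual spreads typical of replicate
single-channel arrays), so the downstream moderation sees its own
generative model — with the batch and biology switched off, probe sample
variances over the 16 arrays divided by s₀² are F(15, 4)-distributed,
which a KS test verifies.  The technical batch is a rank-1 term
(per-array N(0,1) score × per-probe loading) whose share of per-probe
technical variance defaults to 0.40, making PC1 the technical axis by
construction with a controllable ground truth; the main and replication
batches draw independent loading vectors, since the replication arrays
were hybridized and scanned on different equipment in a different lab
and share no technical axis with the originals.  Animal-level biological
sd defaults to 0.1.  Spiked probes emulate immediate-early genes, which
are robustly expressed, so their baselines are reflected above the
baseline mean; spike-ins placed at array-background intensities would
measure the low-signal filter rather than the screen.  Optional "dead"
probes (baseline at the noise floor) exercise that filter explicitly.

**Peaks.** Each replicate carries each true locus with probability
`presence_prob`, boundaries jittered N(0, jitter_sd) and clamped at 0
(a jitter inverting an interval is truncated to width ≥ 1); Poisson
noise peaks arrive per Mb on a declared toy contig.

**Methylation.** Per-(animal, assay) random intercepts induce the
within-animal correlation; the Sex × Diet interaction (+3% in LPD
females by default) is confined to the intron assays; values clamp to
[0, 100].  Animal and residual sds default to 1.5 each, calibrated so
the designed experiment (n = 12/cell, 5 CpGs) has ≈ 85% power for the
+3% interaction — the signal-to-noise regime implied by the interaction
F statistics such designs report; larger noise (2.0/2.0) would put the
same design near 65% power.

**qPCR / behavior.** Housekeeping Cts vary around fixed means with small
sd; target shifts are declared per (gene, factor, level) in cycles.
Behavioral responses are Gaussian with declared Sex × Diet cell means.

**What the generator does not emulate.** No probe sequences or
hybridization chemistry (no intensity-dependent dye or GC effects), no
read-level ChIP or bisulfite data, no litter structure or maternal
covariates, no qPCR efficiency curves, and technical batch is strictly
rank-1.  Passing tests therefore demonstrate that the statistical
machinery is correct and well calibrated under the stated noise models —
not that real arrays meet those models.

## Problem sizes and determinism

The analysis chain itself is deterministic given its inputs.  Simulation
sizes used by the test suite and the acceptance script: 50 null and 5
spiked screens at 60,000 probes × 24 arrays; 200 + 100 methylation
experiments; 100 random consensus instances of ≤ 10 kb; 200 behavioral
experiments — sizes chosen so Monte-Carlo error is small relative to the
margins being checked.
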