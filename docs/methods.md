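# Methods

This note documents the models, parameter choices and limitations of
`homeobias`. Nothing here reports an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Study design emulated by the generator

The synthetic experiment mirrors a five-group comparison of
allopolyploids with their diploid progenitors: two diploid groups
(`Cg2`, `Co2`), two resynthesized allotetraploid groups (`Sd`,
whole-genome-duplication-first, and `Sh`, hybridization-first) and one
natural allotetraploid group (`Cbp`), with six lines per group and one
RNA individual per line, one tissue per run.

Per-gene baseline expression is log-normal: the Cg parent's two-copy
expectation is 2^μ_g with μ_g ~ N(`baseline_log2_mean` = 5,
`baseline_log2_sd` = 2); the Co parent differs by δ_g, which is 0 with
probability 1 − `parental_divergence_prob` (default 0.3) and otherwise
N(0, `parental_divergence_sd` = 1) in log2 units.

**Copy-number blocks.** Each allotetraploid individual draws, per
chromosome, a Poisson(`breakpoint_rate` = 0.833) number of
homoeologous-exchange breakpoints at uniform positions. The segment
touching one (randomly chosen) chromosome end keeps the balanced state
2 (cg copies out of 4; co copies are the complement), and each
subsequent segment draws uniformly from the other four states. Anchoring
one end at 2:2 reflects that exchanges perturb a balanced baseline; at
the default rate it yields roughly 30 % of gene–individual pairs with
unbalanced homoeolog content, the regime the package targets. The true
post-meiotic distribution of segment states is unknown; the uniform
draw is a testbed, not an inference.

**Regulatory effects.** Fractions of genes are flagged for ELD
(`eld_fraction`), TRE (`tre_fraction` = 0.013) and homoeolog expression
loss (`loss_fraction` = 0.01). ELD genes are forced to a detectable
parental gap (|δ| ≥ `eld_min_divergence` = 1.5). The `eld_scenario`
switch decides how flagged genes achieve dominance:

- `trans_driven` — the EL-recessive homoeolog's per-copy expectation is
  moved fully to the dominant parent's level (complete ELD); the
  dominant homoeolog is untouched.
- `copy_driven` — no regulatory shift; flagged genes instead carry a
  consistent 3:1 dosage toward the higher-expressed parent in every
  individual. Dosage can only hold the total within the 2× band of the
  *higher* parent (3:1 of the lower parent's homoeolog still matches the
  higher parent), so the dominant side is the higher parent by
  construction. These focal states are part of the copy-state truth but
  not of the block-breakpoint truth.
- `random` — both homoeologs receive independent
  N(0, `random_effect_sd` = 1.5) log2 shifts; dominance emerges by
  chance. Shifting one homoeolog fully to the other's level would be
  indistinguishable from `trans_driven` in the fold-change diagnostic,
  which is why symmetric independent shifts model the
  "stochastic mechanism" scenario.

TRE genes move the whole gene `tre_log2_effect` = 2 log2 units beyond
the extreme parent. Loss genes multiply one homoeolog's expectation by
`loss_multiplier` = 1e−4 in every allotetraploid individual — small
enough that the silenced residual sits well below the 0.5-CPM detection
bound at desk-scale transcriptome sizes (the average gene's CPM is
10⁶/n_genes, so with a few thousand simulated genes a 10⁻³ residual
would straddle the bound), yet non-zero so that CPM thresholds rather
than structural zeros drive detection. Loss genes draw their baseline
one log2 unit above the global mean so the eligibility screen (diploid
CPM > 5) usually passes.

**Counts and phasing.** Homoeolog expectations scale with copies/2 and
the regulatory multipliers, are normalized to a lognormal library size
(`library_size_mean` = 1e7 for diploids, ×1.8 for tetraploids, CV 0.1)
and read out as negative binomial counts via a gamma–Poisson mixture
(`nb_dispersion` = 0.05). The default depth is chosen so the loss
rule's two CPM thresholds correspond to read counts that sampling noise
cannot straddle. Phasing is binomial thinning at `phasing_efficiency`
(default 0.5, matching the ~45–55 % achievable with diagnostic SNPs);
the remainder is "unassigned", so cg + co + unassigned reconstructs the
unphased count exactly.

What the generator does **not** emulate: mapping or phasing bias between
subgenomes, correlated expression between neighbouring genes, shared
exchange breakpoints between related individuals, tissue effects within
a run, or cis/trans interactions beyond the three stylized scenarios.
Passing recovery tests therefore demonstrates correctness of the
estimators under the stated noise model, not performance on real reads.

## Normalization and differential expression

CPM, strict-threshold expression filtering (CPM > 1 in ≥ 2 samples),
TMM normalization (30 % M-trim, 5 % A-trim, precision-weighted,
reference = sample with upper quartile closest to the mean; factors
rescaled to geometric mean 1) and exact without-replacement
downsampling (multivariate hypergeometric per sample) follow the
field's standard definitions; the TMM implementation is cross-checked
against an independent reference implementation in the test suite.

Differential expression fits, per gene, a one-factor NB GLM with log
link and offsets log(library × TMM factor). Dispersions are pooled
method-of-moments estimates shrunk toward an abundance-trended running
median with 20 prior degrees of freedom, clamped to [1e−4, 10]. The
test statistic is a quasi-likelihood F ratio: (null deviance − full
deviance) over the full-model deviance per residual degree of freedom,
referred to F(1, n−2). This is an independent implementation of the
NB-QL approach, not a numerical clone of any package; the binding
interface is the threshold rule (FC > 2 and FDR < 0.05
Benjamini–Hochberg, both configurable; a 1.5-fold threshold is
available for enrichment-style gene lists). Fitted means are floored at
0.5 counts (at the average effective depth) before fold changes, so
log2FC is finite; the floor is deliberately not scale-free.

For phased comparisons each subgenome of each allotetraploid group is
treated as its own group (`Sd_cg`, `Sd_co`, …) and tested against the
diploid groups after rescaling diploid counts by the per-gene phasing
proportion, pooled across the allotetraploid group being contrasted
(pooling per contrasted group, rather than across all allotetraploids,
stabilizes low-count proportions; the alternative is a one-line change
in `rescale_diploid_by_phasing` inputs).

## Expression categories

The ten-category scheme operationalizes "=" as a non-significant DE
verdict and "</>" as significant verdicts — no equivalence testing.
Patterns with the allotetraploid between the parents, or matching both
parents while the parents differ, fall into the catch-all category b
("partial ELD or additive with parental differentiation"). Complete-ELD
categories c–f do not additionally require the parents to differ
significantly, matching the printed criteria literally. Cross-group ELD
sharing requires matching dominance side *and* direction.

## HEB segmentation

HEB tracks use the joint gene set with phased CPM ≥ 1 in every
allotetraploid individual (each individual's phased library is its
cg + co sum). Emissions are Student's-t densities on the logit scale:
state k has location logit(m_k), shared scale (default 0.25) and 3
degrees of freedom; heavy tails absorb the occasional 0/1 ratios of
low-count genes, which are nudged into [1e−3, 1 − 1e−3] before the
logit. Transitions start at self-probability *e* with uniform
off-diagonal mass. `em_iterations = 0` (default) decodes with these
parameters — fully deterministic; with EM on, transition rows are
re-estimated under a Dirichlet prior of weight `strength` on the
initial rows and per-state scales by posterior-weighted second moments.
Viterbi runs in log space; backtrace ties resolve to the lower state.
Presets: resynthesized e = 1 − 1e−10, strength = 1e12 (one meiosis,
exchanges rare); natural e = 1 − 1e−7, strength = 1e7. Natural-group
output is flagged `candidate_only`: expression alone cannot confidently
establish copy number in long-established polyploids, where regulatory
divergence blurs the state medians.

A chromosome quartet is one chromosome × one individual. Summaries
report breakpoints per quartet (mean ± se), quartets with no synapsis
signal (zero breakpoints and constant state 2 — a constant non-2 state,
i.e. whole-chromosome replacement, *is* a signal), and the fraction of
genes in non-2 states. Variance of HEB explained by the decoded copy
number is the deviance-based R² of a quasi-binomial logit GLM of cg
reads out of total homoeolog reads on the state factor (R² = 0 when
only one state occurs).

## Loss of homoeolog expression

A homoeolog is screened only when the corresponding diploid group shows
CPM > 5 in **all** of its individuals; an event requires CPM < 0.5 in
an allotetraploid individual (both inequalities strict, following the
rule's printed form). Homoeolog CPM uses the subgenome's own library
size by default, making the statistic robust to genome-wide bias
between subgenomes; the combined cg + co denominator is a config
switch. Expression data cannot distinguish physical loss from
silencing, and zero-copy blocks produced by homoeologous exchange
remove expression exactly as silencing does; the generator's truth
accessor (`SimTruth.expression_lost`) therefore includes both injected
silencing and zero-copy states. The 10× buffer between the two
thresholds deliberately leaves a band where genuinely suppressed (but
not silenced) homoeologs may or may not be called; recovery tests judge
false positives only on homoeologs whose expected CPM is at or above
the eligibility bound.

## ELD mechanism diagnostic

For each complete-ELD class (dominance side × direction) the module
reports the mean, 10 %-trimmed mean and a Welch two-sample t-test of
the dominant vs recessive homoeolog fold changes. The *decision* uses
the trimmed means: complete-loss and zero-copy genes contribute fold
changes of magnitude 3–10 at the class tails, and a handful of them can
drag an otherwise clear class mean across the tolerance. With tolerance
τ (default 0.25 log2 units, the package's operationalization of
"closer to zero"): copy-driven requires dominant > +τ and recessive
< −τ; random-effects requires |dominant − recessive| < τ; trans-driven
requires |dominant| < τ with the recessive moving ≥ τ in the ELD
direction. Classes with fewer than 20 genes are ignored; the overall
verdict requires all informative classes to agree, else `other`. TRE
genes are reported but never enter the decision. Under the `random`
generator scenario the conditional means of observed-ELD genes need not
match any template, so `other` is a legitimate outcome there.

## Numerical choices

- NB GLM fitting: per-group Newton iterations on the log rate
  (score Σ(y − μ)/(1 + φμ)), steps clipped to ±5, log rates to ±50;
  all-zero groups land on the −50 bound and contribute ≈ 0 deviance.
- Zero-deviance-drop genes get p = 1 exactly; the QL denominator is
  floored at 1e−8.
- BH adjustment delegates to statsmodels (`fdr_bh`) after validating
  the input range.
- Downsampling leaves samples already below target unchanged and logs a
  warning, so group contrasts never silently lose samples.
- All randomness flows from `numpy.random.default_rng` seeds carried in
  the configuration objects; two runs with equal seeds produce
  byte-identical stage outputs.

## Problem sizes

Default simulated size is 8 chromosomes × 400 genes (3 200 genes) × 30
samples, the scale at which every recovery property in the acceptance
suite is exercised; HMM recovery uses 50 simulated individuals
(400 quartets). These sizes keep a full run in seconds while leaving
per-quartet breakpoint statistics and category tallies large enough for
stable Monte-Carlo comparisons.

## Known limitations

- The natural-allopolyploid preset flags candidates only; no attempt is
  made to model regulatory divergence accumulated since polyploid
  formation.
- The QL F-test is calibrated by simulation (type-I error checked near
  nominal), not guaranteed to match any reference implementation
  numerically.
- Emission hyperparameters beyond the state medians (scale, df) are
  declared defaults, config-exposed, not estimates.
- The category scheme itself assigns additive genes with strong
  parental divergence (|δ| > log2 3) to ELD at expectation — a known
  property of threshold-based classification, visible in the
  expectation-level oracle used by the recovery tests.
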