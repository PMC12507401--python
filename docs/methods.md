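# Methods

This note documents the models and procedures implemented in `guildaging`,
the assumptions behind them, the defaults that matter, and what the
synthetic cohorts do and do not emulate.

## Compositional correlation (module `sparcc`)

Sequencing counts are compositional: only relative abundances are observed,
so Pearson correlations of fractions are biased by the closure. SparCC works
from log-ratio variances, which are invariant to per-sample scaling:

    t_ij = Var_s log(x_is / x_js) = ω_i² + ω_j² − 2 ρ_ij ω_i ω_j,

where ω_i² is the variance of component i's unobserved basis log-abundance.
Assuming most true correlations are negligible (sparsity), summing over
partners gives a linear system for the ω², solved by least squares; ρ then
follows by inverting the identity, clipped to [−1, 1]. Pairs whose estimated
|ρ| exceeds 0.8 violate sparsity and are excluded from the system one per
round, up to 10 rounds (conventional settings, exposed as configuration).
Negative solved variances are floored at 1e-10 with a warning.

Choices worth knowing:

- **Pseudo-count 0.5 on counts** before logs, matching the CLR convention
  used downstream; configurable.
- **Deterministic point estimate.** No inner averaging over Dirichlet
  resamples of the fractions: a single solve from the observed counts. This
  makes results exactly reproducible and testable; the estimator is
  cross-checked against an independently written dense least-squares solve
  of the same system (agreement ≤ 1e-8 on 4–6 component systems).
- **Permutation p-values.** Each OTU's counts are shuffled across samples
  independently and the full estimator re-run; two-sided add-one p-values
  (1 + #{|ρ*| ≥ |ρ|}) / (R + 1). Under an independent-basis null the
  per-pair p is uniform on its grid, and the observed fraction of pairs
  below 0.05 sits at the theoretical 0.04–0.045 for R = 199.

When many components are genuinely correlated (large blocks), the sparsity
approximation inflates basis variances and attenuates |ρ| towards zero; the
ranking and the block structure survive, which is what the guild step uses.

## Network and connectivity (module `network`)

Edges require p < 0.05 and |ρ| > 0.4, both strict. The weight of an edge is
|ρ|, so "weighted edges" totals count negative correlations positively. With
a guild partition, an edge is intraguild iff both endpoints share a guild;
intra + inter equals the weighted total exactly. Per-age-group contrasts
re-estimate SparCC and the network per group on the shared OTU set, holding
the cohort-level partition fixed (the guild structure is treated as the
stable object; connectivity varies), with a shared permutation seed so
identical groups give identical networks.

## Guild construction (module `guilds`)

The distance D = 1 − ρ (range [0, 2]) is clustered by Ward linkage. The tree
is cut top-down: at each internal node, the two child clades are the groups
in a PERMANOVA over the OTUs of the clade, with D restricted to the clade as
the dissimilarity. A split is accepted while p < α (default 0.05, 999
permutations) and both children hold at least `min_guild_size` (default 3)
OTUs; rejected nodes become guilds. The per-split α is uncorrected across
the tree — a deliberate configuration choice; a tree-wide correction would
make the cut more conservative.

Because the split being tested was chosen by Ward to maximise separation,
the permutation test is anti-conservative on perfectly homogeneous clades;
on realistic estimation noise this produces occasional small sub-splits of
true blocks rather than wholesale fragmentation. On synthetic cohorts with 8
planted blocks (correlation 0.8, n = 500, 240 OTUs) the recovered partition
agrees with the truth at 1 − NVI ≈ 0.97–1.0.

Dominant OTU per guild: argmax weighted degree; if a guild has no edges,
argmax mean relative abundance (per-sample closure, then mean); exact ties
go to the lexicographically smaller OTU id.

Partition similarity uses the normalized variation of information with
natural logs, NVI = (H₁ + H₂ − 2I) / log n over the shared OTU universe, so
1 − NVI lies in [0, 1] and equals 1 only for identical partitions.

## Diversity (module `diversity`)

- Rarefaction subsamples each sample without replacement to an exact depth
  (multivariate hypergeometric), a single seeded draw; under-depth samples
  are an error, never dropped silently. The pipeline default is the cohort's
  minimum library size, the standard "rarefy to minimum depth" rule.
- Chao1 is bias-corrected, S + F₁(F₁−1)/(2(F₂+1)), defined when F₂ = 0;
  Shannon uses natural logs; Pielou J = H/ln S with J = 1 for S = 1.
- Uniqueness is the minimum Bray–Curtis dissimilarity to any other sample in
  the analysis stratum. Because the analyses are sex-stratified, uniqueness
  is computed within sex by default (configurable to cohort-wide); it can
  only shrink as the comparison set grows, so the stratum must be stated.
- PERMANOVA uses Anderson's pseudo-F from sums of squared dissimilarities;
  p by add-one permutation, or exact enumeration of all distinct label
  assignments when requested (used by tests at n ≤ 8). A sequential
  (Type I) multi-term variant supports covariate screens.
- PCoA is classical double-centering; negative eigenvalues are dropped and
  their mass recorded. The age arrow is the vector of per-axis OLS slopes of
  score on age, rescaled so its length is 80% of the largest coordinate
  radius (display convention, configurable).

## Abundance associations (module `assoc`)

CLR: zeros replaced by 0.5 (half the minimum nonzero count), log, per-sample
centering; rows sum to zero and the transform is invariant to library size.
Per feature, OLS of CLR abundance on age adjusted for BMI and total energy
intake (the default confounder set; education/lifestyle/collection-time sets
are supported for sensitivity analyses), fitted per sex; a combined-sex
model with age, sex and age × sex provides the interaction family. BH-FDR
is applied across features, separately for main and interaction p-values.
The explicit OLS-on-CLR fit replaces a wrapped external model-fitting
package: the models are plain linear models with stated covariates, and an
explicit fit is transparent and directly testable.

## Microbial age (module `age`)

Features are the sex-specific age-related guilds at raw p < 0.05 —
deliberately uncorrected, since the forest pools weak signals. The forest
uses ntree = 1000, mtry = max(1, ⌊p/3⌋), minimum leaf size 5, fixed seed.

Two discipline rules are enforced by construction:

- **Out-of-bag scoring for training samples.** In-bag predictions would
  track chronological age almost perfectly and destroy the deviation
  construct; the model object refuses to `predict` on its own training
  samples, which must use the stored OOB predictions. Applied (diseased)
  samples are scored by the fitted forest.
- **Old/young labelling.** The sex-specific healthy line is the OLS fit of
  microbial age on chronological age over healthy samples; deviation is
  microbial age minus the line's fitted value; "old" requires deviation
  strictly > 0 (a deviation of exactly 0 is "young").

A 10-fold cross-validated MSE curve over decreasing feature counts (ranked
by importance) is reported for model diagnostics but never used to prune.
Expect low R² of OOB prediction on age (of order 0.05–0.3 depending on
signal): microbial age is a composite indicator of age-related microbiome
state, not an accurate age predictor, and the deviation — not the fit
quality — is the downstream quantity.

Disease contrasts are OLS of microbial age on a disease indicator against
the disease-free reference: Model 1 adjusts for age; Model 2 adds BMI,
energy, education, exercise, smoking, drinking; Model 3 adds medication
indicators and excludes analgesic/hormone users.

## Lifestyle and survival (module `outcomes`)

HLI counts four healthy behaviours (0–4); ≤ 2 is "low". A healthy diet is
either the boolean flag in the metadata or, when a 0–45 food-pagoda diet
score / fiber intake are supplied, top-two-quintiles of the score (quantiles
computed within the loaded population) or fiber > 20 g/day. Long-term
adherence crosses the baseline and recent low/high groups; regressions of
microbial age on HLI (per point) and on adherence (low-low reference) adjust
for age, sex, BMI and education.

Residual life expectancy is ∫₄₅¹⁰⁰ S(t)/S(45) dt from a right-censored
parametric MLE. The family is selectable — exponential, Weibull, or
Gompertz (default, the standard adult-mortality hazard shape); the target
quantity is an area under the survival curve and is family-agnostic, so a
parametric family stands in for spline-based baselines, which are out of
scope. The exponential uses its closed forms; other families use
Nelder-Mead on log-parameters with numerical SEs and adaptive quadrature.

Competing risks: cumulative incidence by the Aalen–Johansen estimator
(cross-checked against an independent survival library), which conserves
S(t) + ΣCIF(t) = 1 at every event time to 1e-9; a permutation contrast of
the integrated CIF difference between groups; and a cause-specific Cox model
(competing events censored, Efron ties) fitted via `lifelines`. The
cause-specific hazard formulation covers the reported hazard ratios without
re-deriving subdistribution weighting.

## Synthetic cohorts (module `synth`)

The generator draws, per guild block, a latent factor model
z = √c·f_g + √(1−c)·ε (pairwise correlation exactly c within a block,
independence across blocks), adds per-OTU baseline log-abundances and
per-sample age/sex/disease shifts on the log scale, closes to relative
abundances, samples multinomial counts at a per-sample depth, and applies
Bernoulli dropout whose probability decays with the entry's count
(zi·exp(−c/10 reads)). Dropout concentrated on low-abundance entries mirrors
how technical zeros arise in real libraries; masking high-count entries
uniformly would inject log-scale outliers with no biological counterpart
and artificially fragment co-abundance blocks. Each sample also carries a
latent "aging deviation" (SD 2 years) that shifts age-related guilds exactly
as extra chronological age would and multiplies the diabetes cause-specific
hazard (log-HR 0.095/year ≈ HR 1.10), so construct recovery and prospective
hazards can be tested against known truth. Survival uses constant
cause-specific hazards (closed-form oracles) with uniform administrative
censoring at 48–84 months.

Defaults describe a middle-aged-to-elderly urban cohort: ages uniform on
51–89, BMI ~ N(23.4, 2.2²), energy ~ N(2026, 540²), sex-specific smoking and
drinking prevalences, disease prevalences whose joint "relatively healthy"
fraction is near one half, and sequencing depths 16,332–60,000 reads. Age
effects default to ±0.02 latent log-units per year on three guilds — chosen
for testability at the cohort sizes the tests use (n ≈ 500–600), as
field-scale effect sizes on the latent scale are not identifiable from
published summaries.

What the generator does **not** emulate: taxon-specific mean-variance
relationships, phylogenetic correlation, batch effects, read-level artifacts
or chimeras, time-varying hazards, or lifestyle–microbiome coupling. A
passing test suite therefore demonstrates the estimators' correctness and
calibration under the stated generative model, not performance on any real
cohort.

## Numerical and scale choices

- All permutation tests use the add-one estimator; "exact" enumeration is
  used where the assignment count is small.
- Problem sizes in the tests and the acceptance script (e.g. 8 blocks × 30
  OTUs × 500 samples for recovery; 200 × 300 for the end-to-end run; 99–999
  permutations) are chosen so the full suite runs in minutes on a single
  core while leaving planted effects several standard errors above noise.
- Every stage takes an explicit seed; the generator uses one global seed
  with named per-stage substreams, and pipeline artifacts are byte-identical
  across reruns with the same config and seed (floats written with 10
  significant digits, manifests hash only analysis-relevant settings).

## Known limitations

- The PERMANOVA tree cut inherits PERMANOVA's sensitivity to dispersion
  differences and the selection bias of testing tree-derived groups; α is
  a practical knob, not a calibrated false-split rate.
- SparCC attenuates correlations when blocks are large relative to the
  component count; basis-variance exclusion mitigates but does not remove
  this.
- The parametric residual-life-expectancy fit treats ages at death/censoring
  as time from birth without left truncation; with a cohort recruited in a
  narrow age band this overweights early survival, and the quantity should
  be read comparatively (old vs young microbial age), not demographically.
- Cause-specific hazard ratios answer an etiological question; they are not
  subdistribution (cumulative-incidence-scale) effects.
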