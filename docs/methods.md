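# Methods

This note records the models behind each module, the defaults that
matter, and the choices made where the design was genuinely open.

## Life-history records and traits

A female is an ordered list of clutches on an integer day axis (day 0 =
birth; oviposition days strictly increasing and no later than death).
Derived traits: fecundity (Σ eggs laid), number of ovipositions,
inter-oviposition interval (mean of successive oviposition-day
differences; median available — the aggregator is a choice, since a
single per-female "interval" admits either), age at first oviposition,
mean hatching time over the female's hatched eggs, total hatched eggs,
and hatching percentage (100 × hatched/fecundity). Undefined traits
(no clutch, no hatched egg, fecundity 0) are left missing, never
imputed — a female with no eggs has *no* hatching percentage rather
than 0%, which matters because imputing 0 would silently double-punish
her under the fitness zero rule. The reference scale the code must
represent without trouble: lifespans to ~700 d, ~90 eggs, ~34 clutches.

## Fitness score

Components: min-max normalized fecundity and total hatched eggs;
inverted min-max normalized mean hatching time and age at first
oviposition; score = mean of the four; hard zero for females with
fecundity 0 or no hatched egg.

Open choices, resolved as follows:

- **Normalization pool.** Bounds are computed once over *all* scored
  females (both generations and temperatures pooled), so all scores
  share one scale and are comparable across groups — the natural choice
  when scores are then compared among groups. `pool="per-temperature"`
  is available for sensitivity analysis.
- **Degenerate bounds** (all females identical in a trait): the
  component is set to 0.5. An uninformative trait should not force a
  female to either extreme; with all four traits degenerate every
  non-zero-rule female scores 0.5, which is testable and transparent.
- **Zero-rule females and bounds.** Their fecundity and hatched-egg
  values (0) are real observations and enter those bounds; their
  undefined hatch-time/age traits do not.

## Cohort statistics

GLM families follow the response because no single family fits all
traits: gaussian-identity for durations; Poisson log for counts, with an
automatic switch to negative binomial (method-of-moments dispersion)
when the Pearson dispersion of the Poisson fit exceeds 1.5; binomial
logit with clutch-count weights for hatching percentage. Reference
levels are the parental generation (or F1 when P is absent) and 5 °C.
Intervals and p-values use the Wald z approximation, which is what
statsmodels' GLM reports.

Standardized coefficients come from refitting on standardized data:
numeric predictors are always centered/scaled to unit SD; the response
is standardized only for gaussian models, because counts and
proportions must keep their natural support under a log or logit link.
This matches the refit convention of standardize-parameters tooling in
the R ecosystem.

Fitness scores are compared with the tie-corrected Kruskal–Wallis H
(identical pooled values short-circuit to H = 0, p = 1, where the rank
test is undefined), followed by pairwise two-sided Mann–Whitney tests
with Bonferroni (default) or Holm correction. The post-hoc routine is a
choice — letter-grouping displays in this literature rarely name their
test.

Clutch-level models (fertility vs oviposition order, hatch time or
hatching percentage vs clutch size) are fit on one row per clutch via
`life_history.clutch_table`.

## Negative-binomial DEG engine

The DEG backend is a deliberately small NB2 machine rather than a
wrapper around an existing DGE package; its contract is planted-truth
recovery and type-I error control, not bit-compatibility.

- **Dispersion.** Per gene, method of moments: with fitted means μ from
  the closed-form Poisson group fit (or, when nuisance covariates are in
  the model, from a per-gene Poisson IRLS fit of the full design so that
  variance explained by covariates is not booked as dispersion), solve
  Σ(n/(n−k)·(y−μ)² − μ) = α·Σμ². The n/(n−k) factor corrects the
  downward bias of residuals around k fitted means. Raw values are
  floored at 0 and shrunk 50/50 toward the across-gene mean.
- **Fitting.** IRLS for the NB2 log-linear model with log library size
  as offset, fixed α, step-halving on likelihood decrease, linear
  predictor clipped at ±30 (groups of all-zero counts push a
  coefficient to −∞; clipping leaves the likelihood numerically exact).
- **Testing.** Likelihood-ratio test of the temperature factor (full:
  intercept + temperature + covariates; reduced: intercept +
  covariates) against χ² with (levels − 1) df. A gene with identical
  counts everywhere gets statistic 0 and p = 1 by construction.
  P-values are Benjamini–Hochberg adjusted; significance is fdr < 0.01.
- **Expression filter.** Keep genes with CPM > 1 in at least as many
  samples as the smallest temperature × exposure group — a concrete
  stand-in for filter-by-expression routines whose exact rule varies.
- **Known limitation.** With few replicates the plug-in dispersion and
  the χ² approximation are mildly anti-conservative in the far tail;
  on all-null simulations the fraction of genes passing fdr < 0.01
  stays well under 1%, but the realized FDR in strong-signal
  simulations exceeds the nominal 1% (of order 10%). Exact-test or
  quasi-likelihood machinery is out of scope here.

Per-temperature log2 fold changes versus 5 °C are the temperature
coefficients divided by ln 2. The up/down/flat label is the sign of the
least-squares slope of group-mean log2-CPM against numeric temperature
— a deliberately simple monotone-trend summary.

## Empirical controls and unwanted variation

"Least varying" is operationalized as the smallest omnibus LRT
statistic in a first-pass all-groups (temperature × exposure) analysis
of the expression-filtered genes; the lowest 1000 (default) are the
control list. The statistic, not the p-value, is the ranking key — at
equal df they order identically, but the statistic avoids ties at p ≈ 1.

Unwanted factors W are the first k left singular vectors of the
samples × controls matrix of gene-centered log-CPM. This is the
factor-analysis reading of control-gene batch removal: directions of
shared variation among genes assumed condition-independent. W enters
the DEG model as covariates; k = 0 reproduces the unadjusted analysis
exactly.

## Outlier samples

The study this mirrors flagged outliers by eye on MDS/PCA plots; here
the rule is fixed and deterministic. Samples are embedded in the first
two PCs of gene-centered log-CPM; each axis is whitened by a robust
(MAD-based) estimate of the pooled within-group spread, because a
single aberrant sample otherwise captures a whole component and
collapses the remaining samples onto one axis, deflating its own
apparent distance. A sample is flagged when the log of its whitened
distance to its group centroid exceeds the pooled median by more than
c × 1.4826 × MAD (default c = 2.5); distances are strictly positive and
right-skewed, hence the log scale. Flagging peels: one sample per
round, then everything is recomputed, so one outlier cannot drag its
group-mates over the cutoff. At the default simulation scale this
flags nothing in ~95% of homogeneous experiments and isolates a
planted aberrant sample essentially always.

## Enrichment

Upper-tail hypergeometric test per term against the expressed-gene
universe; expected = nK/N, O/E = k/expected; BH across tested terms;
significance requires both fdr < 0.05 and O/E > 3. Terms with no
annotated universe gene are skipped. The universe defaults to the genes
passing the expression filter in the analyzed subset (whether the
universe should be per-exposure or global is not fixed by convention;
per-subset matches the contrast actually tested).

## Synthetic data

The life-history generator emulates individually reared females in a
generation × temperature layout. Durations (lifespan, age at first
oviposition, intervals, hatch times) are lognormal matched by moments
to the configured mean/SD; clutch sizes are 1 + Poisson with an
order-dependent mean so clutches can grow over the life span; eggs
hatch independently with a group hatch probability. Default parameters
echo a cold-adapted parthenogen (first oviposition ≈ day 34, hatch
time ≈ 22 d and oviposition every ≈ 14 d at 5 °C; everything faster and
shorter-lived at 15 °C), and the warm F2 group plants 13 no-egg and 13
no-hatch females. These defaults are configuration, not claims about
any real population. Ordinary females are guaranteed at least one
clutch and one hatched egg (one hatch is forced in the rare draw where
none occurs), so the planted zero-fitness counts are exact by
construction — the property the zero-rule worked example checks.

The expression generator produces NB counts over the 4-temperature ×
2-exposure × 3-replicate design (24 samples). DEG genes change
monotonically: direction ±1, mean × 2^(direction · f · step) at
temperature step 0–3 with per-step log2 fold change f (default 1.0,
i.e. 8-fold at 20 °C); defaults: 2000 genes, 10% DE, NB dispersion 0.1,
library sizes uniform in 0.8–1.2 M. Batch structure multiplies a
configurable fraction of genes by 2^(±batch effect) in second-batch
samples with gene-specific sign — correlated variation that library
size cannot absorb, which is the point: a truly global multiplicative
shift is exactly an offset change and undetectable by construction.
For the same reason a planted outlier sample shifts a random half of
its genes (default 10-fold) rather than all of them. The second batch
is the last replicate of every cell, keeping batch orthogonal to
temperature and exposure.

What the simulations do *not* emulate: gene–gene correlation,
mean-dependent dispersion trends, composition effects between samples,
alignment/quantification noise, or any real biological covariance
structure. Passing the planted-truth suites therefore demonstrates
correctness of the machinery under the stated model, not performance on
real libraries.

Simulation sizes used in tests and the acceptance script (2000 genes,
24 samples, 100-replicate coverage runs) are chosen as the smallest
scales at which the distributional checks are stable.
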