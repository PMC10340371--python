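# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the limitations of `radbench`.  Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Synthetic data generator

The generator produces the three inputs a radiosensitivity-signature
validation study needs.  All outputs are bit-for-bit reproducible from
`SimulationConfig.seed`; per-gene "biology" (mean expression, factor
loadings) is drawn from a separate `biology_seed` so a cell-line panel and a
clinical cohort set describe the same gene universe.

**Expression model.**  Gene $g$ in sample $s$ is
$x_{gs} = \mu_g + \ell_g^\top F_s + \varepsilon_{gs}$ with per-gene means
$\mu_g \sim N(8, 2^2)$ (log2 scale), latent factor scores
$F_s \sim N(0, I_m)$, loadings
$\ell_{gj} \sim N(0, \texttt{factor\_var}/m)$ and unit noise.  Defaults:
$m = 3$ factors contributing `factor_var = 0.1` of variance.  The factors
model shared biological programs (proliferation-like axes) present in both
cell lines and tumours; they are the mechanism by which signatures trained
in vitro pick up outcome-associated variation in the clinic.  Without them
(independent genes), the effective log HR of a randomly weighted signature
is provably independent of its size — the covariance of the score with the
hazard and the score's SD both scale as $\sqrt{k}$ — so the empirically
observed growth of resampled-signature significance with signature size
cannot occur.  `factor_var = 0`, `hazard_factor_coef = 0` recovers the
independent-gene global-null generator used in the calibration tests.

**Cell-line panel.**  SF2 is generated from the within-line rankings of a
planted signature:
$\mathrm{lin} = \beta_0 + \sum_g \beta_g r_g + \gamma F_1 + N(0,
\texttt{noise\_sd}^2)$, pushed through a logistic link (default) or an
identity link, then clamped to (0.01, 0.99) so SF2 is a valid surviving
fraction.  The identity link makes the generating model coincide with the
rank-linear model form, enabling exact closed-loop coefficient recovery;
the logistic default keeps SF2 bounded under arbitrary coefficients.
`sf2_factor_coef` ($\gamma$, default 0.6) couples SF2 to the first latent
factor — the in-vitro endpoint is partly driven by the same general
programs that drive outcome, which is precisely the confounding the
benchmark is designed to expose.

**Clinical cohorts.**  A `frac_prognostic` subset of genes (default 0.15)
receives log-hazard coefficients $\beta_g \sim N(0, \texttt{effect\_sd}^2)$
(default 0.2), shared between the RT and no-RT arms; an optional
`rt_specific_frac` adds RT-only effects for specificity experiments.
Survival times are exponential with rate
$\exp(\sum_g \beta_g z_{gs} + \delta F_{1s})$ (baseline rate 1), with
`hazard_factor_coef` $\delta = 0.3$.  Censoring is independent exponential
with its rate solved numerically (Brent) so the expected censored fraction
equals `censoring_target` (default 0.5) — the simplest mechanism satisfying
the non-informative censoring assumed by Cox regression.  The default
cohort layout mirrors a multi-cohort validation study: ten cohorts crossing
{OS, FR} x {RT, noRT} with sizes 186/77/65, 55/82/364, 282/77 and 62/82
(1332 patients).  Ground truth (which genes are prognostic, their
coefficients, the censoring rate) is returned alongside the data.

**Calibration.**  `factor_var`, `sf2_factor_coef` and `hazard_factor_coef`
were chosen once so that the default conditions land in the regime reported
for real multi-cohort data — roughly 12–18% of genes univariately
significant at p < 0.05 and a resampled-signature significance fraction
that exceeds the nominal 5% and grows with signature size.  They were not
revisited afterwards.

**Probe-level arrays.**  Gene-level truth is expanded to
`probes_per_gene` probes (default 5, minimum 3):
$I_{pa} = 2^{\,t_{ga} + a_p + s_a + f_a(t_{ga}) + \varepsilon}$ with probe
affinities $a_p \sim N(0, 0.5^2)$, array offsets $s_a \sim N(0, 0.25^2)$,
iid noise (SD 0.1), and $f_a$ a per-array random cubic polynomial in
expression level rescaled to amplitude `array_nonlinearity_amp = 0.3`.
Random cubics are generically non-monotone, so inter-array maps genuinely
disagree and the three normalizers cannot all be rank-equivalent.

**What the generator does not emulate.**  Marginal expression distributions
of real platforms, realistic inter-gene correlation beyond a low-rank
factor model, copy-number/mutation covariates, mismatch probes, batch
structure, or non-proportional hazards.  Passing tests therefore show that
the *pipeline machinery* is correct and that the *mechanisms* (resampled
nulls beating naive nulls; normalization-induced rank disagreement) operate
as described — not that any quantitative result transfers to a specific
real cohort.

## Normalization pipelines

All three emit log2 gene x array matrices, keeping downstream rank
operations comparable.

* **MAS5-style**: each array scaled so its trimmed mean (2% per tail)
  equals 500 on the natural scale; genes summarized by a one-step Tukey
  biweight of log2 probe intensities with c = 5, eps = 1e-4.  No
  mismatch-probe correction (the synthetic arrays have no MM probes).
* **RMA-style**: probe-level quantile normalization (each array's sorted
  values replaced by across-array means of order statistics; ties within an
  array receive the mean of the across-array means at their tied ranks),
  log2, then per-gene median polish (max 10 iterations, tolerance 0.01);
  gene value = overall + array effect.  The background-correction
  convolution model is omitted: it addresses absolute accuracy, not the
  rank-agreement question studied here.
* **IRON-style**: reference array = the one maximizing mean Spearman
  correlation with the rest; each other array is pruned to a rank-invariant
  probe set (3 iterations keeping the 90% of probes with smallest absolute
  rank difference vs the reference), a running median of log-ratio vs mean
  log-intensity (window = 5% of invariant probes, minimum 11) is fitted on
  that set, interpolated, and subtracted; summarization as in MAS5-style.
  At least 50 invariant probes are required for curve fitting.

**Agreement.**  `bland_altman` returns the mean difference, the sample SD
of differences (n−1), and limits mean ± 1.96 SD.  A subtlety worth
recording: the IRON-style correction is exactly zero only when the
log-ratio to the reference is exactly constant.  For biologically distinct
arrays the running median carries $O(1/\sqrt{\text{window}})$ noise even
with zero probe-level distortion, which can perturb within-sample ranks.
Exact zero-distortion rank transport for all three methods therefore holds
for technical-replicate arrays (identical truth across arrays) — also the
scientifically clean design for isolating normalization-induced
disagreement — and that is how the corresponding test is constructed.
MAS5- and RMA-style normalization are within-array monotone maps, so their
rank transport holds for arbitrary truth.

## Signature models

Within-sample ranks are computed among the k signature genes (1 = lowest
expression, average ranks for ties); ranking within the full array instead
is available via `rank_scope="array"`.  Because signature-scoped ranks sum
to k(k+1)/2, the intercept-plus-ranks design has a one-dimensional null
space; the sum-zero-coefficient gauge is imposed (predictions unchanged,
coefficients exactly identified).  A design whose rank falls below the
intrinsic rank — e.g. a gene whose mean is so extreme that its rank is
constant across lines — raises an error naming the offending genes;
resampling redraws such gene sets.

PCR centres and unit-scales each gene (SD with n−1), takes the SVD,
retains the smallest number of components reaching cumulative explained
variance 0.8 (cap 10; both configurable; the variance threshold is a
declared default, recorded in the signature metadata), and regresses SF2 on
the component scores.  With all components retained PCR reproduces full
OLS.  Predictions are not clipped to (0, 1): survival analysis z-scores
them, so scale is irrelevant there; the Bland–Altman analysis uses the raw
(unclipped) scores.

Resampled controls draw gene sets uniformly without replacement from the
panel universe (published genes remain eligible by default; an exclusion
list is supported).  Sizes 10 and 31 use the matched published forms
(rank-linear and PCR).  Size-100 controls use PCR: a rank-linear OLS with
100 genes is rank-deficient on a 60-line panel, so PCR is the only
well-posed matched form at that size.

## Survival analysis

The stratified Cox partial likelihood (per-cohort risk sets, Efron tie
correction; Breslow by flag) is maximized by Newton–Raphson with
step-halving, max 50 iterations, convergence |Δ log-lik| < 1e-9.  Monotone
likelihood is detected via |beta| > 20 and flagged (`converged=False`)
rather than raised, so genome-wide scans proceed.  Wald CIs and p-values
are reported.  Scores are z-scored within the pooled analysis group
(per-cohort standardization behind `zscore_scope="cohort"`).  Strata
without events contribute nothing and are skipped; a group with no events
at all is an error.

The genome-wide scan uses a vectorized single-covariate Newton iteration
(all genes simultaneously, suffix-sum risk sets, Efron fallback for tied
event times), with per-gene z-scored expression so hazard ratios are per
SD and comparable across genes.  Zero-variance and non-converged genes are
flagged and excluded from KS tests and significance proportions, with
counts reported.  The significance boundary is strict (p < alpha).

Cohort-restricted covariates (the MGMT-like adjustment in overall-survival
analyses) are centred within each applicable cohort and zero-filled
elsewhere — equivalent to cohort-mean imputation after centring, so
non-applicable strata contribute nothing to that coefficient's score.  How
a real multi-cohort analysis entered a single-cohort covariate is not
derivable from the study description; zero-after-centring is this package's
declared choice.

## Enrichment

ORA uses the hypergeometric upper tail on the scoreable universe, requiring
at least 2 overlapping genes before BH adjustment (guards against
single-gene hits from 10-gene signatures).  Preranked GSEA ranks genes by
log HR (monotone in HR, so the ordering matches an HR-ranked list;
ties broken by stable input order) with weighted running sum (weight 1),
gene-set permutation null (n_perm = 1000, seeded; phenotype permutation is
impossible given a precomputed per-gene HR list), set-size filters 5–500,
signed ES/NES, and BH across sets.  The RT-vs-noRT analysis ranks genes by
log-HR difference (raw-HR difference behind a flag).  Term reduction
replaces GO semantic similarity with greedy Jaccard clustering of member
genes at threshold 0.7 — a declared stand-in, not an equivalent: it needs
no ontology database, but Jaccard overlap and semantic similarity measure
different things.

## Pipeline and reproducibility

`run_experiment` executes simulate → train → survival → resample →
normalize → scan → enrich and writes per-stage TSVs, a resolved-config
snapshot with a config hash, and a JSON report.  A single global seed fans
out to per-stage child seeds via SHA-256 of `"{seed}:{stage}"` (taken mod
2^31), so stages can be rerun in isolation.  Problem sizes used by the
default experiment and the acceptance script: 1000 genes, 60 cell lines,
1332 patients, 100 resampled signatures per size, 60 arrays in the
normalization-agreement experiment, 1000 GSEA permutations — sizes chosen
so the full experiment completes in well under a minute on one CPU while
keeping Monte-Carlo noise on reported fractions near the percent level.

## Known limitations

* The SF2 distribution and dynamic range of real training panels are not
  matched; the logistic-link defaults are placeholders, not calibrated to
  any published SF2 set.
* The latent-factor structure is low-rank and Gaussian; real co-expression
  is heavier-tailed and modular.
* Quantitative outputs (limits-of-agreement widths, hazard ratios,
  significant-gene proportions) depend on the synthetic regime and are not
  estimates of any real cohort's values; only the qualitative mechanisms
  are expected to transfer.
* No competing risks, time-varying effects, or proportional-hazards
  diagnostics beyond the convergence flag.
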