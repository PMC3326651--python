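# Methods

This note records the statistical models behind `tissueorigin`, the
parameter defaults and why they were chosen, and what the synthetic-data
results do and do not establish about real specimens.

## Synthetic cohort model

Real training and validation cohorts for this assay class are proprietary,
so every pipeline stage is exercised on simulated data. On the log2 scale,
the intensity of probeset *g* in specimen *s* is

    log2 x_gs = mu_g + delta_g · 1[s is endometrial] + eps_gs

* `mu_g ~ Normal(base_intensity_log2 = 8, baseline_sd = 2)`, drawn once per
  probeset and shared across specimens — typical of the dynamic range of a
  short-oligo array after summarization.
* `delta_g = ±effect_size` at the `n_markers` planted markers (signs split
  evenly so each class has both up- and down-markers), 0 elsewhere. The
  default `effect_size = 2` log2 units (4-fold) represents a strong
  tissue-lineage marker such as the homeobox or kallikrein genes that
  dominate gynecologic tissue classification panels.
* `eps_gs` has standard deviation `specimen_noise_sd = 1` for ordinary
  probesets and `stable_noise_sd = 0.05` at the `n_stable = 61` planted
  stable probesets, putting stable-probeset variance two to three orders of
  magnitude below the cohort median — the operational definition of a
  housekeeping panel.
* Laboratory/batch effects multiply raw intensities by a per-lab factor
  (`lab_scale_factors`), i.e. shift every probeset by the same log2 offset.
  This is exactly the artifact the standardization algorithm is designed to
  remove, and nothing more.
* Replicate adjacent sections share the specimen's lab-free signal plus
  fresh `Normal(0, section_noise_sd = 0.15)` log2 noise per section.
  0.15 log2 units (~11 %) reflects the section-to-section repeatability a
  precision study with CV% mostly under 10 implies.

Default cohort sizes mirror the production training database (365
endometrial / 484 ovarian); tests and the acceptance script use desk-scale
cohorts of 100/100 specimens × 2,000 probesets with 50 markers, which a
single CPU processes in seconds.

**What the simulator omits** — and hence what green tests do *not* show
about real data: FFPE RNA degradation and its length bias, probe-level
(pre-summarization) structure, correlated marker blocks, histologic-subtype
heterogeneity within a class, and non-multiplicative batch distortions
(e.g. intensity-dependent dye or scanner effects). A classifier that is
perfect here can only be said to recover planted multiplicative-plus-shift
structure; clinical accuracy claims require clinical data.

The 82-row processing fixture is a deterministic table whose failure
pattern reproduces a realistic attrition chain (82 → 81 after RNA gates →
80 after cDNA yield → 79 after array QC, then four entry-criteria
exclusions → 75 analyzable, split 45/30). Entry-criteria exclusion is a
boolean flag: the underlying reason (a specimen vendor's QC lapse) is not a
computable gate.

## QC metrics

Specimen gates apply in processing order — RNA (yield ≥ 30 ng,
concentration ≥ 9.5 ng/µl, A260/A280 ≥ 1.0), labeled cDNA (≥ 2.5 µg), array
data quality — and a specimen failing an earlier stage is not evaluated
later, so stage counts are independent of downstream fields. All
thresholds are inclusive.

The three array metrics have locked pass thresholds (overall signal ≥ 10,
percent present ≥ 5, regional discontinuity ≤ 0.84) but their original
formulas are part of a proprietary processing stack; this package
operationalizes them as: mean log2(x+1); percent of probesets whose log2
intensity clears a detection threshold (background + 1 log2 unit,
configurable); and the maximum relative deviation of a spatial block's mean
log2 intensity from the array-wide mean over a 4×4 partition of the
physical grid. Whether "overall signal" is meant on the linear or log
scale is not documentable; the log scale was chosen so the threshold of 10
sits inside the simulated dynamic range. These choices preserve the
pass/fail contract and detect the intended artifact classes (dim arrays,
empty arrays, spatial blemishes) without claiming formula-level fidelity.

## Standardization

Stable probesets are selected by lowest coefficient of variation of
log2(x+1) across training specimens (ties broken by probeset id); CV is the
standard stability criterion for housekeeping-style panels and the original
selection rule is not public. The reference summary is the median across
training specimens of each specimen's stable summary, defined as **log2 of
the median raw stable intensity**.

Standardization multiplies the raw profile by `2^(reference − summary)` —
a single additive shift on the log2 scale. Applying the correction on the
raw scale *before* the log2(x+1) display transform makes three properties
hold exactly rather than approximately: scale invariance
(`standardize(c·x) = standardize(x)` for any c > 0), idempotence, and
zero between-lab variance of stable summaries after standardization. A
pseudocount-first formulation (normalizing log2(x+1) values directly) was
considered and rejected because the pseudocount breaks exact multiplicative
invariance; with intensities well above 1 the two differ negligibly, but
the exact contract is worth keeping. Per-probeset quantile mapping was
rejected as under-determined by the available description of the original
algorithm.

## Classifier

Markers are ranked by the absolute pooled-variance two-sample t statistic
(ties by probeset id). The model on the top-k markers is an L2-regularized
logistic regression on z-scored features — the minimal probabilistic linear
family consistent with "coefficients combined into two probability-like
scores"; the original learner is not named publicly. Fitting is
deterministic (lbfgs, fixed start), so refits are byte-identical.

The endometrial similarity score is the class probability × 100, rounded
half-away-from-zero to one decimal; the ovarian score is the rounded
complement, so the printed pair sums to 100.0 by construction. The call is
the strictly higher score; an exact 50.0/50.0 tie is reported as
*indeterminate* rather than resolved arbitrarily.

`cv_performance_curve` uses stratified k-fold cross-validation and re-ranks
markers inside every training fold, so feature selection never sees the
held-out fold (verified by a pure-noise null staying at AUC ≈ 0.5).
`select_k` returns the smallest k whose AUC is within a tolerance of the
maximum — the "simplest model with maximal achievable performance" rule;
tolerance 0 gives the argmax with smallest-k tie-breaking.

## Adaptive validation design

Each class's agreement probability carries an independent Beta prior,
uniform Beta(1, 1) by default (the original design's prior is in
non-public supplementary material; the prior is a config field). After x
agreements in n specimens the posterior is Beta(1+x, 1+n−x); "mean PPA" is
read as the posterior mean and the credible interval is equal-tailed.

Acceptance at a look requires **both** classes to satisfy posterior mean
≥ 0.80 and 95 % credible lower bound ≥ 0.65 (inclusive). Looks fall at
½, ¾ and all of `n_max = 150` — the maximum sample size is inferred from
the executed study, whose first look analyzed 75 specimens; class
allocation follows the observed 45:30 mix (`class_a_share = 0.6`, a 1:1
option is a config change). Success is checked before futility;
termination is final; a final look that fails the criteria terminates for
futility.

The predictive probability of success at `n_max` integrates future data
over the beta-binomial posterior predictive. Because both acceptance
quantities are non-decreasing in x at fixed n, each class has a minimal
sufficient final count, and the predictive probability is an exact product
of beta-binomial tail probabilities. That closed form backs `run_trial` and
the operating-characteristic simulator; a Monte-Carlo path (fixed seed) is
kept and is cross-checked against exact enumeration in the tests, with
exact enumeration the default whenever at most 12 specimens remain per
class.

Operating characteristics simulate full enrollment streams with agreement
indicators thresholded against common uniform draws (agree iff u < true
PPA), so under a fixed seed the success probability is exactly monotone in
the true PPA, trial by trial — the monotonicity check is sharp, not
statistical. At the defaults, 2,000 simulated trials complete in well
under a minute; the design accepts with probability ≥ 0.98 at true PPA
0.95 per class and ≤ 0.05 at 0.50. The scenario/prior under which the
original study quoted its 98 % power and 5 % type-I error is not public, so
these are properties under the stated assumptions, not reproductions.

## Agreement statistics

* Exact binomial intervals are Clopper-Pearson via beta quantiles — the
  method was identified by exactly reproducing published bracketed
  intervals such as (29/30) → [82.8, 99.9] and (67/67) → [94.6, 100];
  Wilson and Wald do not reproduce them.
* Fisher's exact test is two-sided by hypergeometric summation
  (probabilities ≤ observed), which reproduces published subgroup p-values
  (0.646, 0.3524, 0.0517).
* The diagnostic odds ratio is (tp·tn)/(fn·fp); any zero cell triggers the
  Haldane-Anscombe +0.5 correction, flagged in the result.
* AUC is the Mann-Whitney rank statistic with ties counted ½, equivalent
  to brute-force pair counting (property-tested).
* Score bins are half-open [0,10) … [80,90) with closed top bin [90,100];
  threshold analyses use the strict rules "> 80" / "≤ 20".
* Display rounding is half-away-from-zero to one decimal; a row's percent
  non-agreement is the rounded complement of its PPA so the pair sums to
  100.0 exactly.
* Concordance: a missing call drops the pair; indeterminate is discordant
  with any definite call; both-indeterminate pairs are excluded. Kappa uses
  the standard asymptotic CI, clipped to [−1, 1], and is flagged undefined
  when both raters are constant and identical. CV% uses the sample (n−1)
  standard deviation — replicate counts are tiny (typically 3), so the
  convention matters and is stated. When replicate calls disagree, CV% is
  computed on the known-diagnosis score (the alternative — the higher score
  per replicate — would mix the two score scales across replicates).

## Problem sizes

Test-suite and acceptance-script workloads are desk-scale by design:
100/100-specimen cohorts with 2,000 probesets, 50-marker models,
5-fold cross-validation on single-k grids, and 2,000-trial design
simulations. The full suite runs in a few seconds on one CPU; the
acceptance script in a few seconds more.

## Known limitations

* The production assay's 375 marker identities, coefficients and the 61
  stable probeset identities are proprietary; this package reproduces the
  *machinery*, trains on synthetic cohorts, and treats the published
  contingency counts as inputs to the statistics suite.
* Published whole-study quantities that depend on unpublished per-specimen
  scores or rater cross-tables (validation AUC 0.997, score medians
  95.6/60.8, inter-site kappas 0.87/0.93/0.86, CV medians 1.38/3.02) are
  not recomputable and are covered by property-based tests instead.
* The array-QC metric formulas are operationalizations (above), not the
  original definitions.
* One published interval — tumor-content stratum (19/19) printed as
  [85.4, 100] — is inconsistent with the exact method that reproduces every
  other interval (Clopper-Pearson gives [82.4, 100]); it is treated as a
  typesetting error, as are two internally inconsistent cells of the
  patient-attribute table.
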