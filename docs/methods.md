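# Methods

This note documents the statistical model behind `pathfabric`, the
defaults and why they were chosen, the numerical conventions, and what the
synthetic cohorts do and do not establish about real data.

## Data model and normalization

Expression is held on the linear scale, strictly positive, one column per
array, with a sample sheet assigning each array a sex, a condition
(SNS, BNS, BYS, BYA, BYP) and a replica number. BNS is the fixed reference
of every contrast. Probe-level tables are collapsed to genes by the
per-sample median across probes (robust to single bad spots); the
across-probe CV is retained per gene as its technical variability.

WPR is linear in the reference mean μ, so its magnitude would inherit
arbitrary fluorescence units. Every array is therefore divided by its own
median, putting μ in *array-median units*: WPR becomes dimensionless and
O(1–10), and any common per-array scale factor cancels. The normalization
is idempotent, and only WPR ratios computed under one normalization scheme
are comparable — absolute WPR values from differently normalized data are
not.

Missing values are handled pairwise-complete with the effective replica
count recorded; genes quantified in one sex only are analysed within that
sex. Condition cells with fewer than two replicas are refused (the call
criterion needs a variance).

## Regulation calls

For each gene, the signed fold-change is x = μ_test/μ_ref when
μ_test ≥ μ_ref, else −μ_ref/μ_test, so |x| ≥ 1 and equal means give +1.
The call is U (or D) only when both hold:

* |x| ≥ cut, with cut = 1 + √(cv_test² + cv_ref² + tech_test² + tech_ref²).
  The cut-off realizes "ratio exceeds the pooled biological and technical
  variabilities" as a root-sum-square of the four CVs; technical CVs
  default to 0 when only gene-level data exist. A fold-change exactly at
  the cut counts as regulated (the ≥/≤ convention mirrors the fold-change
  branch).
* Welch (unequal-variance) two-tailed p < α (default 0.05), computed on
  log2 values since fold-changes are multiplicative. Means and CVs for x
  and the cut stay on the linear scale. Identical samples, or zero
  variance on both sides with equal means, give p = 1.

No multiple-testing correction is applied — the combined criterion is used
with a raw per-gene α, as is standard for this scoring approach, and the
null calibration below quantifies the consequence. At n = 4 replicas the
estimated-CV cut-off turns out to be almost entirely subsumed by the
t-test: under the null, genes with p < 0.05 nearly always clear the
estimated cut as well, so the realized false-call rate is ≈ 4%, just below
α rather than far below it. This matters for interpreting GER (see
Limitations).

## Scores

* **WPR** averages μ·(|x|−1)·(1−p) over *all* quantified pathway genes —
  the (1−p) term weights by confidence instead of filtering, which is the
  score's point. WPR ≥ 0, zero only if every gene has |x| = 1 or p = 1,
  and scales linearly with μ units (hence the median normalization).
  The whole transcriptome (`ALL`) is treated as one large pathway; genes
  in several pathways contribute fully to each.
* **GER** uses the nine (disease-call, treated-call) classes; {XX} genes
  are excluded from numerator and denominator. An all-XX table leaves GER
  undefined; it is reported as NaN (not applicable), never 0.
* **PRE** is undefined when the untreated WPR is 0 (nothing to restore);
  likewise NaN.
* Treatments are compared across the five per-pathway scores with an
  unpaired Welch t-test by default; a paired variant is available behind a
  flag since the pairing scheme is a genuine modelling choice.

## ANOVA sample size

Fixed-effects one-way ANOVA power uses the noncentral F distribution:
noncentrality λ = f²·k·n for Cohen's effect size f, df (k−1, k·n−k), power
= the noncentral-F upper tail above the central-F critical value at α. The
required per-group n is the smallest integer (from 2) reaching the target;
power is non-decreasing in n, so linear search is exact. The test suite
cross-checks the noncentral-F route against a 20,000-replicate Monte-Carlo
ANOVA.

## Coordination networks

Within one sex and condition only (never pooled across conditions), each
unordered pathway gene pair is classified from the Pearson correlation of
log2 expression across the four replicas: synergistic (r > 0, p < 0.05),
antagonistic (r < 0, p < 0.05), independent otherwise, with
t = r·√((n−2)/(1−r²)) on n−2 df and p = 0 by convention at |r| = 1.
Constant or incompletely quantified genes are skipped. At n = 4 the rule
is equivalent to |r| ≥ 0.950 (3 d.p.); with per-pair α = 0.05 and no
multiplicity correction about 5% of truly independent pairs are expected
to appear coordinated, and the suite verifies that calibration.

## Synthetic cohorts

The generator reproduces the study's design so that calls, scores and
networks can be validated against planted truth: 2 sexes × 5 conditions ×
4 replicas, 17,000 genes by default with 3.5% unquantified in females
(≈16.4k quantified), 1–4 probes per gene, lognormal baselines
(log2 mean 3, sd 2 — a typical array dynamic range).

Defaults, chosen once as the study conditions:

* per-gene biological CV uniform in (0.05, 0.40); technical CV 0.05;
* 30% of genes regulated in BYS vs BNS, |FC| uniform in (1.5, 4.0), half
  up-regulated;
* treatments copy the disease effects, revert a recovery fraction
  (BYA 0.65, BYP 0.75) and newly perturb 2% of unaffected genes with the
  same effect-size distribution. These values place the recovery scores in
  the reported 55–75% band and preserve the reported ordering (PMX53
  slightly more efficient than ACTH). Every gene is exactly one of
  restored / persistent / side-effect / untouched per treatment;
* the female cohort shares the planted gene sets and directions but scales
  |FC − 1| by 1/3, so the score system — not the gene lists — must
  separate the sexes;
* SNS is generated identically to BNS (that contrast is out of analytic
  scope);
* optional co-expressed blocks share a latent replicate factor (default
  correlation 0.9) to plant network structure.

Noise is multiplicative lognormal (normal on log2) for both biological and
technical components, mean-corrected so the expectation equals the planted
level. Everything is bit-reproducible from (config, seed), and the truth
ledger round-trips through tab-delimited text.

What the generator does **not** emulate: dye/channel effects and spatial
artifacts of two-colour arrays, probe-specific affinity, correlated
gene–gene structure beyond the optional blocks, heavy-tailed outliers, and
real KEGG pathway memberships (pathway sets are random gene sets of
synapse-pathway size; a small illustrative GMT of the five synapse
pathways ships in `data/`). Passing tests therefore establish the
*statistical* behaviour of the pipeline under the design's sampling
structure, not agreement with any real-data values.

## Problem sizes in tests and analyses

The analysis scripts run the full 17,000-gene design. The test suite uses
cohorts of 300–6,000 genes and 10–20 seeds per property — sizes at which
binomial error on a 30% fraction is ≤ 1 point and each property's
expected effect is many standard errors wide.

## Known limitations

* **GER dilution.** Because the combined call criterion's realized null
  rate is ≈ 4% at n = 4, false calls dilute GER's denominator: measured
  GER sits several points below the planted (restored − side-effect)
  balance over the planted regulated genes, and tracks it closely only
  when referred to the genes *called* regulated in either contrast (the
  score's own "all regulated genes" denominator). This is the arbitrariness
  of cut-off-based recovery scores that PRE is designed to avoid.
* **Cross-sex WPR ratio attenuation.** Scaling female |FC − 1| by s does
  not scale WPR by s: weaker effects carry larger p (smaller 1 − p
  weights), and unregulated genes contribute a small noise floor to both
  sexes. At s = 1/3 the realized whole-transcriptome male:female ratio is
  ≈ 2.5 rather than 3; the same mechanism lowers the female regulated
  *percentage* (≈ 21% vs the male 30%), more than the modest sex
  difference reported on real data. A generator aiming to match both the
  percentage and the ratio would need a different female effect model
  (e.g. scaling a subset of effects only).
* Absolute WPR magnitudes depend on the normalization; only within-scheme
  comparisons and ratios are meaningful.
* The per-spot technical variability of duplicate probes is summarized as
  a per-gene CV; no claim is made that this matches the original arrays'
  spot-level model.
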