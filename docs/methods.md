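# Methods

## Disproportionality model

A spontaneous-report database is summarised per cancer type by a 2×2 table:
`a`/`b` count study-drug reports (≥1 suspect anti-PD-1/PD-L1 agent, no
anti-CTLA-4 agent in any role, receipt date inside the reporting window)
with/without an irAE term, and `c`/`d` count every other in-window report.
The reporting odds ratio is ROR = (a·d)/(b·c); its 95% interval is the Wald
interval on the log scale, exp(ln ROR ± z₀.₉₇₅·√(1/a+1/b+1/c+1/d)). Choices
behind this:

- **CI method.** Wald on log-ROR is the standard closed form in
  disproportionality work and has a testable coverage property: the
  acceptance suite verifies empirical coverage within [0.93, 0.97] at true
  OR ∈ {0.5, 1, 3} over 2,000 simulated tables per setting with expected
  cell counts ≥ 5. Exact (conditional) intervals are asymmetric and would
  be preferable for single-digit cells, but they have no closed form;
  published small-count intervals that are asymmetric on the log scale
  (e.g. a rare-type interval like 0.65 with CI 0.02–4.18) are consistent
  with an exact method and will not match the Wald interval.
- **Zero cells.** Haldane–Anscombe: +0.5 on all four cells, applied only
  when at least one cell is zero, flagged in the output
  (`correction_applied`). This keeps rare-cancer strata estimable.
- **Report = patient.** A report counts once in `a` no matter how many
  irAE terms it lists; matching of adverse-event preferred terms against
  the curated irAE list is case-insensitive after whitespace collapsing.
- **Comparator.** The full database minus the study stratum, regardless of
  indication. Reports excluded from the study stratum because of
  anti-CTLA-4 co-treatment remain part of the database and therefore of
  the comparator.
- **Dates.** ISO-8601, window endpoints inclusive; default window
  2014-07-01..2019-06-30. Drug matching is exact on lower-cased generic
  names — no fuzzy matching.

## Omics scores

- **TMB**: count of MAF records per sample whose variant classification is
  protein-altering (Missense/Nonsense, frameshift and in-frame indels,
  splice site, nonstop, translation start). Unknown classifications warn
  and count as silent (configurable to error). Samples on the roster with
  no records get 0.
- **Cytolytic activity**: exp(mean(ln(x + 0.01))) over GZMA and PRF1 on the
  TPM-like scale. The 0.01 offset guards against zeros while perturbing
  typical values negligibly.
- **Signature score**: mean per-gene z-score of log2(x+1) expression,
  sample standard deviation (n−1), computed across the samples of the
  matrix it is given — call it per cancer type for within-type scoring
  (the default posture; pan-cancer scoring is a matter of which matrix you
  pass). Zero-variance genes are excluded with a warning. This is a
  deliberately simple monotone summary of coordinate up-regulation; scores
  are *not* GSVA/ssGSEA enrichment scores and are not claimed to match
  them.
- **Medians**: per factor and cancer type, with the midpoint convention at
  even n. Missing values stay missing (NaN) — never silently zero —
  and each model later selects its own complete cases.

## Screening

Spearman's ρ between each factor's per-type medians and the ROR vector,
pairwise-complete per factor, with factors skipped (warning) below 4
complete pairs or at zero rank variance. Two-sided p-values use the exact
permutation null for n ≤ 9 (full n! enumeration over rank orders, tie-aware)
and the t transformation t = ρ·√((n−2)/(1−ρ²)) with n−2 df otherwise; at
n = 7 the two agree within 0.05 absolute (verified by enumeration).
Benjamini–Hochberg adjustment runs within feature family by default (mRNA,
curated factors, …) because the families differ by orders of magnitude in
size; a joint option exists. Ordering is deterministic: |ρ| descending,
ties by factor name.

Over-representation of a query gene set in annotation categories uses the
hypergeometric upper tail P(X ≥ k) with BH across categories; query genes
outside the universe are dropped with a warning.

## Model selection

OLS with intercept via `numpy.linalg.lstsq` on the complete cases of each
candidate combination (per-model complete cases, not listwise). The
Gaussian log-likelihood is ℓ = −n/2·(ln(2πσ̂²)+1) with σ̂² = RSS/n floored
at 1e−12 so noiseless fixtures keep finite likelihoods. Leave-one-out
cross-validation refits on every n−1 subset and scores Rs =
Spearman(held-out predictions, observed response); a poisoning test in the
suite verifies that a row's own prediction is unaffected by its response.

The response is the **log-ROR by default** in the pipeline wrapper: odds
ratios live on a multiplicative scale (their sampling intervals are
log-normal), and regressing the raw ROR on linear factors leaves a shared
curvature residual that masks the incremental contribution of a second
predictor. `fit_linear`/`enumerate_models` themselves are scale-agnostic —
they model whatever response the factor table carries — and
`run_pipeline(response_scale="natural")` reproduces the raw-ROR
formulation, whose printed equations are the familiar
`b₁·x₁ + b₂·x₂ + intercept` form.

**Selection rule** (forward-stepwise over arity):

1. best univariate by Rs, gated by its improvement over the intercept-only
   model;
2. among all pairs, the highest-Rs pair that raises Rs and significantly
   improves on its best nested univariate;
3. beyond two factors, only one-factor *extensions* of the current model
   are tested, each against the current model, with BH adjustment across
   the extensions tried in that round.

Gates use the exact-F form of the nested Gaussian comparison: the
chi-square reference for 2·Δℓ is anti-conservative at n in the twenties
(the suite measures its null p-distribution and the F form's calibration),
while F is exact under normal errors. `likelihood_ratio_test` itself
reports the conventional chi-square statistic and p, and the model report
carries both (`lrt_p`, `gate_p`). The report also BH-adjusts the Rs
p-values within each arity stratum (`rs_fdr`) and lists every model in a
deterministic order (Rs descending, then predictor tuple).

The stepwise structure — rather than admitting any model whose own LRT
gate passes — matters: candidate factors emerging from a >2,000-feature
screen on 26 data points include chance correlates of the realized
response, and within the same dataset no refit can unmask them (the screen
already used every row, so their association survives cross-validation).
The FDR gate at the screening stage is the principled defence, and the
selection stage tests one guarded refinement per arity instead of running
an unprotected race among dozens of near-ties.

VIF for factor j is 1/(1−R²) from regressing j on the other candidates
over joint complete cases; exact collinearity is reported as an infinite
VIF flag, not an exception.

## Patient-level validation

Markers are compared between groups with the pooled-variance Student t
test by default (Welch by flag), combined across markers by per-patient
geometric mean (positive values required; an explicit offset handles
zeros), and scored by ROC/AUC in the Mann–Whitney rank formulation with
half-credit ties. The trapezoidal area of the reported curve equals the
rank AUC to 1e−10 in the absence of ties (tested). Subgroup analyses are
filters on `irae_category`/`cancer_group` before the same statistics.

## Synthetic data: what it emulates, and what it does not

`SimulationConfig` defaults define the reference conditions:

| parameter | default | rationale |
|---|---|---|
| cancer types | 26 TCGA codes | pan-cancer anti-PD-1/PD-L1 reporting breadth |
| study reports | ~18.8k total, 260–2,400 per type | matches the scale of a five-year anti-PD-1/PD-L1 extract; moderately heavy-tailed with a per-type floor so every stratum yields a usable ROR |
| comparator size | 30,000 | large enough that comparator noise is negligible |
| baseline irAE probability p₀ | 0.10 | with the planted ROR spectrum this yields an overall study-side irAE fraction near 19% — the regime of real anti-PD-1/PD-L1 reporting |
| planted ROR | 3.3 (LUAD) … 0.65 (UCS) | spans the published range of per-cancer irAE RORs |
| study irAE probability p₁(t) | odds(p₁)/odds(p₀) = ROR_t | plants the ROR exactly |
| null features | 2,000 | large-screen multiplicity at desk scale |
| samples per type | 50 | median noise ≈ 1.2533σ/√n appreciably below the between-type signal |
| planted pair | LCP1, ADPGK; joint R² 0.85 | two expression features whose latent components sum to log-ROR |
| contrast share | 0.03 of Var(L) | zero-sum latent contrasts split the signal so the pair is jointly, not individually, optimal |
| curated factors | TCR diversity, CD8, neoantigen load, eosinophils, neutrophils | weak-to-moderate correlates (planted ρ ≈ 0–0.4), mirroring single-factor biomarkers |
| mutations | overdispersed Poisson, log-mean slope 0.08 on L, lognormal sd 1.0 | TMB is a real but weak correlate, with realistic overdispersion |
| cohort | 14 irAE + 14 non-irAE, 26/28 lung, markers lognormal with d = 1.1 (LCP1, ADPGK), 0.3 (CD8) | a small IHC validation cohort; analytic AUC Φ(d/√2) ≈ 0.78 for the main markers |

The planted R² of 0.85 is defined **against the observed response**: the
generator computes the expected Wald sampling variance of the log-ROR
under the configured reporting volumes and budgets it inside the 15%
unexplained share, so the pair's regression on the *estimated* log-ROR —
what the pipeline actually fits — attains the target. If the configured
volumes are so small that estimation noise alone exceeds the unexplained
budget, configuration fails loudly rather than silently planting a weaker
signal.

Decoy reports exercise every exclusion branch (anti-CTLA-4 co-treatment,
out-of-window dates, concomitant-only study drugs) and are flagged in the
ground truth; in-window decoys are counted into the comparator cells, as
the full-database comparator dictates. All generation is driven by
`numpy.random.Generator` streams spawned from the single seed; identical
configurations produce byte-identical files (tested).

Deliberately not emulated: MedDRA term hierarchies and coding noise,
duplicate reports, reporting-rate secular trends, TCGA batch structure,
expression count distributions (features are truncated Gaussians on a
log-like scale), linkage disequilibrium among features beyond one
equicorrelated block (per-type shared latent, pairwise r = 0.9, for VIF
checks), and any real biology connecting the factor names to the planted
signal. Passing the benchmarks therefore demonstrates that the *pipeline
machinery* recovers known structure under honest multiplicity and noise —
not that any particular gene predicts irAEs in patients.

## Benchmarks and problem sizes

The acceptance suite runs, at fixed seeds: Wald coverage (3 × 2,000
tables, 200 study / 1,000 comparator reports per table); screening FDR
(200 replicates of 2,000 nulls + 20 planted factors at 26 types; mean
false-discovery proportion ≤ 0.08 at the 0.05 level); null-LRT uniformity
(1,000 replicates at n = 200, where the chi-square reference is valid);
planted-pair recovery (50 full-pipeline replicates at the reference
configuration, ≥ 90% required); t-test size (10,000 null replicates,
rejection rate within [0.04, 0.06]); binormal AUC agreement; and
byte-identical end-to-end determinism.

## Known limitations

- The Wald interval undercovers when expected cells drop to single digits;
  rare-type RORs (few hundred reports, low baseline rates) carry log-scale
  noise of sd ≈ 0.2 that no downstream model can remove.
- With 26 observations, factors surviving a >2,000-feature screen can be
  chance correlates; the pipeline controls their *rate* (BH), not their
  individual identity, and roughly one seed in seven admits one such
  factor to the candidate set.
- The chi-square LRT p-values reported per model are asymptotic; at n = 26
  they overstate significance (hence the exact-F adoption gates).
- `signature_score` is not an enrichment method; gene-set scores from GSVA
  or ssGSEA will differ in value (though typically not in rank) and should
  not be compared numerically.
- The report parser expects the package's normalised long-format dialect;
  raw FAERS quarterly ASCII ingestion (deduplication, drug-name mapping)
  is out of scope.
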