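# iraescreen

Discovery and validation of biomarkers for **immune-related adverse events
(irAEs)** — the autoimmune-like toxicities (pneumonitis, colitis,
myocarditis, …) of anti-PD-1/PD-L1 checkpoint immunotherapy — by combining
real-world pharmacovigilance data with tumor multi-omics profiles.

The package is aimed at computational biologists and pharmacoepidemiologists
who want to screen molecular factors against population-level toxicity
signals when a patient-level multi-omics irAE cohort of adequate size is
unavailable.

## The method

1. **Disproportionality analysis.** From individual safety reports (one
   report ≈ one patient, with drugs, suspect/concomitant roles, cancer
   indication and adverse-event terms), reports naming an anti-PD-1/PD-L1
   agent as *suspect* — and no anti-CTLA-4 agent — form the study stratum.
   Per cancer type *t* the reporting odds ratio against the full database
   comparator is

   ROR_t = (a_t / b_t) / (c / d),

   with a Wald 95% CI, exp( ln ROR ± 1.96·√(1/a + 1/b + 1/c + 1/d) ), and a
   Haldane–Anscombe +0.5 correction when a cell is zero.

2. **Per-cancer factor medians.** Per-sample omics scores — every gene's
   expression, tumor mutational burden (nonsilent mutations per sample),
   cytolytic activity (geometric mean of *GZMA* and *PRF1*), mean z-score
   signature scores, and precomputed immunological factors (TCR diversity,
   immune-cell abundances, neoantigen load) — are collapsed to one median
   per cancer type.

3. **Screening.** Each factor's per-type medians are correlated with the
   ROR vector by Spearman's ρ (exact permutation p for n ≤ 9, t
   approximation otherwise) with Benjamini–Hochberg FDR control per feature
   family. Top genes can be tested for category over-representation with a
   hypergeometric test.

4. **Model selection.** All univariate, bivariate and trivariate OLS models
   over the significantly screened factors are scored by the Spearman
   correlation Rs between leave-one-out cross-validated predictions and the
   observed (log-)ROR, and 1 − Rs² is reported as unexplained variance.
   Selection is forward-stepwise with likelihood-ratio gates: a larger
   model is adopted only when it raises Rs *and* significantly improves the
   fit over its best nested submodel. Multicollinearity is checked with
   variance inflation factors.

5. **Patient-level validation.** Candidate markers quantified per patient
   are compared between irAE and non-irAE groups with an unpaired
   Student's t test, combined by geometric mean, and evaluated as
   classifiers by ROC/AUC (Mann–Whitney formulation, ties half credit).

A fully parameterised synthetic-data generator (`iraescreen.simulate`)
emulates all three inputs — FAERS-style report tables, TCGA-style omics
matrices and an IHC validation cohort — with planted ground truth (true
per-cancer RORs, a planted factor pair tied to log-ROR, known marker effect
sizes), so the whole pipeline is testable end to end without any downloads.

## Worked example

```python
from iraescreen.pipeline import run_pipeline
from iraescreen.simulate import SimulationConfig

result = run_pipeline(SimulationConfig(seed=1))

luad = next(r for r in result.ror_results if r.cancer_type == "LUAD")
print(f"LUAD ROR = {luad.ror:.2f} (95% CI {luad.ci_low:.2f}-{luad.ci_high:.2f})")
print(result.screen.head(3)[["factor", "rho", "fdr", "family"]].to_string(index=False))
sel = result.model_report.selected
row = result.model_report.models.set_index("predictors").loc[[sel]].iloc[0]
print(f"selected model: {' + '.join(sel)}  (CV Rs = {row['rs']:.2f}, "
      f"unexplained variance = {1 - row['rs']**2:.2f})")
for marker, v in result.validation.items():
    print(f"{marker}: AUC = {v['auc']:.2f}, t-test p = {v['p']:.3f}")
```

prints

```
LUAD ROR = 3.30 (95% CI 2.99-3.64)
   factor       rho      fdr family
     LCP1  0.860513 0.000035   mRNA
    ADPGK  0.809231 0.000561   mRNA
GENE01610 -0.656068 0.183174   mRNA
selected model: ADPGK + LCP1  (CV Rs = 0.90, unexplained variance = 0.20)
LCP1: AUC = 0.81, t-test p = 0.001
ADPGK: AUC = 0.80, t-test p = 0.030
LCP1+ADPGK: AUC = 0.95, t-test p = 0.001
```

Reading: lung adenocarcinoma shows the strongest irAE reporting signal
(odds of an irAE report ~3.3× the full-database comparator). The screen
surfaces the two planted genes at the top of ~2,000 candidates; the
selected bivariate model predicts the held-out log-ROR with rank
correlation 0.90, leaving 20% of the variation unexplained; and in the
28-patient cohort each marker separates irAE from non-irAE patients
(AUC ≈ 0.8), with the geometric-mean combination doing better than either
alone.

## Command line

Each stage is also a subcommand of `irae`:

```bash
irae simulate --seed 1 --out sim/          # synthetic input bundle + ground truth
irae ror      --reports sim/reports.tsv --out ror_out
irae factors  --expr sim/expression.tsv --annot sim/annot.tsv \
              --maf sim/mutations.maf.tsv --curated sim/curated_factors.tsv \
              --out factors.tsv
irae screen   --factors factors.tsv --ror ror_out.tsv --out screen.tsv
irae select   --factors factors_with_ror.tsv --max-arity 3 --out select_out
irae validate --cohort sim/cohort.tsv --markers LCP1,ADPGK --out val_out
irae enrich   --query top_genes.txt --gmt sets.gmt --universe universe.txt \
              --out enrich.tsv
```

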