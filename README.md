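# pharmvig-tma

Pharmacovigilance signal detection and risk modelling for thrombotic
microangiopathy (TMA) associated with VEGF-ligand inhibitors (VEGFi, e.g.
bevacizumab) and VEGF-receptor inhibitors (VEGFRi, e.g. sunitinib) in
oncology.

TMA — microvascular thrombosis with mechanical haemolysis and platelet
consumption, typically renal — is a rare but severe complication of
anti-angiogenic cancer therapy. This package implements, as one tested
pipeline, the computational chain that links drug exposure to TMA risk:

1. **Spontaneous-report signal detection.** Individual case safety reports
   (ICSRs) are validated, deduplicated on seven key fields, and drug names
   normalised against a bundled dictionary of 6 VEGFi and 16 VEGFRi
   generics. For a drug (or class) *E* and event set *A* over a report
   cohort, the reporting odds ratio is computed from the 2×2 table

   |            | event A | no event |
   |------------|---------|----------|
   | exposed    | a       | b        |
   | unexposed  | c       | d        |

   as ROR = ad/(bc) with the Woolf 95% CI
   exp(ln ROR ± z₀.₉₇₅ √(1/a + 1/b + 1/c + 1/d)) (Haldane–Anscombe 0.5
   correction when a cell is zero). A pair is a *signal* when a ≥ 3 and the
   CI lower bound exceeds 1.
2. **Covariate models.** Univariate and multivariate logistic regression of
   TMA occurrence on gender, age band, and drug class, reported as odds
   ratios with Wald intervals.
3. **Time to onset.** Days from therapy start to event onset, summarised by
   median/IQR, compared across groups by the Mann–Whitney U test, and
   displayed as cumulative-onset curves.
4. **Biochemical risk score.** Five markers (platelet count, creatinine,
   indirect bilirubin, RBC count, MCV) are standardised against the
   pre-treatment baseline, oriented so larger = worse, and combined as
   Σ sign(zᵢ)·log₂(1+|zᵢ|). Patients are binned into four tiers by baseline
   quartiles; a TTP rule (platelet < 30×10⁹/L and creatinine < 199 µmol/L,
   after the French criteria) flags patients at risk of thrombotic
   thrombocytopenic purpura. Pre→post shifts are tested with the G-test and
   Fisher's exact test.
5. **Pathway enrichment.** Single-sample GSEA (rank-weighted ECDF
   difference, exponent α = 0.25), two-group permutation GSEA
   (signal-to-noise ranking, gene-label permutation null, BH adjustment),
   and Spearman correlation of per-cancer pathway scores against per-cancer
   RORs.

Real FAERS/Vigibase extracts, hospital biochemistry, and TCGA expression are
not redistributable, so a first-class synthetic-data module
(`pharmvig_tma.synthetic`) generates seeded datasets with the same schema
and planted ground truth (association ratios, injected duplicates, shifted
gene sets, target rank correlations) for recovery testing.

## Worked example

```bash
python analysis/01_simulate_cohorts.py
python analysis/02_signal_scan.py
python analysis/03_biomarker_risk.py
python analysis/04_pathway_enrichment.py
```

Step 02 prints, for a 200 000-report synthetic cohort with class-level
reporting ratios 5 (VEGFi) and 1.2 (VEGFRi) planted over a 0.2% background:

```
deduplication: 200000 -> 189997 reports
signals: 8 of 25 exposures flagged
    exposure   a      ror   ci_low  ci_high
brolucizumab  19 5.760982 3.629179 9.145019
       VEGFi  89 5.069916 4.020575 6.393128
 bevacizumab  17 4.947727 3.040159 8.052211
...
TTO VEGFi: median 172.0 d [IQR 73.0-499.0], n=89
TTO VEGFRi: median 46.0 d [IQR 38.5-76.5], n=15
Mann-Whitney VEGFi vs VEGFRi onset: U=1105, p=5.27e-05
```

The VEGFi class and its member drugs are recovered as signals at roughly the
planted strength, the VEGFRi class is not, and the planted difference in
onset timing (log-normal medians 201 vs 35 days) is detected. Step 03
reports the pre→post marker shifts (platelet 232.6→173.8 ×10⁹/L,
p ≈ 1e-183), the upward migration of risk tiers (G-test p ≈ 2e-95), and the
TTP-flag increase with its Fisher p. Step 04 recovers the planted
down-regulated pathway (ES = −0.876, adjusted p = 0.011) and the planted
per-cancer correlation (ρ = 0.79, p = 0.0013).

The same stages are available as a CLI (`pharmvig-tma simulate|scan|
assess-risk|enrich|correlate|run-all`) and as library calls
(`pharmvig_tma.pipeline`).

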