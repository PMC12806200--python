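# Methods

This note documents the statistical procedures, the synthetic study
conditions, the numerical conventions, and the design choices made where the
problem was genuinely open. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Disproportionality analysis

For exposure *E* (a drug, or a class pooling its member drugs) and an
adverse-event term set *A* over a deduplicated report cohort, the 2×2 table
counts each report exactly once: exposed means the suspect-drug set
intersects *E* (concomitant-only exposure is excluded by default, the
standard ICSR convention), event means the report's term set intersects *A*
(case-insensitive). The reporting odds ratio is ROR = ad/(bc) with the
Woolf (log-normal) interval; when any cell is zero the Haldane–Anscombe 0.5
correction is added to all four cells and flagged. The signal rule — at
least 3 exposed event reports and CI lower bound strictly above 1 — is
deliberately strict at both boundaries.

Choices the source material left open, fixed here and configurable:

* **Comparator** = all reports in the supplied (oncology) cohort, including
  the other study class. Class-level RORs therefore attenuate toward each
  other when both classes are planted with elevated ratios; this matches
  how a class scan over one database behaves.
* **No multiplicity adjustment** on scans by default (raw RORs are
  reported); Benjamini–Hochberg flagging is available.
* Per-cancer scans emit strata with fewer than 3 exposed event reports as
  `excluded=True` rather than dropping them silently.

The Woolf interval is asymptotic: for exposures with very few expected
event reports (roughly a < 10) it is mildly anti-conservative, and the
signal rule's false-positive rate can exceed the nominal one-sided 2.5%
level there. The n ≥ 3 gate absorbs part of this; the calibration tests
evaluate the rule in the asymptotic regime it is designed for.

## Deduplication

Records are duplicates when they agree exactly on all seven key fields:
gender, age, region, event date, adverse-event set, medication (suspect ∪
concomitant, order-insensitive), and indication. Missing values participate
as a distinct sentinel, so two records both missing age can still match.
The first record by stable input order survives; the operation is
idempotent. Whether the original procedure compared full event *sets* or
any shared term is not stated anywhere authoritative; set equality is
implemented.

## Logistic covariate models

Binary TMA occurrence is regressed on categorical factors (gender, age
band, drug class) with reference levels male / 0–44 / VEGFRi, by maximum
likelihood (Newton scoring via statsmodels) with Wald intervals — the
standard pharmacovigilance presentation. Univariate mode fits one factor at
a time; multivariate enters all three. Complete or quasi-complete
separation is reported as a non-converged fit with a diagnostic, never as
silent output. Age bands are half-open [lo, hi): 0–44, 45–64, 65–74, ≥75;
only the outer bands are anchored by the source material, the middle split
is a documented choice. Missing covariates: complete-case analysis.

## Time to onset

TTO = whole days from therapy start to event onset; missing or non-positive
intervals (including same-day onsets) are excluded and counted. Quartiles
use linear interpolation between order statistics (type 7) — IQRs depend on
this convention, so it is fixed and documented. The Mann–Whitney U test is
exact (enumeration-equivalent) when n₁+n₂ ≤ 20 with no ties, otherwise the
normal approximation with tie and continuity corrections. Cumulative-onset
curves are right-continuous step functions reaching 100%.

## Composite biochemical risk score

Markers are standardised against pre-treatment baseline means/SDs, then
multiplied by a risk orientation: −1 for platelet and RBC (decreases are
risk), +1 for creatinine, indirect bilirubin, and MCV. The composite is
Σᵢ sign(zᵢ)·log₂(1+|zᵢ|). A plain log₂ of a Z-score is undefined for
z ≤ 0; the signed variant is defined everywhere, odd, strictly monotone in
every marker, and approaches log₂|z| for large |z|. A raw Z-sum is
available (`method="raw"`). Tier cutpoints are the pre-treatment quartiles
of the composite (no numeric tier definition exists in the source
material); intervals are half-open with boundary scores going to the upper
tier. The TTP rule is the French-criteria conjunction, strict inequalities:
platelet < 30×10⁹/L AND creatinine < 199 µmol/L; missing markers yield an
undetermined flag, not `False`.

Pre/post comparisons use the unpaired Mann–Whitney test to match the named
procedure even though the design is paired (Wilcoxon signed-rank would be
more powerful; the choice is about fidelity, not power). The G-test
(2ΣO·ln(O/E), no Williams correction) is applied to the marginal pre-vs-post
tier distribution by default; the 4×4 transition-matrix G-test is also
computed since the intended table is ambiguous.

## Enrichment scoring

**ssGSEA.** Per sample, genes are ranked by expression (average ranks for
ties) and walked in decreasing order; a set's score is Σᵢ (Pᵢₙ(i) −
Pₒᵤₜ(i)) with in-set weights ∝ rank^α, α = 0.25. "Min-max" normalization
divides the whole score matrix by its range (max − min), the GSVA
convention: sign-preserving, so down-regulated sets stay negative — needed
by the downstream ROR correlation. Sets with fewer than 2 member genes
present are skipped with a warning (configurable; the documented toy oracle
uses `min_size=1`).

**Two-group GSEA.** Genes are ranked by signal-to-noise (m₁−m₂)/(s₁+s₂)
with the SD floor sᵢ ≥ 0.2·|mᵢ| + 0.2 against division blow-ups; ES is the
signed maximum deviation of the weighted Kolmogorov–Smirnov running sum
(weights |metric|^1). The null is **gene-label permutation** (seeded,
vectorised as uniform random sets of matched size): with 6 samples per
group, phenotype permutation admits at most 924 distinct relabelings —
too few for a stable null. p_perm uses the plus-one estimator
(1+#{|ES₀|≥|ES|})/(n_perm+1), so its floor is 1/(n_perm+1); NES divides ES
by the mean |ES₀| of the same sign; BH adjustment runs across sets.
Gene-label permutation under a true group difference makes null sets
slightly anti-conservative (the metric itself is shifted), which is the
standard trade-off of this scheme and is visible in the global-null
calibration test, which runs under an actual global null.

**Per-cancer correlation.** Pathway scores are summarised per cancer type
as the mean across samples (median available); Spearman ρ with average
ranks and the two-sided t-approximation p; cancers without an ROR (excluded
strata) are dropped pairwise; at least 4 pairs required.

## Synthetic study conditions

The generators' defaults are the study conditions; they are fixed once and
not tuned per test.

**ICSR cohort** (default n = 200 000 reports — a desk-scale stand-in for a
~1.5M-report oncology universe). Suspect drug per report sampled with
class shares VEGFi 4.5% / VEGFRi 5.5% / other 90%, uniform within class
(study drugs are a small minority of real oncology reporting). TMA-spectrum
event probability given the drug = planted relative reporting ratio ×
background rate 0.002 (the ~0.2% incidence seen in a decade of oncology
reports); defaults plant class ratios 5.0 (VEGFi) and 1.2 (VEGFRi).
A ratio × background exceeding 1 is a configuration error, raised before
sampling. Non-TMA reports draw a background adverse event; 30% of reports
carry a second unrelated term. Onset delays for TMA reports are log-normal
per class with medians 201 d (VEGFi) and 35 d (VEGFRi) and dispersions
calibrated so the quartiles match the printed IQRs (70–415 and 21–70 d):
σ = ln(q₃/q₁)/(2·0.6745), i.e. 1.32 and 0.89. Onset distributions are not
otherwise documented; log-normal is the standard right-skewed choice for
onset times. A configured fraction (default 5%) of records are exact copies
of earlier records on all dedup key fields with fresh report ids, recorded
in the truth sidecar. Demographic mixes are plausible database proportions;
they carry no planted structure.

**Biochemistry cohort** (default n = 1698 patients). Each marker is
bivariate normal across the two timepoints (correlation 0.7), truncated at
physiologic floors (> 0 by resampling). Default means are the printed
cohort means (platelet 233.4→171.1 ×10⁹/L, creatinine 76.4→76.7 µmol/L,
indirect bilirubin 6.9→7.9 µmol/L, RBC 3.9→3.8 ×10¹²/L, MCV 90.19→91.3 fL);
SDs are not printed anywhere and are set to clinically plausible values
(55/45, 22/23, 3.0/3.5, 0.5/0.5, 5.5/5.5) under which the printed shifts
are detectable at the reported significance. TTP flags are planted
Bernoulli fractions (1.18% pre, 3.77% post); flagged patients draw platelet
~ U(5, 30) with creatinine forced below 199. The bulk platelet mean is
adjusted so the forced-flag mixture still hits the configured mean, and
bulk draws below 30 are clipped to the threshold (strictness of the rule
keeps them unflagged), so the flagged fraction equals the configured
fraction in expectation. Note the creatinine condition is a near-null mean
shift by construction: the source cohort's creatinine change was a
distribution-shape effect (mean up, median down) that a two-mean normal
model cannot express, so no test on this synthetic marker can reach
p < 0.001 — the recovery tests therefore assert significance for the four
genuinely shifted markers only.

**Expression experiment.** log₂ expression ~ Normal(per-gene baseline
U(3,9), dispersion 1.0), 6 samples per group; planted sets' member genes
are shifted by the configured log₂ amount in the treated group; the linear
matrix is strictly positive. **Pathway-vs-ROR.** A Gaussian copula targets
the planted Spearman ρ via the Pearson parameter 2·sin(πρ/6); |ρ| = 1 uses
an exact monotone transform so the sample rank correlation is exactly ±1.

What the synthetic conditions deliberately do **not** model: stimulated
reporting and secular reporting trends, real drug co-prescription patterns,
MedDRA hierarchy effects, TCGA covariance structure, and the skewed or
heteroscedastic shapes of real laboratory markers. Passing recovery tests
shows the estimators and rules are correct and calibrated under the stated
generative model — not that real databases would yield the same numbers.

## Problem sizes and determinism

Every stochastic component takes an explicit seed and is bit-reproducible;
generators record their planted truth in JSON sidecars. The test suite runs
the recovery checks at the study sizes (200 000 reports × 100 seeds for
signal recovery; 1698 patients × 100 seeds for the biomarker stage; 2000
tables per CI-coverage point; 500 fits for Wald coverage; 50 seeds × 1000
permutations for GSEA recovery; 500 seeds for ρ recovery). Monte-Carlo
rate assertions use the nominal level plus two binomial standard errors of
the design as their bound, fixed in advance.

## Known limitations

* Exposure misclassification, dose, and therapy duration are outside the
  data model; exposure is the suspect-drug flag only.
* The logistic models fit main effects of three factors; no interactions,
  no regularisation, no exact (conditional) logistic for sparse strata.
* The TTO analysis has no censoring machinery; reports without onset dates
  are simply excluded and counted.
* ssGSEA scores are comparable within a matrix run, not across runs with
  different set collections (the range normalisation is global).
* The bundled cancer-type lookup maps exact indication strings; free-text
  indications beyond the bundled synonyms fall into "other".
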