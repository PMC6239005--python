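# Methods

This note documents the models, numeric conventions and design choices
behind `fatscreen`, and what its tests do and do not demonstrate.

## BMI-for-age z-scores

The LMS method summarises a growth reference at each age and sex by a
Box-Cox power L, a median M (kg/m²) and a coefficient of variation S.
The z-score of a BMI value X is

    z = ((X/M)^L − 1) / (L·S),    with the limit z = ln(X/M)/S as L → 0

(the switch to the logarithmic limit uses |L| < 1e-7). Beyond |z| = 3 we
apply the WHO restricted-tail convention: the scale is linearised between
the reference's 2 SD and 3 SD values, z′ = 3 + (X − SD3pos)/(SD3pos −
SD2pos) above and the mirror image below. Without this, the negative L of
BMI references makes extreme-BMI z-scores explode; with it, z is
continuous and strictly increasing in BMI everywhere (a property test).

**Age handling.** Ages are carried in whole months, and L, M, S are
linearly interpolated to the exact age before the formula is applied.
Standard reference software instead rounds to completed months; the
difference is below one reporting decimal everywhere, and interpolation
makes z continuous in age. This is a deliberate, documented deviation.

**Classification.** Obesity is z > +2.00 SD and overweight (including
obesity) z > +1.00 SD, both strict inequalities; the same strict ">"
convention is used for every ROC threshold.

## Deuterium-dilution body composition

The dose is 0.5 g D₂O per kg body weight, recorded at the 0.001 g
weighing precision of the balance. Saliva enrichment (mg D₂O per kg
saliva water, above the pre-dose baseline) is measured at 3 h and 4 h
post-dose; the plateau value is their mean minus baseline — the mean is
the operative quantity because the 2% plateau-agreement criterion is
defined relative to it. Total body water is

    TBW (kg) = [dose (mg) / Δenrichment (mg/kg)] / 1.041

where 1.041 is the conventional ratio of the deuterium dilution space to
TBW, correcting for exchange with non-aqueous hydrogen. It is exposed as
`DILUTION_SPACE_RATIO` so alternative corrections can be tested; field
protocols for saliva FTIR measurements use this value, but any given
study's exact convention cannot always be confirmed from its report.

Fat-free mass is TBW divided by the hydration of fat-free mass. The
hydration coefficients ship as an editable CSV keyed by sex and one-year
age band (Lohman-type constants: boys 0.768 / 0.762, girls 0.776 / 0.770
for 8–10 / 10–12 years); the table file, not hard-coded numbers, is the
source of truth, because these constants are configuration, not part of
the method. Fat mass = weight − FFM (returned even when negative, which
QC then flags), body-fat % = 100·FM/weight, FMI = FM/height², FFMI =
FFM/height². The identities FM + FFM = weight and FMI + FFMI = BMI hold
to 1e-9 on every record and are asserted in tests.

Excessive fatness — the truth label of the diagnostic analysis — is body
fat > 25% in boys and > 30% in girls (strict), thresholds at which
cardiometabolic risk rises markedly in childhood.

## Quality control

Four criteria, in cascade:

1. **Plateau agreement** — each post-dose sample within 2% (inclusive) of
   the two samples' mean; a zero mean fails.
2. **Enrichment range** — TBW/weight must lie in [0.30, 0.80] (the
   physiological hydration-fraction envelope), and the record must not be
   an outlier (|studentized residual| > 3) in the cohort OLS regression
   of ln TBW on ln height.
3. **Fat outlier** — body-fat % must lie in [3, 60] and not be an
   outlier (same cut) in the cohort regression of fat % on BMI-z.
4. **Centre exclusion** — a centre whose failure rate over criteria 1–3
   strictly exceeds 10% is dropped wholesale, including its passing
   records.

The numeric bounds in 2–3 are this package's operationalisation of
screens that dosing protocols describe qualitatively; they are defaults
in `QCThresholds`, not universal constants, and the report logs them.
The regression screens are fitted once on the pre-filter cohort (a
deterministic single fit; iterative refitting is available behind
`refit_after_exclusion`), restricted to records passing the bounds
screens — otherwise grossly corrupted records (e.g. enrichments implying
negative fat) inflate the residual scale and mask moderate outliers.
Cohorts with fewer than 10 usable records skip the regression screens
and apply the bounds only.

## Diagnostic accuracy

Sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), PPV = TP/(TP+FP),
NPV = TN/(TN+FN), prevalence = (TP+FN)/n, each reported as a percentage
with a 95% binomial CI. The default interval is Clopper–Pearson exact
(beta quantiles, with the k=0 and k=n bounds exactly 0 and 100); Wilson
score intervals are first-class via `ci_method="wilson"`. The exact
method was pinned after verifying that it reproduces all fifteen
published one-decimal intervals of the reference analysis while Wilson
reproduces only four — that verification is a test in the suite.
Zero-denominator metrics return an explicit undefined marker. Display
rounding is half-up to one decimal, matching printed tables; JSON exports
keep full precision.

## ROC and Youden analysis

Operating points are evaluated at every observed score plus a −∞
sentinel, under the strict "score > threshold" rule, so the curve is
exact for the empirical distribution. AUC is the trapezoid over
(1 − specificity, sensitivity), which for this construction equals the
Mann–Whitney probability with ½ credit for ties — the equivalence is a
pinned test on random instances, not an assumption. The Youden cutoff
maximises J = sensitivity + specificity − 1; exact ties break toward the
smallest cutoff (maximal sensitivity) by default, with the largest-cutoff
rule behind a flag, and ties are flagged on the curve object. The
country-level association between median BMI-z and median fat % uses
Spearman rank correlation with average ranks for ties.

AUC and the optimal cutoff cannot be validated against published
headline values without the raw per-child scores, which are never
printed; they are therefore validated against brute-force oracles and
the binormal closed form Φ(μ/√2) on synthetic data instead.

## Synthetic cohorts

The generator emulates the structure the analysis assumes, not any real
country's data:

* eight centres — seven of ~150 children, one of 350 — with BMI-z means
  from −1.32 to +0.68 (locations echoing the spread observed across
  urban African study sites) and common SD 1.30, truncated at ±3 SD;
* sex ratio 53.5% girls; ages uniform over 96–143 months;
* a deterministic LMS fixture reference with smooth parameter curves
  (negative L, S rising with age); BMI is obtained by inverting the
  z-score formula (restricted tails included), so pipeline z-scores
  recover the drawn z exactly;
* heights from a linear growth model (≈5.5–6 cm/year, noise SD 4 cm);
* fat % linear in BMI-z: intercepts 22.0 (boys) / 26.4 (girls), slope
  4.2 %/SD, residual SD 6.0 truncated at ±2.5 SD and redrawn into
  [4, 58]%. These values were calibrated once so the pipeline lands in
  the regime of a large multicentre child cohort — fat-excess prevalence
  ≈ 0.29 and AUC ≈ 0.86 (both within ±0.05 over 20 seeds) — and are a
  tuning, not a reproduction of any measured cohort;
* enrichments synthesised by inverting the dilution equation from the
  true TBW, with 0.5% multiplicative noise per post-dose sample applied
  on the enrichment scale, where the instrument operates; baseline
  ≈ 150 mg/kg (natural deuterium abundance in water).

**QC conditioning.** At realistic noise levels, a 3σ residual screen over
1400 records is expected to flag a handful of genuine draws (the
studentized residual of ln TBW on ln height trends ≈ 0.55σ per BMI-z
unit, so very-high-z children are natural outliers under a height-only
screen). The generator's contract, however, is that clean records pass
QC by construction, so that injected failures are the *only* failures
and the injection ledger is an exact oracle. It therefore previews the
QC cascade with tightened thresholds (residual cut 2.7, ratio bounds
[0.32, 0.78]) and redraws the noise of flagged records — and, for
records that remain unscreenable, their BMI-z — until the cohort passes.
Clean cohorts are thus draws conditioned on passing their own QC. This
is a mild truncation of joint noise tails and a deliberate non-feature
for realism: real cohorts do lose ~2% of measures to QC, and passing
tests on conditioned cohorts demonstrates the pipeline's bookkeeping,
not the field failure rate. The conditioning is deterministic given
(config, seed) and can be disabled (`condition_on_qc=False`).

**Injections.** `inject_qc_failures` corrupts records per criterion at
configurable global or per-centre rates: plateau divergence (3 h sample
shifted 10%, overwhelming any opposing measurement noise), enrichment
compression (implying TBW far above the hydration envelope), or fat/BMI
mismatch (enrichments rewritten so measured fat lands 27 points from the
cohort fat-on-z prediction — anchored at the prediction, not the
record's own fat, so its residual cannot cancel the displacement). Every
injection is ledgered; a record receives at most one.

**What the generator does not model:** real anthropometric covariance
structures, country-specific distributional shapes beyond location,
isotope kinetics over time, or FTIR spectra. Parameter-recovery tests on
these cohorts show the pipeline is unbiased under its own assumptions;
they say nothing about model misspecification on field data.

## Pipeline and reporting

`ObesityScreening.fit()` runs ingest → z-scoring → body composition →
QC → classification → diagnostics → ROC and returns a results object
with a participant-flow account, per-country descriptives (median/IQR),
cross-classifications overall and by country and region (default
grouping: sub-Saharan Africa = Ghana, Kenya, Namibia, Senegal, United
Republic of Tanzania; North Africa = Morocco, Tunisia; African island =
Mauritius; overridable), a metric panel at +2.00, +1.00 and the Youden
optimum, and the ROC export. Sex encodings {M,F}, {male,female}, {1,2}
are normalised at ingest; records with unknown sex are excluded with a
logged reason (both the fatness thresholds and hydration are
sex-specific). Records missing a required field are excluded at the
stage that needs it, with a reason, never silently. Heights are accepted
in cm and converted internally to m. Reruns on identical inputs produce
byte-identical reports.

## Problem sizes used in tests

The default synthetic cohort is n = 1400 (the study-scale eight-centre
configuration); the parameter-recovery check uses 20 such cohorts;
ROC oracle checks use 40–80-record instances where brute force is exact;
the binormal AUC check uses n = 5000; CI coverage uses 2000 binomial
draws at n = 441. These sizes make every Monte-Carlo tolerance
interpretable while keeping the full suite around a minute.

## Known limitations

* The 1.041 dilution-space ratio and the hydration constants are
  conventions/configuration; studies using different values will differ
  at the second decimal of fat %.
* Criteria 2–3 of QC are operationalisations; the package cannot claim
  to reproduce any specific study's literal record-level exclusions.
* The Youden cutoff is reported at an observed score value; with a
  different search convention (e.g. a fixed grid) the reported optimum
  can shift within one grid step.
* Country-level Spearman correlations over eight points are fragile;
  the package reports them without inferential claims.
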