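# Methods

## Scope and data model

The package analyses primary-care EMR extracts of the classic two-file form:
a *patient file* (pseudonymised key, age, sex) and a *journal file* — the
coded longitudinal record split by kind into *prescription* rows (quantity,
daily dose, days' supply) and *event* rows (diagnoses, measurements with a
value, admissions with a discharge date). Clinical concepts are resolved
through a packaged synthetic code list of 65 codes grouped into 27 concepts
(diagnoses, medication classes, contacts, admissions, measurements,
registration exits, cardiovascular comorbidities). It stands in for the
licensed Read-code dictionary used in UK primary care; only the
concept-membership structure matters to the algorithms.

All dates are ISO-8601; every interval in the package is half-open
`[start, end)`, which makes person-time and supply arithmetic unambiguous.

## Synthetic population

The generator emulates an adult primary-care population under study between
2007-01-01 and 2010-01-01 (the baseline year 2008 preceded by a prescription
run-in and followed by the outcome year 2009). Defaults were chosen once to
mirror a de-industrialised UK city population and are not tuned thereafter:

| parameter | default | rationale |
|---|---|---|
| `n_adults` | 3504 | one large practice's adult list size |
| `sex_fraction_male` | 0.5025 | registry sex split |
| `asthma_prevalence` | 0.044 | coded asthma prevalence among adults |
| `copd_prevalence` | 0.045 (age ≥40) | yields ≈2.5% of all adults |
| `comorbid_asthma_given_copd` | 0.384 | share of COPD patients with an asthma label |
| `exac_rate_frequent` / `exac_rate_infrequent` | 1.4 / 0.4 per py | treated-exacerbation rates of the frequent/infrequent phenotypes |
| `frequent_fraction` | 0.25 | mid-range of the ~6% (asthma) to ~50% (COPD) frequent-exacerbator shares; a single scalar by design |
| `gp_visit_rate` | 11 /py | all-cause GP contact rate in chronic respiratory disease |
| `hosp_rate_allcause` / `hosp_rate_respiratory` | 0.30 / 0.06 per py | admission rates; respiratory admissions restricted to diseased patients |
| `los_distribution` | lognormal(μ=1.6, σ=0.8) days | mean stay ≈ 6.8 days, right-skewed |
| `death_hazard` / `transfer_hazard` | 0.01 / 0.03 per year | crude mortality and practice turnover |

Disease labels are Bernoulli draws. COPD applies to adults aged ≥40; a
configured fraction of COPD patients also carries asthma, and the non-COPD
asthma probability is adjusted downward so the *marginal* asthma prevalence
equals `asthma_prevalence` exactly (with zero prevalence the comorbid
probability is forced to zero). Diseased patients' ages are redrawn from
disease-specific truncated normals (asthma 33.1 ± 20.0 yr ≥18; COPD
61.1 ± 12.9 yr ≥40) so baseline tables show the expected age contrast.

Medication-class membership is Bernoulli per disease profile; flagged classes
are issued as 28-day repeat prescriptions from a random phase until
censoring. Combination ICS/LABA therapy is a single combined inhaler 80% of
the time and separate ICS + LABA inhalers otherwise, which exercises the
classifier's co-prescription rule. A small fraction of patients receives
maintenance OCS (28-day supplies), which both trips the severe-asthma
exclusion and occasionally the >12-scripts outlier rule, as intended.

Exacerbation heterogeneity is a two-point Poisson mixture rather than a
negative binomial: each diseased patient is latently *frequent* or
*infrequent* and accrues treated events from a homogeneous Poisson process at
the corresponding rate over their active interval. Asthma events are recorded
as an OCS course (5–7 days' supply); COPD events as OCS and/or antibiotics
(30% both, 30% OCS only, 40% antibiotics only). The two-point mixture
directly supports the ≤1 / ≥2 baseline-exacerbation stratification the
outcome analysis is designed around. GP visits and admissions are independent
Poisson processes; death and deregistration are exponential hazards that
censor every stream and leave a coded exit event in the journal.

Corruption derives a source extract by dropping patients, dropping records by
kind, duplicating records, and re-keying the survivors with source-specific
pseudonyms in shuffled order. The pseudonym→person map is retained on the
extract purely as a test oracle.

What the generator does **not** emulate — and what passing tests therefore do
not establish about real data: free-text records, coding drift between
sources (both extracts derive from identical truth records, so discordance is
purely structural), antibiotics prescribed for non-respiratory reasons
(antibiotic scripts arise only from COPD exacerbations), within-patient
correlation between spirometry and admission risk, seasonality, and
registration churn with re-registration.

## Dual verification

Matching is deterministic and two-stage: exact pseudonym key (emulating
NHS-number linkage where the sources share a keyspace), then exact agreement
on (age, sex, fingerprint of the three earliest record dates). Ambiguous
fingerprints — two or more equally good candidates on either side — are left
unmatched, never guessed. Matched patients' prescription records merge on
(patient, code, date, quantity); diagnosis-record residues are counted the
same way on (patient, code, date). Cohen's kappa is computed from the 2×2
margins; the all-agree degenerate table reports 1.0 with a degeneracy flag
rather than erroring, so identity comparisons produce a readable report.
Percentages are stored unrounded and formatted to 1 d.p. (prescription match
2 d.p.) only at presentation.

## Phenotyping

Eligibility gates apply in a fixed order (diagnosis on or before 2008-12-31;
≥2 bronchodilator scripts in Oct 2007–Dec 2008; age at the 2008-12-31
reference date; exclusion diagnoses in 2008–2009; asthma-only severe-disease
and COPD co-diagnosis rules). Bronchodilator counting includes ICS/LABA
combination products, since they contain a long-acting bronchodilator. The
severe-asthma rule is a *supply* criterion: OCS coverage intervals
`[date, date + days_supply)` are unioned within 2008 so overlapping scripts
cannot exceed calendar coverage, and >90 days excludes. Every failed gate is
logged per patient; flow counts attribute each exclusion to the first gate
that fired, so gate counts plus inclusions sum to candidates.

GOLD staging uses the spirometric convention (I ≥80, II 50–79, III 30–49,
IV <30 % predicted; missing → unknown). Lung function is the first 2008
measurement, ties broken by lowest record id. Smoking and BMI use the latest
record up to end-2008; BMI bands are <18, 18–25, (25,30], >30.
Cardiovascular comorbidity counts codes dated before 2009-12-31 inclusive.
Medication flags come from 2008 scripts; ICS+LABA is a combination product or
co-prescription of both components within the year, ICS monotherapy excludes
that group, and ICS plus LTRA-or-LAMA excludes it likewise.

## Outcomes

Episode construction sorts trigger records (OCS for asthma; OCS or
antibiotics for COPD; respiratory admissions for both) and greedily merges a
record into the running episode when it starts within `merge_window_days`
(default 14) of the episode's end; admissions extend the end to their
discharge date. With a zero window, episodes over prescription-only triggers
equal distinct trigger dates; with an infinite window each patient has at
most one episode. Baseline (2008) stratification applies the same algorithm
to 2008 records.

Follow-up runs through 2009 with exit at the earliest of death,
deregistration, or the administrative end; the stored exit date is the
exclusive bound of the half-open follow-up interval (the death day itself is
not counted), giving 365/365.25 person-years for an uncensored patient. HRU
rates count OCS short courses (days' supply ≤21, separating courses from
maintenance), antibiotic scripts, GP visits deduplicated to one per
patient-day, and admissions (all-cause, respiratory) whose dates fall inside
follow-up. Patients with >12 OCS scripts during 2008 are removed from the OCS
row — numerator and denominator — as outliers. Hospital-day summaries clip
stays to follow-up and divide by person-years.

## Alerts

The engine evaluates each rule per batch against new matching records plus a
per-(rule, patient) event buffer for count-in-window predicates. Record ids
make replay idempotent: re-ingesting an identical batch adds no state and
emits no duplicate alerts. Alerts are append-only; record retraction is out
of scope. The shipped rule file is illustrative — no canonical production
rule set exists for this design.

## Numerical and design choices

- Single-seed determinism: the pipeline derives per-stage seeds from the
  global seed via `numpy.random.SeedSequence`; no stage reads the clock.
- Person-year denominator 365.25 days; all intervals half-open.
- Tie-breaks are always explicit (record id, sorted keys) so outputs are
  byte-identical across runs.
- Degenerate inputs: empty extracts round-trip as header-only CSVs; empty
  strata emit flagged zero-person-year rows with no division; kappa on an
  empty table raises.
- Test problem sizes were chosen as the smallest that give the statistical
  checks sharp oracles: calibration checks use 99% binomial/Poisson
  confidence intervals from scipy at 3,000–10,000 patients; stratum-rate
  recovery uses ≥2,000 patients per stratum so the Poisson 99% CI half-width
  is ≈5% of the rate.

## Known limitations

- Linkage is exact-key/exact-fingerprint only; probabilistic (Fellegi–Sunter)
  linkage and clerical review are out of scope, so demographic matching
  degrades when record corruption perturbs the earliest record dates.
- Exacerbation identification from prescriptions misclassifies OCS/antibiotic
  use for other indications; the generator's antibiotics are exacerbation-only,
  so real-data specificity will be lower than test behaviour suggests.
- The COPD-with-comorbid-asthma subgroup is flagged but not separately
  modelled by the generator beyond label assignment.
- Baseline tables report crude percentages; no survey weighting or missing
  data modelling beyond explicit "unknown" bands.
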