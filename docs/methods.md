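# Methods

## Phecode status assignment

Billing codes map many-to-one onto phecodes within each vocabulary; ICD-9
and ICD-10 entries are looked up independently and never cross-mapped.
The count for a (patient, phecode) pair is the number of *distinct
calendar dates* with any mapped code — several codes mapping to one
phecode on the same day count once, and counts aggregate over the entire
record regardless of encounter type.  Status is a pure function of the
counts: case at ≥ 2 dates, missing at exactly 1 (a single mention is
treated as diagnostically ambiguous), control at 0 — unless a phecode in
the phenotype's exclusion range is present (count ≥ 1), which removes the
patient from the controls.  Exclusion handling only ever demotes would-be
controls; it cannot demote a case.  The status matrix spans the union of
the map's phecode universe and the observed phecodes, so phenotypes nobody
carries still have well-defined controls.

Covariates derived per patient: `record_length` (days between first and
last code event; 0 for single-visit records), `unique_phecode_count`
(phecodes with ≥ 1 occurrence — single-instance codes included, since they
still index utilization), and the total-illness covariate
ln(1 + unique_phecode_count).  The +1 offset keeps zero-phecode patients
finite; it is an implementation convention.  Missing sex/race map to an
explicit "unknown" level that is always retained in designs.

## Pairwise comorbidity

For each (index, other) phecode pair at each site, two logistic
regressions are fitted (each phenotype once as outcome, once as
predictor), on patients non-missing for both phecodes, with the covariate
design: current age, EHR age, ln-unique-phecodes, and dummy-coded sex and
race with the modal category as reference.  Current age and EHR age enter
jointly despite their collinearity; the Newton fitter tolerates it, and
fits that fail (non-convergence, non-finite standard errors, or |β| > 15,
a conservative quasi-separation screen) are flagged and dropped rather
than silently repaired.  No Firth fallback is applied by default so that
reported effects are plain maximum-likelihood estimates.

Each fit requires at least `min_cases` (default 20) outcome cases *and*
predictor cases in the analyzable subset; smaller fits produce unstable
Wald statistics and are skipped with a reason code.

The two directional Wald Zs are combined per site by their arithmetic
mean (the default `direction_rule`).  The two directions estimate the
same dependence and their Zs are strongly correlated, so the mean changes
little relative to either direction while damping occasional one-sided
instability; `outcome_direction_only` and `stouffer` are available for
sensitivity analyses.  If only one direction converged, every rule returns
that Z.

The scan universe is the set of phecodes occurring (count ≥ 1) in at
least one index case.  Full-grid mode schedules every ordered pair of the
universe (n² directional regressions) lazily; the index-restricted scan is
the default because only the index row/column feeds the downstream stages.

## Cross-site combination

Site Zs combine by the shared-patient-weighted average with weights
`N_AB^s` = number of patients who are cases for *both* phecodes at site s
(the joint-analyzable count is a config alternative).  The combined Z is
therefore always bracketed by the site Zs and invariant to site order.
Pairs testable at a single site keep that site's Z and are flagged
`single_site`.  If every contributing site has zero shared cases the
unweighted mean is used and logged.  p-values are `2 Φ(−|Z|)`, never
truncated to zero (underflow is clamped to the smallest positive float),
and Bonferroni control uses the number of tests actually performed as the
denominator, recorded in the output provenance.

## PRS PheWAS and meta-analysis

The score is standardized to mean 0, SD 1 within each analysis sample, so
downstream Cohen's-d equivalence bounds have a stable scale and results
are invariant to affine rescaling of the input score.  Covariates: sex,
current age, record length and the first 10 ancestry PCs (any PC columns
present in the score table are included).  Index-disorder cases are
excluded by default to isolate genetic effects independent of the
diagnosis itself.  Site estimates combine by fixed-effect inverse-variance
weighting; phecodes converged at fewer than all sites are excluded from
the meta table by default, mirroring a both-site analysis set.

Variance explained is reported as the Nagelkerke pseudo-R² difference
between the full and covariate-only models, in percent — the convention of
the PheWAS ecosystem; a liability-scale alternative would require an
assumed population prevalence per phecode and is not computed.

## TOST equivalence and Fisher combination

Equivalence bounds are Cohen's d = ±0.2 — the conventional
smallest-effect-size-of-interest — converted to the raw scale with
`s_pool = √((s₁² + s₂²)/2)`; the pooled-by-degrees-of-freedom conversion
and a pooled-variance t variant are config-switchable.  The one-sided
tests are Welch t tests with Satterthwaite degrees of freedom:

    t_upper = ((m₁ − m₂) − d_low · s_pool) / SE     rejects d ≤ d_low
    t_lower = ((m₁ − m₂) − d_high · s_pool) / SE    rejects d ≥ d_high
    SE = √(s₁²/n₁ + s₂²/n₂),   p_TOST = max(p_lower, p_upper)

TOST runs on raw (unstandardized) scores of the same sample as the
PheWAS — index cases excluded — from group summary statistics, so the
module accepts pre-summarized data.  TOST is applied to phenotypes that
are significantly comorbid *and* carry a cross-site PRS meta result; the
Bonferroni denominator is the number of phenotypes actually entering the
meta-combination, reported rather than hard-coded.  Per-site p-values
combine by Fisher's method, `χ² = −2 Σ ln p` on 2k df; a zero p (possible
only by underflow) is clamped to the smallest positive float and flagged.
All Bonferroni comparisons use strict inequality at the boundary.

## Tier classification

Tiers are a pure function of the boolean evidence and nest by
construction: equivalent-and-comorbid ⊇ additionally PRS-nonsignificant
after correction ⊇ additionally PRS p > 0.05.  The stored enum is the most
specific applicable tier; boolean columns preserve the nesting.  A
phenotype that is PRS-significant but not even nominally comorbid
(combined comorbidity p > 0.05) is reported as its own tier.  Absence from
the equivalence stream means "not shown equivalent" — non-significant
comorbidities never enter TOST, so their absence is informative, not
missing; absence of comorbidity or PRS results is missing data and forces
tier OTHER with a flag.  The literature comorbidity list used by the
hypergeometric overlap test ships as an editable TSV of transcribed
metadata, and the test takes its margins as explicit arguments because the
appropriate universe size depends on the phenome definition at hand.

## Synthetic cohort generator

The generator emulates the minimal structure the pipeline's contrasts
require, per site, from one pseudo-random stream keyed on (seed, site
index):

* score ~ N(0, 1); index liability `√h²_s · score + √(1 − h²_s) · ε` with
  threshold set by the target prevalence (liability-threshold model);
* phenotype case status from
  `logit P = logit(prev) + site + g·score + c·1[index] + b·z_u +
  age/sex terms`, where `z_u` is standardized log-utilization — the
  simplest structure exhibiting the contrast between shared-genetic (g)
  and consequence-driven (c) comorbidity, with utilization (b) as a
  confounding path;
* utilization is log-normal with a +0.25 log-shift for index cases, and
  filler-phecode event counts are Poisson in the utilization rate, so the
  ln-unique-phecode covariate has a real confounder to absorb;
* cases emit 2 + Poisson(1) events on guaranteed-distinct dates;
  non-cases emit exactly one event at rate 0.04 (exercising the
  single-instance-missing rule); one phenotype per class carries an
  exclusion-range decoy phecode emitted in ~3% of patients;
* site B applies a −0.15 intercept shift and mixes ICD-9/ICD-10 coding
  while site A is ICD-9 only (no cross-mapping is ever needed: the map
  covers both vocabularies).

Defaults, chosen once as a realistic desk-scale regime: 2 sites × 20,000
patients; index prevalence 0.02 — above the ~1% population prevalence of
the motivating disorder so that a 20,000-patient site still carries ~400
index cases, the same order of case counts per test that a 250,000-patient
cohort at 1% would provide after scaling; h²_s = 0.10, giving a
case/control score gap of d ≈ 0.75, in line with current index-disorder
PRS discrimination; 40 phenotypes at prevalence 0.05 in four blocks of 10
(genetic g = 0.15, consequence c = 1.0, mixed, null), all with burden
loading b = 0.25; log-utilization μ = ln 8, σ = 0.6; 30 filler phecodes.
Ground-truth class labels live only in `ground_truth.tsv`, never in a
pipeline-input file.

What the generator does **not** emulate: realistic ICD vocabularies,
visit-level temporal dynamics, genotype-level scores, ancestry structure
in the PCs (they are pure noise covariates), care fragmentation across
sites, or diagnosis-dependent coding intensity beyond the single
utilization shift.  Passing the recovery benchmark therefore shows the
statistical machinery is wired correctly and calibrated under the model's
own assumptions — not that the pipeline is robust to EHR pathologies the
generator omits.

## Problem sizes and numerical conventions in the test suite

The suite runs the full benchmark once (2 × 20,000 patients, seed 1,
~35 s) and reuses it across tests.  Monte-Carlo checks use sizes at which
their stated tolerances sit at ≥ 3 Monte-Carlo standard errors where the
band is two-sided (e.g. 1000 null scan pairs for the |mean Z| < 0.1
check); the TOST type-I calibration uses 2000 replicates at 500 per arm
with a one-sided 2-SE allowance.  Logistic oracle comparisons use exact
2×2 closed forms; the Fisher combiner is checked against the closed-form
even-df chi-square survival series; IVW is cross-checked against an
independent meta-analysis routine and TOST against an independent
equivalence-test implementation.

## Known limitations

* The comorbidity measure is cross-sectional: no temporal ordering of
  comorbidity onset relative to the index diagnosis, so tiers do not carry
  causal direction.
* Equivalence is relative to the d = ±0.2 bounds; a true effect of
  d = 0.1 can be *both* significantly nonzero and significantly
  equivalent in large samples — the EQUIVALENT_COMORBID tier exists for
  exactly this case.
* Wald inference throughout; rare phenotypes near the `min_cases` floor
  have noisy standard errors, which the floor mitigates but does not
  remove.
* Phecode hierarchy roll-up beyond what the map encodes is not performed.
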