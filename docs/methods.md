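# Methods

## Cohort procedure

The pipeline consumes three delimited tables — patients (demographics,
service-connection percent), encounters (one row per patient-date visit,
inpatient/outpatient), diagnoses (ICD codes per encounter) — and executes,
in order: code-set loading, encounter-level self-harm flagging, index-date
assignment, eligibility filtering, utilization stratification, lookback
exposure classification, Charlson scoring, and stratified estimation.
Every stage is deterministic given the run seed; the manifest records the
seed, thresholds, reference levels, and code-set checksum so a rerun is
bit-identical.

### Case definition

An encounter is intentional self-harm if its codes satisfy condition A
(explicit self-harm code), B (suicidal ideation AND injury/poisoning), or
C (injury/poisoning AND mental disorder). Conjunctions are evaluated
within one encounter ID — the strictest reading of "assigned for the same
encounter" — not within a calendar day. A single code may fill both slots
of a conjunction when it belongs to both sets (e.g., an intent-encoded
poisoning T-code is both explicit and injury); membership, not slot
exclusivity, is what the definition tests. Matching is prefix-based on
dot-stripped upper-cased codes and system-aware (an ICD-9 prefix never
matches an ICD-10 code). Prefix semantics is the standard dialect for
administrative extracts whose recorded digit depth varies.

The bundled code lists are **reconstructions**: the published supplement
listing the exact algorithm tables was not available, so the defaults
assemble the ranges the self-harm phenotyping literature uses (ICD-9
E950–E958 explicit, V62.84 ideation, 800–999 + E-code ranges injury,
290–319 mental disorder; ICD-10 X71–X83/T14.91 plus intent-encoded
T36–T65 poisoning codes, R45.851, S00–T88, F01–F99) and the standard
TBI/PTSD surveillance lists. All lists live in
`src/vetharm/data/default_codesets.csv` and are replaceable per run.

### Index dates and matching

Cases: date of the first flagged encounter; ties within a date resolve to
the smallest encounter ID. Controls: a calendar bin (monthly by default)
is sampled from the empirical distribution of case index dates, then one
of the control's own *index-eligible* encounters in that bin is chosen
uniformly; if the bin has none, the nearest bin containing one is used
(ties to the earlier bin). Monthly bins balance fidelity to the case
distribution against sparse per-patient encounter histories.

An encounter is *index-eligible* when it lies in the study window and the
patient has ≥2 distinct visit dates in the preceding 5 years. Restricting
control sampling to such dates is a deliberate design choice: sampling a
date that immediately disqualifies the veteran (eligibility requires
those two lookback visits) and then excluding them would both shrink the
cohort and distort the matched date distribution. Controls with no
index-eligible encounter are excluded with a logged reason.

### Eligibility, utilization, covariates

The lookback is the half-open interval `[index − 5y, index)`: the index
encounter's own codes are outcome, never exposure — otherwise condition
C's mental-disorder code would contaminate the exposure groups.
Eligibility keeps veterans with ≥2 distinct visit dates in the lookback
(the pre-index form of the inclusion rule; the alternative
"twice-in-window" reading is expressible through the config).
Utilization is distinct lookback visit dates / 5, cut at 6.6 and 15.6
visits/year by default — the published 50th/75th percentile values — or
at empirical percentiles of the eligible cohort ("at or below"
convention, LOW ⇔ rate ≤ p50) when requested.

Age is computed in completed years at the index date and binned <30,
30–44, 45–69, ≥70; service-connection bins are none / <50% / ≥50%;
unmappable race routes to Other and missing marital status to Unknown
(both retained as levels — complete-case dropping would silently change
denominators). The Charlson Comorbidity Index uses a Quan-style
ICD-9/ICD-10 prefix mapping (editable CSV) with original weights 1/2/3/6,
each condition counted once, and severity hierarchies (complicated
diabetes over uncomplicated, moderate/severe liver over mild, metastatic
tumor over other malignancy). No age points are added, since age is its
own covariate in the models. Bands follow the textual cut points: <5 low,
5–15 medium, >15 high. The CCI window equals the 5-year lookback
(config-overridable); the mapping edition is a package default because
the source analysis does not state one.

### Estimation

Per stratum: cell prevalences (half-up rounding to 2 decimals at the
report layer only); bivariable ORs as `ad/bc` with Woolf (log-normal)
95% CIs, Haldane +0.5 correction flagged on zero cells; minimally
adjusted (age, sex, race) and fully adjusted (+ ethnicity, marital,
service-connection, CCI band) logistic models fit by IRLS with Wald CIs
`exp(β ± 1.96·SE)`. The unexposed (NEITHER) group is the exposure
reference; other covariates take their largest observed category as
reference, logged in the manifest, because the source tables do not state
reference levels. On a saturated single-factor design the logistic route
reproduces the 2×2 log-OR and Woolf SE analytically, which the test suite
uses as an oracle. Non-convergence (score norm above tolerance after 50
IRLS iterations) and quasi-separation (|β| > 15) are flagged on the
result, never silently returned; a rank-deficient design raises an error
naming the collinear columns.

## Synthetic-EHR generator

The generator emulates the structure the analysis assumes: a 10-year
encounter window (2008-01-01..2017-12-31), ICD-9→ICD-10 coding transition
at 2015-10-01, heterogeneous visit rates spanning the utilization cut
points, the four exposure groups at roughly the published margins, and
self-harm outcomes either at exact configured cell counts (fixture mode)
or from a logistic model (stochastic mode). Visits are distinct
(patient, date) pairs; visit rates default to 4 / 11 / 20 visits/year for
the low/medium/high strata — values chosen inside the bands with margin
so a ±1-visit wobble cannot flip a stratum. Covariate margins default to
the published cohort's overall composition. In stochastic mode,
per-exposure-group margin overrides make covariates genuine confounders;
the default recovery scenario shifts the comorbid group young with age
effects +1.2 / +0.6 log-odds, which reproduces the crude-versus-adjusted
attenuation pattern of the reference analysis.

Fixture mode is engineered so the pipeline recovers every configured
stratum × exposure × outcome cell exactly, under any generator or
pipeline seed. Cases carry exactly one qualifying encounter (conditions
A/B/C rotating) at their designated index, so their index is
deterministic. Controls are built so that *every* index-eligible
encounter classifies identically: LOW controls keep all visits within a
<5-year span ending at the designated index; MEDIUM/HIGH controls carry
their bulk history before the window start (not sampleable as index) plus
a short in-window tail, which confines their designated indices to the
first ~4.5 years of the window. Exposure codes sit on the two earliest
lookback visits, never sharing an encounter (a TBI code is injury-class
and a PTSD code mental-class, so co-assignment would itself satisfy
condition C).

What the generator does **not** emulate: disease trajectories, repeat
self-harm, mortality, correlated covariates beyond the configured
overrides, realistic visit clustering (fixture visit spacing is regular
by construction), coding noise, or cross-system code mapping drift.
Passing round-trip tests therefore demonstrates the pipeline's logical
correctness on structurally faithful data, not robustness to real-world
coding error.

## Numerical choices

- 1.96 is used for all 95% intervals (Woolf and Wald alike) so the
  saturated-design identity holds exactly.
- IRLS: deviance tolerance 1e-10, max 50 iterations; convergence is
  additionally verified by the score norm (max |X'(y−μ)| below 1e-8,
  relaxed proportionally for large n).
- Report rounding is decimal half-up, applied only at the report layer;
  unrounded values are kept internally.
- Cell counts scaled for fixtures are rounded half away from zero.
- Monthly bins are indexed from the window start; nearest-bin fallback
  ties resolve to the earlier bin.

## Problem sizes

The bundled test suite and acceptance script run the complete round trip
at 1/100 of the reference cell counts (~67k veterans, ~3.5M encounters)
and parameter-recovery simulations at 50,000 veterans × 100 replicates
(coverage checks) and 200,000 × 12 replicates (point recovery), sizes at
which the Monte-Carlo error of recovered odds ratios is a few percent.

## Known limitations

- Wald/Woolf intervals undercover slightly when the exposed-case cell is
  small (a few hundred events or fewer); coverage checks near the nominal
  rate are therefore noisy at 100 replicates.
- The bundled code sets and Charlson mapping are reconstructions and
  defaults, not the exact published supplement lists; results on real
  extracts depend on the lists supplied.
- Control index sampling assumes each control's encounter dates span the
  case-index distribution reasonably well; with very sparse controls the
  nearest-bin fallback dominates and matching degrades (tested property:
  the chi-square distance shrinks as the control pool grows).
- Empirical utilization thresholds use linear-interpolated percentiles;
  heavy ties at the cut points shift stratum shares.
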