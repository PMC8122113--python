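# Methods

This note documents the model, its parameters and the design choices
behind `crcsim`, in the spirit of a model-description vignette.

## Natural history

Each simulated person carries an independent realization of:

1. **Other-cause mortality.** A death age is drawn from the annual
   probabilities qx of the life table, uniform within the year of
   death.  The life table is all-cause mortality; we do not subtract
   CRC mortality from it, which double-counts a small amount of death
   risk for CRC cases (a standard, conservative simplification).
2. **Adenoma onset.** A nonhomogeneous Poisson process with
   piecewise-constant (per year of age) intensity λ(a), scaled by an
   optional birth-cohort multiplier.  Onset intensity is the only
   natural-history quantity adjusted between countries.
3. **Lesion progression.** Every lesion starts as a small adenoma and
   grows small → medium → large with exponential dwell times (shared
   growth rates).  A single Bernoulli draw at lesion birth decides
   whether the lesion is *ever-progressive*; only progressive lesions
   take the large-adenoma → preclinical-stage-I transition.
   Nonprogressive adenomas may still reach the large class but never
   leave the adenoma states — this is what lets adenoma prevalence far
   exceed cancer incidence.  At each preclinical stage k the lesion
   either progresses (rate ρₖ) or surfaces clinically (rate σₖ),
   competing exponentials; preclinical IV can only surface.
4. **First clinical cancer ends the natural history** for that person
   (no second primaries).
5. **CRC survival.** Death from CRC is sampled by inverse-CDF with
   linear interpolation on the cumulative stage-specific relative
   survival over 0–10 years since diagnosis; survivors of the 10-year
   horizon never die of CRC (cure point).  Relative survival is used
   as net, cause-specific survival.  The reported death is whichever
   of CRC death and other-cause death comes first.

**Stage at diagnosis.** Clinically surfacing cancers draw their
recorded stage from the (country-supplied or benchmark) stage
distribution at diagnosis; screen-detected cancers keep the
mechanistic preclinical stage at the moment of detection.  The chain's
emergent stage mix cannot be matched to a registry's stage
distribution without re-estimating the progression/surfacing rates,
which we deliberately hold fixed (below); the categorical draw makes
the clinical stage mix exactly the registry's, while the mechanistic
stage of screen-detected cancers preserves the stage-shift benefit.
The survival benefit of screening therefore flows exclusively through
earlier stage (and adenoma removal), never through a lead-time
adjustment.

**Ages are continuous** internally (persons are born mid-year);
reported ages use completed years, half-open bands [a, a+5).

## The incidence oracle

Adenoma onsets are Poisson and lesions independent, so the surfacing
events of a person form a thinned Poisson process and the hazard of
*first* clinical diagnosis at age a is exactly

    h(a) = p_progressive · ∫₀ᵃ λ(s) g(a−s) ds

where g is the phase-type density of onset-to-surfacing time, computed
from the matrix exponential of the lesion chain's 7-state
sub-generator.  `cohort_oracle` evaluates h on a fine grid (default
step 0.02 y) with midpoint sampling of the piecewise-constant hazard —
midpoint sampling is exact across the hazard's year-boundary jumps, so
halving the step changes the result by far less than 0.1% (measured
~1e-5 relative at rates above 0.1/100k).  A mass-conservation check
(occupancy + surfaced mass = 1 ± 0.001) guards the step size.  The
oracle gives incidence per at-risk (alive and undiagnosed)
person-year, independent of other-cause mortality, and the test suite
holds the Monte Carlo engine to it within 3 binomial standard errors
per 5-year age band at 2×10⁵ persons.

## Country template and quality checks

The canonical template is a directory of CSV sections with a manifest
(`population`, `lifetable`, `incidence`, `stage_distribution`,
`relative_survival`, `screening_history`, `participation`); an XLSX
workbook with identically named sheets is accepted.  Must-have
sections are **incidence, screening-programme design, and
participation**; all others fall back to the regional benchmark and
are flagged as such.  Quality checks (errors block calibration;
warnings do not): probabilities in [0,1], stage fractions summing to
1 ± 0.001, nonnegative incidence and population counts, terminal-age
qx = 1, programme ages within 0–100 and interval ≥ 1 year,
plausibility warning when incidence jumps more than 5-fold between
adjacent bands, and a warning when stage survival curves are not
ordered I ≥ II ≥ III ≥ IV.

## Calibration (benchmark adjustment)

Four benchmark parameter sets ship with the package (Western, Eastern,
Northern, Southern Europe).  They are plausible defaults constructed
in code — onset levels scaled by region, one shared progression core —
not estimates from any specific registry.  Adjusting a benchmark to a
country replaces demography, survival, stage distribution and
screening parameters where supplied, and calibrates the onset hazard
to the country's age-band incidence.  Progression and surfacing rates
are never altered: between-country incidence differences are carried
entirely by onset.

Because expected incidence is *linear* in the onset hazard, the
per-band onset multipliers solve a linear inverse problem: the oracle
evaluates one kernel column per onset band, and a nonnegative
least-squares solve (with a light ridge toward multiplier 1, weight
1e-4 of the kernel's largest entry) returns the multipliers in one
shot.  The ridge only binds bands whose onsets barely reach the
incidence window (ages 90+), pinning them at the benchmark value
instead of leaving them unidentified.  We first implemented the more
obvious per-band incidence-ratio iteration; it diverges, because the
onset-to-diagnosis delay has a standard deviation (~8.6 y under the
default rates) wider than a 5-year band, so same-band ratios chase a
lagged, smeared signal.  A damped, lag-shifted ratio polish is kept as
a fallback for residuals above tolerance (2% maximum relative error
per band, at most 10 iterations; exceeding this raises an error naming
the worst band).  In practice the direct solve recovers synthetic
countries with known multipliers in [0.5, 2] to ~0.01%.

The template's incidence is treated as *no-screening* incidence.  Real
registry incidence from a screened population is perturbed by
screening (polypectomy lowers it; a prevalence round inflates it);
correcting for that would require modelling the historical programme
inside the calibration loop and is out of scope.  Users should prefer
pre-screening-era incidence where available.

## Screening overlay

Invitations follow the programme's age grid (start age, start +
interval, … ≤ stop age) restricted to calendar years in which the
programme operates, and stop at death or CRC diagnosis.  Attendance is
an independent Bernoulli(coverage × participation) per round — no
never-attender fraction; the config point exists to add one later.
Each prevalent lesion is detected independently with the test's
per-state sensitivity (per-round independent errors, no persistent
per-lesion miss).  A lesion-free attendee is falsely positive with
probability 1 − specificity; the false-positive flag is set only when
a positive has zero detected lesions.  Positive stool/FS tests go to
diagnostic colonoscopy with the follow-up adherence probability; the
colonoscopy re-examines *all* prevalent lesions with its own
sensitivity (so it can find lesions the stool test missed, or nothing
after a false positive).  A positive without follow-up returns the
person to the routine schedule.  Colonoscopy screening is direct
visualization: the positive result is the finding itself, with no
separate follow-up, no false positives at the default specificity of
1, and the follow-up row of the report rendered "–".

Detected adenomas are resected and never progress.  Detected
preclinical cancer becomes screen-detected at its current stage.
Findings with ≥3 adenomas or any large adenoma are high-risk and
trigger a surveillance colonoscopy after 3 years (80% participation);
low-risk findings return the person to the programme.  While a
surveillance is pending, routine invitations are suppressed.
Surveillance colonoscopies are counted separately and included in
total colonoscopy volume, flagged in the report.  Complications
(serious / cardiovascular / other) are independent Bernoulli draws per
endoscopy procedure.

## Scenario engine, common random numbers, scaling

Persons are simulated as the birth cohorts that pass through ages
40–100 during 2018–2050 (93 cohorts, equal persons per cohort).
Cohorts alive at the 2018 base year have other-cause death conditioned
on surviving to their 2018 age, since their earlier mortality is
already embodied in the pyramid; adenoma histories still run from
birth, and the pre-2018 programme history applies.  CRC deaths before
2018 are not re-conditioned (a ~1% bias in the oldest cohorts,
accepted for simplicity).

Latent natural histories are realized once per (seed, cohort) and
shared by every scenario — common random numbers, so scenario
contrasts are nearly noise-free and a scenario with inert screening is
*bitwise* identical to no screening.  Screening draws use two streams
per cohort: a pre-switch stream shared across screening scenarios
(making pre-2018 screening identical across them, as the switch-year
semantics require) and a scenario-specific post-switch stream.  The
per-person survival uniform is also shared, so a screen-detected
person's death time responds only to the stage shift.

Events are attributed to the calendar year containing their continuous
event time; counts are tallied per (year, 5-year age band, birth
cohort) and scaled by per-cohort factors (pyramid count / simulated
persons) — exact linearity.  The population is closed to migration.
Person-years are computed from a deterministic cohort-component
projection of the pyramid (deaths uniform within the year), hence
identical across scenarios; mortality benefit is reported through
death counts, not person-year gains.  Age windows "40–100" and
"50–74" are inclusive of both endpoints, evaluated at event time.

## Reporting

The headline table reports ×10,000 counts rounded half-up to two
decimals; percentage-reduction rows are recomputed from the table's
own rounded count rows, making the printed table self-consistent by
construction (recomputing a published table of this shape from its
rounded inputs can disagree with its printed reduction cells by a few
hundredths of a point — our construction avoids that by definition).
Reductions render at two decimals with trailing zeros trimmed.  False
positives are reported as a count and as a percentage of positive
tests, with the definition printed in the report (other denominators —
of all tests, of attendees — exist in the literature; ours is stated
explicitly).  Per-year series provide incidence and mortality rates
per 100,000 demographic person-years and total colonoscopies (primary
+ diagnostic follow-up + surveillance, flagged).

The default alternative scenario is 5-yearly primary colonoscopy in
the current programme's age range.  Published comparisons of this
shape variously describe colonoscopy screening as 5- or 10-yearly; the
interval is a free parameter, and at 10 years the deaths ordering
versus biennial FIT becomes a statistical tie under the shipped
defaults (biennial FIT accumulates more stage-shift benefit than three
colonoscopy rounds prevent).

## Synthetic countries

`synthetic_country` generates complete, internally consistent
templates: Gompertz-style mortality, a mildly ageing pyramid with
small seeded noise, stage mix and survival jittered within plausible
ranges (monotonicity and stage ordering preserved), 71.3% FIT
participation with a biennial 55–75 programme since 2014, and —
crucially — an incidence section computed from the ground-truth
parameters via the oracle, so calibration has an exact fixed point and
parameter recovery is testable.  What the generator does *not* emulate:
screening-perturbed registry incidence, cohort trends in risk,
migration, gender differences, and reporting artifacts of real
registries.  Passing tests therefore demonstrate internal correctness
and recoverability, not validation against any real population.

## Tunable parameters (defaults)

| Parameter | Default | Notes |
|---|---|---|
| Growth rates small→medium, medium→large | 0.20 /y | mean 5 y per class |
| Invasion rate large→preclinical I | 0.25 /y | progressive lesions only |
| Stage progression ρ (I, II, III) | 0.60, 0.60, 0.50 /y | |
| Surfacing σ (I–IV) | 0.25, 0.45, 0.70, 1.00 /y | mean preclinical sojourn ≈ 2.5 y |
| p_progressive | 0.07 | lifetime clinical risk ≈ 5% with competing death |
| FIT sensitivity (sm/md/lg adenoma; P I–IV) | .04/.10/.32; .70/.78/.84/.88 | 47 µg Hb/g label |
| FIT specificity | 0.97 | |
| Colonoscopy sensitivity | .77/.87/.95; .95/.97/.98/.98 | specificity 1.0 |
| Colonoscopy complications | 0.002/0.001/0.012 per procedure | serious/CV/other |
| Surveillance | high-risk at ≥3 adenomas or any large; 3 y; 80% participation | |
| Follow-up adherence | 0.85 | |
| Simulation size | 10⁵–2×10⁵ persons | ~10–35 s for 3 scenarios |

Problem sizes in the test suite and acceptance script (2×10⁵ persons
for scenario comparisons and oracle checks, 10⁵ for specificity
recovery) were chosen to make 3-standard-error bands decisive for the
properties under test while keeping a full run on a single CPU in the
low minutes.

## Known limitations

* No gender stratification, no lesion location (colon vs rectum), no
  serrated pathway, no quantitative hemoglobin model behind FIT
  cutoffs (a cutoff is a label selecting a sensitivity/specificity
  set), no two-sample FIT strategies, no endoscopy capacity
  constraints, no cost-effectiveness layer.
* Survival carries no calendar-period or lead-time effects beyond the
  stage shift.
* Surveillance has no age cap and continues while findings remain
  high-risk.
* The no-screening counterfactual removes the historical programme as
  well (a fully unscreened population), which is the right reference
  for "what screening achieves overall" but not for "what changing the
  programme in 2018 achieves"; the current-programme scenario serves
  as the latter reference.
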