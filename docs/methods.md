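# Methods

## Model structure and assumptions

The model is a two-arm decision tree from the perspective of the English
NHS, 2021 prices. The decision is whether to train an allied health
professional (dietitian or therapeutic radiographer) in non-medical
prescribing. The trained arm carries the training cost in year 1 and may
price a share of its patient contacts at the dearer
consultation-with-prescribing rate; both arms refer a fraction of contacts
to an external prescriber at a referral consultation cost. Safety is
assumed equal across arms (no adverse-event branch), deprescribing and
waiting-time outcomes are out of scope, and the non-prescriber arm has
`p_use_rights = 0` and zero training cost by construction.

The published probabilities are marginals — the fraction of contacts
needing prescription management, the fraction of consultations in which
the prescriber used their own qualification, and the referral fraction —
without a stated joint structure. The tree therefore treats
`p_require_rx × p_use_rights` as the share of contacts priced at the
prescribing rate and the referral as an independent per-contact cost
add-on. This uses exactly the printed marginals; it is validated against a
brute-force enumeration of all eight branch combinations in the test
suite.

### Two cost routes, deliberately

The exact unit-cost mix behind the published per-patient arm costs and
per-prescriber annual totals sits in unpublished appendices, so the
package keeps two routes side by side:

* **Reported route** — the fixtures carry the published per-patient arm
  summaries (mean, SD) and 1-/5-year arm totals verbatim; the base-case
  CEA, the PSA and the savings calculations run on these, which is why
  they reproduce the published ΔC, ICER sign/quadrant and savings exactly.
* **De-novo route** — the decision tree evaluated from main-text unit
  costs and probabilities. It agrees with the reported route to within
  roughly 5–10% (e.g. dietitian non-prescriber ≈ £179 per patient both
  ways) and is the route the tornado analysis varies, because a
  sensitivity analysis must respond to the underlying inputs. De-novo
  totals are reported next to the published ones in
  `analysis/02_service_costs.py` and are expected to agree only
  approximately.

## Key parameters

| parameter | default | unit | why |
|---|---|---|---|
| daily pay rate | salary/365 | £/day | uniquely reproduces the published backfill (£2,522), employer-paid (£797) and personal-study (£929–£7,965) costs |
| work-time fraction on course | 0.5 | — | trainees spent about half their work time on the programme |
| weeks worked | 48 | weeks/year | stated working-year assumption |
| discount rate | 0.035 | p.a. | NICE reference case; years 2+ only, year 1 undiscounted |
| WTP threshold λ | 30,000 | £/QALY | NICE threshold used for the decision rule |
| PSA iterations / bootstrap reps | 5,000 / 5,000 | — | stated analysis sizes |
| QALY duration | 1.0 | year | single timepoint × 1 year; no area-under-curve |

Scenario 1 (base case) includes out-of-pocket and personal-study costs in
the training total (they may be reimbursed by the employer); scenario 2
excludes both. Supervised-day costs are inside the course fee and never
added separately. Currency is kept unrounded internally and rounded
half-up to the pound only at reporting.

The fixtures store the published component *means* verbatim where those
were computed on unrounded survey data (TR employer-paid £951, dietitian
personal-study £3,791): rounded day-counts × daily rate gives £929/£3,850
instead, and the published totals are sums of the published components.
The derived-cost functions remain available and are exact wherever the
arithmetic closes (all dietitian components, TR personal study).

Probabilities without a published range (`p_use_rights`, `p_refer` in both
arms) get ±50% relative bounds clipped to [0, 1] for sensitivity and PSA
purposes — a package choice, recorded here because the published tornado
bounds are in unpublished appendices.

## Effectiveness estimation

EQ-5D-5L states are scored by table lookup against a pluggable value set;
the England tariff is licensed content and is not shipped, so a toy
additive set (1 − 0.05 per level step; 11111 → 1.0, 55555 → 0.0) ships for
tests and synthetic data. Negative utilities are admitted if a supplied
tariff contains them. Likert items map linearly onto 0–100 via
`(item − 1)/4 × 100`, averaged over items; the transform behind the
published satisfaction scores is unstated, so the fixtures carry those
summaries verbatim and the transform is used only for synthetic data.

Adjustment fits `outcome ~ group + age + gender + general_health` with a
site random intercept (REML). Adjusted means are marginal: the average
fixed-effect prediction with every patient assigned to each arm in turn,
so the group difference equals the group coefficient. At the
zero-site-variance boundary the mixed-model optimizer can return a
degenerate solution; the implementation detects this (non-convergence or
estimated site variance ≤ 1e−10) and falls back to OLS, which is the exact
limit of the model there.

The bootstrap resamples patients with replacement within site × group
strata (preserving the matched design) and re-estimates the adjusted
difference inside each replicate by OLS with site fixed effects and the
same covariates — a fast fixed-effects stand-in for the mixed model that
keeps 5,000 replications (and the 100-replication coverage check in the
test suite) cheap; the point estimate itself always comes from the mixed
model. CIs are percentile intervals, deterministic given the seed.

## PSA distributions

Families are unstated in the source analysis, so the package uses standard
health-technology-assessment assignments, every one overridable per
parameter: gamma for nonnegative costs and beta for probabilities, both
moment-matched to (point, SD) with SD = (high − low)/4 when only a range
is available; normal for effect differences with SE = bootstrap-CI
width/3.92. The default PSA samples at the level where published
uncertainty exists — per-arm per-patient cost mean/SD and the adjusted
QALY difference — which reproduces the published CEAC values (~37%/44% at
£30,000) and plane quadrant occupancies to within about a point.
Zero-width parameters are degenerate and always draw their point. NMB ties
(exactly 0) count as not cost-effective, per the strict decision rule. The
CEAC grid is £0–£50,000 in £1,000 steps and always contains the threshold.

## Synthetic data

`synthetic_data` emulates the study design: 8 sites × 2 matched arms ×
(default) 12 patients, latent utility = 0.78 baseline + group effect
(−0.012 default) + N(0, 0.02) site intercept + small age/gender/health
effects + N(0, 0.15) residual, mapped to the nearest state under the toy
value set (deduction count = round((1 − u)/0.05), split uniformly at
random over the five dimensions, capped at level 5). The residual SD is
deliberately three times the 0.05 utility grid so quantisation does not
mask small mean shifts. Activity logs draw weekly contacts Poisson around
the fixture point and branch counts binomially; zero-width parameters
reproduce their points exactly as deterministic expected counts.

What the generator does *not* emulate: informative missingness, site-level
case-mix differences correlated with group, ceiling effects of real EQ-5D
distributions, or any real tariff's non-additive structure. Passing
recovery tests therefore shows the estimation machinery is unbiased under
the model's own assumptions, not that the published patient data could be
re-derived.

## Numerical choices and problem sizes

* Discounting: year t weight (1 + r)^−(t−1); closed-form geometric sum
  checked to 1e−9.
* Tornado: one parameter at a time at its bounds, others at points,
  output = NMB(λ) through the de-novo tree; stable descending sort by
  swing; zero-width inputs have zero swing and rank last. One-way
  excursions may cross the point-estimate ordering of the two consultation
  rates, so the DSA evaluates the branch expectation directly rather than
  through the validated profile container.
* ICER at ΔE = 0 returns an explicit undefined marker, never a division
  error, and all ICERs are quadrant-qualified since a bare ratio is
  sign-ambiguous in the NW/SW quadrants.
* Result tables are written with full-precision `repr` floats and read
  back with round-trip float parsing, so serialisation is bit-exact.
* Test/validation problem sizes: 208-patient cohorts (13 per site per
  group) for recovery checks, 100 replications × 500 bootstrap reps for
  CI coverage, 5,000 PSA iterations — chosen to exercise the study-scale
  design while keeping the whole suite in well under a minute of compute
  per check.

## Known limitations

* The de-novo cost route cannot reproduce the published arm totals
  exactly (unpublished unit-cost mix); for therapeutic radiographers its
  year-1 incremental cost even flips sign relative to the published +£5,
  which is why base-case reporting uses the published summaries.
* The TR scenario-2 training total printed in the source sums to £5,424
  from the printed components (the source prints £5,425, a rounding
  artifact of unrounded sample means); the fixture stores the printed
  value in its `reported` block, while recomputation yields 5,424.
* Only the toy value set ships; QALY levels (not differences) from it are
  not comparable to tariff-scored values.
* The PSA ignores correlation between arm costs and effects (none is
  published); the CEAC consequently inherits the independence assumption.
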