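# Methods

## Model structure

A partitioned-survival cohort model with three mutually exclusive states —
progression-free (PFS), post-progression (PPS), dead — evaluated on a
weekly grid over ten years (521 grid points).  Occupancy is derived
directly from two survival curves per arm: PFS occupancy is
`min(S_PFS, S_OS)` (clamping resolves crossings of independently estimated
curves, the standard practice), PPS is the gap to overall survival, death
the complement.  The whole cohort starts in PFS.

Time in state is the area under the occupancy curve.  With half-cycle
correction (the default) each cycle contributes the trapezoidal average of
its endpoint occupancies, discounted at mid-cycle with annual factor
`(1+r)^(−t)`; with the correction off, start-of-cycle values and
start-of-cycle discounting reproduce the plain rectangular sum exactly.
A year is 52 weeks everywhere, matching the monthly→weekly cost conversion
(×12/52; e.g. €495.31/month ⇒ €114.30/week).

Entry age (55 years) is metadata only: no background mortality table is
applied, so age has no causal path to outputs and appears in the tornado
diagram as a zero-width bar.

## Survival estimation and extrapolation

Within the trial window the package uses the product-limit (Kaplan-Meier)
estimator, resampled to the weekly grid by last-value carry-forward
(left-closed convention: grid point *i* is elapsed week *i*).  Beyond a
configurable cutover — default 78 weeks (18 months), the length of the
trial's primary follow-up — curves continue parametrically by
conditional-survival scaling, `S(t) = S_KM(c)·S_fit(t)/S_fit(c)`, which is
continuous at the cutover and inherits the parametric per-cycle hazard
beyond it.

Six families are available (exponential, Weibull, gamma, log-normal,
log-logistic, Gompertz; generalized gamma on request, never auto-selected),
all parameterised on an unconstrained scale (logs of positive parameters,
real-valued parameters as-is) so multivariate-normal perturbation in the
probabilistic analysis cannot produce an invalid distribution.  Fits are
right-censored maximum likelihood: the exponential in closed form
(rate = events/exposure, Var(log rate) = 1/events), the rest by multi-start
Nelder-Mead from moment-based initial values (tolerance 1e-10 on the
log-likelihood), with the covariance taken as the inverse observed
information (numerical Hessian, eigenvalues clipped at zero so the
Cholesky factor always exists).  "Gamma" means the two-parameter gamma
distribution.  Family selection minimises AIC with ties broken by fewer
parameters then name; the BIC ranking is reported alongside.  A
log-cumulative-hazard diagnostic (`ln(−ln S)` vs `ln t`, straight-line
slopes per arm) summarises proportional hazards but makes no automated
accept/reject decision.

The base-case extrapolation follows the published choices: exponential
tails for PFS and treatment duration in both arms; a gamma tail for
comparator (crizotinib) OS; and the intervention arm's OS continued with
the *comparator's* extrapolated hazards beyond the cutover — the
conservative assumption of no long-term efficacy advantage.

## Intercurrent events

**Brain metastases.** 25% of the cohort has BM at entry (one-way range
15–35%).  The remainder acquires BM per the within-trial BM-free curve up
to the cutover and an exponential tail beyond; BM is absorbing, prevalence
capped at 1.  BM carries €114.30/week (the published weekly equivalent of
€495.31/month, including a €4.31/month community-neurology component)
applied to the prevalent fraction of the alive cohort; no BM disutility is
applied, since no EQ-5D evidence for one exists.  (The source text also
mentions €461/month for the hospital component; €495.31 − €4.31 = €491
suggests a typo, and the €495.31 ⇒ €114.30 pair is treated as
authoritative.)

**Adverse events.** Grade III/IV events with >2% incidence in either arm
enter at constant weekly probability `p = 1 − exp(−incidence/duration)`
with duration the arm's mean first-line treatment time in weeks,
multiplied by a per-arm re-weighting factor (default 1.0; the overall
grade III/IV rate needed to calibrate it is not published).  Events are
charged while on first-line treatment, each costing its management cost
plus a €79.95 round-trip transport, and each subtracting its disutility
(−0.047 to −0.090; −0.061 for events without published values) for a
finite window of 4 weeks (configurable; the source gives per-event
decrements but no duration, and duration-weighting keeps the decrement
proportional to exposure).

## Treatment pathway and costs

First-line drug cost (alectinib €4,993.63/month, crizotinib €4,473.07/
month) follows the on-treatment fraction: the treatment-duration curve
capped by PFS occupancy.  On progression, second line lasts 50.1 weeks
(range 40.1–60.1): a cohort model does not know individual progression
times, so the second-/third-line split within PPS convolves the per-cycle
progression inflow (the decrement of PFS occupancy) with a 50.1-week
window and rescales so the two layers always sum exactly to PPS occupancy.
Base-case mixes: intervention arm → 100% ceritinib; comparator arm → 80%
alectinib / 20% ceritinib; third line is pemetrexed + cisplatin for
everyone, charged per 21-day session (drug plus €419.57 administration),
until death or the horizon.  Weekly monitoring (€23.76 first line, €23.68
second, €24.40 third) follows the same layers; community disease
management accrues per week alive in PFS and PPS.  All costs in 2017
euros, discounted like the outcomes; the six categories sum exactly to
the total by construction.

Defaults chosen where the source prints no number (all in the reference
configuration, all probed by sensitivity analysis):

| input | default | basis |
|---|---|---|
| ceritinib acquisition | €4,900/month | French list-price magnitude of contemporary ALK inhibitors |
| pemetrexed+cisplatin | €1,350/21-day session | drug-only session cost, French tariffs era |
| PFS management | €25/week | routine community follow-up |
| PPS management | €50/week | more intensive post-progression follow-up |
| per-AE management | €2,900–€8,000/event | hospitalisation-weighted; consistent with the published €10.88 / €18.97 per-week arm-level AE costs |

Note on comparability: the published cost table's "management during PPS"
column evidently bundles post-progression *treatment* costs, which this
package books under acquisition instead (the pathway contract above).
Category-by-category comparison with the published table is therefore not
meaningful; totals and increments are.

## Outcomes

Discounted life years, QALYs by layer (PFS 0.831, second-line PPS 0.743,
third-line PPS 0.586, minus AE decrements — QALYs can never exceed life
years), and the ICER ΔC/ΔQALY with dominance labels (dominant when at
least as effective and no dearer; dominated in the mirror case; ratio
undefined at zero effect difference).  Internally nothing is rounded;
reports round to whole euros.

## Sensitivity analyses

**One-way:** each parameter (utilities at 95% CI bounds, BM-free baseline
65–85%, discount 1.5–6%, unit costs ±20%, second-line duration ±10 weeks,
age ±20%) moved to each bound with the rest at base, full re-evaluation,
bars sorted by ICER width.

**Probabilistic:** 1000 iterations.  Utilities ~ gamma, costs ~
log-normal, both moment-matched to (mean, sd); the sds derive from the
one-way ranges as (high − low)/3.92 since no sds are published.  Survival
tails ~ multivariate normal on the unconstrained scale via the Cholesky
factor of each fit covariance (KM portions carry no sampled uncertainty;
the non-reference OS tail follows the reference draw by construction).
Parameter blocks are sampled independently; utilities are shared by both
arms within an iteration; sampled utilities are capped at 1 (never binding
at the shipped sds).  Iterations with crossing curves are resolved by the
engine's clamping, not rejection; failed iterations would be logged,
excluded and counted.  The acceptability curve uses the net-monetary-
benefit rule `λ·ΔQALY − ΔC > 0`, well defined under dominance.

**Scenario:** second-line mix override (intervention arm → 50% ceritinib /
50% chemotherapy), same engine and clinical inputs, so QALYs are unchanged
and only the cost side moves.

## Synthetic trial generator

The source trial's individual data are not deposited, so the generator
emulates a two-arm trial with the published arm-level characteristics:
exponential PFS at the published medians (25.7 / 10.4 months); OS = PFS +
an exponential post-progression residual calibrated so survival at the
data cutoff matches the published proportions (77% / 73.5%) — which makes
PFS ≤ OS hold by construction; exponential treatment duration at the
published means (32.6 / 16.7 months; the published *medians*, 18.6/17.6,
are carried in the profile but not reconciled — an open inconsistency in
the source); BM baseline 25% at time zero plus exponential onset
calibrated to the published cumulative incidences (9.4% / 41.4%); AE
occurrences weekly over each patient's treatment duration.  Censoring is
purely administrative at 29 / 27 months (no dropout process is described).
Arm sizes 152 / 151.

What a green test does and does not establish: the generator reproduces
the *summary* statistics above at large n, but not the published KM step
functions, their within-trial shape (the real PFS curves are far from
exponential early on), recruitment/calendar-time structure, or any
covariate structure.  Published headline outputs (ICER 90,232 €/QALY,
mean OS 4.62 vs 4.18 years) therefore serve as order-of-magnitude and
directionality checks only; on the synthetic inputs the model yields an
ICER in the tens of thousands €/QALY with the same qualitative behaviour
(intervention more effective and dearer; pathway scenario lowers the ICER;
acquisition-side parameters dominate the tornado).

## Numerical choices

Weekly grid, left-closed; last-value carry-forward between grid points.
Occupancy conservation enforced to 1e-9.  Optimiser tolerance 1e-10 on the
log-likelihood; covariance eigenvalues clipped at 0.  Degenerate inputs
(zero events, curves stuck at 1, zero survival at the cutover, empty
samples) raise informative errors rather than returning silently wrong
numbers.  All randomness flows from named seeds; identical (config, seed)
pairs give byte-identical artifacts.

## Limitations

No background mortality (immaterial over ten years in this population but
formally optimistic); no covariate adjustment or cure fractions; costs of
palliative care and last-line immunotherapy excluded, as in the source;
the AE re-weighting factor defaults to 1.0 for want of the overall
grade III/IV rate; synthetic-data caveats above.
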