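# Methods

## The decision problem

Children with recurrent medulloblastoma can be treated with a doublet of
temozolomide (TMZ) + irinotecan (IRT) or with the same doublet plus
bevacizumab (BEV).  The triplet prolongs event-free survival (EFS, median
9 vs 6 months) and overall survival (OS, median 19 vs 13 months) but adds
a substantial drug cost.  The package asks whether the added survival is
worth the added cost from the perspective of the Chinese health system,
using a Markov cohort model and an incremental cost-effectiveness ratio
(ICER) judged against a willingness-to-pay (WTP) threshold of three times
China's per-capita GDP ($38,136.26/QALY).

## Cohort model

Three mutually exclusive health states: event-free (EFS), progressed
disease (PD), and death (absorbing).  The cohort enters event-free; cycles
are one month; the horizon is 120 cycles (10 years); the trace also stops
early once 99% of the cohort has died.  Occupancy is recorded at cycle
starts, and costs/utilities attach to the occupancy with which a cycle
starts (state-at-entry).  A half-cycle (trapezoid) correction is available
as a settings switch and defaults to off; with monthly cycles the
difference is a few percent of totals and does not move the base-case
conclusion.

Survival enters through parametric curves S(t) = exp(−(t/λ)^k)
parameterized from reported medians (S(median) = 1/2 exactly).  Because a
median identifies only one parameter, the base case uses the exponential
special case k = 1; k is a configuration knob (`survival_shape`) for
scenario analysis.

### Structural modes

Two readings of "derive a Markov model from published EFS and OS curves"
are implemented, selected by `structural_mode`:

* **transition** (default): an explicit three-state transition model.  Each
  cycle, event-free patients die with the OS curve's conditional death
  probability 1 − S_OS(k+1)/S_OS(k), otherwise progress with the EFS
  curve's conditional event probability 1 − S_EFS(k+1)/S_EFS(k); progressed
  patients die at a constant post-progression hazard whose exponential law
  has median (OS median − EFS median).
* **partitioned**: partitioned survival — EFS occupancy is S_EFS(t), death
  is 1 − S_OS(t), and PD is the area between the curves (floored at zero,
  with EFS truncated to S_OS should the curves cross).

The transition mode is the default because it reproduces the published
per-state results far more closely than the partitioned reading under
median-identified exponential curves: the partitioned areas credit every
arm with the full area under its survival curves (e.g. a mean event-free
time of median/ln 2 ≈ 1.44 × median), which substantially overstates
time alive relative to the published per-state QALY decomposition and
*reverses* the published qualitative conclusion (it prices the triplet
below the WTP threshold).  The transition reading also matches the
published transition-diagram description of the model.  Both modes share
every downstream costing, discounting and sensitivity-analysis component,
and both are exercised by the test suite.

## Costs, utilities, discounting

All costs are per 28-day course, in USD (converted once at 6.437 CNY/USD).
The event-free state costs drug + tests + hospitalization + grade-3/4
adverse-event management while treatment lasts — the first 12 cycles,
mirroring the maximum of 12 courses — and tests + hospitalization
thereafter.  Per-cycle drug cost is the sum of its per-agent components
(TMZ 343.75 + IRT 576.15 + BEV 1,883.83 = 2,803.73 for the triplet),
which lets the sensitivity analyses vary a single agent's price.  The PD
state carries the second-line treatment cost only; death costs nothing.
Indirect/hidden costs are excluded by design.

Utilities are annual QALY weights (EFS 0.89, PD 0.73, death 0), so one
cycle contributes weight/12 QALYs.  Costs and QALYs are discounted at an
annual 3% via (1.03)^(−cycle/12).

A dosing calculator exposes per-course mg amounts from the pediatric
body-surface-area rule BSA = 1.05 + (weight − 30) × 0.02 m² (TMZ/IRT
50 mg/m² × 5 days; BEV 10 mg/kg on days 1 and 15).  It is illustrative
only: cycle costs come directly from the per-cycle price table, never from
unit prices, and the default 40 kg weight is a repository choice.

## Incremental analysis

Per arm the model totals discounted cost and QALYs; the comparison reports
incremental cost ΔC, incremental effect ΔE, and ICER = ΔC/ΔE when ΔE ≠ 0
and neither strict-dominance pattern (cheaper-and-better /
dearer-and-worse) applies; dominance and zero-increment cases are flagged
instead of divided.

## Pseudo-IPD reconstruction

Published figures give only a Kaplan–Meier curve and a numbers-at-risk
table.  `reconstruct_ipd` recovers approximate patient-level data with an
interval-wise allocation scheme: within each risk-table interval it
searches (fixed-point iteration on the censor count, censor times spread
uniformly over the interval) for the event counts behind every curve drop
— each drop converted to events by rounding n·(1 − S_new/S_old) to the
nearest integer — such that the reconstructed number at risk matches the
table at the next interval boundary; any residual exits are censored at
the boundary, and patients still at risk after follow-up are censored at
its end.  The procedure is fully deterministic and returns exactly the
initial number at risk.  Kaplan–Meier estimation itself and Weibull
maximum likelihood are delegated to lifelines; the exponential MLE is the
closed form rate = events / total follow-up time.

## Synthetic trial generator

Because no patient-level data are deposited, a generator emulates the
two-arm trial the analysis assumes: per-patient EFS from the Weibull law
at the target median, OS = EFS + an exponential post-progression time
whose rate is solved (Brent root-finding on the marginal survival
function) so the marginal OS median matches its target — guaranteeing the
OS ≥ EFS coherence the model assumes — and administrative censoring at a
fixed calendar time (default 24 months).  Defaults are a small phase-II
screening-trial scale of 50 patients per arm; the recovery tests use 2,000
to separate method error from sampling noise.  The generator does *not*
emulate non-proportional hazards, loss to follow-up, digitization jitter
beyond grid sampling, or covariate structure, so passing recovery tests
demonstrate correctness of the reconstruction machinery under the model's
own assumptions, not robustness to real-world figure quality.

## Sensitivity analyses

**One-way DSA.**  Default ranges are ±20% of base for every cost component
and both bundled EFS-state costs, ±20% for utilities clipped so the
ordering u_death ≤ u_pd ≤ u_efs survives, 0–5% for the discount rate, and
±20% for the (internally inert) exchange rate; any range can be overridden
per parameter.  Survival medians are varied probabilistically in the PSA
rather than in the tornado: the deterministic ranges mirror the
price-survey framing of the underlying cost uncertainty, whereas survival
uncertainty is sampling uncertainty.  Entries are ranked by the absolute
ICER span.  `threshold_search` bisects a single parameter (assumed
monotone, verified by bracketing) to |ICER − target| ≤ $1/QALY, at most
100 iterations.

**PSA.**  1,000 Monte-Carlo iterations.  Costs draw from Gamma laws
moment-matched to mean = base and SD = 20% of base (k = 25, θ = 0.04·mean);
survival medians from Gamma laws at 10% SD with a per-arm redraw enforcing
EFS ≤ OS (violation probability ~10⁻⁶, so the redraw is bias-free in
practice); utilities from Beta laws moment-matched at 10% SD.  The two
utilities share a single uniform quantile (comonotone coupling): this
keeps each Beta marginal exact — so draw means are unbiased — while
preserving u_pd ≤ u_efs everywhere except an extreme lower-tail ~0.1% of
draws, where u_pd is clamped to u_efs (mean distortion ~4×10⁻⁵).  An
independent-draw-with-rejection scheme was rejected because its ~9%
rejection rate truncates both marginals visibly.  The dispersion
percentages are declared defaults, not published values: the source prints
distribution families but no dispersions.  The discount rate is held fixed
in the PSA (it is examined deterministically).  Cost-effectiveness on the
acceptability curve uses the net-monetary-benefit rule
λ·ΔE − ΔC > 0, which handles negative increments coherently; the summary
"median ICER" excludes iterations with non-positive ΔE.

## Numerical conventions and edge cases

* Conditional per-cycle event probabilities are undefined once survival
  reaches zero; this is signalled with a distinct error type.
* Partitioned occupancy is clamped (PD ≥ 0, EFS ≤ S_OS) so the state
  simplex is exact to 1e-12 at every cycle.
* Trace person-time under the default convention equals the left Riemann
  sum of the survival curve (exact geometric closed form for
  exponentials); the trapezoid (half-cycle) person-time reproduces the
  restricted mean ∫S dt to well under 1%.
* Result tables round to 3 decimals; all internal arithmetic is full
  precision.
* Reported seeds make every stochastic path (generator, PSA)
  bit-reproducible.

## Known limitations

* The published absolute totals (e.g. total cost $27,603.420 and 1.147
  QALYs for the triplet) derive from the authors' reconstructed
  patient-level COG data, which are not public; no parameterization
  identifiable from the printed medians reproduces them exactly.  The
  package reproduces every *derived* identity on the printed numbers
  exactly (increments, ratios, component sums) and the absolute totals
  only approximately, via the transition mode.
* Utilities come from published brain-tumor literature, not the trial.
* The exponential base case ignores hazard shape; `survival_shape`
  provides Weibull scenarios but no data exist here to fit it.
* Cohort fractions only; no patient-level heterogeneity or microsimulation.
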