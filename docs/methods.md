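# Methods

## Model structure

The package chains two expected-value cohort models.

**Model I — treatment decision tree.** The only property of primary
treatment that matters downstream is cardiac radiation exposure, so the tree
is collapsed to stage → radiotherapy yes/no → laterality. Left-sided
irradiated tumours are assigned the high mean heart dose (3.6 Gy),
right-sided the moderate dose (1.9 Gy), non-irradiated women 0 Gy. The
published endpoint proportions (0.3680 / 0.3383 / 0.2937) pin down only the
marginal P(RT) = 0.7063 and the laterality split; the defaults therefore use
a calibrated laterality of 0.5210 left vs 0.4790 right (a symmetric 0.5/0.5
split cannot reproduce the published asymmetric endpoints). The internal
stage mix (13% in-situ) and per-stage radiotherapy rates (55% for stage 0,
solved to 72.97% for stages 1–3 so the marginal matches) are plausible
placeholders used only by the stage scenarios, and are user-configurable;
stage-scenario results should be read as qualitative.

**Model II — six-state Markov cohort.** States: the three exposure strata as
initial states, `nonfatal_cv`, `fatal_cv`, `fatal_noncv`; the fatal states
are absorbing and there are no transitions between initial strata. Cycles
are annual over a 20-year horizon. The diagnosis year is cycle 0 with no
events; events occur in cycles 1..20 and the discount exponent for cycle *t*
is *t* − 1, so the first event year is undiscounted. No half-cycle
correction is applied (whole-cycle cohort bookkeeping); the trace exposes
everything needed to add one, but none of the shipped accumulators use it.
Re-events are not modelled: mass entering `nonfatal_cv` stays there until
death, and a one-cycle tunnel distinguishes first-year from subsequent-year
occupancy because first-year costs and sick-leave differ.

## Cardiovascular risk

Ten-year fatal CV risk comes from the two-cause Weibull survival model of
the SCORE project (Conroy et al., Eur Heart J 2003), using the low-risk
region female coefficients (Belgium is a SCORE low-risk country). The
coefficients are data, shipped in
`src/rtburden/data/score_coefficients.csv` with the baseline-survival and
linear-predictor conventions documented in its header. Choices on points the
equations leave open:

- **Cause combination.** The two cause-specific 10-year conditional
  survivals are combined on the survival scale,
  P₁₀ = 1 − S₁₀(CHD)·S₁₀(non-CHD); an additive option
  (P₁₀ = P₁₀(CHD) + P₁₀(non-CHD)) is available via `combine="additive"`.
  The two differ by < 1% of the risk below age 80.
- **Smoking.** Prevalence (0.0951) enters as an exact two-point mixture over
  smoker status, not as a fractional covariate: the mixture is the correct
  expectation for a prevalence.
- **Covariate trajectory.** SBP and cholesterol switch from the 40–64 to the
  65+ band values when the attained age reaches 65.
- **Age range.** SCORE is calibrated from age 40; attained age 39 uses the
  age-40 risk. Beyond age 65 the Weibull functional form is extrapolated to
  attained age 104 (needed for diagnosis at 84 plus the horizon). This
  extrapolation is the model's single largest structural uncertainty; the
  generated risk tables can be replaced via the same CSV interface if
  cohort-specific age tables become available.

Multi-year risks convert to annual probabilities by
p = 1 − (1 − P)^(1/y) (constant-rate assumption). The radiation effect is a
linear-in-dose multiplicative excess, p′ = min(1, p·(1 + 0.041·MHD)),
applied every cycle (no latency or time trend) to the fatal risk *before*
the non-fatal scaling, so non-fatal events inherit the dose effect. The
non-fatal probability is p′ · RR with RR = 2.7515; the post-event fatal
probability (0.0115, secondary-prevention cohort) deliberately receives no
dose adjustment. Composing two excess applications is *not* equivalent to
applying the summed dose; the adjustment is defined on baseline risk only.

## Generated age tables

Only cohort-level summaries of the inputs are published; `rtburden.synthetic`
generates the single-year tables by the mechanism those summaries describe.

- **Incidence weights**: five-year group shares split equally across single
  years and renormalized; re-grouping recovers the printed shares.
- **Background non-CV mortality**: Gompertz-like curve
  q(a) = c·exp(0.09·a), with c solved in closed form so the
  incidence-weighted mean equals the cohort mean 0.0181. The log-slope 0.09
  per year of age is the conventional adult all-cause value; `shape=0`
  degenerates to a flat table.
- **CV tables**: annualized SCORE risk per single year of age (no dose
  adjustment — the excess is applied per stratum downstream), non-fatal =
  fatal × RR at every age. The fatal/non-fatal cohort anchors (0.0427 /
  0.1175) enter the model only through their ratio; an optional single-
  multiplier calibration (`calibrate=True`) can instead rescale the fatal
  table so the weighted cumulative (default, solved by Brent's method) or
  annual probability matches the fatal anchor. The default applies no
  rescaling, since CV mortality is estimated by the SCORE equations and the
  anchors' observation window is not published.

Because these tables are generated, the pipeline reproduces published
cohort-level *means by construction* and event *levels approximately*; tests
of headline reproduction are tolerance-based. Passing tests demonstrate
internal consistency of the mechanism, not agreement with the unpublished
single-year data, and say nothing about populations with different incidence
or background mortality.

## Economics

Direct costs per cycle: new non-fatal events incur the first-year bundle
(A&E 455.62 + inpatient 4547.51 + pharmaceuticals 149.0882 + primary 54.12 +
outpatient 196.33 = €5402.6682); subsequent years in the non-fatal state
incur later-year primary/outpatient follow-up plus the pharmaceutical cost,
which recurs annually (chronic secondary prevention — no first-year/later
split is published for it); directly fatal CV events incur the prehospital
A&E cost once, and deaths out of the non-fatal state incur no new direct
cost. Indirect costs use the human-capital approach on gross wages for the
economically active fraction (0.649): first-year (48 days) and later-year
(25 days) sick leave for the temporarily-sick fraction, and wage annuities
to retirement (65) for permanent disability (3.94% of events) and premature
CV death. Annuities are discounted from the event cycle at the cost rate and
are *not* truncated at the analytic horizon — the productivity loss of a
death in cycle 20 still runs to retirement. All indirect components are zero
once attained age reaches 65. Fatal non-CV deaths carry no production loss:
they are identical across comparators by construction, so the increment is
unaffected. Death utility is 0; the non-fatal state utility transfers a
reference cohort's proportional decrement to the local baseline,
u = 0.77 × (1 − 0.11/0.91) = 0.6769. Monetary values are kept at full
precision internally and rounded only for presentation.

## Parameters and sensitivity analyses

Every input is a typed field with distribution metadata. Quantities the
input table itself derives (RR, dose ratio, non-fatal-state utility) are
properties recomputed from their inputs so perturbations propagate. The
stored non-fatal event anchor is 0.11748905 = 0.0427 × 2.7515, carrying the
precision implied by the published derived ratio (it displays as 0.1175 at
table precision).

Distribution families follow the input table; second moments are not
published, so every non-fixed parameter defaults to a coefficient of
variation of 0.1, overridable per parameter. Consequences: the probabilistic
spread reported here reflects that convention, not an evidence-based
uncertainty quantification, and the PSA minima/maxima should not be compared
against published ones.

- **One-way DSA**: each parameter set to 70% / 130% of base, full aggregate
  rerun (including table regeneration, so SCORE-input perturbations
  propagate), entries sorted by span. Probabilities are clipped at 1 with a
  logged warning; scaling one stratum proportion renormalizes the trio so
  the simplex invariant survives one-way perturbation.
- **PSA**: all non-fixed inputs resampled independently per draw
  (moment-matched beta/gamma/log-normal/normal), stratum proportions
  renormalized as a unit, derived quantities and age tables recomputed per
  draw; infeasible draws (validation failure anywhere in the pipeline) are
  rejected, logged and resampled. Each parameter owns an RNG stream keyed by
  (master seed, CRC32 of its name), so adding a parameter leaves other
  parameters' draws unchanged. No covariance structure is imposed.

## Numerical conventions and problem sizes

Occupancy conservation is maintained to 1e-12 per cycle; transition-matrix
rows whose event probabilities exceed 1 raise rather than renormalize.
Background-mortality calibration is closed-form; the optional CV-table
calibration uses Brent root-finding to 1e-12. The shipped analyses use 46
single years of diagnosis age × 3 strata × 2 comparators × 20 cycles per
aggregate run, 1000 PSA iterations, and a 200 000-individual microsimulation
as the independent oracle for the cohort trace (agreement within three
binomial standard errors).

## Known limitations

- SCORE (2003) rather than SCORE2; no HDL or diabetes covariates.
- Constant excess per Gy over time; no latency, no dose–response saturation
  below the probability cap.
- Single non-fatal state: no re-events, severity grades or event subtypes.
- Stage-scenario internals are calibrated placeholders (see Model I).
- Chemotherapy-related cardiotoxicity, transportation/informal-care costs
  and ICERs are out of scope.
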