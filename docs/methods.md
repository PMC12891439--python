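# Methods

## Study design and data model

Sampling is organised on a grid of consecutive calendar months
("occasions"). A capture record is assigned to the month containing its
date; repeated sightings of a tag within one month collapse to a single
detection. Field searches did not happen every month for every
(site, species) cell: the bundled capture calendar
(`upwellsurv.fielddata`) marks 10 searched months for *C. granosus* and 6
for *S. zebrina* at Talcaruca, and 13 and 12 at Quintay, out of 26
occasions (Nov 2019 – Dec 2021). Unsearched months carry no information
and the detection probability for those occasions is pinned to exactly 0;
a record dated in an unsearched month is treated as a calendar/effort
mismatch and rejected.

Morphometric and physiological covariates (body length, buoyant weight,
standard metabolic rate, heart rate) are taken from the record at first
capture and treated as time-constant. Because these traits drift over
time, covariate models are intended to be fitted on a short window of the
data (`restrict_window`, default width 6 months), which keeps only
individuals first captured inside the window. Tag loss (estimated below
5% in the field) is ignored: re-tagged individuals are assumed recorded
under one identity. Individuals first captured at the final occasion are
retained but contribute a likelihood factor of 1.

## The Cormack–Jolly–Seber model

Apparent monthly survival φ_t (death confounded with permanent
emigration) and detection p_t are estimated conditional on first capture.
Instead of augmenting the data with explicit alive/dead indicators, the
likelihood marginalizes the latent state through the χ recursion

    χ_T = 1,  χ_t = (1 − φ_t) + φ_t (1 − p_{t+1}) χ_{t+1},

the probability of never being seen after occasion t given alive there.
This is mathematically identical to the state-space formulation but
deterministic, cheap, and directly testable against brute-force
enumeration over death times (the test suite checks exact agreement to
1e−12 and that post-release history probabilities sum to 1).

Five survival structures are supported; detection is always fully
time-varying to absorb the irregular search calendar:

| structure    | shorthand | survival model                                |
|--------------|-----------|-----------------------------------------------|
| `phi_dot`    | φ(·)      | one constant monthly φ                        |
| `phi_site`   | φ(Po)     | one φ per site, sites fitted jointly          |
| `phi_time`   | φ(t)      | one φ per monthly interval                    |
| `phi_length` | φ(L)      | logit(φ_i) = α + β·x̃ (body length)           |
| `phi_perf`   | φ(F)      | logit(φ_i) = α + β·x̃ (standard metabolic rate)|

Covariates are standardized over the individuals entering the fit, so β
is a log-odds change per covariate standard deviation; individuals with a
missing covariate are excluded (the count is recorded on the model).
Under `phi_site` each site keeps its own detection vector, since the
effort calendars differ; the two sites share only the occasion grid.

For the time-structured models the likelihood is evaluated through the
m-array (releases tabulated by occasion of first recapture), a sufficient
statistic that makes an evaluation O(T²) instead of O(nT). Releases exist
for occasions 1..T−1; a detection at the final occasion is terminal and
is not a release. The test suite verifies exact equivalence (1e−10)
between the m-array and per-history likelihoods on simulated data for all
three time-structured forms.

## Posterior sampling

All free parameters are sampled on unconstrained scales: probabilities by
logit transform — a Uniform(0,1) prior then contributes the
standard-logistic density (prior plus Jacobian) — and α, β on the
identity scale with Normal(0, 10²) priors. Detection parameters of
unsearched months are not sampled at all.

The sampler is component-wise random-walk Metropolis. Per-component
proposal scales adapt in batches of 50 iterations toward an acceptance
rate of 0.44 (the one-dimensional optimum), with diminishing adaptation
steps min(0.05, b^−1/2); adaptation stops at the end of burn-in, so the
kept draws come from a fixed transition kernel with the correct
stationary distribution. Chains start from independent prior draws
(over-dispersed relative to the posterior), which makes the split-chain
Gelman–Rubin statistic a meaningful convergence check; the default
protocol is 3 chains of 10,000 iterations with a burn-in of 1,000, no
thinning, and a convergence criterion of split R-hat < 1.1 for every
monitored parameter. Posterior summaries report mean, sd, 2.5/50/97.5%
quantiles (type-7 linear interpolation), split R-hat computed in-package,
and effective sample size via arviz.

Under `phi_time`, monthly survivals inside an unsearched span are only
identified as a product, and the terminal survival is confounded with the
final detection probability; `survival_series` flags such intervals
rather than suppressing them (their posteriors are prior-influenced).

## Derived quantities

Annual survival is the monthly draw raised to the 12th power — the model
is parameterized on a monthly grid, so calendar gaps do not change the
exponent. Population contrasts use the posterior draws of the constant-φ
model: draws from independently fitted populations are paired by
(chain, iteration) index — fits are independent, so any exhaustive
pairing estimator converges to the same probability, and index pairing is
deterministic. P(A > B) uses strict inequality; ties count as "not
greater". A covariate effect is called unsupported when the central 95%
credible interval of β contains 0.

## Carbonate-system solver

Speciation from (pH_total, TA) at in-situ temperature and salinity:
carbonate alkalinity is TA minus borate and water alkalinity plus the
free-proton, bisulfate and fluoride terms; HCO₃⁻ and CO₃²⁻ follow in
closed form from K2, CO₂(aq) from K1, fCO₂ from K0, and pCO₂ through the
Weiss virial fugacity factor (≈0.997 at field temperatures). Saturation
states use calcium from the conservative salinity ratio and the Mucci
(1983) solubility products; nutrients (phosphate, silicate) are assumed
zero, as they were not measured.

Constants: K1/K2 Lueker et al. (2000, total scale), K0 Weiss (1974),
KB Dickson (1990), KW Millero (1995) converted from the seawater to the
total scale via the bisulfate/fluoride equilibria (KS Dickson 1990,
KF Dickson & Riley 1979), total borate from Uppström (1974). Each
formulation reproduces its published check value at 25 °C / S = 35 to the
printed precision (verified in the test suite). The inverse problem
(pH from DIC and TA) is solved by Brent bracketing on pH ∈ (3, 12) with
tolerance 1e−12, and the round trip pH → speciation → pH recovers the
input to better than 1e−8 across the coastal envelope
(pH 7.5–8.3, TA 2100–2400 µmol/kg, 8–18 °C, S 32–35).

Measured pH is interpreted on the total hydrogen-ion scale, matching the
TRIS-buffer calibration of the field protocol; an NBS-scale reading can
be converted through the Takahashi activity-coefficient approximation
(`nbs_to_total`), which is documented as approximate. The solver is not
expected to reproduce a table of per-sample means computed elsewhere:
speciation is non-linear, so the carbonate system evaluated at averaged
pH/TA/SST differs from averaged per-sample speciation.

## Variance tests and seasonal summaries

Site contrast in this system is primarily a contrast of environmental
*variability*. "Levene's test" is implemented as the Brown–Forsythe
variant (ANOVA on absolute deviations from group medians, the robust
default in modern software; the mean-centered original is available via
`center="mean"`), alongside the rank-based Fligner–Killeen test; both are
invariant to per-group location shifts and group relabeling. Low-pH
exposure is summarized by counting days under a threshold (default
pH 7.3) per austral season (spring Sep–Nov, summer Dec–Feb, autumn
Mar–May, winter Jun–Aug), with percentages to one decimal.

## Synthetic data

`simulate_histories` draws from the exact generative model the CJS
likelihood assumes: entry (= first capture) at a searched occasion with
probability proportional to recruitment weights — by default the observed
monthly capture counts of the cell, so synthetic datasets mimic the real
entry pattern — then survival as a per-interval Bernoulli chain and
detection only on searched occasions. Covariates are drawn once at entry
and held constant, matching the fitting assumption. Defaults reflect the
study conditions: 26 monthly occasions with the real search masks,
monthly survival in the 0.85–0.95 range, detection ~0.4.

The generator deliberately omits features real data may have: individual
heterogeneity in detection, trap response, tag loss, transience,
density dependence, and movement between sites. Recovery and coverage
tests on synthetic data therefore demonstrate correctness of the
estimator under its own assumptions, not robustness to their violation.

`simulate_environment` produces daily SST (annual sinusoid peaking in
austral summer plus AR(1) noise, site-specific amplitude and variance)
and pH (baseline noise minus an upwelling-event process whose daily rate
is season-specific). The `semipermanent_site` profile runs events
year-round with larger thermal variance; the `seasonal_site` profile
concentrates events in spring, so its corrosive days cluster there by
construction.

## Problem sizes and numerical choices

The test suite and the acceptance script use desk-scale problem sizes
chosen to estimate each quantity comfortably: the headline convergence
experiment uses the full study protocol (300 individuals, 3 × 10,000
iterations); interval-coverage checks use 20 replicates at 2 × 3,000
iterations and the two-site comparison 3 × 4,000, settings at which the
unimodal constant-survival posterior converges (R-hat is checked
in-test). Quantiles use numpy's default type-7 definition. Degenerate
inputs fail loudly: histories with no detection, all-masked detection
(unidentifiable), inverted calendars, infeasible water samples (negative
carbonate alkalinity), and groups of fewer than two values all raise
typed errors rather than returning numbers.

## Known limitations

* No multi-state (movement) models, no tag-loss or transience modeling,
  no continuous-time capture formulation.
* No information-criterion model ranking for the CJS variants; model
  comparison is by posterior inspection of the fitted structures.
* The Metropolis sampler is adequate for the ≤ ~35-parameter models here
  but is not a replacement for gradient-based samplers on larger
  problems.
* The NBS→total pH conversion is an activity-coefficient approximation
  and should not be used where precise scale conversion matters.
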