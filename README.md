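# upwellsurv

Bayesian survival analysis for intertidal mollusks living under
contrasting coastal-upwelling regimes, together with the environmental
characterization that motivates the comparison.

Two rocky-shore mollusks — the chiton *Chiton granosus* and the limpet
*Scurria zebrina* — were tagged and resighted monthly over 26 months
(November 2019 – December 2021) at two Chilean sites: Talcaruca, inside a
semi-permanent upwelling center, and Quintay, where upwelling is seasonal.
`upwellsurv` provides everything needed to analyse such a design, or a
synthetic replica of it, end to end:

* **Capture–mark–recapture data model** — monthly occasion calendars with
  per-(site, species) search gaps, encounter-history construction from raw
  capture records, m-array tabulation, and the study's own monthly capture
  calendar bundled as `upwellsurv.fielddata`.
* **Cormack–Jolly–Seber model** (`CJSModel` / `CJSResults`) — apparent
  monthly survival φ and time-varying detection p, with p fixed at exactly
  0 in months without a field search. Five survival structures:
  constant φ(·), site-dependent φ(Po), fully time-varying φ(t), and
  logit-linear in body length φ(L) or standard metabolic rate φ(F).
  The likelihood marginalizes the latent alive state with the χ recursion
  (no data augmentation) and, for time-structured models, is evaluated
  through the m-array sufficient statistic.
* **Posterior sampling** — component-wise adaptive random-walk Metropolis
  on unconstrained scales, uninformative priors (Uniform(0,1) on
  probabilities, Normal(0, 10²) on logit-scale coefficients), split-chain
  Gelman–Rubin diagnostics and arviz effective sample sizes.
* **Derived quantities** — annual survival (φ¹²), fold differences,
  the Bayesian probability that one population's survival exceeds
  another's, covariate-slope summaries, and time-varying survival series
  with confounded intervals flagged.
* **Carbonate chemistry** — full speciation (DIC, pCO₂, CO₃²⁻,
  Ω_calcite, Ω_aragonite) from pH (total scale) and total alkalinity,
  using the conventional constant set (Lueker 2000 K1/K2, Weiss 1974 K0,
  Dickson 1990 KB/KS, Millero 1995 KW, Mucci 1983 Ksp).
* **Environmental variability** — Brown–Forsythe/Levene and
  Fligner–Killeen variance-homogeneity tests and austral-season summaries
  of corrosive (pH < 7.3) days.
* **Synthetic data** — a CJS generative simulator on the real search
  calendar, covariate-driven survival, and daily SST/pH series for
  semi-permanent and seasonal upwelling profiles, so the entire pipeline
  runs without any field data.

## The model

For individual *i* released at occasion *f*, last seen at *l*, the CJS
likelihood conditional on first capture is

```
P(y_i) = ∏_{t=f}^{l-1} φ_t · p_{t+1}^{y_{t+1}} (1 − p_{t+1})^{1 − y_{t+1}} · χ_l
χ_T = 1,   χ_t = (1 − φ_t) + φ_t (1 − p_{t+1}) χ_{t+1}
```

where φ_t is apparent monthly survival (death is confounded with permanent
emigration) and p_t the detection probability, fixed at 0 in unsearched
months. Covariate structures set logit(φ_i) = α + β·x̃_i with x̃ the
standardized body length or metabolic rate.

## Worked example

Simulate the two-site experiment (monthly survival 0.92 at Talcaruca vs
0.85 at Quintay, detection 0.4, 300 individuals per site on each site's
real search calendar), fit the constant-survival model to each, and
compare the populations:

```python
import upwellsurv as u

truth_t = u.TruthConfig(n_individuals=300, phi=0.92, p=0.4, site="talcaruca", seed=41)
truth_q = u.TruthConfig(n_individuals=300, phi=0.85, p=0.4, site="quintay", seed=42)
res_t = u.CJSModel(u.simulate_histories(truth_t)).fit(n_chains=3, n_iter=4000, n_burn=500, seed=43)
res_q = u.CJSModel(u.simulate_histories(truth_q)).fit(n_chains=3, n_iter=4000, n_burn=500, seed=44)

res_t.summary().round(3).head(4)
#             mean     sd   q2.5  median  q97.5   rhat       ess
# parameter
# phi        0.915  0.009  0.897   0.916  0.931  1.002  1138.962
# p[2]       0.478  0.077  0.332   0.478  0.627  1.001  2655.252
# p[3]       0.480  0.066  0.352   0.480  0.615  1.001  2286.452
# p[14]      0.478  0.092  0.301   0.474  0.660  1.001  1951.691

res_t.annual_survival()   # {'mean': 0.347, 'median': 0.347, 'q2.5': 0.272, 'q97.5': 0.423}
res_q.annual_survival()   # {'mean': 0.128, 'median': 0.127, 'q2.5': 0.086, 'q97.5': 0.178}

cmp = res_t.compare_phi(res_q, "talcaruca", "quintay")
cmp.prob_greater          # 1.0  — posterior probability of higher survival at Talcaruca
cmp.diff_mean             # 0.0737, 95% CrI (0.0448, 0.1052) on the monthly scale
```

The posterior means recover the simulated truths (0.915 vs 0.92; 0.841 vs
0.85), every split R-hat is ≈ 1.00, and the annual survivals (monthly φ
raised to the 12th power) differ ~2.7-fold, mirroring the kind of contrast
the field comparison is designed to detect.

The bundled site-mean water chemistry gives the carbonate-system context:

```python
for site, m in u.fielddata.WATER_MEANS.items():
    s = u.WaterSample(None, site, m["ph_total"], m["ta_umol_kg"],
                      m["temperature_c"], m["salinity_psu"])
    print(site, u.solve_from_ph_ta(s))
# talcaruca  DIC 2081.1  pCO2 406.0  CO3 141.3  Omega_ca 3.40  Omega_ar 2.17
# quintay    DIC 2008.1  pCO2 442.4  CO3 121.1  Omega_ca 2.91  Omega_ar 1.86
```

A command-line pipeline mirrors the library
(`upwellsurv simulate|build-histories|fit|compare|carbonate|envtests|report`);
see `upwellsurv --help`.

## Documentation

`docs/methods.md` describes the statistical model, the sampler, the
numerical choices in the carbonate solver, what the synthetic-data
generator does and does not emulate, and known limitations.
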