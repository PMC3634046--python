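# otogrowth

Hierarchical Bayesian otolith ageing-error modelling and two-stanza
Von Bertalanffy (VB-logK) growth estimation for tropical tuna, with
age-length-key machinery to convert catch-at-size into catch-at-age.

## The problem

Fish ages are usually read by counting daily growth increments in otolith
cross-sections. Readings are noisy (repeat counts of the same otolith
disagree), increments are lost at the otolith nucleus during preparation
and at the compressed margin, and the deposition rate perceived by a
reader can differ from one increment per day. The traditional method —
average the counts, call the result days — ignores all of this and
propagates biased, overconfident ages into growth curves and into the
age-structured catch data that stock assessments consume.

`otogrowth` implements, for the Indian Ocean yellowfin tuna
(*Thunnus albacares*) mark–recapture setting:

- **an ageing-error model**: repeat counts of an otolith section are
  Gaussian around the expected count with multiplicative error,
  `N_read ~ Normal(N, (p·N)²)`, where for a fish of age `a` (days),
  time-at-liberty `TAL`, deposition rate `ρ` and signed nucleus/edge
  biases `b_N`, `b_E`:

  ```
  E[nucleus→OTC-mark]  = ρ·a_tag + b_N
  E[OTC-mark→edge]     = ρ·TAL   + b_E
  E[nucleus→edge]      = ρ·a_rec + b_N + b_E
  ```

  The deposition rate is first estimated by Bayesian regression on a
  reliable subsample of oxytetracycline(OTC)-marked fish (reading CV ≤ 10 %,
  recapture-date CV ≤ 5 %); its posterior then serves as the prior when
  estimating individual ages, and imprecise times-at-liberty are uniform
  latent variables between their logbook bounds.

- **a two-stanza growth model** (VB-logK): the growth coefficient moves
  logistically from a juvenile `K1` to an adult `K2 = δ·K1` at age
  `α` after `t0`, with transition rate `β`:

  ```
  L(a) = L∞·(1 − exp(−[K1·(a−t0) + (K2−K1)/β · log((1+e^{β(a−t0−α)})/(1+e^{−βα}))]))
  ```

  Observed fork lengths are Gaussian around the curve (sd `σ_L`). The
  asymptotic-length prior is a generalized extreme value (GEV) law fitted
  by maximum likelihood to historical per-(platform, fishery, year)
  maximum fork lengths.

- **the coupled model**: latent ages are shared between the ageing and
  growth submodels, so reading uncertainty propagates into growth
  estimates. Sampling is adaptive Metropolis-within-Gibbs with a jointly
  adapted multivariate block for the correlated growth parameters;
  convergence is monitored with the Gelman–Rubin statistic.

- **simulation designs and metrics** used to validate the approach
  (deposition-rate recovery, reading-count comparison against the
  traditional and rate-corrected estimators, the 252-fish growth
  sensitivity design), plus relative RMSE / MSE / MRE and paired Wilcoxon
  comparisons.

- **age-length keys**: `P(age class | length bin)` by Bayes inversion of a
  fitted curve (uniform age prior; plug-in or posterior-averaged), and
  mass-conserving catch-at-size → catch-at-age conversion.

## Worked example

```sh
python examples/growth_curve_summaries.py
```

prints, for the case study's posterior-mode parameter set
(L∞ = 146.243 cm, K1 = 0.246 /y, K2 = 0.664 /y, α = 2.61 y, β = 12.583 /y,
t0 = −0.43 y):

```
length at 1 y:    43.4 cm
length at 3 y:   101.6 cm
first-stanza rate minimum: 1.75 cm/month at 1.83 y (62 cm)
transition rate maximum:   3.54 cm/month at 2.37 y (79 cm)
mean juvenile rate 22->63 cm: 2.10 cm/month
```

i.e. juvenile growth slows to 1.75 cm/month just before the logistic
transition, accelerates to 3.54 cm/month at about 2.4 years (79 cm), and
the mean juvenile rate of 2.10 cm/month sits inside the 1.3–2.9 cm/month
range reported for small yellowfin. `examples/deposition_rate.py` fits the
deposition regression on a simulated 25-fish OTC dataset (true rate
0.95/day) and prints the posterior mode (0.957), its 95 % interval
([0.939, 0.977]) and the resulting rejection of the daily-deposition
hypothesis; the other examples cover individual age estimation, the
coupled growth fit and the age-length-key conversion.

A thin CLI mirrors the pipeline
(`otogrowth simulate / fit-deposition / estimate-ages / fit-growth /
build-alk / convert-catch / report`); every stage writes a
`manifest.json` with inputs, config hash and seed.

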