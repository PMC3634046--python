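# Methods

This note records the models implemented in `otogrowth`, the assumptions
behind them, the defaults and why they were chosen, and what the synthetic
data generators do and do not emulate.

## Ageing-error model

**Observation model.** Each otolith section is read 2–5 times. Counting
errors are treated as equiprobable per increment, so the absolute error
grows with the number of increments; reads are therefore Gaussian around
the section's expected count with a *multiplicative* standard deviation
`p · expected`, where `p ∈ [0, 0.5]` is the relative misread fraction (the
normal replaces a Poisson count law, which it approximates closely at the
hundreds-of-increments scale relevant here; a warning is issued below 20
increments, where the approximation and the continuous latent-count
treatment would both become questionable).

**Process model.** Expected counts are linear in elapsed time: deposition
rate `ρ` (increments/day) times the elapsed days, plus a signed bias for
each end of the counting path that appears in the section
(`b_N` nucleus, `b_E` edge). `ρ = 1` is the daily-deposition hypothesis,
tested via the 95 % credible interval of `ρ` after the deposition
regression.

**Latent structure.** The per-fish latent variable is the *true increment
count* of the fish's primary section; ages are deterministic transforms,
`a = (N − biases)/ρ`. This follows the model's own bookkeeping (the
increment counts are the quantities the reading likelihood acts on) and is
not merely cosmetic: with flat-in-age latents every capture-only fish
contributes a `1/ρ` measure factor to the marginal of `ρ`, and a few
hundred such fish can drag `ρ` far below even a tight informative prior.
With flat-in-count latents the marginal for `ρ` is driven by the data and
the prior, as intended.

**Case handling per fish.**

- *A* — OTC-marked, precise recapture date, nucleus→mark counts: latent is
  the count at tagging; age-at-recapture = age-at-tagging + TAL.
- *B* — full (nucleus→edge) counts, known TAL: latent is the full count;
  age-at-tagging = age-at-recapture − TAL (constrained positive).
- *C* — capture-only or imprecise date: only age-at-recapture is defined;
  an imprecise TAL is itself uniform between its logbook bounds.

**Two-step estimation.** The deposition regression is fitted first on the
filtered OTC subsample (reading CV ≤ 10 %, date CV ≤ 5 %; both
configurable). Its posterior for `ρ` and `b_E` enters the age-estimation
and coupled models as moment-matched normal priors — a deliberate
approximation chosen over resampling posterior draws because the
deposition posteriors are close to normal in practice and a closed-form
prior keeps the second-stage density cheap and smooth. `b_N` keeps its
elicited prior: full counts contain nothing that separates the nucleus
bias from age, so its posterior equals its prior (a property the test
suite checks).

## Growth model

The VB-logK curve integrates a logistic growth coefficient; see the README
for the closed form. `t0` anchors zero length, `α` is the inflection age
relative to `t0`, and `β` sets the transition abruptness; `δ = K2/K1 ≥ 1`
is sampled rather than `K2` so the adult coefficient inherits the
juvenile scale. Degenerate settings are handled exactly: `δ = 1` or
`β = 0` recover classic single-coefficient Von Bertalanffy growth (at
`β = 0` the coefficient is the midpoint of `K1` and `K2`).

Numerical choices: `log(1+e^x)` is evaluated with `logaddexp`;
length-to-age inversion brackets the root in `[t0, t0+50 y]` and solves to
`xtol = 1e-12` years (the curve is strictly monotone, so the root is
unique; brackets are doubled if the target is very close to `L∞`); rate
extrema are located on a 0.001-year grid and polished with bounded scalar
minimisation. Curve summaries printed in months use 1 month = 1/12 year;
day-scale ages meet year-scale growth through a 365 day/year convention.

## Priors

All hyperparameters are configuration with these defaults:

| parameter | default prior | rationale |
|---|---|---|
| ρ | dilated Beta(2,2) on [0.5, 1.5] | bounded support, no trend within it |
| b_N | Normal(−2.5, 2²) trunc. [−15, 0] | up to 15 increments lost at the core, typical 2–3 |
| b_E | Normal(−3.5, 5²) trunc. [−20, 20] | up to 20 lost at the margin, typical 3–4; over-counting allowed |
| p | Uniform(0, 0.5) | weakly informative on the misread fraction |
| L∞ | GEV fitted to length maxima | block-maxima argument: yearly per-platform/fishery maxima bound the asymptote |
| K1 | Gamma(mean 0.3 /y, CV 0.5) | literature scale for juvenile growth |
| δ | Uniform(1, 10) | adult coefficient at least the juvenile one |
| α | Gamma(mean 2.5 y, CV 0.5) | transition around 2–3 years |
| β | Uniform(0, 20) /y | from near-linear blend to sharp switch |
| t0 | Uniform(−3, 0) y | hatch length is positive, so t0 < 0 |
| σ_L | trunc. Normal from repeat measurements | `sd(Δlength)/√2` of fish re-measured within 7 days |

The GEV is parameterised with the extreme-value sign convention (shape
ξ > 0 = heavy tail); scipy's `genextreme` uses `c = −ξ` internally. ML
fitting uses scipy's optimizer; non-convergence raises with diagnostics.

## Sampler

Adaptive Metropolis-within-Gibbs. Scalar parameters take Gaussian
random-walk steps (scales adapted to ≈ 44 % acceptance during burn-in);
per-fish latent vectors are updated element-wise in one vectorised pass
(valid because fish are conditionally independent given the globals); and
the correlated block (ρ and the free growth parameters, whose posterior is
a ridge with |corr| up to ≈ 0.93) additionally takes a jointly adapted
multivariate step with covariance learned during burn-in
(`2.38²/d · Σ̂`, global scale adapted to ≈ 23 % acceptance). All
adaptation freezes at the end of burn-in, so retained draws come from a
fixed-kernel Markov chain. Without the joint block the growth ridge mixes
an order of magnitude more slowly (Gelman–Rubin ≈ 1.3–1.5 where the
blocked sampler reaches < 1.07).

Convergence is declared at Gelman–Rubin < 1.05 (all parameters), computed
by default on half-split chains; posterior modes use a Gaussian KDE with
Silverman bandwidth, evaluated coarse-then-fine with a quadratic fit to
the log-density within one bandwidth of the argmax (stabilises the argmax
of a flat-topped density). Scalar prior densities use closed forms
verified against scipy to 10⁻⁹.

Default production settings mirror the study (3 chains, burn-in 5000,
thinned draws); tests and the acceptance script use scaled-down runs
(2–3 chains, 1000–2000 kept draws, burn-in 1000–3000) sized so the full
suite runs on one CPU in well under half an hour — the scaling affects
Monte-Carlo error only, and the Gelman–Rubin check guards each fit.

## Synthetic-data generators

Generators emulate the three validation designs:

- *deposition recovery*: 25 OTC fish, TAL ~ U(30, 970) days, 4 reads of
  the mark→edge section, rate 0.95 (optionally per-fish
  Normal(0.95, 0.02²) — the 0.02 is our choice of "small individual
  variability", not a published value).
- *reading count*: 500 capture-only fish, five equal-width age classes
  partitioning 0.5–5 years (equal width is our reading of "five classes
  from 6 months to 5 years"), 2–5 reads of the full section.
- *growth sensitivity*: four fork lengths per 2-cm class over 20–146 cm
  (252 fish) on the reference modal curve; true ages by numeric inversion;
  counts through the ageing generator with the case study's posterior
  ageing parameters (ρ = 0.939, b_E = −0.54; b_N = −2.5 is the prior
  centre, unpublished); observed lengths add Normal(0, 8.809²) cm.

Unpublished generator constants, fixed once: misread fraction `p = 0.10`
(the reliability filter accepts reading CVs up to 10 %, so a 10 % relative
read error is the natural scale); 3 reads per otolith in the sensitivity
design (the reading-count analysis concludes three reads are the
cost-accuracy compromise); length maxima from GEV(loc 167, scale 12,
shape −0.10), giving a mean near 173 cm — the scale of asymptotic-length
estimates derived from industrial fisheries size data; and a bimodal
catch-at-size histogram (modes ≈ 45 cm and ≈ 120 cm) imitating the
FAD/free-school structure of purse-seine yellowfin catch. Counts are
rounded to whole increments and floored at zero.

What the generators do **not** emulate: reader-to-reader differences
(single-reader model), age-dependent selectivity of recaptures, seasonal
growth oscillation, sexual dimorphism in `L∞`, spatial structure of the
fishery, and non-uniform length distributions within 2-cm classes.
Passing tests therefore demonstrate internal consistency of the method
under its own assumptions — not robustness to these real-data features.

## Estimator comparison metrics

Per-fish relative RMSE is `sqrt(mean((â − a)²))/a`; for a point estimator
this is the relative absolute error, and the *Bayesian* age entering the
comparison is the per-fish posterior mean. The posterior-spread-inclusive
alternative (RMSE over draws) was considered and rejected: it lower-bounds
the Bayesian RMSE by the posterior spread, which in turn is bounded below
by the reading scatter, so it would mechanically rank any
uncertainty-carrying estimator below any point estimator regardless of
bias — contradicting the purpose of the comparison (bias from uncorrected
deposition rate vs noise). MSE and MRE are computed over MCMC draws
against generating values; rank comparisons use the paired Wilcoxon
signed-rank test (identical vectors short-circuit to "not significant").

## Age-length key

`P(bin | age)` is the Gaussian length-measurement mass over the bin at the
curve mean, evaluated on an age grid (default step 0.01 y over 0–10 y);
with a uniform age prior, `P(class | bin) ∝ Σ_{ages in class} P(bin|age)`.
Keys are built either at plug-in parameters (posterior modes) or averaged
over posterior draws (default, 200 draws): each draw's key is normalised
and the average renormalised, so uncertainty in the curve widens the age
composition instead of being collapsed first. Rows sum to 1 to 10⁻⁹ and
conversion conserves total catch exactly. Comparisons between two keys'
compositions report per-bin total-variation distance and a chi-square
style contrast, at 10-cm reporting bins by default.

## Known limitations

- The two-step use of the deposition posterior (normal approximation) is
  not a full joint fit over both data sets.
- The coupled model's `ρ` is only weakly identified by capture-only data;
  it relies on the deposition-informed prior (by design, but worth knowing).
- With sparse data above ~3 years, the GEV asymptotic-length prior
  dominates `L∞` and, through the strong negative correlation, biases the
  adult coefficient downward — the sensitivity analysis quantifies
  exactly this effect, and the magnitude of the bias varies substantially
  between 252-fish realisations (which is why the acceptance computation
  averages replicate datasets).
- Single reader; integer rounding of counts is ignored by the continuous
  likelihood (immaterial above ~20 increments).
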