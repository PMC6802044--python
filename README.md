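# bomarisk

Carnivore raids on fortified vs. traditional livestock enclosures: a tested,
reusable implementation of the full analysis chain for paired case–control
*boma* monitoring studies in East African rangelands — for quantitative
ecologists and human–wildlife-conflict researchers who want the whole
pipeline (data model, risk model, model selection, economics) runnable and
checkable end to end without the original field data.

## The problem

Livestock night enclosures (bomas) are raided by large carnivores — mostly
spotted hyenas — and herders retaliate, mostly against lions. Fortifying
bomas with chain-link fencing is a leading mitigation, but its efficacy and
its economics are rarely evaluated with a controlled design. The study
design implemented here pairs each fortified ("experimental") boma with a
nearby traditional ("control") boma in the same village and revisits both on
a thirty-day interval for five years, recording raid attempts, successful
raids, species, and livestock losses.

## The models

**Risk.** For boma-month *i* in village *v(i)* and year *t(i)*, the response
y_i indicates any spotted-hyena raid attempt (or success) in the window:

    y_i ~ Bernoulli(p_i),  logit(p_i) = x_i'β + u_{v(i)} + w_{t(i)},
    u_v ~ N(0, σ_v²),  w_t ~ N(0, σ_t²)   (village × year, crossed)

estimated by Laplace-approximated maximum likelihood (the crossed design
does not factor, so per-group quadrature is unavailable). Five a-priori
fixed-effect structures — boma type + season, five landscape covariates ±
season ± boma type, and boma type alone — are ranked by AICc with Akaike
weights w_i = exp(−Δ_i/2)/Σ exp(−Δ_m/2), after a collinearity screen
(all VIF < 2.5). Effect sizes are odds ratios exp(β̂) with Wald z, p and CIs.

**Economics.** Fortification is an investment C₀ repaid by avoided losses:
CF = Σ_class (rate_control − rate_experimental) × price, discounted at the
true interest rate r (nominal − inflation), NPV(t) = −C₀ + Σ_{s≤t} CF(1+r)^−s,
with the break-even year the first t with NPV(t) ≥ 0, over a grid of three
boma size classes × four interest-rate scenarios.

**Synthetic studies.** A generator (`bomarisk.synthetic`) simulates complete
studies with this exact structure — paired registry, logistic-normal raid
process, hyena-dominated species mixture, goat-dominated losses, Poisson
retaliation — calibrated by default to the published study conditions
(45 + 45 bomas, 631/521 revisits, marginal monthly raid rates 0.102/0.081,
89% hyena share). Every stage of the pipeline is tested against it.

## Worked example

```sh
python analysis/01_simulate_study.py      # write the default study to results/study/
python analysis/02_descriptive_summaries.py
python analysis/03_fit_depredation_models.py
python analysis/04_cost_benefit.py
python analysis/05_parameter_recovery.py
```

The drivers print, for the bundled seed:

```
monthly raid attempts: 0.106/boma-month (traditional) vs 0.087 (fortified)
species shares (%): spotted_hyena 90.0, leopard 4.5, jackal 3.6, lion 0.9, cheetah 0.9
retaliation: 23.8 +/- 1.5 lions killed per year
pair distance: 235 m (range 44-972)

[attempt] top model: Boma type + Season (AICc 659.24, weight 0.960)
     term  estimate     se       z      p  ci_low  ci_high  odds_ratio
intercept   -2.8345 0.3149 -9.0011 0.0000 -3.4517  -2.2172         NaN
boma_type   -0.3413 0.2142 -1.5935 0.1111 -0.7611   0.0785      0.7108
   season    0.7715 0.2399  3.2162 0.0013  0.3013   1.2417      2.1631
```

Raids are rare at any single household (about one attempt per boma per ten
months), dominated by spotted hyena, and roughly twice as likely in the wet
season (odds ratio 2.2 in this one simulated study; the generating value is
3.0 and a single 1,152-visit study carries that much sampling noise —
`05_parameter_recovery.py` refits at 30,000 boma-months and returns 2.92).
The management model wins the AICc ranking, and the fortification effect
points the right way (odds ratio 0.71) without reaching significance at this
sample size. The economics:

```
true interest rate: 9.18% - 7.2% = 1.98%
annual avoided-loss cash flow: 97.89 USD/yr

break-even year by size class and interest rate:
size          1.98%     5.0%    10.0%    15.0%
small             1        1        1        1
average           2        3        3        3
large            19        -        -        -
```

An average-sized fortification (US$186) pays for itself in two to three
years; a small one within the first year; a large one (US$1509) only after
19 years at the 1.98% true rate — fortification is cost-effective except for
the largest enclosures.

The same pipeline is scriptable via the CLI (`bomarisk simulate|analyze|
recover|cba`), each run writing a manifest (config, seed, checksums,
timings) sufficient to reproduce it bit-identically.

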