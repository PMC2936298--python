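# birthmix

Modeling birthweight distributions and birthweight-specific
fetal-infant mortality with normal mixtures and component-specific
logistic risk curves.

## The problem

Conventional birthweight categories (ELBW, VLBW, MLBW, NBW, HBW)
discretize a continuous phenomenon, and they cannot express the idea
that two infants born at the *same* weight may face very different
mortality risks because they come from qualitatively different
pregnancies.  `birthmix` implements a two-stage framework for perinatal
epidemiologists that addresses both limitations:

1. **Mixture stage.**  The birthweight density is a k-component normal
   mixture `sum_j p_j f(x; mu_j, sigma_j)`; components represent latent
   subpopulations (e.g. compromised vs uncompromised pregnancies), and
   k is chosen from the data (BIC/AIC/ICL, or fixed by the analyst).
2. **Risk stage (generalized PMLR).**  Within each component, mortality
   risk is `r_j(x) = logit^-1[q_j(z_j)]` with `q_j` a quartic
   polynomial in the component-standardized birthweight
   `z_j = (x - mu_j)/sigma_j`, fitted by maximum likelihood conditional
   on the mixture.  The population curve is the posterior-weighted
   average `R(x) = sum_j tau_j(x) r_j(x)`.

On top sit the multi-sample ("meta-sample") tools: estimates from N_rep
samples of one population are combined on the logit scale, with
confidence intervals

    theta_bar ± { B_theta + C · S_theta / sqrt(N_rep) },

where `B_theta` is a simulation-based bias adjustment and `C` is
calibrated by a built-in coverage study (C_0 = 4.0 for risk targets).
When samples overlap because the population is finite, C is inflated to
`C_phi = C_0 · phi · N_rep / {1 - (1-phi)^N_rep}` with `phi` the
sampled fraction.  Odds ratios comparing two components of one
population, or the same component of two populations, come with
intervals on the same footing.

## Worked example

```python
import birthmix as bm

# the built-in reference scenario: a 4-component mixture with quartic
# per-component mortality curves
spec = bm.four_component_scenario()

# a small study design: 5 overlapping samples of 20,000 from a finite
# population of 100,000
design = bm.ScenarioSpec(spec.mixture, spec.risk, 100_000, 20_000, 5, seed=42)
pop = bm.make_finite_population(design)
samples = bm.draw_overlapping_samples(pop, 20_000, 5, seed=42)
fits = []
for s, sample in enumerate(samples):
    mix = bm.fit_mixture_em(sample, k=4, seed=s)
    fits.append(bm.fit_pmlr(sample, mix, seed=s))

# combined risk in component 2 at 3000 g, with an overlap-corrected
# interval
meta = bm.combine_risk_estimates(fits, j=2, x=3000.0)
c = bm.overlap_constant(4.0, phi=design.phi, n_rep=meta.n_rep)
iv = bm.risk_interval(meta, c, use_bias=False)
print(f"risk in component 2 at 3000 g: "
      f"{1000 * iv.point:.1f} per 1000 ({1000 * iv.lower:.1f}, {1000 * iv.upper:.1f})")

# odds ratio: component 2 vs component 4 at 3000 g
orr, _ = bm.odds_ratio_within(fits, 2, 4, 3000.0, c)
print(f"odds ratio comp2/comp4 at 3000 g: "
      f"{orr.point:.2f} ({orr.lower:.2f}, {orr.upper:.2f})")
```

Output:

```
risk in component 2 at 3000 g: 8.5 per 1000 (0.2, 250.3)
odds ratio comp2/comp4 at 3000 g: 2.57 (0.00, 10679.90)
```

The first line estimates mortality risk at 3000 g *for births belonging
to component 2* — here about 8.5 per 1000, against roughly 2-4 per 1000
in the dominant component at the same weight.  The odds-ratio line
quantifies that heterogeneity directly: a single birthweight, two
different risks — exactly the statement single-curve models of the
birthweight-mortality relationship cannot make.  The intervals are very
wide because splitting the population curve into component curves is
weakly identified from five modest samples; the reference study design
(25 samples of 50,000, and the bias adjustment `B_theta`) exists
precisely to tame this, and even then such odds-ratio intervals span an
order of magnitude.

A command-line interface mirrors the stages:

```bash
birthmix simulate --n 20000 --seed 1 --out records.csv
birthmix fit --input records.csv --k 4 --out-mixture mix.json --out-risk risk.json
birthmix meta --fits risk1.json --fits risk2.json --odds-ratio 2,3 --out table.csv
birthmix coverage --scale 0.1 --reps 3 --out coverage.csv
```

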