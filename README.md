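# elemove

Landscape-scale movement-behaviour analysis for GPS-collared African
forest elephants (*Loxodonta cyclotis*) — and for any hourly-sampled
terrestrial tracking dataset with a similar design.

Wildlife managers designing reserves and corridors need to know how much
space an elephant uses, when it moves, how faithful it is to a site, and
whether individuals differ consistently — a question about *behavioral
syndromes*, correlated suites of behaviors across individuals.  `elemove`
turns raw fix tables into those answers:

1. **Track cleaning** — sequential 7 km/h speed filter, burst
   segmentation at 2-h gaps, fix-regularity reporting.
2. **State segmentation** — a 2-state hidden Markov model with
   gamma step lengths and von Mises turning angles,
   p(x_t | s_t) = Gamma(l_t; mu_s, sigma_s) · vonMises(theta_t; m_s, kappa_s),
   fitted by maximising the exact forward likelihood and decoded with the
   Viterbi algorithm into *encamped* vs *exploratory* steps.
3. **Five behaviors** per individual per month/year — movement distance
   (km), 95% kernel-density home range (km²), site fidelity (overlap of
   consecutive ranges), diurnality index
   D = (day − night)/total daily distance in [−1, +1], and the proportion
   of exploratory steps.
4. **Covariates** — human footprint, temperature seasonality, rainfall
   and gap-filled NDVI rasters averaged within each home range.
5. **Variance partitioning** — bespoke parameter-expanded Gibbs samplers
   for Gaussian mixed models: per-behavior fixed effects and adjusted
   repeatability R = V_ind / (V_ind + V_region + V_month + V_resid), and
   a 4-trait model with unstructured covariances whose among-individual
   matrix yields correlations r_I(x,y) = COV_I(x,y)/√(V_I(x)·V_I(y)) and,
   via per-draw eigen decomposition, syndrome axes with credible
   intervals.
6. A **synthetic-population generator** (biased correlated random walk
   with individual-level random effects, state switching, day/night
   modulation and home-range attraction) standing in for the
   non-deposited field data, with stored ground truth.

## Worked example

```python
import numpy as np
import elemove as em

cfg = em.RunConfig(n_individuals=12, months=6, seed=0,
                   out_dir="demo_out", n_restarts=3)
res = em.run_pipeline(cfg)   # simulate -> clean -> HMM -> metrics -> models

params = res["hmm_params"]
print("HMM: mu =", np.round(params.mu, 1), " sigma =", np.round(params.sigma, 1))
tab = res["tables"]["monthly"]
print("monthly records:", len(tab), " fixed h (m):", round(tab.attrs["h_used"]))
rep = res["univariate"]["monthly"]["distance_km"]["repeatability"]
print(f"distance repeatability R = {rep['mean']:.2f} "
      f"({rep['ci_low']:.2f}, {rep['ci_high']:.2f})")
print("eigenvalue shares:", np.round(res["syndrome"]["axes"].shares, 2))
```

prints

```
HMM: mu = [102.3 996.2]  sigma = [ 83.2 616.7]
monthly records: 72  fixed h (m): 606
distance repeatability R = 0.31 (0.02, 0.77)
eigenvalue shares: [0.7  0.28 0.01 0.  ]
```

Reading the output: the fitted HMM recovers the generator's step-length
regimes (means 100 m encamped vs 1000 m exploratory).  Each of the 12
simulated elephants contributes 6 monthly records; home ranges use one
fixed kernel bandwidth (here 606 m, the mean reference bandwidth across
windows).  About 31% of the variance in monthly distance, after fixed
effects, is attributable to consistent individual differences — with a
wide interval, as expected from only 12 individuals.  The leading
among-individual axis carries 70% of the (co)variation; with the default
generator's independent behavior modifiers it aligns with the single most
variable trait rather than a cross-trait syndrome.  Planting a correlated
axis in `SimConfig.sigma_i_sim` (or via `simulate_behavior_table`)
produces — and the pipeline recovers — a joint
distance/home-range/exploration axis instead.

The same run from a shell:

```bash
elemove all --seed 0 --out demo_out
```

writes `behavior_monthly.csv`, `effects.csv`, `repeatability.csv`,
`among_individual_matrix.csv` (diagonal V_I, covariances below, r_I
above, CIs in parentheses), `syndrome_loadings.csv` and a `manifest.json`
recording the seed, resolved configuration and every excluded window.
Subcommands `simulate`, `hmm`, `metrics`, `fit` and `syndrome` run the
stages separately on files.

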