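# plume-ed

Distance-decay analysis of dredging pressure fields and coral smothering
responses, with ED10/ED50 effect distances.

## The problem

Capital dredging near coral reefs generates turbid plumes that can be seen
for tens of kilometres, but the zone where settling sediment actually
smothers corals is much smaller. Quantifying both footprints from monitoring
data — *in situ* turbidity, underwater light and deposition-sensor records,
seabed particle-size surveys, and fortnightly photographic scoring of tagged
coral colonies — is central to impact prediction and to managing dredging
with spatial zonation schemes.

`plume-ed` implements that analysis as a reusable, tested pipeline for
biostatisticians and environmental scientists working with gradient designs
around a point source. Because raw dredging-campaign monitoring data are
rarely public, the package includes a first-class synthetic-data module that
generates campaigns with the same statistical structure, so every stage is
testable end to end.

## The model

Each pressure or response metric `y` is transformed to a scale on which its
mean is linear in log distance (log10 for turbidity-derived SSC, square root
for daily light integrals, logit for bounded indices and proportions) and
fitted with the Bayesian linear mixed model

```
y_ij = β0 + β1·log10(d_i) + u_site(i) + v_fortnight(j) + ε_ij
u_s ~ N(0, σ_u²),  v_f ~ N(0, σ_v²),  ε ~ N(0, σ_ε²)
```

by a self-implemented Gibbs sampler over the conjugate full conditionals
(Normal(0, 100²) priors on β, InverseGamma(0.001, 0.001) on variances),
run as multiple overdispersed chains with split-R̂ diagnostics.

The headline statistic is the **effect distance** ED_q: the distance at
which only a fraction `q` of the effect — the difference between the
back-transformed predicted values at the closest (0.19 km) and farthest
(34.8 km) monitored distances — remains:

```
f(ED_q) = f(d_far) + q·(f(d_near) − f(d_far)),   f(d) = g⁻¹(β0 + β1·log10 d)
```

ED10 is where 90% of the effect has dissipated; ED50 the half-effect
distance. EDs are computed per posterior draw, giving a median and a 95%
credible band.

## Worked example

```python
from plume_ed.decay import DecayModelSpec
from plume_ed.pipeline import RunConfig, run_pipeline

config = RunConfig(mcmc=DecayModelSpec.test_profile(), seed=1)
result = run_pipeline(config)
print(result.ed_summary.to_string(index=False))
```

```
           metric ED10_km ED10_ci95_km ED50_km ED50_ci95_km
              ssc      10       5.6-17    0.89     0.59-1.7
              dli      24        23-25     4.4      3.9-4.9
       depo_index      21        20-22     3.1      2.8-3.4
        silt_clay      14        13-15     1.4      1.3-1.5
        mucus_ge3     1.7      1.5-1.8    0.49    0.46-0.52
     sediment_ge3     1.8        1.7-2    0.54    0.51-0.58
mortality_nonzero     5.5      4.1-7.9    0.66    0.59-0.78
```

Each row is one metric; ED10/ED50 are posterior-median effect distances in
km with 95% credible intervals. The ordering is the scientifically expected
one: water-column pressures (SSC, light as DLI, the deposition index)
extend 10–25 km from the source, the seabed silt+clay signature is
intermediate, and the biological responses of massive *Porites* —
mucous-sheet cover, sediment smothering, non-zero mortality — are confined
to within a few kilometres. Per-metric posterior summaries are in
`result.fit_summaries`; e.g. the SSC fit returns the slope on log10(km)
with its credible interval and split-R̂ for every parameter.

The same run is available from the shell:

```bash
plume-ed run --seed 1 --profile test --out results/run1
```

with subcommands `simulate`, `preprocess`, `score`, `psd`, `fit` and `ed`
for the individual stages (all plain CSV/JSON in and out).

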