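# dhaflux

Quantifying microbial growth and exchange fluxes from batch time courses
when the substrate won't sit still.

Dihydroxyacetone (DHA) — and many other reactive small molecules — degrades
spontaneously in mineral growth medium. A batch culture of *E. coli* on DHA
therefore loses substrate through two routes at once: biological uptake and
abiotic chemistry. Fitting a naive exponential-growth/uptake model to such
data misattributes the chemical loss to the cells and overestimates the
uptake flux. `dhaflux` is a Python library (plus a thin CLI) for researchers
quantifying physiology from shake-flask data under these conditions.

## The model

Biomass X (gDW L⁻¹) and each extracellular metabolite Mᵢ (mM) follow

```
dX/dt  = μ·X
dMᵢ/dt = −kᵢ·Mᵢ + qᵢ·X
```

with growth rate μ (h⁻¹), first-order abiotic degradation constant kᵢ
(h⁻¹) and specific exchange flux qᵢ (mmol gDW⁻¹ h⁻¹, production positive,
uptake negative). These integrate to

```
X(t)  = X₀·e^{μt}
Mᵢ(t) = qᵢ·X₀/(μ+kᵢ)·(e^{μt} − e^{−kᵢt}) + Mᵢ₀·e^{−kᵢt}
```

with an optional lag phase (biomass constant and exchange inactive until
t_lag; degradation acts from t = 0). The estimator minimizes the weighted
sum of squares over all series jointly with box-bounded trust-region least
squares; k is fixed from noninoculated control fits by default. Precision
comes from a parametric bootstrap; goodness of fit is the Pearson
correlation between observed and fitted values.

Around the estimator sit the supporting analyses used in this kind of
study: first-order decay fitting with derived time constants and molar
branch yields, carbon-molar (Cmmol) partitioning of co-consumed substrates,
and FBA/FVA on a genome-scale model constrained with measured uptakes
(via cobrapy).

## Worked example

```python
from dhaflux import FitConfig, fit_timecourse, generate_culture
from dhaflux.synthetic import GeneratorConfig

tc, truth = generate_culture(GeneratorConfig(seed=42))      # known ground truth
config = FitConfig(k_fixed={"DHA": 0.0086}, seed=42)        # k from abiotic controls
fit = fit_timecourse(tc, config, with_precision=True)
```

Running `python examples/estimate_fluxes.py` (the same computation) prints

```
data: 11 time points over 20 h (truncated before substrate exhaustion)
growth rate: 0.150 +/- 0.003 1/h   (truth 0.15)
uptake rate: 5.32 +/- 0.15 mmol/gDW/h          (truth 5.2)
pooled observed-vs-fitted Pearson r: 0.9998
```

The growth rate and uptake flux are recovered within the bootstrap
uncertainty; the ± values are parametric-bootstrap standard deviations,
i.e. the spread of refitted estimates over datasets re-simulated with the
configured noise model. The `examples/` directory has one short script per
capability (forward simulation, flux estimation, abiotic decay, carbon
partitioning, FBA/FVA); each prints its numbers with a note on what they
mean. The same operations are exposed as CLI subcommands
(`dhaflux generate|fit|degrade|carbon|fba`).

To run the genome-scale comparison you must supply the *E. coli* model
iJO1366 yourself (BiGG, or Biomodels MODEL1108160000) at
`models/iJO1366.json`; everything else ships with the package or is
generated at run time.

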