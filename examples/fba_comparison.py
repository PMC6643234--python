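"""Compare measured uptake rates against a constraint-based model.

Runs FBA and FVA on the bundled toy network (one substrate, two parallel
routes to biomass) to show the workflow and the characteristic degeneracy
of FBA optima. To reproduce the genome-scale comparison, download the
E. coli model iJO1366 (BiGG, or Biomodels MODEL1108160000) to
models/iJO1366.json and rerun: the optimum with the four measured uptake
rates is the predicted growth rate, to be compared with the measured one.
"""

from pathlib import Path

from dhaflux.fba import (
    FluxModelSpec,
    WILDTYPE_UPTAKES,
    apply_uptake_constraints,
    build_toy_model,
    load_model,
    run_fba,
    run_fva,
)

model = build_toy_model(uptake=10.0)
result = run_fba(model)
print(f"toy network FBA optimum: {result.objective_value:.2f} (uptake bound 10)")

fva = run_fva(model, ["ROUTE1", "ROUTE2"], fraction_of_optimum=0.95)
print("FVA at 95% of optimum (each route individually dispensable):")
print(fva)

genome_scale = Path(__file__).resolve().parent.parent / "models" / "iJO1366.json"
if genome_scale.exists():
    model = load_model(genome_scale)
    spec = FluxModelSpec(uptake_rates=dict(WILDTYPE_UPTAKES))
    apply_uptake_constraints(model, spec)
    result = run_fba(model)
    print(f"\niJO1366 with measured uptakes: optimal growth "
          f"{result.objective_value:.2f} 1/h (measured: 0.15 1/h)")
else:
    print(f"\n(genome-scale step skipped: no model at {genome_scale})")
# both routes span [0, 10]: stoichiometry alone does not pin down which
# pathway carries the flux, only the achievable growth rate
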