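"""Constraint-based comparison of measured uptakes with a genome-scale model.

Measured specific uptake rates are imposed as exchange bounds on a
genome-scale metabolic model (SBML Level 3 + FBC, or BiGG-style JSON), the
biomass objective is maximized by flux balance analysis (FBA), and flux
variability analysis (FVA) maps the flux range of each reaction while the
objective is held at a fraction of its optimum. Because FBA optima are
typically degenerate, only the objective value is a sharp prediction —
FVA quantifies how loose everything else is.

The constraint convention follows COBRA exchanges (uptake is a negative
exchange flux): a measured uptake of u mmol/gDW/h sets the exchange lower
bound to -u. Starting from the model's default medium, every other
carbon-containing exchange is closed for uptake, so the measured
substrates are the only carbon sources; inorganic nutrients and oxygen
stay at model defaults (aerobic).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

import cobra
from cobra.flux_analysis import flux_variability_analysis

from .errors import ConfigurationError, InputError, NumericalError

__all__ = [
    "FluxModelSpec",
    "DEFAULT_EXCHANGE_MAP",
    "WILDTYPE_UPTAKES",
    "load_model",
    "apply_uptake_constraints",
    "run_fba",
    "run_fva",
    "build_toy_model",
]

#: iJO1366 exchange reactions for the study's four co-consumed substrates
DEFAULT_EXCHANGE_MAP = {
    "DHA": "EX_dha_e",
    "formate": "EX_for_e",
    "glycolate": "EX_glyclt_e",
    "acetate": "EX_ac_e",
}

#: measured wild-type uptake rates (mmol/gDW/h, uptake positive)
WILDTYPE_UPTAKES = {"DHA": 5.2, "formate": 3.2, "glycolate": 1.0, "acetate": 0.1}


@dataclass
class FluxModelSpec:
    """Model handle plus constraint mapping.

    ``objective`` defaults to the model's configured objective (usually the
    biomass reaction). ``fraction_of_optimum`` applies to FVA only.
    """

    model_path: str | Path | None = None
    exchange_map: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_EXCHANGE_MAP))
    uptake_rates: dict[str, float] = field(default_factory=lambda: dict(WILDTYPE_UPTAKES))
    objective: str | None = None
    fraction_of_optimum: float = 0.95
    close_other_carbon_uptake: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.fraction_of_optimum <= 1:
            raise InputError(
                f"fraction_of_optimum must be in (0, 1], got {self.fraction_of_optimum}"
            )
        for name, rate in self.uptake_rates.items():
            if rate < 0:
                raise InputError(f"uptake rate for {name!r} must be >= 0, got {rate}")


def load_model(path) -> cobra.Model:
    """Load an SBML (.xml/.sbml) or BiGG-style JSON (.json) model."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"model file not found: {path}")
    if path.suffix == ".json":
        return cobra.io.load_json_model(str(path))
    if path.suffix in (".xml", ".sbml"):
        return cobra.io.read_sbml_model(str(path))
    raise InputError(f"unrecognized model format {path.suffix!r} (want .json/.xml/.sbml)")


def _contains_carbon(metabolite: cobra.Metabolite) -> bool:
    elements = metabolite.elements or {}
    return elements.get("C", 0) > 0


def apply_uptake_constraints(model: cobra.Model, spec: FluxModelSpec) -> cobra.Model:
    """Impose measured uptake rates as exchange bounds (in place).

    Each mapped exchange gets lower bound -uptake (upper bound untouched);
    with ``close_other_carbon_uptake`` every unmapped exchange whose
    metabolite contains carbon has its lower bound raised to 0, leaving
    the measured substrates as the only carbon sources.
    """
    missing = [rid for rid in spec.exchange_map.values() if rid not in model.reactions]
    if missing:
        candidates = sorted(r.id for r in model.exchanges)[:20]
        raise ConfigurationError(
            f"exchange reactions {missing} not in model; examples of valid ids: {candidates}"
        )
    unknown = set(spec.uptake_rates) - set(spec.exchange_map)
    if unknown:
        raise ConfigurationError(f"uptake rates for unmapped substrates {sorted(unknown)}")

    mapped = set(spec.exchange_map.values())
    if spec.close_other_carbon_uptake:
        for rx in model.exchanges:
            if rx.id in mapped:
                continue
            if any(_contains_carbon(m) for m in rx.metabolites) and rx.lower_bound < 0:
                rx.lower_bound = 0.0
    for name, rid in spec.exchange_map.items():
        uptake = spec.uptake_rates.get(name, 0.0)
        model.reactions.get_by_id(rid).lower_bound = -uptake
    if spec.objective is not None:
        model.objective = spec.objective
    return model


@dataclass
class FBAResult:
    objective_value: float
    objective_id: str
    fluxes: pd.Series
    status: str


def run_fba(model: cobra.Model, objective: str | None = None) -> FBAResult:
    """Maximize the objective; raise NumericalError on infeasibility."""
    if objective is not None:
        model.objective = objective
    solution = model.optimize()
    if solution.status != "optimal":
        raise NumericalError(f"FBA did not reach an optimum: status {solution.status!r}")
    obj_ids = [r.id for r in model.reactions if r.objective_coefficient != 0]
    return FBAResult(
        objective_value=float(solution.objective_value),
        objective_id=obj_ids[0] if len(obj_ids) == 1 else ",".join(obj_ids),
        fluxes=solution.fluxes,
        status=solution.status,
    )


def run_fva(
    model: cobra.Model,
    reactions: list[str] | None = None,
    fraction_of_optimum: float = 0.95,
) -> pd.DataFrame:
    """Per-reaction (minimum, maximum) flux at a fraction of the optimum.

    Returns a DataFrame indexed by reaction id with columns
    ``minimum``/``maximum``.
    """
    if not 0 < fraction_of_optimum <= 1:
        raise InputError(f"fraction_of_optimum must be in (0, 1], got {fraction_of_optimum}")
    if reactions is not None:
        missing = [r for r in reactions if r not in model.reactions]
        if missing:
            raise ConfigurationError(f"FVA reactions {missing} not in model")
        reactions = [model.reactions.get_by_id(r) for r in reactions]
    try:
        return flux_variability_analysis(
            model, reaction_list=reactions, fraction_of_optimum=fraction_of_optimum
        )
    except Exception as exc:  # cobra wraps solver failures inconsistently
        raise NumericalError(f"FVA failed: {exc}") from exc


def build_toy_model(uptake: float = 10.0) -> cobra.Model:
    """Minimal network with a degenerate optimum, for tests and examples.

    One substrate A enters through an exchange (uptake bound), two parallel
    routes convert A to B, and B feeds a biomass sink. The optimum equals
    the uptake bound; how it splits between the routes is free — the same
    degeneracy structure genome-scale models show at scale.
    """
    model = cobra.Model("toy_parallel_routes")
    a = cobra.Metabolite("A", compartment="c")
    b = cobra.Metabolite("B", compartment="c")

    ex_a = cobra.Reaction("EX_A")
    ex_a.add_metabolites({a: -1})
    ex_a.bounds = (-uptake, 1000.0)

    r1 = cobra.Reaction("ROUTE1")
    r1.add_metabolites({a: -1, b: 1})
    r1.bounds = (0.0, 1000.0)

    r2 = cobra.Reaction("ROUTE2")
    r2.add_metabolites({a: -1, b: 1})
    r2.bounds = (0.0, 1000.0)

    biomass = cobra.Reaction("BIOMASS")
    biomass.add_metabolites({b: -1})
    biomass.bounds = (0.0, 1000.0)

    model.add_reactions([ex_a, r1, r2, biomass])
    model.objective = "BIOMASS"
    return model
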