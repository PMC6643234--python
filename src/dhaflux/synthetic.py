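"""Synthetic batch-culture and abiotic-decay data with known ground truth.

Generates the two kinds of dataset the estimators consume:

* culture time courses — exponential growth (optional lag) coupled to
  metabolite exchange and abiotic degradation, sampled on a regular grid
  (every 2 h over 48 h by default, the cadence of the shake-flask
  experiments this emulates), truncated at substrate exhaustion, with
  additive Gaussian measurement noise;
* noninoculated decay curves — first-order substrate decay with fixed
  molar branch yields to its degradation products.

Noise is additive Gaussian and deliberately unclipped: slightly negative
concentrations near depletion are a real feature of measured data and part
of what downstream fitting must tolerate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from .degradation import DEFAULT_YIELDS, ConversionYields
from .errors import InputError
from .io import OD_TO_GDW_DEFAULT, TimeCourse
from .kinetics import KineticParameters, MetaboliteParams, simulate_biomass, simulate_metabolite

__all__ = [
    "GeneratorConfig",
    "PRESETS",
    "wildtype_params",
    "generate_culture",
    "generate_abiotic",
    "exhaustion_time",
]

#: high-salt decay constant chosen so that 82% degrades in 48 h
HIGH_SALT_K = -np.log(1 - 0.82) / 48.0


def wildtype_params() -> KineticParameters:
    """Ground truth of the wild-type preset.

    Inoculation at OD600 0.05 (x 0.37 gDW/OD = 0.0185 gDW/L), growth rate
    0.15 1/h, 15 mM substrate taken up at 5.2 mmol/gDW/h while degrading
    abiotically at 0.0086 1/h.
    """
    return KineticParameters(
        x0=0.05 * OD_TO_GDW_DEFAULT,
        mu=0.15,
        metabolites=(MetaboliteParams(name="DHA", m0=15.0, q=-5.2, k=0.0086),),
    )


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian noise: sd = max(relative*|value|, floor)."""

    relative: float = 0.0
    floor: float = 0.0

    def __post_init__(self) -> None:
        if self.relative < 0 or self.floor < 0:
            raise InputError("noise levels must be >= 0")

    @property
    def is_zero(self) -> bool:
        return self.relative == 0 and self.floor == 0

    def sd(self, values: np.ndarray) -> np.ndarray:
        return np.maximum(self.relative * np.abs(values), self.floor)


#: defaults mirroring the fitting weights: 5% biomass, 2% metabolites
DEFAULT_BIOMASS_NOISE = NoiseSpec(relative=0.05, floor=0.002)
DEFAULT_METABOLITE_NOISE = NoiseSpec(relative=0.02, floor=0.05)


@dataclass
class GeneratorConfig:
    """Culture-generator settings (see module docstring for defaults)."""

    params: KineticParameters = field(default_factory=wildtype_params)
    start: float = 0.0
    end: float = 48.0
    interval: float = 2.0
    biomass_noise: NoiseSpec = DEFAULT_BIOMASS_NOISE
    metabolite_noise: NoiseSpec = DEFAULT_METABOLITE_NOISE
    seed: int | None = None
    biomass_unit: str = "gdw_per_l"  # or "od600"
    od_to_gdw: float = OD_TO_GDW_DEFAULT
    truncate_at_exhaustion: bool = True

    def __post_init__(self) -> None:
        if self.interval <= 0:
            raise InputError("sampling interval must be > 0")
        if self.end <= self.start:
            raise InputError("end must be after start")

    @property
    def noisy(self) -> bool:
        return not (self.biomass_noise.is_zero and self.metabolite_noise.is_zero)


def preset(name: str, **overrides) -> GeneratorConfig:
    """Named study conditions; see PRESETS for the catalogue."""
    try:
        factory = PRESETS[name]
    except KeyError:
        raise InputError(f"unknown preset {name!r}; have {sorted(PRESETS)}") from None
    return replace(factory(), **overrides) if overrides else factory()


PRESETS = {
    "wildtype_dha": lambda: GeneratorConfig(params=wildtype_params()),
}


def exhaustion_time(params: KineticParameters, name: str, horizon: float = 1e4) -> float | None:
    """First time at which a consumed metabolite's trajectory crosses zero.

    Returns None when the trajectory stays positive up to the horizon
    (e.g. a produced or inert metabolite).
    """
    f = lambda t: float(simulate_metabolite(params, name, np.array([t]))[0])
    met = params.metabolite(name)
    if met.m0 == 0:
        return 0.0
    t_lo, t_hi, step = 0.0, 1.0, 1.0
    while f(t_hi) > 0:
        t_lo, t_hi = t_hi, t_hi + step
        step *= 1.5
        if t_hi > horizon:
            return None
    return float(brentq(f, t_lo, t_hi, xtol=1e-10))


def generate_culture(config: GeneratorConfig) -> tuple[TimeCourse, KineticParameters]:
    """Simulate a culture time course; returns (data, ground truth).

    The sampling grid is truncated so the last emitted point still has
    every consumed substrate above zero in the noiseless trajectory; noise
    is then added on top. Deterministic given the seed (mandatory whenever
    any noise level is nonzero).
    """
    if config.noisy and config.seed is None:
        raise InputError("seed is mandatory when noise > 0")
    params = config.params
    times = np.arange(config.start, config.end + 1e-9, config.interval)
    if config.truncate_at_exhaustion:
        cutoffs = [
            t for m in params.metabolites
            if (t := exhaustion_time(params, m.name, horizon=config.end + 1)) is not None
        ]
        if cutoffs:
            times = times[times < min(cutoffs)]
    if times.size == 0:
        raise InputError("no sampling points before substrate exhaustion")

    biomass = simulate_biomass(params, times)
    mets = {m.name: simulate_metabolite(params, m.name, times) for m in params.metabolites}

    rng = np.random.default_rng(config.seed)
    if not config.biomass_noise.is_zero:
        biomass = biomass + rng.normal(0.0, config.biomass_noise.sd(biomass))
    if not config.metabolite_noise.is_zero:
        mets = {
            name: series + rng.normal(0.0, config.metabolite_noise.sd(series))
            for name, series in mets.items()
        }

    unit = config.biomass_unit
    if unit == "od600":
        biomass = biomass / config.od_to_gdw
    elif unit != "gdw_per_l":
        raise InputError(f"unknown biomass unit {unit!r}")
    tc = TimeCourse(times=times, biomass=biomass, biomass_unit=unit, metabolites=mets)
    return tc, params


@dataclass
class AbioticPreset:
    k: float
    m0: float = 15.0
    yields: ConversionYields = DEFAULT_YIELDS


ABIOTIC_PRESETS = {
    # 5x-diluted salts: the fitted decay constant of the study conditions
    "abiotic_lowsalt": AbioticPreset(k=0.0086),
    # full-strength salts: k chosen so 82% of substrate degrades in 48 h
    "abiotic_highsalt": AbioticPreset(k=HIGH_SALT_K),
}


def generate_abiotic(
    k: float,
    m0: float = 15.0,
    yields: ConversionYields = DEFAULT_YIELDS,
    start: float = 0.0,
    end: float = 48.0,
    interval: float = 2.0,
    noise: NoiseSpec = DEFAULT_METABOLITE_NOISE,
    seed: int | None = None,
    substrate_name: str = "DHA",
) -> TimeCourse:
    """Simulate a noninoculated decay curve with product formation.

    Substrate M(t) = M0 exp(-k t); each product accumulates as
    yield * M0 * (1 - exp(-k t)). Biomass is identically zero (the medium
    is sterile). Noise as configured, deterministic given the seed.
    """
    if k < 0 or m0 < 0:
        raise InputError("k and m0 must be >= 0")
    if not noise.is_zero and seed is None:
        raise InputError("seed is mandatory when noise > 0")
    times = np.arange(start, end + 1e-9, interval)
    decay = m0 * np.exp(-k * times)
    lost = m0 - decay
    series = {substrate_name: decay}
    for name, y in yields.items():
        series[name] = y * lost

    rng = np.random.default_rng(seed)
    if not noise.is_zero:
        series = {
            name: s + rng.normal(0.0, noise.sd(s)) for name, s in series.items()
        }
    return TimeCourse(
        times=times,
        biomass=np.zeros_like(times),
        biomass_unit="gdw_per_l",
        metabolites=series,
    )
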