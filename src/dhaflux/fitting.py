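"""Joint nonlinear least-squares estimation of growth and exchange fluxes.

Given a batch time course of biomass and extracellular metabolite
concentrations, this module estimates the initial biomass X0, the specific
growth rate mu, optionally a lag duration, and per-metabolite exchange
fluxes q and initial concentrations M0, by fitting the analytic batch
model (see :mod:`dhaflux.kinetics`) to all series jointly.

The objective is the weighted sum of squares

    sum_series sum_t ((obs - model) / sigma_series)^2

minimized over box-bounded parameters with a trust-region reflective
least-squares solver. Abiotic degradation constants k are fixed from
noninoculated control fits by default (the recommended workflow:
characterize the chemistry first, then quantify the biology) but can be
co-estimated.

Precision is assessed by parametric bootstrap: replicate datasets are
simulated from the fitted parameters plus the configured noise model and
refit; per-parameter standard deviations and 2.5/97.5 percentile intervals
summarize the spread.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import pearsonr

from .errors import InputError, NumericalError
from .io import TimeCourse
from .kinetics import KineticParameters, MetaboliteParams, simulate_biomass, simulate_metabolite

__all__ = [
    "SeriesWeight",
    "FitConfig",
    "FitResult",
    "PrecisionResult",
    "fit_timecourse",
    "estimate_precision",
    "goodness_of_fit",
    "predict",
    "write_fit_tsv",
]

BIOMASS_SERIES = "biomass"


@dataclass(frozen=True)
class SeriesWeight:
    """Measurement noise model of one series.

    Either an absolute standard deviation, or a relative fraction of the
    observed value with an absolute floor: sigma = max(relative*|y|, floor).
    """

    relative: float = 0.0
    floor: float = 0.0
    absolute: float | None = None

    def __post_init__(self) -> None:
        if self.absolute is not None:
            if self.absolute <= 0:
                raise InputError("absolute sigma must be > 0")
        elif self.relative <= 0 and self.floor <= 0:
            raise InputError("relative sigma and floor cannot both be zero")

    def sigma(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if self.absolute is not None:
            return np.full_like(values, self.absolute)
        return np.maximum(self.relative * np.abs(values), self.floor)


#: biomass: 5% relative with a 0.002 gDW/L floor
DEFAULT_BIOMASS_WEIGHT = SeriesWeight(relative=0.05, floor=0.002)
#: metabolites: 2% relative with a 0.05 mM floor
DEFAULT_METABOLITE_WEIGHT = SeriesWeight(relative=0.02, floor=0.05)

DEFAULT_BOUNDS = {
    "x0": (1e-6, 10.0),
    "mu": (1e-4, 2.0),
    "t_lag": (0.0, 24.0),
    "q": (-50.0, 50.0),
    "k": (0.0, 1.0),
    # m0 upper bound is data-dependent: 2 * max(observed) per metabolite
}


@dataclass
class FitConfig:
    """Options controlling :func:`fit_timecourse`.

    Attributes
    ----------
    estimate_lag : bool
        Include a lag-phase duration as a free parameter.
    k_fixed : dict
        Per-metabolite degradation constants (1/h), typically taken from
        abiotic control fits. Metabolites not listed get k = 0.
    co_estimate_k : bool
        Estimate k jointly instead of fixing it. Off by default.
    weights : dict
        Per-series noise models; keys are ``"biomass"`` or metabolite
        names. Unlisted series get the defaults above.
    bounds : dict
        Box-bound overrides keyed like DEFAULT_BOUNDS (or per-parameter
        names such as ``"q:DHA"``).
    mc_iterations : int
        Parametric-bootstrap replicate count.
    seed : int or None
        Random seed for the bootstrap; mandatory when the bootstrap runs.
    window : (float, float) or None
        Fit window in hours; observations outside are excluded.
    """

    estimate_lag: bool = False
    k_fixed: dict[str, float] = field(default_factory=dict)
    co_estimate_k: bool = False
    weights: dict[str, SeriesWeight] = field(default_factory=dict)
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    mc_iterations: int = 100
    seed: int | None = None
    window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.mc_iterations < 1:
            raise InputError("mc_iterations must be >= 1")
        for name, k in self.k_fixed.items():
            if k < 0:
                raise InputError(f"fixed k for {name!r} must be >= 0, got {k}")
        for lo, hi in self.bounds.values():
            if not lo < hi:
                raise InputError(f"bounds must satisfy lower < upper, got ({lo}, {hi})")

    def weight_for(self, series: str) -> SeriesWeight:
        if series in self.weights:
            return self.weights[series]
        return DEFAULT_BIOMASS_WEIGHT if series == BIOMASS_SERIES else DEFAULT_METABOLITE_WEIGHT

    def bound_for(self, kind: str, data_default: tuple[float, float] | None = None) -> tuple[float, float]:
        if kind in self.bounds:
            return self.bounds[kind]
        base = kind.split(":", 1)[0]
        if base in self.bounds:
            return self.bounds[base]
        if base in DEFAULT_BOUNDS:
            return DEFAULT_BOUNDS[base]
        if data_default is not None:
            return data_default
        raise InputError(f"no bounds known for parameter {kind!r}")


@dataclass
class PrecisionResult:
    """Parametric-bootstrap spread of the estimates."""

    sd: dict[str, float]
    ci_low: dict[str, float]
    ci_high: dict[str, float]
    n_replicates: int
    n_failed: int
    warning: bool  # > 20% of replicates failed to converge
    samples: pd.DataFrame | None = None


@dataclass
class FitResult:
    """Point estimates, fit diagnostics and (optionally) precision."""

    estimates: KineticParameters
    parameter_names: list[str]
    parameter_values: np.ndarray
    converged: bool
    objective: float
    initial_objective: float
    n_obs: int
    message: str
    residuals: dict[str, np.ndarray]
    pearson_r: dict[str, float | None]
    pooled_r: float | None
    precision: PrecisionResult | None = None

    def parameter_series(self) -> dict[str, float]:
        """Flat name -> estimate mapping (for replicate aggregation)."""
        return dict(zip(self.parameter_names, map(float, self.parameter_values)))

    def to_dict(self) -> dict:
        out = {
            "converged": self.converged,
            "objective": self.objective,
            "n_obs": self.n_obs,
            "message": self.message,
            "estimates": self.parameter_series(),
            "pearson_r": {k: v for k, v in self.pearson_r.items()},
            "pooled_pearson_r": self.pooled_r,
        }
        if self.precision is not None:
            out["precision"] = {
                "method": "parametric bootstrap",
                "n_replicates": self.precision.n_replicates,
                "n_failed": self.precision.n_failed,
                "warning": self.precision.warning,
                "sd": self.precision.sd,
                "ci95_low": self.precision.ci_low,
                "ci95_high": self.precision.ci_high,
            }
        return out


# ---------------------------------------------------------------------------
# parameter vector layout

_UNITS = {"x0": "gDW/L", "mu": "1/h", "t_lag": "h", "q": "mmol/gDW/h", "m0": "mM", "k": "1/h"}


class _Layout:
    """Maps between the flat optimizer vector and KineticParameters."""

    def __init__(self, met_names: list[str], estimate_lag: bool, co_estimate_k: bool,
                 k_fixed: dict[str, float]):
        self.met_names = list(met_names)
        self.estimate_lag = estimate_lag
        self.co_estimate_k = co_estimate_k
        self.k_fixed = dict(k_fixed)
        self.names: list[str] = ["x0", "mu"]
        if estimate_lag:
            self.names.append("t_lag")
        for name in self.met_names:
            self.names += [f"q:{name}", f"m0:{name}"]
            if co_estimate_k:
                self.names.append(f"k:{name}")

    def to_params(self, vec: np.ndarray) -> KineticParameters:
        i = 0
        x0, mu = vec[0], vec[1]
        i = 2
        t_lag = 0.0
        if self.estimate_lag:
            t_lag = vec[i]
            i += 1
        mets = []
        for name in self.met_names:
            q, m0 = vec[i], vec[i + 1]
            i += 2
            if self.co_estimate_k:
                k = vec[i]
                i += 1
            else:
                k = self.k_fixed.get(name, 0.0)
            mets.append(MetaboliteParams(name=name, m0=max(m0, 0.0), q=q, k=k))
        return KineticParameters(x0=x0, mu=mu, t_lag=t_lag, metabolites=tuple(mets))

    def unit(self, name: str) -> str:
        return _UNITS[name.split(":", 1)[0]]


# ---------------------------------------------------------------------------
# observation bookkeeping


def _series_observations(tc: TimeCourse, window):
    """Per-series (times, values) with NaN and out-of-window points removed."""
    tmin, tmax = (-math.inf, math.inf) if window is None else window
    in_window = (tc.times >= tmin) & (tc.times <= tmax)
    out = {}
    mask = in_window & ~np.isnan(tc.biomass)
    out[BIOMASS_SERIES] = (tc.times[mask], tc.biomass[mask])
    for name, series in tc.metabolites.items():
        mask = in_window & ~np.isnan(series)
        out[name] = (tc.times[mask], series[mask])
    return out


def _initial_guess(obs, layout: _Layout, bounds_lo, bounds_hi) -> np.ndarray:
    """Deterministic starting point.

    mu and X0 come from a log-linear regression of biomass against time
    (positive observations only); each M0 from the first observation; each
    q from an integrated mass balance, q0 = (dM + k*int M dt) / int X dt;
    t_lag starts at 0 and k (when co-estimated) at its fixed/default value.
    """
    tb, xb = obs[BIOMASS_SERIES]
    pos = xb > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(tb[pos], np.log(xb[pos]), 1)
        mu0, x00 = max(slope, 0.0), float(np.exp(intercept))
    else:
        mu0, x00 = 0.1, max(float(xb[0]), 1e-6)
    guess = {"x0": x00, "mu": mu0, "t_lag": 0.0}

    for name in layout.met_names:
        tm, ym = obs[name]
        k = layout.k_fixed.get(name, 0.0)
        m00 = max(float(ym[0]), 0.0)
        if tm.size >= 2 and tm[-1] > tm[0]:
            int_m = np.trapezoid(ym, tm)
            # biomass integral from the regression-model curve on this grid
            int_x = np.trapezoid(x00 * np.exp(mu0 * tm), tm)
            q0 = (ym[-1] - ym[0] + k * int_m) / max(int_x, 1e-12)
        else:
            q0 = 0.0
        guess[f"q:{name}"] = q0
        guess[f"m0:{name}"] = m00
        guess[f"k:{name}"] = k

    vec = np.array([guess[n] for n in layout.names])
    # clip strictly inside the box so the solver can move in both directions
    span = bounds_hi - bounds_lo
    return np.clip(vec, bounds_lo + 1e-12 * span, bounds_hi - 1e-12 * span)


def _build_bounds(obs, layout: _Layout, config: FitConfig):
    lo, hi = [], []
    for name in layout.names:
        base = name.split(":", 1)[0]
        if base == "m0":
            met = name.split(":", 1)[1]
            m_max = float(np.nanmax(np.abs(obs[met][1]))) if obs[met][1].size else 1.0
            b = config.bound_for(name, data_default=(0.0, max(2.0 * m_max, 1e-6)))
        else:
            b = config.bound_for(name)
        lo.append(b[0])
        hi.append(b[1])
    return np.array(lo), np.array(hi)


def _residual_vector(vec, obs, layout: _Layout, sigmas) -> np.ndarray:
    params = layout.to_params(vec)
    parts = []
    for series, (t, y) in obs.items():
        if t.size == 0:
            continue
        if series == BIOMASS_SERIES:
            model = simulate_biomass(params, t)
        else:
            model = simulate_metabolite(params, series, t)
        parts.append((y - model) / sigmas[series])
    return np.concatenate(parts)


def fit_timecourse(data: TimeCourse, config: FitConfig | None = None,
                   with_precision: bool = False) -> FitResult:
    """Fit the batch model to a measured time course.

    Requires at least 4 biomass observations and 3 per metabolite series.
    Biomass in OD600 is converted to gDW/L with the default factor; convert
    explicitly beforehand to use a different one. Returns a
    :class:`FitResult`; non-convergence is flagged on the result, not
    silently ignored. With ``with_precision=True`` the parametric bootstrap
    runs immediately (``config.seed`` required).
    """
    config = config or FitConfig()
    tc = data.in_gdw()
    obs = _series_observations(tc, config.window)

    nb = obs[BIOMASS_SERIES][0].size
    if nb < 4:
        raise InputError(f"need >= 4 biomass observations, got {nb}")
    for name in tc.metabolite_names:
        n = obs[name][0].size
        if n < 3:
            raise InputError(f"metabolite {name!r}: need >= 3 observations, got {n}")

    layout = _Layout(list(tc.metabolite_names), config.estimate_lag,
                     config.co_estimate_k, config.k_fixed)
    lo, hi = _build_bounds(obs, layout, config)
    sigmas = {s: config.weight_for(s).sigma(y) for s, (t, y) in obs.items()}
    x_init = _initial_guess(obs, layout, lo, hi)

    r0 = _residual_vector(x_init, obs, layout, sigmas)
    sol = least_squares(
        _residual_vector,
        x_init,
        args=(obs, layout, sigmas),
        bounds=(lo, hi),
        method="trf",
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12,
        max_nfev=2000,
    )
    params = layout.to_params(sol.x)
    converged = bool(sol.success)
    if not converged:
        # flagged, not raised: the caller sees diagnostics on the result
        pass

    residuals, pearson, pooled = _diagnostics(params, obs)
    result = FitResult(
        estimates=params,
        parameter_names=layout.names,
        parameter_values=sol.x.copy(),
        converged=converged,
        objective=float(2 * sol.cost),
        initial_objective=float(r0 @ r0),
        n_obs=sum(t.size for t, _ in obs.values()),
        message=str(sol.message),
        residuals=residuals,
        pearson_r=pearson,
        pooled_r=pooled,
    )
    if with_precision:
        result.precision = estimate_precision(data, result, config)
    return result


def _diagnostics(params: KineticParameters, obs):
    residuals: dict[str, np.ndarray] = {}
    pearson: dict[str, float | None] = {}
    all_obs, all_fit = [], []
    for series, (t, y) in obs.items():
        if series == BIOMASS_SERIES:
            model = simulate_biomass(params, t)
        else:
            model = simulate_metabolite(params, series, t)
        residuals[series] = y - model
        all_obs.append(y)
        all_fit.append(model)
        if t.size < 2 or np.ptp(y) == 0 or np.ptp(model) == 0:
            pearson[series] = None  # undefined for constant series
        else:
            pearson[series] = float(pearsonr(y, model).statistic)
    yo, yf = np.concatenate(all_obs), np.concatenate(all_fit)
    pooled = None
    if yo.size >= 2 and np.ptp(yo) > 0 and np.ptp(yf) > 0:
        pooled = float(pearsonr(yo, yf).statistic)
    return residuals, pearson, pooled


def predict(params: KineticParameters, times) -> dict[str, np.ndarray]:
    """Model curves for every series at the given times."""
    out = {BIOMASS_SERIES: simulate_biomass(params, times)}
    for m in params.metabolites:
        out[m.name] = simulate_metabolite(params, m.name, times)
    return out


def goodness_of_fit(data: TimeCourse, fit: FitResult, window=None):
    """Per-series and pooled Pearson r between observed and fitted values.

    Constant observed or fitted series have no defined correlation and are
    reported as None rather than NaN.
    """
    obs = _series_observations(data.in_gdw(), window)
    _, pearson, pooled = _diagnostics(fit.estimates, obs)
    return pearson, pooled


def estimate_precision(data: TimeCourse, fit: FitResult, config: FitConfig) -> PrecisionResult:
    """Parametric bootstrap around a converged fit.

    Simulates ``config.mc_iterations`` replicate datasets from the fitted
    parameters plus the configured noise model (at the observed sampling
    times), refits each with the same settings, and reports per-parameter
    SD and 2.5/97.5 percentiles. Deterministic given ``config.seed``.
    Non-converged replicates are excluded and counted; more than 20%
    failures sets the warning flag.
    """
    if not fit.converged:
        raise NumericalError("cannot bootstrap a non-converged fit")
    if config.seed is None:
        raise InputError("config.seed is required for the bootstrap")

    tc = data.in_gdw()
    obs = _series_observations(tc, config.window)
    curves = {s: None for s in obs}
    for series, (t, _) in obs.items():
        if series == BIOMASS_SERIES:
            curves[series] = simulate_biomass(fit.estimates, t)
        else:
            curves[series] = simulate_metabolite(fit.estimates, series, t)

    rng = np.random.default_rng(config.seed)
    samples = []
    n_failed = 0
    boot_cfg = FitConfig(
        estimate_lag=config.estimate_lag,
        k_fixed=config.k_fixed,
        co_estimate_k=config.co_estimate_k,
        weights=config.weights,
        bounds=config.bounds,
        mc_iterations=config.mc_iterations,
        seed=config.seed,
        window=None,  # observations were already windowed
    )
    for _ in range(config.mc_iterations):
        sim = _simulate_replicate(tc, obs, curves, config, rng)
        try:
            refit = fit_timecourse(sim, boot_cfg)
        except (InputError, NumericalError):
            n_failed += 1
            continue
        if not refit.converged:
            n_failed += 1
            continue
        samples.append(refit.parameter_values)

    if not samples:
        raise NumericalError("all bootstrap replicates failed to converge")
    mat = pd.DataFrame(np.vstack(samples), columns=fit.parameter_names)
    sd = mat.std(axis=0, ddof=1)
    lo = mat.quantile(0.025)
    hi = mat.quantile(0.975)
    return PrecisionResult(
        sd=sd.to_dict(),
        ci_low=lo.to_dict(),
        ci_high=hi.to_dict(),
        n_replicates=len(samples),
        n_failed=n_failed,
        warning=n_failed > 0.2 * config.mc_iterations,
        samples=mat,
    )


def _simulate_replicate(tc: TimeCourse, obs, curves, config: FitConfig, rng) -> TimeCourse:
    """One parametric-bootstrap dataset at the observed sampling times."""
    def noisy(series, t, clean):
        sigma = config.weight_for(series).sigma(clean)
        return clean + rng.normal(0.0, sigma)

    tb, _ = obs[BIOMASS_SERIES]
    biomass = noisy(BIOMASS_SERIES, tb, curves[BIOMASS_SERIES])
    # replicate series live on their own (possibly NaN-thinned) grids; a
    # union grid with NaN padding restores the TimeCourse layout
    grids = {BIOMASS_SERIES: (tb, biomass)}
    for name in tc.metabolite_names:
        tm, _ = obs[name]
        grids[name] = (tm, noisy(name, tm, curves[name]))
    all_t = np.unique(np.concatenate([g[0] for g in grids.values()]))

    def pad(t, y):
        out = np.full(all_t.shape, np.nan)
        out[np.searchsorted(all_t, t)] = y
        return out

    return TimeCourse(
        times=all_t,
        biomass=pad(*grids[BIOMASS_SERIES]),
        biomass_unit="gdw_per_l",
        metabolites={n: pad(*grids[n]) for n in tc.metabolite_names},
    )


def write_fit_tsv(fit: FitResult, path) -> None:
    """Flat TSV: parameter, estimate, sd, ci_low, ci_high, unit.

    Uptake fluxes (q < 0 in the model's production-positive convention)
    additionally get an ``uptake_rate`` row with the positive magnitude,
    matching how uptake rates are conventionally reported.
    """
    layout_units = _Layout(
        [m.name for m in fit.estimates.metabolites], False, False, {}
    )
    prec = fit.precision
    rows = []
    for name, value in fit.parameter_series().items():
        rows.append(
            {
                "parameter": name,
                "estimate": value,
                "sd": prec.sd.get(name) if prec else None,
                "ci_low": prec.ci_low.get(name) if prec else None,
                "ci_high": prec.ci_high.get(name) if prec else None,
                "unit": layout_units.unit(name),
            }
        )
        if name.startswith("q:") and value < 0:
            rows.append(
                {
                    "parameter": f"uptake_rate:{name.split(':', 1)[1]}",
                    "estimate": -value,
                    "sd": prec.sd.get(name) if prec else None,
                    "ci_low": -prec.ci_high.get(name) if prec else None,
                    "ci_high": -prec.ci_low.get(name) if prec else None,
                    "unit": "mmol/gDW/h",
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_fit_json(fit: FitResult, path) -> None:
    Path(path).write_text(json.dumps(fit.to_dict(), indent=2, default=float))
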