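"""First-order abiotic degradation kinetics and conversion yields.

Dihydroxyacetone (DHA) is chemically unstable in mineral medium: it decays
without any cells present, at a rate that depends strongly on salt
concentration, and the degraded carbon reappears mainly as formate,
glycolate and acetate. This module fits the decay constant k of

    M(t) = M0 * exp(-k t)

to noninoculated control curves, derives characteristic times, and applies
fixed molar branch yields to partition the degraded substrate among its
products. The remainder (yields need not sum to 1) is booked as
"unidentified".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import pearsonr

from .errors import InputError, NumericalError

__all__ = [
    "DegradationResult",
    "ConversionYields",
    "DEFAULT_YIELDS",
    "fit_degradation",
    "degraded_fraction",
    "characteristic_times",
    "apply_yields",
    "coconsumption_fluxes",
]


@dataclass(frozen=True)
class ConversionYields:
    """Molar branch yields: mol product formed per mol substrate degraded.

    Yields are read as molar fractions; they may sum to less than 1, in
    which case the balance is attributed to unidentified products.
    """

    yields: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, y in self.yields.items():
            if y < 0:
                raise InputError(f"yield for {name!r} must be >= 0, got {y}")
        total = sum(self.yields.values())
        if total > 1 + 1e-12:
            raise InputError(f"yields sum to {total:.4f} > 1")

    @property
    def unidentified(self) -> float:
        return max(0.0, 1.0 - sum(self.yields.values()))

    def items(self):
        return self.yields.items()


#: Molar conversion yields of DHA in 5x-diluted-salt M9 medium.
DEFAULT_YIELDS = ConversionYields(
    {"formate": 0.36, "glycolate": 0.26, "acetate": 0.013}
)


@dataclass
class DegradationResult:
    """Fitted first-order decay and derived quantities.

    ``reciprocal_time`` is 1/k (the time constant, often loosely called a
    half-life in this field); ``half_life`` is the true exponential
    half-life ln2/k. Both are ``inf`` when k = 0.
    """

    k: float
    k_sd: float
    m0: float
    m0_sd: float
    reciprocal_time: float
    half_life: float
    pearson_r: float
    converged: bool
    clamped_at_zero: bool = False
    fitted: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "k_per_h": self.k,
            "k_sd": self.k_sd,
            "m0_mM": self.m0,
            "m0_sd": self.m0_sd,
            "reciprocal_time_h": self.reciprocal_time,
            "half_life_h": self.half_life,
            "pearson_r": self.pearson_r,
            "converged": self.converged,
            "clamped_at_zero": self.clamped_at_zero,
            "yield_basis": "molar (assumed)",
        }


def characteristic_times(k: float) -> tuple[float, float]:
    """Return (1/k, ln2/k): the exponential time constant and the half-life.

    Both are labelled explicitly because 1/k is sometimes reported as a
    "half-life" although the true half-life of first-order decay is ln2/k.
    k = 0 yields (inf, inf) — decay never happens.
    """
    if k < 0:
        raise InputError(f"rate constant must be >= 0, got {k}")
    if k == 0:
        return math.inf, math.inf
    return 1.0 / k, math.log(2.0) / k


def degraded_fraction(k: float, t: float):
    """Fraction of substrate degraded after time t: 1 - exp(-k t)."""
    k = np.asarray(k, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(k < 0) or np.any(t < 0):
        raise InputError("k and t must be nonnegative")
    out = -np.expm1(-k * t)
    return float(out) if out.ndim == 0 else out


def fit_degradation(times, concentrations, sigma: float | None = None) -> DegradationResult:
    """Fit M(t) = M0 exp(-k t) to a noninoculated decay curve.

    Parameters
    ----------
    times, concentrations : array-like
        Sampling times (h) and measured concentrations (mM); >= 3 points.
    sigma : float, optional
        Measurement standard deviation used to weight residuals (absolute,
        mM). Unweighted when omitted — with a single series the point
        estimate is unaffected, only k_sd scales.

    Both k and M0 are estimated, with k bounded below at 0: a drifting-up
    control curve yields k = 0 with ``clamped_at_zero`` set rather than a
    negative rate.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    if t.shape != c.shape or t.ndim != 1:
        raise InputError("times and concentrations must be 1-D and aligned")
    if t.size < 3:
        raise InputError(f"need >= 3 points to fit decay, got {t.size}")
    if np.any(c <= 0):
        raise InputError("concentrations must be > 0 for log-linear initialization")

    # log-linear regression gives the starting point
    slope, intercept = np.polyfit(t, np.log(c), 1)
    k0 = max(-slope, 0.0)
    m0_0 = float(np.exp(intercept))
    w = sigma if sigma and sigma > 0 else 1.0

    def resid(p):
        m0, k = p
        return (m0 * np.exp(-k * t) - c) / w

    sol = least_squares(
        resid,
        x0=[m0_0, k0],
        bounds=([0.0, 0.0], [np.inf, np.inf]),
        method="trf",
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    if not sol.success:
        raise NumericalError(f"degradation fit failed: {sol.message}")
    m0_hat, k_hat = sol.x
    # a rate indistinguishable from zero (flat or drifting-up curve) is
    # reported as exactly zero with the clamp flag set
    clamped = bool(k_hat < 1e-10)
    if clamped:
        k_hat = 0.0
    fitted = m0_hat * np.exp(-k_hat * t)

    # covariance from the Jacobian at the optimum, residual-variance scaled
    dof = max(t.size - 2, 1)
    s2 = 2 * sol.cost / dof
    try:
        cov = s2 * np.linalg.inv(sol.jac.T @ sol.jac)
        m0_sd, k_sd = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        m0_sd = k_sd = float("nan")

    if np.ptp(fitted) == 0 or np.ptp(c) == 0:
        r = float("nan")
    else:
        r = float(pearsonr(c, fitted).statistic)
    rec, half = characteristic_times(k_hat)
    return DegradationResult(
        k=float(k_hat),
        k_sd=float(k_sd),
        m0=float(m0_hat),
        m0_sd=float(m0_sd),
        reciprocal_time=rec,
        half_life=half,
        pearson_r=r,
        converged=bool(sol.success),
        clamped_at_zero=clamped,
        fitted=fitted,
    )


def apply_yields(amount_degraded: float, yields: ConversionYields = DEFAULT_YIELDS) -> dict[str, float]:
    """Partition a degraded amount (mmol) among products by molar yield.

    The returned mapping includes an ``"unidentified"`` entry so that the
    products sum exactly to the input amount.
    """
    if amount_degraded < 0:
        raise InputError(f"degraded amount must be >= 0, got {amount_degraded}")
    out = {name: y * amount_degraded for name, y in yields.items()}
    out["unidentified"] = yields.unidentified * amount_degraded
    return out


def coconsumption_fluxes(
    k: float,
    yields: ConversionYields,
    substrate_series,
    biomass_series,
    times=None,
) -> dict[str, float]:
    """Specific co-consumption fluxes of degradation products (mmol/gDW/h).

    When a culture shows no accumulation of the degradation products, the
    cells must consume them as fast as abiotic chemistry produces them.
    Under that quasi-steady balance the specific consumption flux of
    product P at time t is

        q_P(t) = yield_P * k * M_substrate(t) / X(t)

    and the reported value is the time average over the series (trapezoidal
    in t when times are given, plain mean otherwise). This quasi-steady
    construction is this package's estimate, not a fitted quantity.
    """
    m = np.asarray(substrate_series, dtype=float)
    x = np.asarray(biomass_series, dtype=float)
    if m.shape != x.shape or m.ndim != 1 or m.size == 0:
        raise InputError("substrate and biomass series must be 1-D and aligned")
    if np.any(m < 0):
        raise InputError("substrate series must be nonnegative")
    if np.any(x <= 0):
        raise InputError("biomass must be > 0 everywhere in the window")
    if k < 0:
        raise InputError(f"rate constant must be >= 0, got {k}")

    inst = k * m / x
    if times is not None and m.size > 1:
        t = np.asarray(times, dtype=float)
        avg = float(np.trapezoid(inst, t) / (t[-1] - t[0]))
    else:
        avg = float(np.mean(inst))
    return {name: y * avg for name, y in yields.items()}
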