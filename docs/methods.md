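# Methods

## Model and assumptions

The batch model couples exponential growth to extracellular metabolite
exchange and first-order abiotic degradation:

dX/dt = μX,  dMᵢ/dt = −kᵢMᵢ + qᵢX,

solved analytically as X(t) = X₀e^{μt} and
Mᵢ(t) = qᵢX₀/(μ+kᵢ)·(e^{μt} − e^{−kᵢt}) + Mᵢ₀e^{−kᵢt}.

Assumptions: growth is exponential over the fitted window (no substrate
limitation kinetics, no stationary phase); each metabolite's specific
exchange flux qᵢ is constant; abiotic degradation is first order in the
metabolite with a condition-specific constant kᵢ (its strong dependence on
medium salt concentration is handled by letting k be a per-experiment
value, not by modelling ionic strength); degradation of a substrate and
consumption of its degradation products are independent processes.

The sign convention is production-positive (q < 0 is uptake), which keeps
the mathematics identical to the governing equations; reporting layers
print uptake rates as |q|. Units are fixed to hours, mM and gDW/L
throughout; the only converter is OD600 → gDW/L at the I/O boundary
(default 0.37 gDW per OD600 unit, the strain-specific factor for these
conditions).

With a lag phase, biomass stays at X₀ and biological exchange is inactive
for t ≤ t_lag, while degradation acts from t = 0 — degradation is
chemistry, indifferent to the cells' physiological state. The analytic
solution then shifts t by t_lag in the growth term only. Only metabolites
explicitly present in the parameter set are tracked; products formed
during the lag are not modelled separately.

## Estimation

The fit minimizes Σ_series Σ_t ((obs − model)/σ_series)² over box-bounded
parameters with SciPy's trust-region reflective least-squares solver. The
inequality constraints this problem needs are all box constraints, so a
box-bounded solver realizes them exactly.

Initialization is deterministic and cheap: μ₀ and X₀ from a log-linear
regression of biomass against time; M₀ from the first observation; q₀
from the integrated mass balance (ΔM + k·∫M dt)/∫X dt with trapezoidal
integrals; t_lag₀ = 0; the start point is clipped strictly inside the
bounds.

Default box bounds: X₀ ∈ [10⁻⁶, 10] gDW/L, μ ∈ [10⁻⁴, 2] h⁻¹,
t_lag ∈ [0, 24] h, q ∈ [−50, 50] mmol gDW⁻¹ h⁻¹, M₀ ∈ [0, 2·max(obs)] mM,
k ∈ [0, 1] h⁻¹ when co-estimated. These comfortably bracket heterotrophic
batch physiology; all are overridable.

Default measurement-noise model (used both for weighting and for the
bootstrap): biomass 5% relative with a 0.002 gDW/L floor, metabolites 2%
relative with a 0.05 mM floor. The 2% matches typical quantitative-NMR
proportional error; the floors keep weights finite near depletion. The
weighting scheme is a package decision — per-series weighting schemes are
rarely reported in this literature — and is configurable per series
(relative + floor, or absolute).

k is fixed from noninoculated control fits by default: the recommended
workflow characterizes the chemistry on sterile medium first, then
quantifies the biology with k known. Co-estimation is available but off —
k is weakly identifiable from culture data alone, where biological uptake
dominates the substrate trajectory.

All observations in the (optional) fit window are used, including points
before an estimated lag or after apparent substrate exhaustion; window
selection is explicit user intent, never silent.

Precision: parametric bootstrap. Replicate datasets are simulated from the
fitted curves plus the configured noise model at the observed sampling
times, refit with identical settings, and summarized by per-parameter SD
and 2.5/97.5 percentiles (default 100 replicates; deterministic given the
mandatory seed). Non-converged replicates are excluded and counted; more
than 20% failures raises a warning flag. This bootstrap SD is a different
quantity from the spread across biological replicates; the replicate
aggregator labels its output `sd_across_replicates` (n−1 denominator) to
keep the two distinguishable.

Goodness of fit is the Pearson correlation between observed and fitted
values, per series and pooled over all series; a constant series has no
defined correlation and is reported as such rather than as silent NaN.

## Abiotic chemistry

First-order decay M₀e^{−kt} is fitted by the same bounded least-squares
machinery (k ≥ 0; a flat or drifting-up control clamps to k = 0 with a
flag). Both characteristic times are exposed under unambiguous names: the
time constant 1/k — which this literature sometimes loosely calls a
half-life — and the true exponential half-life ln2/k. For k = 0.0086 h⁻¹
these are 116 h and 81 h respectively.

Branch yields (defaults 0.36 formate, 0.26 glycolate, 0.013 acetate per
mole degraded) are treated as molar fractions; they may sum to less than
one and the balance is booked as "unidentified" so that moles always
close exactly. A carbon-based reading of the percentages would change the
numbers; the molar assumption is recorded in output metadata.

Co-consumption fluxes of degradation products use a quasi-steady balance:
when a culture accumulates none of a product that chemistry is
continuously producing, consumption must balance production, giving
q_P(t) = yield_P·k·M(t)/X(t), reported as the time average over the
window. This construction is the package's own estimate and is labelled
as such.

## Synthetic data

The generator emulates the study conditions: inoculation at OD600 0.05
(0.0185 gDW/L), μ = 0.15 h⁻¹, 15 mM substrate consumed at 5.2 mmol gDW⁻¹
h⁻¹ with k = 0.0086 h⁻¹, sampled every 2 h over 48 h; abiotic presets at
k = 0.0086 h⁻¹ (5×-diluted salts) and k = −ln(0.18)/48 ≈ 0.0357 h⁻¹
(full-strength salts, i.e. 82% degraded in 48 h). Culture grids are
truncated at the last sample where the noiseless substrate trajectory is
still positive (≈ 20.5 h for the wild-type preset). Noise is additive
Gaussian, seeded, and deliberately unclipped — slightly negative
concentrations near depletion are a feature of real measurements that the
estimators must tolerate.

What the generator does not emulate: biological replicate-to-replicate
variability, substrate-dependent growth slowdown near exhaustion,
stationary phase, autocorrelated instrument drift, or the substrate's
hydrate equilibrium (the pool is treated as a single species). Passing
recovery tests therefore demonstrates estimator correctness under the
stated noise model, not robustness to every artefact of real data.

## Constraint-based comparison

Measured uptakes enter a genome-scale model as exchange lower bounds
(−uptake, COBRA convention). The medium baseline is a package decision:
starting from the model's default exchange bounds, every unmapped
carbon-containing exchange is closed for uptake, so the measured
substrates are the only carbon sources; oxygen and inorganic nutrients
stay at model defaults (aerobic). The run report records this choice.
FBA maximizes the model's biomass objective; FVA reports per-reaction flux
ranges at a fraction of the optimum (default 0.95). Only the objective
value is treated as a sharp prediction — optima are degenerate, and the
internal pathway split (e.g. between parallel DHA-phosphorylating routes)
is deliberately not a target. LP tolerances: 10⁻⁹ feasibility, 10⁻⁶
reporting; any solver meeting the contract is acceptable (GLPK via
cobrapy here). The toy network in `dhaflux.fba.build_toy_model` reproduces
the degeneracy structure at a size where brute-force LP enumeration is an
independent oracle.

## Numerical choices

* The metabolite solution divides by μ+k; it is evaluated as
  e^{−kt}·expm1((μ+k)t)/(μ+k), which is stable for small μ+k, and switches
  below |μ+k| = 10⁻⁹ to the second-order series limit
  t(1 + (μ+k)t/2)e^{−kt}; the branch switch is continuous to ~10⁻¹⁴.
* The ODE integrator (LSODA, rtol 10⁻¹⁰) is kept solely as an independent
  oracle for the analytic solutions; the lag discontinuity is handled by
  capping the step size.
* Fitted k below 10⁻¹⁰ h⁻¹ snaps to exactly zero with the clamp flag, so
  "no decay" is reported as 0 and an unbounded half-life rather than a
  denormal rate.
* Degradation-fit uncertainty (k_sd) is the standard linearized-covariance
  estimate (residual-variance-scaled inverse Gauss-Newton Hessian); the
  culture fit uses the bootstrap instead.
* CSV round trips use round-trip float parsing so written data re-reads
  bit-identically.

## Problem sizes

The test suite and acceptance script run entirely on generated data:
parameter-recovery studies use 50 synthetic cultures (11 points, 2 series
each), bootstraps 100–200 replicates, and decay-curve studies up to 200
fixtures of 25 points — sizes at which the Monte-Carlo summaries
(medians, SD ratios, interval coverage) are stable without being wasteful.

## Known limitations

* Constant-q exponential growth only; no Monod/logistic alternatives and
  no model selection between growth laws.
* No hierarchical multi-experiment fitting; replicates are aggregated
  after fitting, not jointly estimated.
* The quasi-steady co-consumption estimate assumes exactly zero product
  accumulation; partial accumulation would need the products fitted as
  ordinary metabolite series instead.
* k co-estimation from culture data alone is poorly conditioned when
  biological uptake dominates (the default workflow avoids it).
* The genome-scale model file is not redistributed; the FBA/FVA machinery
  is fully tested on the toy network, and the genome-scale run requires a
  user-supplied iJO1366 file.
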