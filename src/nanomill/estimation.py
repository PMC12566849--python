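"""Evolutionary estimation of population balance parameters from PSD series.

The inverse problem: given laser-diffraction volume-percent curves at
several milling times, find the kernel parameters whose forward simulation
reproduces them.  The objective compares full volume-percent curves (not
just D50) as a sum of squared differences over all times after t = 0; the
t = 0 curve is consumed as the initial condition of the initial-value
problem, not fitted.

The search is differential evolution (rand/1/bin, F = 0.7, CR = 0.9),
seeded and single-threaded so a fit is bit-reproducible.  Scale parameters
K1 and K2 are searched in log10 space because their plausible ranges span
decades; the shape parameters are searched linearly.  A candidate whose
simulation fails (kernel overflow, integrator breakdown) receives a large
finite penalty instead of aborting the fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import differential_evolution

from .exceptions import FitError
from .grid_psd import PSDRecord, SizeGrid, psd_to_state, rebin_volume
from .kernels import PARAM_NAMES, PBMParams
from .solver import simulate

__all__ = ["FitSpec", "FitOutcome", "psd_objective", "fit_pbm"]

#: Penalty returned for candidates whose forward simulation fails.
FAILURE_PENALTY = 1e9

#: Parameters searched on a log10 scale.
LOG_PARAMS = frozenset({"K1", "K2"})


@dataclass
class FitSpec:
    """Search specification for :func:`fit_pbm`.

    ``bounds`` maps parameter names to (lower, upper) in natural units;
    parameters absent from ``bounds`` must appear in ``fixed``.  The DE
    population is ``popsize`` per free dimension as in scipy's convention.
    """

    bounds: dict
    fixed: dict
    seed: int = 0
    popsize: int = 15
    maxiter: int = 40
    tol: float = 0.0

    def __post_init__(self) -> None:
        unknown = (set(self.bounds) | set(self.fixed)) - set(PARAM_NAMES)
        if unknown:
            raise FitError(f"unknown parameter names: {sorted(unknown)}")
        self.free = [n for n in PARAM_NAMES if n in self.bounds and n not in self.fixed]
        missing = [n for n in PARAM_NAMES if n not in self.free and n not in self.fixed]
        if missing:
            raise FitError(f"parameters neither bounded nor fixed: {missing}")
        for name in self.free:
            lo, hi = self.bounds[name]
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise FitError(f"bounds for {name} must be finite with lower < upper")
            if name in LOG_PARAMS and lo <= 0:
                raise FitError(f"{name} is searched in log space; bounds must be > 0")


@dataclass
class FitOutcome:
    """Best parameters found, with the convergence trace."""

    params: PBMParams
    objective: float
    trace: list = field(repr=False)
    n_evaluations: int = 0


def _decode(x: np.ndarray, spec: FitSpec) -> PBMParams:
    values = dict(spec.fixed)
    for name, xi in zip(spec.free, x):
        values[name] = 10.0**xi if name in LOG_PARAMS else xi
    return PBMParams(**values)


def psd_objective(
    candidate: PBMParams,
    observed: list[PSDRecord],
    grid: SizeGrid,
) -> float:
    """Sum of squared volume-percent differences over times after t = 0.

    The first observed record (t = 0) is converted to the initial state;
    the candidate parameters are simulated forward to the remaining
    observation times; each simulated state is expressed as volume percents
    on the *observed* diameter binning before differencing.  Simulation
    failure yields the finite penalty ``1e9``.
    """
    if len(observed) < 2:
        raise FitError("need the t = 0 record plus at least one later record")
    if observed[0].time != 0.0:
        raise FitError("the first observed record must be at t = 0")
    try:
        initial = psd_to_state(observed[0], grid)
        times = [rec.time for rec in observed[1:]]
        result = simulate(initial, grid, candidate, times)
    except Exception:
        return FAILURE_PENALTY
    sse = 0.0
    for rec, state in zip(observed[1:], result.states):
        vol = grid.pivots * state.N
        on_obs, _lost = rebin_volume(vol, grid.d_edges_nm, rec.d_edges_nm)
        total = vol.sum()
        sim_pct = 100.0 * on_obs / total
        diff = sim_pct - rec.vol_pct
        sse += float(diff @ diff)
    return sse


def fit_pbm(
    observed: list[PSDRecord],
    spec: FitSpec,
    grid: SizeGrid,
) -> FitOutcome:
    """Differential-evolution fit of the free kernel parameters.

    Deterministic given ``spec.seed``; fixed parameters pass through
    unchanged.  Raises if no candidate simulated successfully within the
    budget.
    """
    n_eval = 0
    best_so_far = [np.inf]

    def objective(x: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        try:
            candidate = _decode(x, spec)
        except Exception:
            return FAILURE_PENALTY
        val = psd_objective(candidate, observed, grid)
        best_so_far[0] = min(best_so_far[0], val)
        return val

    if not spec.free:
        params = _decode(np.empty(0), spec)
        val = psd_objective(params, observed, grid)
        if val >= FAILURE_PENALTY:
            raise FitError("simulation failed at the fixed parameter point")
        return FitOutcome(params=params, objective=val, trace=[val], n_evaluations=1)

    de_bounds = []
    for name in spec.free:
        lo, hi = spec.bounds[name]
        if name in LOG_PARAMS:
            lo, hi = np.log10(lo), np.log10(hi)
        de_bounds.append((lo, hi))

    trace: list[float] = []

    def callback(xk, convergence=None):
        trace.append(best_so_far[0])
        return False

    result = differential_evolution(
        objective,
        de_bounds,
        strategy="rand1bin",
        mutation=0.7,
        recombination=0.9,
        popsize=spec.popsize,
        maxiter=spec.maxiter,
        tol=spec.tol,
        seed=spec.seed,
        polish=False,
        init="latinhypercube",
        updating="immediate",
        workers=1,
        callback=callback,
    )
    if result.fun >= FAILURE_PENALTY:
        raise FitError(
            f"no candidate simulated successfully in {n_eval} evaluations; "
            "check bounds and grid span"
        )
    trace.append(float(result.fun))
    # enforce the nonincreasing-trace contract against callback ordering quirks
    trace = list(np.minimum.accumulate(trace))
    return FitOutcome(
        params=_decode(result.x, spec),
        objective=float(result.fun),
        trace=trace,
        n_evaluations=n_eval,
    )
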