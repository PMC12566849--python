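"""nth-order comminution kinetics for the median particle size D50(t).

During wet media milling the cumulative D50 decays monotonically toward a
grinding limit.  The decay is modelled by the nth-order law

    D50(t) = Dlim + [ (D50(0) - Dlim)**(1-n) + (n-1) * k * t ]**(1/(1-n))

with grinding-limit size ``Dlim`` (nm), crushing rate constant ``k``
(nm^(1-n) min^-1) and kinetics order ``n > 1``.  At t = 0 the bracket
reduces to D50(0); as t -> inf the bracketed term vanishes and D50 -> Dlim.
On log-log axes, D50(t) - Dlim has asymptotic slope -1/(n-1).

Parameters are estimated by least squares on the *logarithm* of D50
(the size spans two decades, so log residuals weight the whole trajectory
evenly), with ``Dlim`` constrained below the smallest observation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .exceptions import FitError, NanomillError

__all__ = ["KineticsParams", "KineticsFitReport", "d50_model", "fit_kinetics"]


@dataclass(frozen=True)
class KineticsParams:
    """Parameters of the nth-order D50(t) model."""

    dlim: float   # grinding limit size, nm
    k: float      # crushing rate constant, nm^(1-n) min^-1
    n: float      # kinetics order, dimensionless
    d50_0: float  # initial D50, nm

    def __post_init__(self) -> None:
        if self.dlim <= 0:
            raise NanomillError("Dlim must be positive")
        if self.d50_0 <= self.dlim:
            raise NanomillError("D50(0) must exceed Dlim")
        if self.k <= 0:
            raise NanomillError("k must be positive")
        if self.n <= 1:
            raise NanomillError("kinetics order n must exceed 1")


def d50_model(t, params: KineticsParams):
    """Evaluate the nth-order comminution law at time(s) ``t`` (minutes)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise NanomillError("time must be nonnegative")
    one_minus_n = 1.0 - params.n
    # (D50(0) - Dlim)**(1-n) in log space; the difference is positive by the
    # parameter invariants.
    base = np.exp(one_minus_n * np.log(params.d50_0 - params.dlim))
    bracket = base + (params.n - 1.0) * params.k * t
    out = params.dlim + np.exp(np.log(bracket) / one_minus_n)
    return out if out.ndim else float(out)


@dataclass
class KineticsFitReport:
    """Fit result with goodness-of-fit on both log and linear scales."""

    params: KineticsParams
    r2_log: float
    ssr_log: float
    r2_linear: float
    ssr_linear: float
    residuals_log: np.ndarray
    n_restarts_used: int


def _residuals(theta: np.ndarray, t: np.ndarray, log_d50: np.ndarray, d50_0: float):
    dlim, k, n = theta
    p = KineticsParams(dlim=dlim, k=k, n=n, d50_0=d50_0)
    return np.log(d50_model(t, p)) - log_d50


def fit_kinetics(
    times,
    d50s,
    initial_guess: KineticsParams | None = None,
    d50_0: float | None = None,
    n_restarts: int = 5,
) -> KineticsFitReport:
    """Fit (Dlim, k, n) to a D50(t) series by damped least squares on log D50.

    ``D50(0)`` is taken from the t = 0 datum when present (and is then not
    fitted); otherwise it must be supplied via ``d50_0``.  ``Dlim`` is
    constrained below the smallest observation.  If the primary solve does
    not converge, up to ``n_restarts`` deterministically perturbed restarts
    are attempted and the best result returned.
    """
    t = np.asarray(times, dtype=float)
    d = np.asarray(d50s, dtype=float)
    if t.size != d.size or t.size < 5:
        raise FitError("need at least 5 (time, D50) pairs")
    if np.any(d <= 0):
        raise FitError("D50 values must be positive")
    if np.unique(t).size != t.size:
        raise FitError("times must be distinct")
    order = np.argsort(t)
    t, d = t[order], d[order]

    if t[0] == 0.0:
        d0 = float(d[0])
    elif d50_0 is not None:
        d0 = float(d50_0)
    else:
        raise FitError("times must include t = 0 or d50_0 must be supplied")

    d_min = float(d.min())
    log_d = np.log(d)
    lb = np.array([1e-6, 1e-12, 1.0 + 1e-9])
    ub = np.array([d_min * (1.0 - 1e-12), np.inf, 30.0])

    if initial_guess is not None:
        theta0 = np.array([initial_guess.dlim, initial_guess.k, initial_guess.n])
    else:
        theta0 = np.array([0.8 * d_min, 0.5, 2.5])
    theta0 = np.clip(theta0, lb * (1 + 1e-9), np.where(np.isfinite(ub), ub, theta0))

    def solve(theta_start):
        return least_squares(
            _residuals,
            theta_start,
            bounds=(lb, ub),
            args=(t, log_d, d0),
            method="trf",
            xtol=1e-15,
            ftol=1e-15,
            gtol=1e-15,
            max_nfev=2000,
        )

    best, used = None, 0
    rng = np.random.default_rng(0)  # deterministic restart perturbations
    start = theta0
    for attempt in range(n_restarts + 1):
        try:
            res = solve(start)
        except (FloatingPointError, NanomillError):
            res = None
        if res is not None and (best is None or res.cost < best.cost):
            best = res
            used = attempt
        if best is not None and best.cost < 1e-20:
            break
        start = np.clip(
            theta0 * rng.uniform(0.7, 1.3, size=3),
            lb * (1 + 1e-9),
            np.where(np.isfinite(ub), ub * (1 - 1e-9), theta0 * 2),
        )
    if best is None:
        raise FitError("kinetics fit failed to converge from all starting points")

    params = KineticsParams(dlim=best.x[0], k=best.x[1], n=best.x[2], d50_0=d0)
    res_log = _residuals(best.x, t, log_d, d0)
    ssr_log = float(res_log @ res_log)
    sst_log = float(np.sum((log_d - log_d.mean()) ** 2))
    fitted = d50_model(t, params)
    res_lin = fitted - d
    ssr_lin = float(res_lin @ res_lin)
    sst_lin = float(np.sum((d - d.mean()) ** 2))
    return KineticsFitReport(
        params=params,
        r2_log=1.0 - ssr_log / sst_log,
        ssr_log=ssr_log,
        r2_linear=1.0 - ssr_lin / sst_lin,
        ssr_linear=ssr_lin,
        residuals_log=res_log,
        n_restarts_used=used,
    )
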