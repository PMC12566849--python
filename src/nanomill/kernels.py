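"""Rate kernels of the breakage–agglomeration population balance model.

Three rate functions drive the model:

* breakage rate ``a(v) = K1 * v**mu`` -- the frequency at which a particle
  of (dimensionless) volume ``v`` breaks;
* diffusion-limited agglomeration rate
  ``beta(v1, v2) = K2 * (v1**y1 + v2**y2) * (v1**(-y1) + v2**(-y2))``,
  the generalized Brownian coagulation kernel -- at ``y1 = y2 = 1/3`` it is
  exactly the classical diffusion-limited form, and as ``y -> 0`` it tends
  to the size-independent (constant) kernel;
* daughter distribution ``b(v | eps)`` -- the density of fragment volumes
  ``v`` produced when a parent of volume ``eps`` breaks.

The daughter distribution is self-similar: with ``xi = v / eps`` it reduces
to a function ``theta(xi)`` that is ``p`` times a Beta(a, b) density with

    a = c + 1,        b = (c + 1) * (p - 1),

so its number integral is exactly ``p`` (mean daughter count) and its mass
integral is exactly ``eps``.  The shape parameter ``c`` classifies the
breakage regime: ``c < 0`` means abrasion/erosion (fine debris dominates),
``c = 0`` uniform random breakage, and ``c > 1`` an interior-mode fragment
size typical of efficient, uniform milling.

All powers are evaluated in log space with an explicit overflow guard;
saturating silently would corrupt downstream parameter fits.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import betainc, gammaln

from .exceptions import KernelOverflowError, NanomillError

__all__ = [
    "PBMParams",
    "breakage_rate",
    "agglomeration_rate",
    "daughter_density",
    "theta_self_similar",
    "daughter_number_fraction",
    "daughter_mass_fraction",
]

#: |exponent * log v| beyond this would overflow float64 (exp(709) ~ 1e308).
_LOG_OVERFLOW = 700.0

#: Canonical parameter order used throughout estimation and I/O.
PARAM_NAMES = ("K1", "mu", "K2", "y1", "y2", "c", "p")


@dataclass(frozen=True)
class PBMParams:
    """The seven kernel parameters of the population balance model.

    Attributes
    ----------
    K1 : breakage frequency constant (per minute, nondimensional volume scale)
    mu : breakage power factor
    K2 : agglomeration frequency constant (normalized-concentration scale)
    y1, y2 : agglomeration power factors (positive)
    c : daughter-distribution shape parameter (> -1)
    p : mean number of daughter particles per breakage event (>= 1)
    """

    K1: float
    mu: float
    K2: float
    y1: float
    y2: float
    c: float
    p: float

    def __post_init__(self) -> None:
        if self.K1 < 0 or self.K2 < 0:
            raise NanomillError("K1 and K2 must be nonnegative")
        if self.y1 <= 0 or self.y2 <= 0:
            raise NanomillError("y1 and y2 must be positive")
        if self.p < 1:
            raise NanomillError("p (mean daughter count) must be >= 1")
        if self.c <= -1:
            raise NanomillError("c must exceed -1")
        # Integrability of the daughter density at xi -> 1 requires the
        # second Beta shape parameter (c+1)(p-1) to be positive.
        if self.c + (self.c + 1.0) * (self.p - 2.0) <= -1.0:
            raise NanomillError(
                "daughter density not integrable: need c + (c+1)(p-2) > -1"
            )

    def replace(self, **kw) -> "PBMParams":
        return replace(self, **kw)

    def as_dict(self) -> dict:
        return {name: float(getattr(self, name)) for name in PARAM_NAMES}

    # Beta-density shape parameters of theta(xi) / p.
    @property
    def _beta_a(self) -> float:
        return self.c + 1.0

    @property
    def _beta_b(self) -> float:
        return (self.c + 1.0) * (self.p - 1.0)


def _guarded_pow(v, exponent: float):
    """``v**exponent`` via exp(exponent * log v), raising on overflow."""
    logv = np.log(np.asarray(v, dtype=float))
    arg = exponent * logv
    bad = np.abs(arg) > _LOG_OVERFLOW
    if np.any(bad):
        worst = float(np.max(np.abs(arg)))
        raise KernelOverflowError(
            f"kernel power overflow: |exponent*log v| = {worst:.1f} > {_LOG_OVERFLOW}"
        )
    return np.exp(arg)


def breakage_rate(v, params: PBMParams):
    """Power-law breakage rate ``a(v) = K1 * v**mu`` (per minute)."""
    v = np.asarray(v, dtype=float)
    if np.any(v <= 0):
        raise NanomillError("breakage_rate needs v > 0")
    if params.K1 == 0.0:
        return np.zeros_like(v) if v.ndim else 0.0
    out = params.K1 * _guarded_pow(v, params.mu)
    return out if v.ndim else float(out)


def agglomeration_rate(v1, v2, params: PBMParams, symmetrize: bool = False):
    """Diffusion-limited agglomeration rate kernel.

    ``beta = K2 * (v1**y1 + v2**y2) * (v1**(-y1) + v2**(-y2))``.

    The power factors y1, y2 are the kernel exponents: 1/3 recovers the
    classical Brownian kernel, 0 the constant kernel.  (Exponents of order
    1/y with the fitted y values near 0.1 would make the cross terms
    ``(v1/v2)**(1/y)`` astronomically large for any realistic size span and
    the model unintegrable, so the fitted values are necessarily the
    exponents themselves.)

    With ``y1 != y2`` the expression depends on argument order; the discrete
    double sum over ordered particle pairs supplies the effective
    symmetrization, so by default the kernel is evaluated exactly as
    written.  ``symmetrize=True`` averages both argument orders instead.
    """
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    if np.any(v1 <= 0) or np.any(v2 <= 0):
        raise NanomillError("agglomeration_rate needs positive volumes")
    if params.K2 == 0.0:
        out = np.zeros(np.broadcast(v1, v2).shape)
        return out if out.ndim else 0.0
    s1, s2 = params.y1, params.y2
    beta = params.K2 * (
        (_guarded_pow(v1, s1) + _guarded_pow(v2, s2))
        * (_guarded_pow(v1, -s1) + _guarded_pow(v2, -s2))
    )
    if symmetrize:
        beta2 = params.K2 * (
            (_guarded_pow(v2, s1) + _guarded_pow(v1, s2))
            * (_guarded_pow(v2, -s1) + _guarded_pow(v1, -s2))
        )
        beta = 0.5 * (beta + beta2)
    return beta if beta.ndim else float(beta)


def theta_self_similar(xi, params: PBMParams):
    """Self-similar daughter distribution ``theta(xi)``, ``xi = v/eps``.

    theta(xi) = p * xi**c * (1-xi)**(c+(c+1)(p-2))
                * Gamma(c+(c+1)(p-1)+1) / (Gamma(c+1) * Gamma(c+(c+1)(p-2)+1))

    which is ``p`` times the Beta(c+1, (c+1)(p-1)) probability density, so
    that the number integral over (0, 1) is ``p`` and the mass integral
    ``int xi*theta dxi`` is 1.
    """
    xi = np.asarray(xi, dtype=float)
    if np.any(xi <= 0) or np.any(xi >= 1):
        raise NanomillError("theta_self_similar needs xi strictly in (0, 1)")
    a, b = params._beta_a, params._beta_b
    log_theta = (
        np.log(params.p)
        + (a - 1.0) * np.log(xi)
        + (b - 1.0) * np.log1p(-xi)
        + gammaln(a + b)
        - gammaln(a)
        - gammaln(b)
    )
    out = np.exp(log_theta)
    return out if out.ndim else float(out)


def daughter_density(v, eps, params: PBMParams):
    """Fragment-volume density ``b(v | eps) = theta(v/eps) / eps``.

    Number conservation: ``int_0^eps b dv = p``.
    Mass conservation:   ``int_0^eps v b dv = eps``.
    Both hold exactly by the Beta-function normalization of theta.
    """
    v = np.asarray(v, dtype=float)
    eps = np.asarray(eps, dtype=float)
    if np.any(eps <= 0):
        raise NanomillError("parent volume eps must be positive")
    if np.any(v >= eps) or np.any(v <= 0):
        raise NanomillError("fragment volume must satisfy 0 < v < eps")
    out = theta_self_similar(v / eps, params) / eps
    return out if out.ndim else float(out)


def daughter_number_fraction(xi, params: PBMParams):
    """``int_0^xi theta dxi' / p``: fraction of daughter *count* below xi.

    Closed form: the regularized incomplete beta I(xi; a, b).
    """
    return betainc(params._beta_a, params._beta_b, np.clip(xi, 0.0, 1.0))


def daughter_mass_fraction(xi, params: PBMParams):
    """``int_0^xi xi' theta dxi'``: fraction of parent *mass* below xi.

    Closed form: I(xi; a+1, b), using p*a/(a+b) = 1.
    """
    return betainc(params._beta_a + 1.0, params._beta_b, np.clip(xi, 0.0, 1.0))
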