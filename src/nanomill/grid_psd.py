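"""Size coordinate system and particle-size-distribution conversions.

All internal computation lives on a geometric grid of *dimensionless*
particle volumes.  Laser-diffraction instruments report volume percent per
diameter bin; particles are treated as equivalent spheres, so a diameter
``d`` (nm) maps to the volume ``v = (pi/6) d**3`` which is then divided by
the volume of a reference diameter ``d_ref`` to keep the extreme power-law
exponents of the rate kernels numerically tame.  Because the pi/6 factor
cancels in the ratio, the dimensionless volume of a particle is simply
``(d / d_ref)**3``.

Module contents:

* :class:`SizeGrid` -- geometric volume grid (edges + pivots).
* :class:`ParticleState` -- per-bin number concentrations at one time.
* :class:`PSDRecord` -- instrument-style volume-percent curve at one time.
* :func:`build_grid`, :func:`psd_to_state`, :func:`state_to_psd`,
  :func:`percentiles`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import GridError, PSDError

__all__ = [
    "SizeGrid",
    "ParticleState",
    "PSDRecord",
    "build_grid",
    "psd_to_state",
    "state_to_psd",
    "percentiles",
    "diameter_to_volume",
    "volume_to_diameter",
]

#: Hard cap on grid size; geometric grids beyond this are almost certainly
#: a unit mistake (nm vs um) rather than a deliberate choice.
MAX_BINS = 10_000

#: Relative tolerance for clipping small negative number concentrations
#: produced by the ODE integrator.
NEG_CLIP_RTOL = 1e-8


def diameter_to_volume(d_nm, d_ref_nm: float):
    """Sphere-equivalent dimensionless volume of diameter ``d_nm`` (nm).

    ``v = (pi/6) d^3`` nondimensionalized by ``(pi/6) d_ref^3``.
    """
    d = np.asarray(d_nm, dtype=float)
    return ((math.pi / 6.0) * d**3) / ((math.pi / 6.0) * d_ref_nm**3)


def volume_to_diameter(v, d_ref_nm: float):
    """Inverse of :func:`diameter_to_volume`; returns nm."""
    return np.cbrt(np.asarray(v, dtype=float)) * d_ref_nm


@dataclass(frozen=True)
class SizeGrid:
    """Geometric grid of dimensionless particle volumes.

    Attributes
    ----------
    edges : ndarray, shape (M+1,)
        Strictly increasing bin edges ``v_0 < ... < v_M``.
    pivots : ndarray, shape (M,)
        Representative volume per bin (geometric bin centers),
        ``v_i <= x_i <= v_{i+1}``.
    ratio : float
        Constant geometric factor ``r`` with ``v_{i+1} = r * v_i``.
    d_ref : float
        Reference diameter in nm used for nondimensionalization.
    """

    edges: np.ndarray
    pivots: np.ndarray
    ratio: float
    d_ref: float

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges, dtype=float)
        pivots = np.asarray(self.pivots, dtype=float)
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "pivots", pivots)
        if edges.ndim != 1 or edges.size < 2:
            raise GridError("grid needs at least one bin (two edges)")
        if np.any(np.diff(edges) <= 0):
            raise GridError("grid edges must be strictly increasing")
        ratios = edges[1:] / edges[:-1]
        if np.any(np.abs(ratios / self.ratio - 1.0) > 1e-12):
            raise GridError("grid edge ratio is not constant")
        if self.ratio <= 1.0:
            raise GridError("geometric ratio must exceed 1")
        if pivots.size != edges.size - 1:
            raise GridError("pivot count must equal bin count")
        if np.any(pivots < edges[:-1]) or np.any(pivots > edges[1:]):
            raise GridError("pivots must lie inside their bins")

    @property
    def n_bins(self) -> int:
        return self.pivots.size

    @property
    def d_edges_nm(self) -> np.ndarray:
        """Bin edges as sphere-equivalent diameters in nm."""
        return volume_to_diameter(self.edges, self.d_ref)

    @property
    def pivot_diameters_nm(self) -> np.ndarray:
        return volume_to_diameter(self.pivots, self.d_ref)


@dataclass
class ParticleState:
    """Number concentrations per grid bin at one time point.

    ``N[i]`` is the number of particles per unit suspension volume in bin i,
    on the normalized scale where the total particle volume fraction
    ``sum(x_i * N_i)`` is 1 at t = 0 for a freshly converted PSD.
    """

    time: float
    N: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        N = np.asarray(self.N, dtype=float).copy()
        if N.ndim != 1:
            raise PSDError("N must be a 1-D vector")
        scale = float(N.max(initial=0.0))
        tol = NEG_CLIP_RTOL * max(scale, 1.0)
        if np.any(N < -tol):
            raise PSDError(
                f"negative number concentration beyond tolerance: min={N.min():g}"
            )
        np.clip(N, 0.0, None, out=N)
        self.N = N

    def total_volume(self, grid: SizeGrid) -> float:
        """Total dimensionless particle volume ``sum x_i N_i``."""
        return float(np.dot(grid.pivots, self.N))

    def total_number(self) -> float:
        return float(self.N.sum())


@dataclass
class PSDRecord:
    """Instrument-style volume-percent-per-diameter-bin curve at one time.

    ``d_edges`` are in micrometres (ascending); ``vol_pct`` holds one value
    per bin and sums to 100 within 0.1.
    """

    time: float
    d_edges: np.ndarray
    vol_pct: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d_edges, dtype=float)
        v = np.asarray(self.vol_pct, dtype=float)
        if d.ndim != 1 or v.ndim != 1 or v.size != d.size - 1:
            raise PSDError("need len(vol_pct) == len(d_edges) - 1")
        if np.any(d <= 0) or np.any(np.diff(d) <= 0):
            raise PSDError("diameter edges must be positive and ascending")
        if np.any(v < 0):
            raise PSDError("volume percents must be nonnegative")
        total = float(v.sum())
        if abs(total - 100.0) > 0.1:
            raise PSDError(f"volume percents sum to {total:.4f}, expected 100 +/- 0.1")
        self.d_edges = d
        self.vol_pct = v

    @property
    def d_edges_nm(self) -> np.ndarray:
        return self.d_edges * 1e3


def build_grid(
    d_min: float, d_max: float, bins_per_doubling: int, d_ref: float
) -> SizeGrid:
    """Build a geometric volume grid covering diameters [d_min, d_max] nm.

    The grid ratio is ``r = 2**(1/q)`` in *volume* space with
    ``q = bins_per_doubling``, so one doubling of diameter spans ``3 q``
    bins (``v`` scales as ``d**3``).  The upper edge is rounded up to a
    whole number of bins, so the covered span may slightly exceed
    ``d_max``.  Pivots sit at geometric bin centers.
    """
    if d_min <= 0 or d_max <= 0 or d_ref <= 0:
        raise GridError("diameters must be positive")
    if d_min >= d_max:
        raise GridError("d_min must be smaller than d_max")
    q = int(bins_per_doubling)
    if q < 1:
        raise GridError("bins_per_doubling must be >= 1")
    v_lo = float(diameter_to_volume(d_min, d_ref))
    v_hi = float(diameter_to_volume(d_max, d_ref))
    # Small slack so exact integer spans (e.g. one diameter doubling) do not
    # pick up a spurious extra bin from floating-point noise.
    n_bins = int(math.ceil(q * math.log2(v_hi / v_lo) - 1e-9))
    n_bins = max(n_bins, 1)
    if n_bins > MAX_BINS:
        raise GridError(f"grid would need {n_bins} bins (limit {MAX_BINS})")
    ratio = 2.0 ** (1.0 / q)
    edges = v_lo * ratio ** np.arange(n_bins + 1)
    pivots = np.sqrt(edges[:-1] * edges[1:])
    return SizeGrid(edges=edges, pivots=pivots, ratio=ratio, d_ref=d_ref)


def _overlap_matrix(src_edges_log: np.ndarray, dst_edges_log: np.ndarray) -> np.ndarray:
    """Fraction of each source interval overlapping each destination interval.

    Works in log-diameter so the split is scale-free.  Returns shape
    ``(n_src, n_dst)``; rows sum to <= 1 (equal to 1 when the destination
    grid covers the source interval).
    """
    lo = np.maximum(src_edges_log[:-1, None], dst_edges_log[None, :-1])
    hi = np.minimum(src_edges_log[1:, None], dst_edges_log[None, 1:])
    width = src_edges_log[1:] - src_edges_log[:-1]
    return np.clip(hi - lo, 0.0, None) / width[:, None]


def rebin_volume(
    vol: np.ndarray, src_d_edges_nm: np.ndarray, dst_d_edges_nm: np.ndarray
) -> tuple[np.ndarray, float]:
    """Reallocate per-bin volume onto new diameter edges.

    Allocation is proportional to interval overlap in log-diameter, which
    conserves mass and is deterministic.  Returns ``(dst_vol, lost)`` where
    ``lost`` is the volume falling outside the destination span.
    """
    src_log = np.log(np.asarray(src_d_edges_nm, dtype=float))
    dst_log = np.log(np.asarray(dst_d_edges_nm, dtype=float))
    frac = _overlap_matrix(src_log, dst_log)
    vol = np.asarray(vol, dtype=float)
    dst = frac.T @ vol
    lost = float(vol.sum() - dst.sum())
    return dst, lost


def psd_to_state(
    psd: PSDRecord, grid: SizeGrid, total_volume_fraction: float = 1.0
) -> ParticleState:
    """Convert an instrument volume-percent curve to number concentrations.

    The volume in each instrument bin is reallocated onto the grid bins
    proportionally to overlap in log-diameter, then divided by the pivot
    volume: ``N_i = V_i / x_i``.  Total volume is conserved to 1e-9
    relative; mass outside the grid span is an error.
    """
    total = float(psd.vol_pct.sum())
    if total <= 0:
        raise PSDError("empty distribution: all volume percents are zero")
    vol = psd.vol_pct / 100.0 * total_volume_fraction
    dst, lost = rebin_volume(vol, psd.d_edges_nm, grid.d_edges_nm)
    if abs(lost) > 1e-9 * vol.sum():
        raise GridError(
            f"PSD extends outside the grid span; lost volume fraction {lost:.3e}"
        )
    N = dst / grid.pivots
    state = ParticleState(time=psd.time, N=N)
    v_in = vol.sum()
    if abs(state.total_volume(grid) - v_in) > 1e-9 * v_in:
        raise GridError("volume not conserved during rebinning")  # pragma: no cover
    return state


def state_to_psd(state: ParticleState, grid: SizeGrid) -> PSDRecord:
    """Convert number concentrations back to a volume-percent curve.

    ``vol_pct_i = 100 x_i N_i / sum_j x_j N_j`` on the grid's own diameter
    edges (reported in micrometres).
    """
    vol = grid.pivots * state.N
    total = vol.sum()
    if total <= 0:
        raise PSDError("cannot express an all-zero state as a PSD")
    return PSDRecord(
        time=state.time,
        d_edges=grid.d_edges_nm / 1e3,
        vol_pct=100.0 * vol / total,
    )


def percentiles(psd: PSDRecord, probs) -> np.ndarray:
    """Cumulative-volume percentile diameters (nm), e.g. D10/D50/D90.

    Linear interpolation of cumulative volume percent against log10
    diameter, the convention of laser-diffraction size analysis.  ``probs``
    are fractions in (0, 1); the result is monotone in ``prob``.
    """
    probs = np.atleast_1d(np.asarray(probs, dtype=float))
    if np.any(probs <= 0) or np.any(probs >= 1):
        raise PSDError("percentile probabilities must lie strictly in (0, 1)")
    cum = np.concatenate([[0.0], np.cumsum(psd.vol_pct)])
    cum = cum / cum[-1] * 100.0
    logd = np.log10(psd.d_edges_nm)
    return 10.0 ** np.interp(probs * 100.0, cum, logd)


def d50(psd: PSDRecord) -> float:
    """Median (D50) diameter in nm."""
    return float(percentiles(psd, [0.5])[0])


def volume_weighted_mean_diameter(psd: PSDRecord) -> float:
    """Volume-weighted mean diameter (nm), bins taken at geometric centers.

    The default reference diameter for nondimensionalization: it keeps the
    dimensionless volumes of a typical suspension near 1.
    """
    d_mid = np.sqrt(psd.d_edges_nm[:-1] * psd.d_edges_nm[1:])
    return float(np.dot(psd.vol_pct, d_mid) / psd.vol_pct.sum())
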