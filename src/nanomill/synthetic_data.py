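"""Synthetic inputs with the statistical structure of a milling study.

No raw instrument exports accompany the study this package models, so every
pipeline stage is exercised on generated data:

* an initial PSD built from a two-mode lognormal volume mixture -- raw drug
  suspensions are bimodal at the start of wet grinding (coarse primary
  particles plus a finer fraction), and the default mixture is anchored so
  its D50 is ~14.2 um, the measured starting median;
* PSD time series produced by the package's own population balance
  simulator, with seeded multiplicative lognormal noise on the volume
  percents (laser-diffraction repeatability is relative), renormalized to
  100%;
* D50(t) decay curves from the nth-order comminution law at log-spaced
  times (the early transient is fast);
* absorbance pairs for the scavenging assay, defaulting to the measured
  blank/sample values of the milled-suspension study.

Every generator is bit-deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .exceptions import NanomillError
from .assay import AssaySample
from .grid_psd import PSDRecord, SizeGrid, psd_to_state, state_to_psd
from .kernels import PBMParams
from .kinetics import KineticsParams, d50_model
from .solver import simulate

__all__ = [
    "LognormalMode",
    "SynthScenario",
    "default_scenario",
    "reference_diameter",
    "gen_initial_psd",
    "gen_psd_series",
    "gen_kinetics_series",
    "gen_assay_data",
]


@dataclass(frozen=True)
class LognormalMode:
    """One lognormal mode of the initial volume-weighted diameter mixture."""

    median_nm: float
    gsd: float      # geometric standard deviation, > 1
    weight: float   # volume-fraction weight

    def __post_init__(self) -> None:
        if self.median_nm <= 0 or self.gsd <= 1 or self.weight < 0:
            raise NanomillError("invalid lognormal mode")


# Defaults: PBM truth = 3000 rpm kernel fit; kinetics truth = 3500 rpm
# nth-order fit with the measured starting median 14.2 um; assay truth =
# the measured blank and per-time absorbances.
_DEFAULT_MODES = (
    LognormalMode(median_nm=1_500.0, gsd=1.6, weight=0.35),
    LognormalMode(median_nm=19_000.0, gsd=1.5, weight=0.65),
)
_DEFAULT_PBM = PBMParams(K1=26.701, mu=1.0, K2=23.900, y1=0.129, y2=0.147, c=2.807, p=2.789)
_DEFAULT_KINETICS = KineticsParams(dlim=213.0, k=0.738, n=2.911, d50_0=14_200.0)
_DEFAULT_A0 = 1.508
_DEFAULT_AX = (1.164, 0.822, 0.556, 0.503)
_DEFAULT_ASSAY_LABELS = ("0 min", "10 min", "30 min", "60 min")


@dataclass
class SynthScenario:
    """Everything needed to generate one synthetic study's inputs."""

    seed: int = 0
    modes: tuple = _DEFAULT_MODES
    pbm: PBMParams = _DEFAULT_PBM
    sample_times: tuple = (0.0, 10.0, 30.0, 60.0)
    noise_sd: float = 0.02
    kinetics: KineticsParams = _DEFAULT_KINETICS
    assay_a0: float = _DEFAULT_A0
    assay_ax: tuple = _DEFAULT_AX
    assay_labels: tuple = _DEFAULT_ASSAY_LABELS

    def __post_init__(self) -> None:
        w = sum(m.weight for m in self.modes)
        if abs(w - 1.0) > 1e-9:
            raise NanomillError(f"mode weights sum to {w}, expected 1")
        if self.noise_sd < 0:
            raise NanomillError("noise sd must be nonnegative")
        t = np.asarray(self.sample_times, dtype=float)
        if t[0] != 0.0 or np.any(np.diff(t) <= 0):
            raise NanomillError("sample times must ascend from 0")


def default_scenario(seed: int = 0, **overrides) -> SynthScenario:
    return SynthScenario(seed=seed, **overrides)


def reference_diameter(scenario: SynthScenario) -> float:
    """Volume-weighted mean diameter (nm) of the initial mixture.

    The analytic counterpart of
    :func:`nanomill.grid_psd.volume_weighted_mean_diameter`:
    ``sum_m w_m * median_m * exp(ln(gsd_m)^2 / 2)``.  Used as the default
    nondimensionalization reference, so typical dimensionless volumes are
    near 1.
    """
    return float(
        sum(
            m.weight * m.median_nm * np.exp(0.5 * np.log(m.gsd) ** 2)
            for m in scenario.modes
        )
    )


def _mixture_cdf(d_nm: np.ndarray, modes) -> np.ndarray:
    """Volume-weighted mixture CDF of lognormal diameter modes."""
    F = np.zeros_like(np.asarray(d_nm, dtype=float))
    for m in modes:
        F = F + m.weight * norm.cdf(np.log(d_nm / m.median_nm) / np.log(m.gsd))
    return F


def gen_initial_psd(scenario: SynthScenario, grid: SizeGrid) -> PSDRecord:
    """Initial (t = 0) volume-percent curve of the lognormal mixture.

    The analytic mixture CDF is differenced across the grid's diameter
    edges; the modes must lie essentially inside the grid span (at most
    1e-6 of the mixture volume may fall outside).  Deterministic.
    """
    d_edges = grid.d_edges_nm
    F = _mixture_cdf(d_edges, scenario.modes)
    outside = F[0] + (1.0 - F[-1])
    if outside > 1e-4:
        raise NanomillError(
            f"mixture modes extend outside the grid span (missing {outside:.2e})"
        )
    vol = np.diff(F)
    return PSDRecord(time=0.0, d_edges=d_edges / 1e3, vol_pct=100.0 * vol / vol.sum())


def _apply_noise(records, noise_sd: float, rng: np.random.Generator):
    out = []
    for rec in records:
        v = rec.vol_pct.copy()
        if noise_sd > 0:
            v = v * np.exp(rng.normal(0.0, noise_sd, size=v.size))
        out.append(
            PSDRecord(time=rec.time, d_edges=rec.d_edges, vol_pct=100.0 * v / v.sum())
        )
    return out


def gen_psd_series(scenario: SynthScenario, grid: SizeGrid) -> list[PSDRecord]:
    """PSD records at the scenario's sample times.

    Forward-simulates the scenario's kernel parameters from the initial
    mixture, converts each state to a volume-percent curve, then applies
    seeded multiplicative lognormal noise and renormalizes to 100%.  With
    ``noise_sd = 0`` the output is exactly the simulator's.
    """
    psd0 = gen_initial_psd(scenario, grid)
    initial = psd_to_state(psd0, grid)
    result = simulate(initial, grid, scenario.pbm, scenario.sample_times)
    clean = [state_to_psd(s, grid) for s in result.states]
    rng = np.random.default_rng(scenario.seed)
    return _apply_noise(clean, scenario.noise_sd, rng)


def gen_kinetics_series(
    scenario: SynthScenario,
    times=None,
    n_times: int = 25,
    t_min: float = 1e-3,
    t_max: float = 60.0,
):
    """(times, D50) samples of the nth-order comminution law.

    Times default to ``n_times`` log-spaced points in [t_min, t_max]
    minutes; multiplicative lognormal noise with the scenario's sd is
    applied (``noise_sd = 0`` gives exact model values).
    """
    if times is None:
        times = np.logspace(np.log10(t_min), np.log10(t_max), n_times)
    times = np.asarray(times, dtype=float)
    if np.unique(times).size != times.size:
        raise NanomillError("kinetics sample times must be distinct")
    d50s = np.asarray(d50_model(times, scenario.kinetics), dtype=float)
    if scenario.noise_sd > 0:
        rng = np.random.default_rng(scenario.seed)
        d50s = d50s * np.exp(rng.normal(0.0, scenario.noise_sd, size=d50s.size))
    return times, d50s


def gen_assay_data(scenario: SynthScenario) -> list[AssaySample]:
    """Absorbance pairs for the scavenging assay (defaults: measured values)."""
    if len(scenario.assay_ax) != len(scenario.assay_labels):
        raise NanomillError("one label per absorbance value required")
    return [
        AssaySample(label=lab, a0=scenario.assay_a0, ax=ax)
        for lab, ax in zip(scenario.assay_labels, scenario.assay_ax)
    ]
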