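"""Shared fixtures: fitted parameter sets and small reference grids."""

import numpy as np
import pytest

import nanomill as nm

# Fitted kernel parameter sets per grinding speed (rpm):
# (K1, mu, K2, y1, y2, c, p)
KERNEL_FITS = {
    2000: (13.421, 0.0, 26.760, 0.275, 0.273, -0.541, 3.464),
    2500: (15.892, 0.0, 13.235, 0.164, 0.137, 0.146, 2.35),
    3000: (26.701, 1.0, 23.900, 0.129, 0.147, 2.807, 2.789),
    3500: (35.864, 0.042, 52.089, 0.0112, 0.0132, 2.646, 3.102),
}

# Fitted comminution kinetics per grinding speed: (Dlim nm, k, n)
KINETICS_FITS = {
    2000: (292.0, 0.347, 2.615),
    2500: (241.0, 0.434, 2.744),
    3000: (245.0, 0.706, 2.661),
    3500: (213.0, 0.738, 2.911),
}

D50_INITIAL_NM = 14_200.0

# Measured absorbances: blank plus milled-suspension samples at 0/10/30/60 min.
ASSAY_A0 = 1.508
ASSAY_AX = {"0 min": 1.164, "10 min": 0.822, "30 min": 0.556, "60 min": 0.503}


def pbm_params(rpm: int) -> nm.PBMParams:
    return nm.PBMParams(*KERNEL_FITS[rpm])


def kinetics_params(rpm: int) -> nm.KineticsParams:
    dlim, k, n = KINETICS_FITS[rpm]
    return nm.KineticsParams(dlim=dlim, k=k, n=n, d50_0=D50_INITIAL_NM)


def count_peaks(vol_pct, floor: float = 0.05) -> int:
    """Local maxima of a volume-percent curve above a noise floor."""
    v = np.asarray(vol_pct)
    interior = (v[1:-1] > v[:-2]) & (v[1:-1] >= v[2:]) & (v[1:-1] > floor)
    return int(np.sum(interior))


@pytest.fixture(scope="session")
def scenario():
    """Default noiseless synthetic study."""
    return nm.default_scenario(noise_sd=0.0)


@pytest.fixture(scope="session")
def d_ref(scenario):
    return nm.reference_diameter(scenario)


@pytest.fixture(scope="session")
def production_grid(d_ref):
    """120-bin grid spanning 10 nm - 100 um at 3 bins per volume doubling."""
    return nm.build_grid(10.0, 100_000.0, 3, d_ref)


@pytest.fixture(scope="session")
def estimation_grid(d_ref):
    """30-bin coarse grid (one bin per volume doubling) for inverse problems."""
    return nm.build_grid(100.0, 100_000.0, 1, d_ref)
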