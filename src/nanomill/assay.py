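"""Hydroxyl-radical scavenging-rate statistic for absorbance readings.

The salicylic-acid assay quantifies antioxidant activity indirectly: the
chromogenic product of salicylic acid and hydroxyl radicals absorbs near
510 nm, and a scavenger lowers that absorbance.  The scavenging rate is

    E% = (A0 - Ax) / A0 * 100

where A0 is the blank absorbance and Ax the absorbance after adding the
sample.  E% is scale-invariant in the absorbances and strictly decreasing
in Ax.  A negative E% (Ax > A0, a pro-oxidant reading) is physically
meaningful and is flagged with a warning rather than rejected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .exceptions import NanomillError

__all__ = ["AssaySample", "scavenging_rate", "scavenging_table"]


@dataclass(frozen=True)
class AssaySample:
    """One absorbance pair: blank A0 and sample Ax."""

    label: str
    a0: float
    ax: float

    def __post_init__(self) -> None:
        if self.a0 <= 0:
            raise NanomillError("blank absorbance A0 must be positive")
        if self.ax < 0:
            raise NanomillError("sample absorbance Ax must be nonnegative")


def scavenging_rate(sample: AssaySample) -> float:
    """Scavenging rate E% = (A0 - Ax)/A0 * 100, full precision.

    Round only at the reporting boundary (tables print two decimals).
    """
    e = (sample.a0 - sample.ax) / sample.a0 * 100.0
    if e < 0:
        warnings.warn(
            f"sample {sample.label!r}: Ax > A0 gives negative E% "
            "(pro-oxidant reading)",
            stacklevel=2,
        )
    return e

def scavenging_table(samples: list[AssaySample]) -> pd.DataFrame:
    """Per-sample E% plus the ratio of each E% to the first sample's.

    The first sample is the reference (ratio exactly 1).  Columns:
    label, a0, ax, e_pct (full precision), e_pct_rounded (2 decimals),
    ratio_to_first.
    """
    if not samples:
        raise NanomillError("need at least one sample")
    rates = [scavenging_rate(s) for s in samples]
    if rates[0] == 0.0:
        raise NanomillError("reference sample has E% = 0; ratios undefined")
    return pd.DataFrame(
        {
            "label": [s.label for s in samples],
            "a0": [s.a0 for s in samples],
            "ax": [s.ax for s in samples],
            "e_pct": rates,
            "e_pct_rounded": [round(e, 2) for e in rates],
            "ratio_to_first": [e / rates[0] for e in rates],
        }
    )
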