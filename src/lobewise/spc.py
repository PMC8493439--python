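"""Symmetrized percent change (SPC) of cortical thickness.

For thickness T1, T2 (mm) measured an interval dt (years) apart,

    SPC = 100 * (T2 - T1) / (dt * 0.5 * (T1 + T2))      [% per year]

i.e. the annualized change normalized by the two-timepoint average thickness.
Dividing by the average rather than the baseline makes the measure
antisymmetric under swapping timepoints and bounds it by 200/dt in magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class ThicknessPair:
    """Per-vertex thickness at two timepoints with the inter-scan interval.

    Thickness is in mm and must be strictly positive at every vertex;
    ``interval_years`` must be positive.
    """

    t1: np.ndarray
    t2: np.ndarray
    interval_years: float

    def __post_init__(self) -> None:
        self.t1 = np.asarray(self.t1, dtype=float)
        self.t2 = np.asarray(self.t2, dtype=float)
        if self.t1.shape != self.t2.shape:
            raise ValueError("thickness fields have different shapes")
        if not (np.all(self.t1 > 0) and np.all(self.t2 > 0)):
            raise ValueError("thickness must be strictly positive everywhere")
        if not np.isfinite(self.interval_years) or self.interval_years <= 0:
            raise ValueError("inter-scan interval must be positive")


def symmetrized_percent_change(pair: ThicknessPair) -> np.ndarray:
    """Per-vertex symmetrized percent change in % per year."""
    avg = 0.5 * (pair.t1 + pair.t2)
    return 100.0 * (pair.t2 - pair.t1) / (pair.interval_years * avg)


def thickness_for_spc(
    t1: np.ndarray, spc: np.ndarray, interval_years: float
) -> np.ndarray:
    """Invert the SPC formula: the follow-up thickness that yields ``spc``.

    With s = spc * dt / 100, T2 = T1 * (1 + s/2) / (1 - s/2); requires |s| < 2
    (an SPC magnitude below the 200/dt bound).  Used by the cohort simulator
    to construct timepoint-2 maps with a known true change.
    """
    s = np.asarray(spc, dtype=float) * interval_years / 100.0
    if np.any(np.abs(s) >= 2):
        raise ValueError("requested SPC exceeds the attainable 200/dt bound")
    return np.asarray(t1, dtype=float) * (1 + s / 2) / (1 - s / 2)
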