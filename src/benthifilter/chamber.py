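"""Total sulfide fluxes from benthic chamber incubations.

A lander chamber encloses a known sediment area (651.4 cm2) and a measured
sediment-free water volume; six syringe samples are drawn over a 30–36 h
incubation.  The flux is the OLS slope of concentration against time
multiplied by the enclosed water height (volume/area).  A flux is reported
as below detection ("bdl") when every sample is censored, or when the
slope is statistically indistinguishable from zero (two-sided t-test at
alpha = 0.05 on four or more quantified samples).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .fluxes import FluxEstimate

__all__ = ["ChamberIncubation", "chamber_flux", "deployment_report", "DEFAULT_CHAMBER_AREA_M2"]

DEFAULT_CHAMBER_AREA_M2 = 651.4e-4  # 28.8 cm internal diameter

BDL_ALPHA = 0.05


@dataclass
class ChamberIncubation:
    """One chamber's concentration time series."""

    deployment: str
    chamber: str
    water_depth: float  # m
    times_h: np.ndarray
    conc_uM: np.ndarray
    censored: np.ndarray | None = None  # True where below detection
    chamber_area_m2: float = DEFAULT_CHAMBER_AREA_M2
    enclosed_height_m: float = 0.15  # sediment-free volume / area

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.conc_uM = np.asarray(self.conc_uM, dtype=float)
        if self.times_h.shape != self.conc_uM.shape:
            raise ValueError("times/concentrations length mismatch")
        if np.any(np.diff(self.times_h) <= 0):
            raise ValueError("sampling times must be strictly increasing")
        if self.censored is None:
            self.censored = np.zeros_like(self.conc_uM, dtype=bool)
        self.censored = np.asarray(self.censored, dtype=bool)
        if self.chamber_area_m2 <= 0:
            raise ValueError("chamber area must be positive")
        if self.enclosed_height_m <= 0:
            raise ValueError("enclosed height must be positive")

    @property
    def duration_h(self) -> float:
        return float(self.times_h[-1] - self.times_h[0])


def chamber_flux(inc: ChamberIncubation) -> Optional[FluxEstimate]:
    """Flux (mmol m-2 day-1) from one incubation, or None for "bdl".

    flux = slope(conc vs time, mmol m-3 day-1) x enclosed height (m);
    positive = release from the sediment into the chamber water.
    """
    quantified = ~inc.censored
    n = int(quantified.sum())
    if np.all(inc.censored):
        return None
    if n < 2:
        raise ValueError(
            f"{inc.deployment}/{inc.chamber}: need >=2 quantified samples, got {n}"
        )
    t = inc.times_h[quantified]
    c = inc.conc_uM[quantified]
    res = stats.linregress(t, c)
    if res.slope == 0:
        return None
    if n >= 4:
        # two-sided slope t-test against zero
        if res.stderr == 0:
            p = 0.0
        else:
            tstat = res.slope / res.stderr
            p = 2.0 * stats.t.sf(abs(tstat), df=n - 2)
        if p >= BDL_ALPHA:
            return None
    slope_per_day = res.slope * 24.0  # mmol m-3 day-1
    se_per_day = (res.stderr if np.isfinite(res.stderr) else 0.0) * 24.0
    return FluxEstimate(
        analyte="tH2S",
        value=slope_per_day * inc.enclosed_height_m,
        two_se=2.0 * se_per_day * inc.enclosed_height_m,
        depth_window=None,
        station=inc.deployment,
    )


def deployment_report(incubations: Iterable[ChamberIncubation]) -> pd.DataFrame:
    """One row per chamber, paired chambers grouped by deployment."""
    rows = []
    for inc in incubations:
        est = chamber_flux(inc)
        rows.append(
            {
                "deployment": inc.deployment,
                "chamber": inc.chamber,
                "water_depth_m": inc.water_depth,
                "incubation_h": inc.duration_h,
                "flux_mmol_m2_day": est.value if est is not None else "bdl",
                "two_se": est.two_se if est is not None else "",
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=[
            "deployment",
            "chamber",
            "water_depth_m",
            "incubation_h",
            "flux_mmol_m2_day",
            "two_se",
        ],
    )
    return frame.sort_values(["deployment", "chamber"], ignore_index=True)
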