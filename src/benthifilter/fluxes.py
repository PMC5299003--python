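"""Diffusive flux estimation from porewater microprofiles.

The chain is the classical one for sediment porewater work: a free-solution
diffusion coefficient D for the analyte at in-situ salinity/temperature/
pressure, a tortuosity correction to the sediment diffusivity
Ds = D / (1 - 2 ln φ) (modified Weissberg relation), a least-squares
concentration gradient over a stated depth window, and Fick's first law

    J = φ(0) · Ds · dC/dz

With depth positive downward and 0 at the sediment–water interface, J as
computed here is positive when the flux is directed OUT of the sediment
(an efflux toward the bottom water) and negative for uptake; every output
carries this convention.  Uncertainty is reported as ±2 standard errors of
the fitted gradient (a 95% confidence interval).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .seawater import dynamic_viscosity

logger = logging.getLogger(__name__)

__all__ = [
    "DiffusionConstants",
    "PorewaterProfile",
    "FluxEstimate",
    "diffusion_coefficient",
    "sediment_diffusivity",
    "fit_gradient",
    "diffusive_flux",
    "station_flux_report",
    "DEFAULT_POROSITY",
    "DEFAULT_WINDOW_MM",
]

#: Surface porosity assumed for organic-rich mud when a station does not
#: provide one.  This is an assumption, not a measurement, and it is logged
#: whenever it is used.
DEFAULT_POROSITY = 0.9

#: Default gradient window: the top 0–5 mm of sediment.
DEFAULT_WINDOW_MM = (0.0, 5.0)

CM2_S_TO_M2_DAY = 8.64  # 1 cm2/s = 1e-4 m2/s * 86400 s/day

# Linear pure-water temperature fits for ionic species,
# D0 = (m0 + m1*t) * 1e-6 cm2/s with t in degC (Boudreau-style compilation).
_ION_FITS = {
    "HS-": (10.4, 0.273),
    "Fe2+": (3.31, 0.150),
    "Mn2+": (3.18, 0.155),
}

# LeBas molal volume at the normal boiling point, cm3/mol, for the
# Hayduk–Laudie correlation used for uncharged dissolved gases.
_LEBAS_VOLUME = {
    "H2S": 32.9,
}

_ALIASES = {
    "O2": "O2",
    "oxygen": "O2",
    "H2S": "H2S",
    "tH2S": "H2S",
    "sulfide": "H2S",
    "HS-": "HS-",
    "HS": "HS-",
    "Fe": "Fe2+",
    "Fe2+": "Fe2+",
    "Fe(II)": "Fe2+",
    "Mn": "Mn2+",
    "Mn2+": "Mn2+",
    "Mn(II)": "Mn2+",
}


@dataclass(frozen=True)
class DiffusionConstants:
    """Free-solution diffusion coefficient at stated ambient conditions."""

    analyte: str
    D_free: float  # m2 day-1
    salinity: float
    temperature: float  # degC
    pressure: float  # atm

    def __post_init__(self) -> None:
        if self.D_free <= 0:
            raise ValueError("D_free must be positive")


@dataclass
class FluxEstimate:
    """A diffusive (or chamber) flux with its 95% confidence half-width.

    ``value`` is in mmol m-2 day-1, positive = directed out of the sediment.
    """

    analyte: str
    value: float
    two_se: float
    depth_window: tuple[float, float] | None = None  # mm
    gradient: float | None = None  # mmol m-3 mm-1
    Ds: float | None = None  # m2 day-1
    station: str | None = None
    sign_convention: str = "positive = out of sediment"

    def __post_init__(self) -> None:
        if self.two_se < 0:
            raise ValueError("two_se must be non-negative")


@dataclass
class PorewaterProfile:
    """Depth-gridded analyte concentrations at one station.

    Depth is in mm, positive downward, 0 at the sediment–water interface;
    overlying-water points carry negative depths.  Concentrations are in
    μM (= mmol m-3) with a boolean censoring flag per point (True where the
    value is below the detection limit and reported at the DL).
    """

    station: str
    water_depth: float  # m
    depth_mm: np.ndarray
    concentrations: dict[str, np.ndarray]
    censored: dict[str, np.ndarray] = field(default_factory=dict)
    porosity_surface: float | None = None
    mat_layer: tuple[float, float] | None = None  # mm, ±0.5 mm registration

    def __post_init__(self) -> None:
        self.depth_mm = np.asarray(self.depth_mm, dtype=float)
        if self.depth_mm.ndim != 1:
            raise ValueError("depth_mm must be one-dimensional")
        if np.any(np.diff(self.depth_mm) <= 0):
            raise ValueError("depth_mm must be strictly increasing")
        for analyte, conc in self.concentrations.items():
            conc = np.asarray(conc, dtype=float)
            if conc.shape != self.depth_mm.shape:
                raise ValueError(f"{analyte}: concentration/depth length mismatch")
            self.concentrations[analyte] = conc
            flags = self.censored.get(analyte)
            if flags is None:
                flags = np.zeros_like(conc, dtype=bool)
            self.censored[analyte] = np.asarray(flags, dtype=bool)
        if self.porosity_surface is not None and not 0 < self.porosity_surface <= 1:
            raise ValueError("porosity must be in (0, 1]")

    @property
    def analytes(self) -> list[str]:
        return sorted(self.concentrations)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (depth_mm, analyte, conc_uM, censored)."""
        rows = []
        for analyte in self.analytes:
            rows.append(
                pd.DataFrame(
                    {
                        "depth_mm": self.depth_mm,
                        "analyte": analyte,
                        "conc_uM": self.concentrations[analyte],
                        "censored": self.censored[analyte],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def diffusion_coefficient(
    analyte: str,
    salinity: float,
    temperature: float,
    pressure: float = 1.0,
) -> DiffusionConstants:
    """Free-solution diffusion coefficient, m2 day-1, at ambient conditions.

    Boudreau-style formulation: uncharged gases from viscosity-based
    correlations (a dedicated fit for O2, Hayduk–Laudie for H2S), ionic
    species from linear pure-water temperature fits; a Stokes–Einstein
    viscosity ratio μ(0,t)/μ(S,t,P) rescales to in-situ salinity and
    pressure.  Following the convention of the standard aquatic-science
    toolbox, the gas correlations are evaluated at the in-situ viscosity
    before that rescaling is applied.

    At the brackish study conditions of the Baltic transect
    (S=12, 10 degC, 1 atm) this yields 1.36e-4 (O2), 1.03e-4 (H2S) and
    0.41e-4 (Fe2+) m2 day-1.
    """
    key = _ALIASES.get(analyte)
    if key is None:
        raise ValueError(f"no diffusion coefficient available for analyte {analyte!r}")
    mu_w = dynamic_viscosity(0.0, temperature, 1.0)
    mu_sw = dynamic_viscosity(salinity, temperature, pressure)
    stokes_einstein = mu_w / mu_sw
    t_kelvin = temperature + 273.15

    if key == "O2":
        d0 = (0.2604 + 0.006383 * t_kelvin / mu_sw) * 1e-5  # cm2/s
    elif key == "H2S":
        vb = _LEBAS_VOLUME["H2S"]
        d0 = 13.26e-5 / (mu_sw**1.14 * vb**0.589)
    else:
        m0, m1 = _ION_FITS[key]
        d0 = (m0 + m1 * temperature) * 1e-6
    d = d0 * stokes_einstein * CM2_S_TO_M2_DAY
    return DiffusionConstants(
        analyte=analyte,
        D_free=d,
        salinity=salinity,
        temperature=temperature,
        pressure=pressure,
    )


def sediment_diffusivity(D_free: float, porosity: float) -> float:
    """Tortuosity-corrected sediment diffusivity Ds = D / (1 - 2 ln φ)."""
    if not 0 < porosity <= 1:
        raise ValueError(f"porosity {porosity} outside (0, 1]")
    if D_free <= 0:
        raise ValueError("D_free must be positive")
    return D_free / (1.0 - 2.0 * math.log(porosity))


def fit_gradient(
    profile: PorewaterProfile,
    analyte: str,
    depth_window: tuple[float, float] = DEFAULT_WINDOW_MM,
    depth_unit: str = "mm",
) -> tuple[float, float]:
    """Least-squares concentration gradient over a closed depth window.

    Returns (slope, se_slope) in mmol m-3 mm-1.  Censored (below-detection)
    points are excluded with a logged warning; at least three uncensored
    points are required.  ``depth_unit`` states the unit of the window
    endpoints ("mm" or "m"); the profile grid itself is always in mm.
    """
    if analyte not in profile.concentrations:
        raise KeyError(f"profile has no analyte {analyte!r}")
    lo, hi = sorted(depth_window)
    if depth_unit == "m":
        lo, hi = lo * 1000.0, hi * 1000.0
    elif depth_unit != "mm":
        raise ValueError("depth_unit must be 'mm' or 'm'")
    z = profile.depth_mm
    in_window = (z >= lo) & (z <= hi)
    if not np.any(in_window):
        raise ValueError(f"window {depth_window} {depth_unit} outside profile grid")
    flags = profile.censored[analyte]
    n_censored = int(np.sum(in_window & flags))
    if n_censored:
        logger.warning(
            "%s/%s: excluding %d censored point(s) from gradient window %s",
            profile.station,
            analyte,
            n_censored,
            depth_window,
        )
    use = in_window & ~flags
    if int(use.sum()) < 3:
        raise ValueError(
            f"need >=3 uncensored points in window, got {int(use.sum())}"
        )
    zz = z[use]
    if np.ptp(zz) == 0:
        raise ValueError("zero depth variance in window")
    res = stats.linregress(zz, profile.concentrations[analyte][use])
    return float(res.slope), float(res.stderr)


def diffusive_flux(
    slope: float,
    se_slope: float,
    porosity: float,
    Ds: float,
    analyte: str = "H2S",
    depth_window: tuple[float, float] | None = None,
    station: str | None = None,
) -> FluxEstimate:
    """Fick's-law flux from a fitted gradient.

    ``slope`` and ``se_slope`` are in mmol m-3 mm-1 (as returned by
    :func:`fit_gradient`); the mm→m conversion happens here.  With depth
    positive downward, a concentration increasing into the sediment drives
    an efflux, reported positive.
    """
    if not 0 < porosity <= 1:
        raise ValueError(f"porosity {porosity} outside (0, 1]")
    for name, v in (("slope", slope), ("se_slope", se_slope), ("Ds", Ds)):
        if not math.isfinite(v):
            raise ValueError(f"{name} must be finite")
    slope_m = slope * 1000.0  # mmol m-4
    value = porosity * Ds * slope_m
    two_se = 2.0 * porosity * Ds * abs(se_slope) * 1000.0
    return FluxEstimate(
        analyte=analyte,
        value=value,
        two_se=two_se,
        depth_window=depth_window,
        gradient=slope,
        Ds=Ds,
        station=station,
    )


def station_flux_report(
    profiles: Iterable[PorewaterProfile],
    windows: Mapping[str, Mapping[str, tuple[float, float]]] | None = None,
    salinity: float = 12.0,
    temperature: float = 10.0,
    pressure: float = 1.0,
) -> pd.DataFrame:
    """Batch diffusive fluxes for a transect of profiles.

    ``windows`` maps station → analyte → (top_mm, bottom_mm); stations or
    analytes without an entry use the 0–5 mm surface default.  One row per
    (station, analyte, window), sorted by station then analyte.
    """
    windows = windows or {}
    rows = []
    for profile in profiles:
        porosity = profile.porosity_surface
        if porosity is None:
            porosity = DEFAULT_POROSITY
            logger.info(
                "station %s: assuming surface porosity %.2f (not measured)",
                profile.station,
                porosity,
            )
        station_windows = windows.get(profile.station, {})
        for analyte in profile.analytes:
            window = tuple(station_windows.get(analyte, DEFAULT_WINDOW_MM))
            d = diffusion_coefficient(analyte, salinity, temperature, pressure)
            ds = sediment_diffusivity(d.D_free, porosity)
            slope, se = fit_gradient(profile, analyte, window)
            est = diffusive_flux(
                slope, se, porosity, ds, analyte=analyte,
                depth_window=window, station=profile.station,
            )
            rows.append(
                {
                    "station": profile.station,
                    "analyte": analyte,
                    "flux_mmol_m2_day": est.value,
                    "two_se": est.two_se,
                    "window_top_mm": window[0],
                    "window_bottom_mm": window[1],
                    "gradient_uM_per_mm": slope,
                    "Ds_m2_day": ds,
                    "porosity": porosity,
                }
            )
    frame = pd.DataFrame(
        rows,
        columns=[
            "station",
            "analyte",
            "flux_mmol_m2_day",
            "two_se",
            "window_top_mm",
            "window_bottom_mm",
            "gradient_uM_per_mm",
            "Ds_m2_day",
            "porosity",
        ],
    )
    return frame.sort_values(["station", "analyte"], ignore_index=True)
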