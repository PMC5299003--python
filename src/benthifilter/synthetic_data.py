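"""Ground-truth scenario generator for end-to-end parameter recovery.

Porewater profiles come from a steady-state one-dimensional
reaction–diffusion model with piecewise-constant volumetric rates,

    φ·Ds·d²C/dz² - k(z)·C + R(z) = 0,

solved by second-order finite differences with a Dirichlet top boundary
(bottom-water concentration at the sediment–water interface) and a
zero-gradient bottom boundary.  Depth is positive downward with 0 at the
interface; overlying-water samples carry negative depths.

The scenario vocabulary mirrors the structures seen on a hypoxic-to-euxinic
basin transect: a sulfide production zone at depth (sulfate reduction in
organic-rich mud), an optional surface mat layer that consumes the upward
sulfide flux completely (modelled as a fast first-order sink), and an
optional deep Fe(II) source below the sulfidic layer with FeS precipitation
keeping the Fe(II) and sulfide fields essentially non-overlapping.

Matching synthetic voltammograms and benthic-chamber time series close the
loop so every downstream stage (peak detection, calibration, gradient
fitting, chamber slopes) can be tested by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator
from scipy.linalg import solve_banded

from .chamber import ChamberIncubation
from .fluxes import PorewaterProfile, diffusion_coefficient, sediment_diffusivity
from .voltammetry import (
    DEFAULT_DETECTION_LIMITS,
    SULFIDE_FORWARD_SATURATION_UM,
    CalibrationModel,
    Voltammogram,
)

__all__ = [
    "Scenario",
    "TruthRecord",
    "SolverError",
    "generate_profile",
    "generate_voltammogram",
    "generate_chamber_series",
    "recovery_scenario",
]

#: Ambient conditions of the study transect (brackish Baltic deep water).
AMBIENT = {"salinity": 12.0, "temperature": 10.0, "pressure": 1.0}


class SolverError(RuntimeError):
    """Steady-state solve failed or produced an unphysical field."""


class Scenario(BaseModel):
    """Parameters of one synthetic station.

    Depths in mm (positive down), concentrations in μM, rates in μM/day
    (per bulk sediment volume), fluxes in mmol m-2 day-1.
    """

    station_label: str = "synthetic"
    water_depth: float = 110.0  # m
    bottom_water_conc: dict[str, float] = Field(default_factory=lambda: {"H2S": 0.0})
    production_zone: Optional[tuple[float, float, float]] = None  # (top, bottom, rate)
    mat_layer: Optional[tuple[float, float]] = None  # (top_mm, bottom_mm)
    fe_source: Optional[tuple[float, float]] = None  # (depth_mm, flux)
    porosity: float = 0.9
    depth_step: float = Field(0.5, description="sampling step, mm (>= 0.25)")
    max_depth_mm: float = 120.0
    noise_sd: float = 2.0  # μM
    seed: int = 0
    # numerical/rate knobs
    internal_step_mm: float = 0.025
    mat_sink_rate_per_day: float = 5.0e3
    fes_sink_rate_per_day: float = 30.0  # sulfide loss to FeS below the production zone
    fe_sink_rate_per_day: float = 50.0  # Fe(II) loss where sulfide is present
    n_overlying: int = 2

    @field_validator("depth_step")
    @classmethod
    def _min_step(cls, v: float) -> float:
        if v < 0.25:
            raise ValueError("depth_step must be >= 0.25 mm")
        return v

    @field_validator("porosity")
    @classmethod
    def _porosity_range(cls, v: float) -> float:
        if not 0 < v <= 1:
            raise ValueError("porosity must be in (0, 1]")
        return v

    @model_validator(mode="after")
    def _consistent(self) -> "Scenario":
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.production_zone is not None:
            top, bottom, rate = self.production_zone
            if not 0 <= top < bottom <= self.max_depth_mm:
                raise ValueError("production zone outside the depth domain")
            if rate < 0:
                raise ValueError("production rate must be >= 0")
        if self.mat_layer is not None:
            top, bottom = self.mat_layer
            if not 0 <= top < bottom <= self.max_depth_mm:
                raise ValueError("mat layer outside the depth domain")
        if self.fe_source is not None:
            depth, flux = self.fe_source
            if not 0 < depth <= self.max_depth_mm:
                raise ValueError("fe_source depth outside the depth domain")
            if flux < 0:
                raise ValueError("fe_source flux must be >= 0")
        if self.internal_step_mm <= 0 or self.internal_step_mm > self.depth_step:
            raise ValueError("internal_step_mm must be in (0, depth_step]")
        return self

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Scenario":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()))


@dataclass
class TruthRecord:
    """Exact noiseless field and analytic surface fluxes for a scenario.

    ``true_flux_at_swi`` is φ·Ds·dC/dz at z=0+ (positive = out of the
    sediment); for mat scenarios it is ~0 because the mat consumes the
    upward flux, so ``true_flux_to_mat`` carries the flux delivered to the
    mat base, which is what a gradient fitted below the mat measures.
    """

    scenario: Scenario
    grid_mm: np.ndarray
    true_concentration_field: dict[str, np.ndarray]
    true_flux_at_swi: dict[str, float]
    true_flux_to_mat: dict[str, float] = dc_field(default_factory=dict)
    Ds: dict[str, float] = dc_field(default_factory=dict)


def _solve_steady_state(
    h_m: float,
    phi_ds: float,
    sink: np.ndarray,
    source: np.ndarray,
    c_top: float,
) -> np.ndarray:
    """Tridiagonal solve of φDs·C'' - k·C + R = 0 on a uniform grid.

    Dirichlet top (C[0] = c_top), mirrored zero-gradient bottom.
    """
    n = sink.size
    a = phi_ds / h_m**2
    diag = -2.0 * a - sink
    upper = np.full(n, a)
    lower = np.full(n, a)
    rhs = -source.astype(float)
    # top: Dirichlet
    diag[0] = 1.0
    upper[1] = 0.0
    rhs[0] = c_top
    # bottom: ghost-node mirror C[n] = C[n-2]  ->  2a*C[n-2] - (2a+k)C[n-1] = -R
    lower[n - 1] = 2.0 * a
    ab = np.zeros((3, n))
    ab[0, 1:] = upper[1:]
    ab[1, :] = diag
    ab[2, :-1] = lower[1:]
    try:
        c = solve_banded((1, 1), ab, rhs)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise SolverError(f"steady-state solve failed: {exc}") from exc
    if not np.all(np.isfinite(c)):
        raise SolverError("steady-state solve produced non-finite values")
    return c


def _surface_gradient_per_m(conc: np.ndarray, h_m: float) -> float:
    """One-sided second-order dC/dz at z=0+ (concentration per metre)."""
    return (-3.0 * conc[0] + 4.0 * conc[1] - conc[2]) / (2.0 * h_m)


def generate_profile(scenario: Scenario) -> tuple[PorewaterProfile, TruthRecord]:
    """Solve the scenario and sample a noisy porewater profile from it.

    Returns the sampled :class:`PorewaterProfile` (Gaussian noise truncated
    at zero, detection-limit censoring applied) together with the
    :class:`TruthRecord` holding the exact field and fluxes.
    """
    h_mm = scenario.internal_step_mm
    h_m = h_mm / 1000.0
    grid_mm = np.arange(0.0, scenario.max_depth_mm + h_mm / 2, h_mm)
    n = grid_mm.size
    phi = scenario.porosity

    fields: dict[str, np.ndarray] = {}
    flux_swi: dict[str, float] = {}
    flux_mat: dict[str, float] = {}
    ds_map: dict[str, float] = {}

    sulfide_field: np.ndarray | None = None
    # sulfide first: the Fe(II) precipitation sink depends on its field
    analyte_order = sorted(scenario.bottom_water_conc, key=lambda a: (a != "H2S", a))
    for analyte in analyte_order:
        c_bw = scenario.bottom_water_conc[analyte]
        d = diffusion_coefficient(analyte, **AMBIENT)
        ds = sediment_diffusivity(d.D_free, phi)
        ds_map[analyte] = ds
        sink = np.zeros(n)
        source = np.zeros(n)
        if analyte == "H2S":
            if scenario.production_zone is not None:
                top, bottom, rate = scenario.production_zone
                source[(grid_mm >= top) & (grid_mm <= bottom)] = rate
            if scenario.mat_layer is not None:
                top, bottom = scenario.mat_layer
                sink[(grid_mm >= top) & (grid_mm <= bottom)] += (
                    scenario.mat_sink_rate_per_day
                )
            if scenario.fe_source is not None and scenario.production_zone is not None:
                # FeS precipitation removes sulfide below the production zone
                sink[grid_mm > scenario.production_zone[1]] += (
                    scenario.fes_sink_rate_per_day
                )
        elif analyte in ("Fe", "Fe2+", "Fe(II)"):
            if scenario.fe_source is not None:
                depth, flux = scenario.fe_source
                half_width = 1.0  # mm
                box = (grid_mm >= depth - half_width) & (grid_mm <= depth + half_width)
                width_m = box.sum() * h_m
                if width_m > 0:
                    source[box] = flux / width_m  # mmol m-3 day-1
                if sulfide_field is not None:
                    sink[sulfide_field > 1.0] += scenario.fe_sink_rate_per_day
        conc = _solve_steady_state(h_m, phi * ds, sink, source, c_bw)
        if conc.min() < -1e-6 * max(1.0, conc.max()):
            raise SolverError(
                f"{analyte}: negative concentrations in the noiseless field "
                f"(min {conc.min():.3g} uM)"
            )
        conc = np.clip(conc, 0.0, None)
        if analyte == "H2S":
            sulfide_field = conc
        fields[analyte] = conc
        flux_swi[analyte] = phi * ds * _surface_gradient_per_m(conc, h_m)
        if scenario.mat_layer is not None and analyte == "H2S":
            # gradient just below the mat base, one-sided on the linear side
            # of the kink (the sink is active only inside the mat)
            j = int(np.searchsorted(grid_mm, scenario.mat_layer[1]))
            j = min(max(j, 0), n - 3)
            grad = (-3.0 * conc[j] + 4.0 * conc[j + 1] - conc[j + 2]) / (2 * h_m)
            flux_mat[analyte] = phi * ds * grad

    # --- sample the noisy profile on the coarser measurement grid
    rng = np.random.default_rng(scenario.seed)
    step = scenario.depth_step
    sediment_depths = np.arange(0.0, scenario.max_depth_mm + step / 2, step)
    overlying = -step * np.arange(scenario.n_overlying, 0, -1)
    depths = np.concatenate([overlying, sediment_depths])
    concentrations: dict[str, np.ndarray] = {}
    censored: dict[str, np.ndarray] = {}
    for analyte, truth in fields.items():
        sampled = np.interp(depths, grid_mm, truth)
        sampled[depths < 0] = scenario.bottom_water_conc[analyte]
        noisy = sampled + rng.normal(0.0, scenario.noise_sd, size=sampled.size)
        noisy = np.clip(noisy, 0.0, None)  # concentrations are non-negative
        dl = DEFAULT_DETECTION_LIMITS.get(analyte.split("(")[0].rstrip("2+-"))
        dl = DEFAULT_DETECTION_LIMITS.get(analyte, dl)
        flags = np.zeros(noisy.size, dtype=bool)
        if dl is not None:
            flags = noisy < dl
            noisy = np.where(flags, dl, noisy)
        concentrations[analyte] = noisy
        censored[analyte] = flags
    profile = PorewaterProfile(
        station=scenario.station_label,
        water_depth=scenario.water_depth,
        depth_mm=depths,
        concentrations=concentrations,
        censored=censored,
        porosity_surface=phi,
        mat_layer=scenario.mat_layer,
    )
    truth = TruthRecord(
        scenario=scenario,
        grid_mm=grid_mm,
        true_concentration_field=fields,
        true_flux_at_swi=flux_swi,
        true_flux_to_mat=flux_mat,
        Ds=ds_map,
    )
    return profile, truth


# --- synthetic voltammograms -------------------------------------------------

_PEAK_CENTERS = {
    "FeS": -1.10,
    "Fe": -1.43,
    "Mn": -1.55,
    "O2": -0.35,
}
_PEAK_SIGMA_V = 0.015
_ZEROVALENT_CENTER_V = -0.88
_WAVE_HALF_V = -0.75
_WAVE_WIDTH_V = 0.04
_WAVE_MAX_UM = 1200.0


def _gaussian(e: np.ndarray, center: float, amp: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((e - center) / _PEAK_SIGMA_V) ** 2)


def _sulfide_center(total_uM: float) -> float:
    """Free-sulfide peak centre shifts from -0.70 toward -0.90 V."""
    return -0.70 - 0.20 * min(total_uM, _WAVE_MAX_UM) / _WAVE_MAX_UM


def generate_voltammogram(
    true_conc: Mapping[str, float],
    calib: CalibrationModel,
    noise_sd_nA: float = 0.5,
    seed: int = 0,
    depth_mm: float = 0.0,
    replicate_index: int = 0,
    x: int = 5,
    step_V: float = 0.002,
    background: tuple[float, float] = (0.0, 0.0),
) -> Voltammogram:
    """Synthesize one cyclic scan for the given true concentrations (μM).

    Accepted keys: ``H2S`` (free sulfide), ``polysulfide`` (Sx2- molecules,
    chain length ``x``), ``FeS`` (signal intensity, nA), ``Fe``, ``Mn``,
    ``O2``.  The forward free-sulfide peak saturates above 250 μM and its
    centre drifts negative with concentration; the backward wave tracks
    total dissolved sulfide up to 1200 μM.  ``background`` is a linear
    (offset_nA, slope_nA_per_V) baseline applied to both segments.
    """
    known = {"H2S", "polysulfide", "FeS"} | set(_PEAK_CENTERS)
    unknown = set(true_conc) - known
    if unknown:
        raise ValueError(f"analyte(s) without configured potential window: {unknown}")
    rng = np.random.default_rng(seed)
    e_fwd = np.arange(-0.1, -1.8 - step_V / 2, -step_V)
    e_bwd = e_fwd[::-1]
    offset, bg_slope = background

    c_h2s = float(true_conc.get("H2S", 0.0))
    c_poly = float(true_conc.get("polysulfide", 0.0))
    total_sulfide = c_h2s + c_poly  # molecule basis, as seen by the wave
    slope_h2s = calib.slope("H2S") if total_sulfide > 0 else None

    i_fwd = offset + bg_slope * e_fwd
    if total_sulfide > 0:
        assert slope_h2s is not None
        amp = slope_h2s * min(c_h2s + c_poly, SULFIDE_FORWARD_SATURATION_UM)
        i_fwd = i_fwd + _gaussian(e_fwd, _sulfide_center(total_sulfide), amp)
    if c_poly > 0:
        assert slope_h2s is not None
        amp = slope_h2s * min((x - 1) * c_poly, SULFIDE_FORWARD_SATURATION_UM)
        i_fwd = i_fwd + _gaussian(e_fwd, _ZEROVALENT_CENTER_V, amp)
    for analyte, center in _PEAK_CENTERS.items():
        c = float(true_conc.get(analyte, 0.0))
        if c <= 0:
            continue
        if analyte == "FeS":
            amp = c  # no calibration standard exists; intensity pass-through
        else:
            amp = calib.slope(analyte) * c
        i_fwd = i_fwd + _gaussian(e_fwd, center, amp)

    i_bwd = offset + bg_slope * e_bwd
    if total_sulfide > 0:
        wave_amp = calib.slope("tH2S") * min(total_sulfide, _WAVE_MAX_UM)
        i_bwd = i_bwd + wave_amp / (1.0 + np.exp(-(e_bwd - _WAVE_HALF_V) / _WAVE_WIDTH_V))

    if noise_sd_nA > 0:
        i_fwd = i_fwd + rng.normal(0.0, noise_sd_nA, size=i_fwd.size)
        i_bwd = i_bwd + rng.normal(0.0, noise_sd_nA, size=i_bwd.size)

    return Voltammogram(
        potential=np.concatenate([e_fwd, e_bwd]),
        current=np.concatenate([i_fwd, i_bwd]),
        segment=np.array(["forward"] * e_fwd.size + ["backward"] * e_bwd.size),
        depth_mm=depth_mm,
        replicate_index=replicate_index,
    )


def generate_chamber_series(
    true_flux: float,
    height: float = 0.15,
    n_samples: int = 6,
    duration: float = 33.0,
    noise_sd: float = 0.5,
    seed: int = 0,
    start_conc_uM: float = 0.0,
    detection_limit_uM: float = 1.0,
    deployment: str = "SYN-1",
    chamber: str = "CH1",
    water_depth: float = 110.0,
) -> ChamberIncubation:
    """Linear chamber time series: conc rises at true_flux/height + noise.

    ``true_flux`` in mmol m-2 day-1, ``height`` = enclosed water height in
    m, ``duration`` in hours.  Samples below the (colorimetric) detection
    limit are flagged censored.
    """
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    if duration <= 0:
        raise ValueError("duration must be positive")
    if height <= 0:
        raise ValueError("enclosed height must be positive")
    rng = np.random.default_rng(seed)
    times = np.linspace(0.0, duration, n_samples)
    rate_uM_h = true_flux / height / 24.0
    conc = start_conc_uM + rate_uM_h * times
    if noise_sd > 0:
        conc = conc + rng.normal(0.0, noise_sd, size=conc.size)
    conc = np.clip(conc, 0.0, None)
    return ChamberIncubation(
        deployment=deployment,
        chamber=chamber,
        water_depth=water_depth,
        times_h=times,
        conc_uM=conc,
        censored=conc < detection_limit_uM,
        enclosed_height_m=height,
    )


def recovery_scenario(
    rng: np.random.Generator,
    flux_range: tuple[float, float] = (0.1, 10.0),
) -> tuple[Scenario, tuple[float, float]]:
    """Draw a mat-free parameter-recovery scenario and its fit window.

    The target surface flux is log-uniform over ``flux_range``; a
    production zone below the linear transport zone sustains it.  The fit
    window spans the linear zone, whose length is chosen so that the
    concentration at its base reaches a few hundred μM — the magnitude
    seen in organic-rich basin sediments — wherever the domain allows.
    """
    lo, hi = flux_range
    target_flux = 10 ** rng.uniform(np.log10(lo), np.log10(hi))
    porosity = 0.9
    d = diffusion_coefficient("H2S", **AMBIENT)
    ds = sediment_diffusivity(d.D_free, porosity)
    slope_uM_mm = target_flux / (porosity * ds) / 1000.0
    window_bottom = float(np.clip(240.0 / slope_uM_mm, 6.0, 100.0))
    thickness_mm = 20.0
    rate = target_flux / (thickness_mm / 1000.0)  # μM/day
    scenario = Scenario(
        station_label=f"recovery-{target_flux:.3g}",
        bottom_water_conc={"H2S": 0.0},
        production_zone=(window_bottom, window_bottom + thickness_mm, rate),
        porosity=porosity,
        depth_step=float(rng.choice([0.25, 0.5])),
        max_depth_mm=window_bottom + thickness_mm,
        noise_sd=2.0,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    return scenario, (0.0, window_bottom)
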