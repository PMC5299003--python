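"""Cyclic-voltammogram signal processing for Au/Hg microelectrode scans.

A scan runs forward from -0.1 V to -1.8 V and back at 1000 mV/s.  On the
forward sweep each electroactive analyte produces a sharp reduction peak in
a characteristic potential window; free sulfide peaks near -0.7 V, shifting
toward -0.9 V at high concentration, and saturates above ~250 μM.  On the
backward sweep the dissolved sulfide pool (HS-, H2S, polysulfides, labile
metal sulfides) produces a single wave whose height is proportional to
total dissolved sulfide (ΣH2S) over a much larger range (2–1200 μM).

When polysulfides (Sx2-) are present the forward sulfide signal splits into
a double peak: the more negative peak carries the (x-1) zerovalent sulfur
atoms per molecule, the other the sum of free sulfide plus the terminal
S(-II).  With an assumed chain length (x = 5 by default) and the free-
sulfide calibration slope this double peak yields a polysulfide speciation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "Voltammogram",
    "PeakSignal",
    "CalibrationModel",
    "AnalyteConcentration",
    "PolysulfideSpeciation",
    "CalibrationError",
    "SpeciationError",
    "DEFAULT_WINDOWS",
    "DEFAULT_DETECTION_LIMITS",
    "SULFIDE_FORWARD_SATURATION_UM",
    "detect_peaks",
    "measure_backward_wave",
    "calibrate_standard_additions",
    "pilot_ion_rescale",
    "replicates_to_concentration",
    "speciate_polysulfide",
]


class CalibrationError(ValueError):
    """Raised when a calibration fit is unusable (e.g. non-positive slope)."""


class SpeciationError(ValueError):
    """Raised when speciation signals are mutually inconsistent."""


#: Default forward-scan potential windows (V_min, V_max), volts.
#: The sulfide window is wide enough to hold both the -0.7 V free-sulfide
#: peak (shifted negative at high concentration) and the more negative
#: zerovalent-sulfur peak of the polysulfide double peak.
DEFAULT_WINDOWS: dict[str, tuple[float, float]] = {
    "H2S": (-0.95, -0.60),
    "FeS": (-1.20, -1.05),
    "Fe": (-1.49, -1.35),
    "Mn": (-1.65, -1.50),
    "O2": (-0.50, -0.20),
}

#: Detection limits, μM.  FeS is signal-intensity only (no standard exists).
DEFAULT_DETECTION_LIMITS: dict[str, float] = {
    "O2": 20.0,
    "Mn": 10.0,
    "Fe": 10.0,
    "H2S": 0.2,
}

#: Forward free-sulfide peak saturates near this concentration; above it
#: quantification switches to the backward total-sulfide wave.
SULFIDE_FORWARD_SATURATION_UM = 250.0

#: Valid quantification range of the backward wave, μM.
BACKWARD_WAVE_RANGE_UM = (2.0, 1200.0)

#: Two forward maxima closer than this are treated as one peak with a
#: shoulder rather than a polysulfide double peak (grid-scale robustness).
MIN_DOUBLE_PEAK_SEPARATION_V = 0.05


@dataclass
class Voltammogram:
    """One cyclic scan at a given depth: potential/current series with a
    forward and a backward segment."""

    potential: np.ndarray  # V
    current: np.ndarray  # nA
    segment: np.ndarray  # 'forward' | 'backward' per point
    scan_rate: float = 1000.0  # mV s-1
    conditioning: tuple[float, float] = (-0.9, 10.0)  # (V, s)
    depth_mm: float = 0.0
    replicate_index: int = 0

    def __post_init__(self) -> None:
        self.potential = np.asarray(self.potential, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        self.segment = np.asarray(self.segment, dtype=object)
        if not (self.potential.shape == self.current.shape == self.segment.shape):
            raise ValueError("potential/current/segment must have equal length")
        if self.scan_rate <= 0:
            raise ValueError("scan_rate must be positive")
        for name, sign in (("forward", -1), ("backward", +1)):
            pot = self.potential[self.segment == name]
            if pot.size and np.any(sign * np.diff(pot) <= 0):
                raise ValueError(f"potential not strictly monotone in {name} segment")

    def segment_arrays(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        mask = self.segment == name
        return self.potential[mask], self.current[mask]

    @property
    def has_backward(self) -> bool:
        return bool(np.any(self.segment == "backward"))


@dataclass(frozen=True)
class PeakSignal:
    """A baseline-corrected forward-scan peak."""

    analyte: str
    peak_potential: float  # V
    height: float  # nA above the linear baseline
    baseline_method: str = "linear-window-endpoints"

    def __post_init__(self) -> None:
        if self.height < 0:
            raise ValueError("peak height must be non-negative")


@dataclass(frozen=True)
class CalibrationModel:
    """Per-analyte sensitivities with pilot-ion rescaling state.

    ``sensitivity`` maps analyte → nA/μM.  The backward sulfide wave uses
    the ``tH2S`` entry when present, else the forward H2S slope (the shared-
    slope assumption also used for polysulfide speciation).
    """

    sensitivity: Mapping[str, float]
    detection_limit: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DETECTION_LIMITS)
    )
    pilot_analyte: str = "Mn"
    pilot_reference_sensitivity: float | None = None

    def __post_init__(self) -> None:
        for analyte, s in self.sensitivity.items():
            if s <= 0:
                raise CalibrationError(f"sensitivity for {analyte} must be positive")
        if (
            self.pilot_reference_sensitivity is not None
            and self.pilot_reference_sensitivity <= 0
        ):
            raise CalibrationError("pilot reference sensitivity must be positive")

    def slope(self, analyte: str) -> float:
        if analyte == "tH2S":
            return self.sensitivity.get("tH2S", self.sensitivity["H2S"])
        return self.sensitivity[analyte]


@dataclass(frozen=True)
class AnalyteConcentration:
    """A replicate-averaged concentration with censoring status.

    ``censored`` is one of ``ok``, ``below_dl`` (value reported at the DL),
    or ``saturated`` (forward peak saturated; value taken from the backward
    wave).  ``qc_ok`` flags the paper's <5% replicate-spread criterion; it
    is informational, not a rejection.
    """

    analyte: str
    value: float  # μM
    sd: float  # μM
    censored: str  # 'below_dl' | 'saturated' | 'ok'
    source_signal: str  # 'forward_peak' | 'backward_wave'
    n_replicates: int = 0
    qc_ok: bool = True

    def __post_init__(self) -> None:
        if self.censored not in ("below_dl", "saturated", "ok"):
            raise ValueError(f"bad censoring flag {self.censored!r}")


@dataclass(frozen=True)
class PolysulfideSpeciation:
    """Sx2- speciation from the forward double peak and backward wave."""

    chain_length_x: int
    polysulfide_conc: float  # μM of Sx2- molecules
    zerovalent_conc: float  # μM of S(0) atoms = (x-1) * polysulfide
    free_sulfide: float  # μM HS-/H2S
    total_sulfide: float  # μM ΣH2S from the backward wave
    fraction_of_total: float


def _window_baseline(
    potential: np.ndarray, current: np.ndarray, window: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Points inside the window plus a linear baseline between its edges."""
    lo, hi = sorted(window)
    mask = (potential >= lo) & (potential <= hi)
    pot, cur = potential[mask], current[mask]
    order = np.argsort(pot)
    pot, cur = pot[order], cur[order]
    if pot.size < 5:
        raise ValueError(f"window {window} outside or too sparse in scanned range")
    slope = (cur[-1] - cur[0]) / (pot[-1] - pot[0])
    baseline = cur[0] + slope * (pot - pot[0])
    return pot, cur, baseline


def detect_peaks(
    scan: Voltammogram,
    windows: Mapping[str, tuple[float, float]] | None = None,
    min_height_nA: float = 1.0,
) -> list[PeakSignal]:
    """Local maxima above a linear baseline, per analyte window.

    Within the sulfide window up to two peaks are returned (a resolved
    double peak flags a polysulfide candidate); other windows report at
    most one.  Maxima separated by less than 0.05 V count as a single peak
    (the taller one wins).  Peaks are returned in ascending potential order.
    """
    windows = dict(windows) if windows is not None else dict(DEFAULT_WINDOWS)
    potential, current = scan.segment_arrays("forward")
    if potential.size == 0:
        raise ValueError("scan has no forward segment")
    out: list[PeakSignal] = []
    for analyte, window in windows.items():
        pot, cur, baseline = _window_baseline(potential, current, window)
        residual = cur - baseline
        idx, props = find_peaks(residual, height=min_height_nA)
        if idx.size == 0:
            continue
        # tallest first, then enforce the minimum separation
        order = np.argsort(props["peak_heights"])[::-1]
        kept: list[int] = []
        for i in order:
            if all(
                abs(pot[idx[i]] - pot[idx[j]]) >= MIN_DOUBLE_PEAK_SEPARATION_V
                for j in kept
            ):
                kept.append(i)
        max_peaks = 2 if analyte == "H2S" else 1
        kept = kept[:max_peaks]
        for i in sorted(kept, key=lambda i: pot[idx[i]]):
            out.append(
                PeakSignal(
                    analyte=analyte,
                    peak_potential=float(pot[idx[i]]),
                    height=float(residual[idx[i]]),
                )
            )
    return out


def measure_backward_wave(
    scan: Voltammogram,
    plateau_range: tuple[float, float] = (-0.40, -0.10),
    baseline_range: tuple[float, float] = (-1.80, -1.30),
) -> float:
    """Plateau-minus-baseline height (nA) of the backward sulfide wave.

    The wave rises between the baseline region (potentials more negative
    than -1.3 V) and the plateau region (more positive than -0.4 V); the
    height is the difference of the median currents of the two regions.
    """
    if not scan.has_backward:
        raise ValueError("scan has no backward segment")
    pot, cur = scan.segment_arrays("backward")
    base = cur[(pot >= baseline_range[0]) & (pot <= baseline_range[1])]
    plat = cur[(pot >= plateau_range[0]) & (pot <= plateau_range[1])]
    if base.size == 0 or plat.size == 0:
        raise ValueError("baseline/plateau ranges not covered by backward segment")
    return float(np.median(plat) - np.median(base))


def calibrate_standard_additions(
    additions: Sequence[tuple[float, float]],
    analyte: str = "H2S",
) -> float:
    """Ordinary least-squares sensitivity (nA/μM) from standard additions.

    Requires at least three additions spanning a non-zero concentration
    range; the fitted slope must be positive.
    """
    if len(additions) < 3:
        raise CalibrationError("need at least 3 standard additions")
    conc = np.asarray([a[0] for a in additions], dtype=float)
    signal = np.asarray([a[1] for a in additions], dtype=float)
    if np.ptp(conc) == 0:
        raise CalibrationError("additions span a zero concentration range")
    from scipy import stats

    res = stats.linregress(conc, signal)
    if res.slope <= 0:
        raise CalibrationError(
            f"non-positive calibration slope for {analyte}: {res.slope:.3g}"
        )
    return float(res.slope)


def pilot_ion_rescale(
    calib: CalibrationModel, new_pilot_sensitivity: float
) -> CalibrationModel:
    """Rescale all sensitivities by a fresh pilot-ion calibration.

    The pilot ion (Mn2+ by default) is recalibrated between profiles; every
    analyte sensitivity is multiplied by new/reference and the reference is
    updated.
    """
    if new_pilot_sensitivity <= 0:
        raise CalibrationError("pilot sensitivity must be positive")
    if not calib.pilot_reference_sensitivity:
        raise CalibrationError("calibration has no pilot reference sensitivity")
    factor = new_pilot_sensitivity / calib.pilot_reference_sensitivity
    return replace(
        calib,
        sensitivity={k: v * factor for k, v in calib.sensitivity.items()},
        pilot_reference_sensitivity=new_pilot_sensitivity,
    )


def _forward_signal(
    scan: Voltammogram,
    analyte: str,
    windows: Mapping[str, tuple[float, float]],
    min_height_nA: float,
) -> float:
    peaks = [
        p
        for p in detect_peaks(scan, {analyte: windows[analyte]}, min_height_nA)
        if p.analyte == analyte
    ]
    return max((p.height for p in peaks), default=0.0)


def replicates_to_concentration(
    scans: Sequence[Voltammogram],
    calib: CalibrationModel,
    analyte: str,
    windows: Mapping[str, tuple[float, float]] | None = None,
    min_height_nA: float = 1.0,
) -> AnalyteConcentration:
    """Replicate scans at one depth → mean concentration with censoring.

    Four scans are taken per depth; the first is discarded (electrode
    conditioning) and the rest averaged.  For sulfide the forward peak is
    used below its ~250 μM saturation, else the backward total-sulfide
    wave (flagged ``saturated``).  Means below the detection limit are
    reported at the DL with the ``below_dl`` flag.
    """
    if len(scans) < 4:
        raise ValueError("four scans per depth expected (first is discarded)")
    windows = dict(windows) if windows is not None else dict(DEFAULT_WINDOWS)
    usable = sorted(scans, key=lambda s: s.replicate_index)[1:]
    if len(usable) < 2:
        raise ValueError("fewer than 2 usable replicates after discarding the first")
    slope = calib.slope(analyte)
    conc = np.array(
        [_forward_signal(s, analyte, windows, min_height_nA) / slope for s in usable]
    )
    source = "forward_peak"
    censored = "ok"
    # a forward reading at (or within noise of) the saturation ceiling is
    # untrustworthy: switch to the backward wave from 1% below it
    if analyte == "H2S" and conc.mean() >= 0.99 * SULFIDE_FORWARD_SATURATION_UM:
        wave_slope = calib.slope("tH2S")
        conc = np.array([measure_backward_wave(s) / wave_slope for s in usable])
        source = "backward_wave"
        censored = "saturated"
    mean = float(conc.mean())
    sd = float(conc.std(ddof=1))
    dl = calib.detection_limit.get(analyte)
    if dl is not None and mean < dl:
        return AnalyteConcentration(
            analyte=analyte,
            value=dl,
            sd=sd,
            censored="below_dl",
            source_signal=source,
            n_replicates=len(usable),
        )
    qc_ok = mean == 0 or sd / abs(mean) <= 0.05
    return AnalyteConcentration(
        analyte=analyte,
        value=mean,
        sd=sd,
        censored=censored,
        source_signal=source,
        n_replicates=len(usable),
        qc_ok=qc_ok,
    )


def speciate_polysulfide(
    peak_negative: PeakSignal,
    peak_positive: PeakSignal,
    wave_total: float,
    calib: CalibrationModel,
    x: int = 5,
) -> PolysulfideSpeciation:
    """Polysulfide speciation from the forward double peak.

    Both peaks are quantified with the free-sulfide slope.  The more
    negative peak carries (x-1) zerovalent S atoms per Sx2- molecule, so
    [Sx2-] = peak_neg/slope/(x-1); the other peak is free sulfide plus the
    terminal S(-II), so free = peak_pos/slope - [Sx2-] (floored at zero).
    ``wave_total`` is the backward-wave ΣH2S in μM.
    """
    if x < 2:
        raise ValueError("chain length x must be >= 2")
    if wave_total <= 0:
        raise ValueError("wave_total must be positive")
    slope = calib.slope("H2S")
    zerovalent = peak_negative.height / slope
    polysulfide = zerovalent / (x - 1)
    free = max(peak_positive.height / slope - polysulfide, 0.0)
    fraction = polysulfide / wave_total
    if fraction > 1.0 + 1e-9:
        raise SpeciationError(
            f"polysulfide ({polysulfide:.3g} uM) exceeds total sulfide "
            f"({wave_total:.3g} uM): inconsistent signals"
        )
    return PolysulfideSpeciation(
        chain_length_x=x,
        polysulfide_conc=polysulfide,
        zerovalent_conc=zerovalent,
        free_sulfide=free,
        total_sulfide=wave_total,
        fraction_of_total=min(fraction, 1.0),
    )
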