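import numpy as np
import pytest

from benthifilter.voltammetry import CalibrationModel, Voltammogram


@pytest.fixture
def calib() -> CalibrationModel:
    """Shared-slope calibration: 1 nA/μM sulfide, pilot Mn at 2 nA/μM."""
    return CalibrationModel(
        sensitivity={"H2S": 1.0, "Mn": 2.0, "Fe": 1.5, "O2": 0.8},
        pilot_reference_sensitivity=2.0,
    )


def make_forward_scan(
    peaks=(), step=0.002, noise=0.0, seed=0, with_backward=False, wave_height=0.0,
    replicate_index=0,
):
    """Hand-built cyclic scan: Gaussian peaks on the forward sweep and an
    optional logistic wave on the backward sweep (independent of the
    package's own generator)."""
    rng = np.random.default_rng(seed)
    e_fwd = np.arange(-0.1, -1.8 - step / 2, -step)
    i_fwd = np.zeros_like(e_fwd)
    for center, amp in peaks:
        i_fwd += amp * np.exp(-0.5 * ((e_fwd - center) / 0.015) ** 2)
    potential, current, segment = e_fwd, i_fwd, ["forward"] * e_fwd.size
    if with_backward:
        e_bwd = e_fwd[::-1]
        i_bwd = wave_height / (1.0 + np.exp(-(e_bwd + 0.75) / 0.04))
        potential = np.concatenate([e_fwd, e_bwd])
        current = np.concatenate([i_fwd, i_bwd])
        segment = segment + ["backward"] * e_bwd.size
    current = current + rng.normal(0.0, noise, size=current.size) if noise else current
    return Voltammogram(
        potential=potential,
        current=np.asarray(current),
        segment=np.asarray(segment),
        replicate_index=replicate_index,
    )
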