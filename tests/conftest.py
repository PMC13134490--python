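import numpy as np
import pytest

from voltactf import (
    ElectronOptics,
    FrequencyGrid,
    ImagingCondition,
    PhasePlateModel,
)


@pytest.fixture(scope="session")
def optics_300() -> ElectronOptics:
    return ElectronOptics(voltage_kV=300.0, cs_mm=2.7)


@pytest.fixture(scope="session")
def vpp_default() -> PhasePlateModel:
    return PhasePlateModel()


@pytest.fixture(scope="session")
def vpp_condition(optics_300, vpp_default) -> ImagingCondition:
    """Median experimental condition: 0.78 um defocus, 72 deg phase shift."""
    return ImagingCondition(
        defocus_A=7800.0,
        optics=optics_300,
        base_B_A2=67.6,
        phase_plate=vpp_default,
        attenuation_enabled=True,
    )


@pytest.fixture(scope="session")
def plain_condition(optics_300) -> ImagingCondition:
    """Conventional high-defocus condition without a phase plate."""
    return ImagingCondition(
        defocus_A=19700.0, optics=optics_300, base_B_A2=67.6, phase_plate=None
    )


@pytest.fixture(scope="session")
def small_grid() -> FrequencyGrid:
    return FrequencyGrid(side_length=16, pixel_size_A=1.51)


def scalar_ctf_reference(k: float, condition: ImagingCondition) -> float:
    """Independent scalar-loop CTF oracle (no shared code paths with
    voltactf.optics beyond parameter objects)."""
    lam = condition.optics.wavelength_pm / 100.0
    cs = condition.optics.cs_mm * 1e7
    chi = (
        np.pi * lam * condition.defocus_A * k**2
        - 0.5 * np.pi * lam**3 * cs * k**4
    )
    plate = condition.phase_plate
    phi = 0.0
    s, b = 1.0, condition.base_B_A2
    if plate is not None:
        if k >= plate.cut_on:
            phi = np.deg2rad(plate.phase_shift_deg)
        if condition.attenuation_enabled:
            s = plate.amplitude_factor
            b = condition.base_B_A2 + plate.delta_B_A2
    return -s * np.exp(-b * k**2 / 4.0) * np.sin(chi + phi)
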