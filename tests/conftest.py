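import numpy as np
import pytest

import holosperm as hs
from holosperm.reconstruct import OpticsMeta, PhaseMap


@pytest.fixture(scope="session")
def default_phantom():
    return hs.make_phantom()


@pytest.fixture(scope="session")
def noiseless_hologram(default_phantom):
    return hs.synthesize_hologram(
        default_phantom, illum=hs.IlluminationModel.noiseless()
    )


@pytest.fixture(scope="session")
def reconstructed_noiseless(noiseless_hologram):
    # wide hard window: resolution-limited fidelity for noiseless input
    return hs.reconstruct_phase(noiseless_hologram, window="hard", radius_frac=0.65)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def phase_map_from(values, dx_um=0.1, dy_um=0.1, wavelength_nm=632.8,
                   geometry="reflection", wrapped=False, corrected=True):
    return PhaseMap(
        values=np.asarray(values, dtype=float),
        wrapped=wrapped,
        background_corrected=corrected,
        meta=OpticsMeta(wavelength_nm=wavelength_nm, dx_um=dx_um,
                        dy_um=dy_um, geometry=geometry),
    )


@pytest.fixture(scope="session")
def hemisphere_ot():
    """Discretized hemisphere height field with its closed-form S and V."""
    from holosperm.reconstruct import OpticalThicknessMap

    r_px, dx = 300, 0.1
    r_um = r_px * dx
    n = 2 * r_px + 11
    c = n // 2
    yy, xx = np.mgrid[0:n, 0:n]
    z_um = np.sqrt(np.clip(r_um**2 - ((xx - c) * dx) ** 2 - ((yy - c) * dx) ** 2, 0, None))
    ot = OpticalThicknessMap(values=z_um * 1e3, units="nm", dx_um=dx, dy_um=dx)
    truth = {
        "radius_um": r_um,
        "V_um3": (2.0 / 3.0) * np.pi * r_um**3,
        "S_um2": 3.0 * np.pi * r_um**2,
    }
    return ot, z_um > 0, truth
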