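import numpy as np
import pytest

import azint as az

# hc in keV*nm, energy of the reference setup in keV
HC_KEV_NM = 1.23984193
ENERGY_KEV = 18.57
WAVELENGTH = HC_KEV_NM / ENERGY_KEV * 1e-9  # metres

PIX = 1e-4


@pytest.fixture(scope="session")
def det256():
    return az.Detector((256, 256), PIX, PIX)


@pytest.fixture(scope="session")
def geom256(det256):
    return az.Geometry(dist=0.035, poni1=0.0128, poni2=0.0127,
                       wavelength=1e-10, detector=det256)


@pytest.fixture(scope="session")
def lab6():
    return az.load_calibrant("LaB6", wavelength=1e-10)


@pytest.fixture(scope="session")
def ring_image(geom256, lab6):
    """Noiseless continuous-ring image, ring FWHM 8 mrad."""
    return az.fake_calibration_image(lab6, geom256,
                                     az.CagliotiParams(W=(8e-3) ** 2),
                                     Imax=1000.0)


@pytest.fixture(scope="session")
def spotty(lab6):
    """Spotty fixture on a 512 px detector with ground truth."""
    det = az.Detector((512, 512), PIX, PIX)
    geom = az.Geometry(dist=0.07, poni1=0.0256, poni2=0.0250,
                       wavelength=1e-10, detector=det)
    img, truth = az.spotty_rings_image(lab6, geom, 20, spot_sigma=2.0,
                                       seed=5, min_sep=10)
    return geom, img, truth


def add_spot(img, y, x, sigma, amplitude):
    from azint.calibrant import _add_gaussian_spot
    _add_gaussian_spot(img, y, x, sigma, amplitude)
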