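"""Shared fixtures: small deterministic photosystems built in memory."""

import numpy as np
import pytest

from phikin.spectral_core import SpectralCurve, WavelengthGrid
from phikin.synth_systems import (
    BandSpec,
    LampSpec,
    PhiSpec,
    SystemSpec,
    generate,
)

# the monochromatic single-step reference case: Phi = 0.5, eps = 1e4,
# l = 1 cm, P0 = 1e-6 einstein/s/dm^3, C0 = 5e-5 M (A0 = 0.5), for which
# the trace has the closed form C(t) = Log10(1 + (10^A0 - 1) e^{-kt})/(eps l)
# with k = Phi eps l P0 ln10
MONO = dict(phi=0.5, eps_peak=1e4, p0=1e-6, c0=5e-5, lam=400.0)


@pytest.fixture(scope="session")
def grid():
    return WavelengthGrid(300, 500)


@pytest.fixture(scope="session")
def mono_m1():
    """m1 (transparent product) driven by a single-wavelength lamp."""
    return generate(
        SystemSpec(
            mechanism="m1",
            bands=(BandSpec(MONO["lam"], 40, MONO["eps_peak"]), None),
            phis=(PhiSpec(MONO["phi"], "constant"),),
            lamp=LampSpec(kind="mono", center=MONO["lam"], total=MONO["p0"]),
            c_x0=MONO["c0"],
            lambda_obs=MONO["lam"],
        )
    )


@pytest.fixture(scope="session")
def poly_m1():
    """m1 under a broadband lamp (the simplest polychromatic case)."""
    return generate(
        SystemSpec(
            mechanism="m1",
            bands=(BandSpec(400, 40, 1e4), None),
            phis=(PhiSpec(0.5, "constant"),),
            lamp=LampSpec(kind="broadband", center=400, fwhm=60, total=1e-6),
            c_x0=2e-5,
            lambda_obs=400.0,
        )
    )


@pytest.fixture(scope="session")
def mono_m3():
    """Photoreversible X <-> Y1 under monochromatic light; PSS ratio has
    the closed form (Phi_f eps_X) / (Phi_r eps_Y1)."""
    return generate(
        SystemSpec(
            mechanism="m3",
            bands=(BandSpec(400, 40, 1e4), BandSpec(400, 40, 5e3)),
            phis=(PhiSpec(0.4, "constant"), PhiSpec(0.2, "constant")),
            lamp=LampSpec(kind="mono", center=400, total=1e-6),
            c_x0=2e-5,
            lambda_obs=400.0,
        )
    )


@pytest.fixture(scope="session")
def poly_m3():
    """Photoreversible pair under a broadband lamp (actinometer stand-in)."""
    return generate(
        SystemSpec(
            mechanism="m3",
            bands=(BandSpec(360, 35, 1.2e4), BandSpec(420, 45, 8e3)),
            phis=(PhiSpec(0.5, "constant"), PhiSpec(0.3, "constant")),
            lamp=LampSpec(kind="broadband", center=400, fwhm=80, total=1e-6),
            c_x0=2e-5,
            lambda_obs=360.0,
        )
    )


@pytest.fixture(scope="session")
def m5_system():
    """Diarylethene-like photochrome: X absorbs in the UV part only, the
    product also in the visible; flat lamp spanning both regions."""
    return generate(
        SystemSpec(
            mechanism="m5",
            bands=(BandSpec(330, 30, 1.2e4), BandSpec(400, 60, 9e3)),
            phis=(
                PhiSpec(0.5, "falling", 360, 6),
                PhiSpec(0.1, "falling", 360, 6),
                PhiSpec(0.3, "rising", 360, 6),
            ),
            lamp=LampSpec(kind="flat", lo=310, hi=440, total=1e-6),
            c_x0=2e-5,
            lambda_obs=330.0,
        )
    )


@pytest.fixture
def flat_curve(grid):
    def _make(value, kind, lo=None, hi=None):
        wl = grid.wavelengths
        vals = np.full(len(grid), float(value))
        if lo is not None:
            vals[(wl < lo) | (wl > hi)] = 0.0
        return SpectralCurve(grid, vals, kind)

    return _make
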