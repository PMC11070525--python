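"""Deterministic, seeded generator of complete synthetic photosystems.

Real absorptivity spectra, quantum-yield profiles and lamp emission
profiles are smooth curves; the generator emulates them with Gaussian
absorption bands, logistic (sigmoid) quantum-yield transitions and
Gaussian or flat lamp bands, all on the shared 1-nm grid.  Every catalog
mechanism (m1-m5, the divergent Phi-shaped branch, tri- and tetra-cyclic
graphs) can be instantiated, so the whole toolkit is testable without any
external data.

All randomness flows through one seeded generator passed explicitly;
identical spec + seed reproduce byte-identical bundles.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .spectral_core import (
    IrradiationSetup,
    Mechanism,
    MECHANISM_TOPOLOGIES,
    Medium,
    SpectralCurve,
    WavelengthGrid,
    build_mechanism,
)

__all__ = [
    "BandSpec",
    "PhiSpec",
    "LampSpec",
    "SystemSpec",
    "PhotoSystem",
    "generate",
    "random_system",
    "benchmark_suite",
    "gaussian_band",
    "logistic_profile",
    "make_lamp",
]

#: default shared grid (near-UV / visible window typical of drug
#: photostability and actinometry work)
DEFAULT_GRID = WavelengthGrid(300, 500)

#: default total incident photon flux, einstein s^-1 dm^-3 summed over the
#: lamp band (typical of low-irradiance photostability setups)
DEFAULT_P0_TOTAL = 1e-6

#: initial absorbance kept below the rate-law validity limit
A0_CAP = 0.45


def gaussian_band(grid: WavelengthGrid, center: float, fwhm: float, peak: float) -> np.ndarray:
    """Gaussian band with far tails (< 1e-6 of the peak) truncated to
    exactly zero, so generated curves have finite support and the OSIA
    (defined on strictly positive values) has sharp edges."""
    wl = grid.wavelengths.astype(float)
    v = peak * np.exp(-4.0 * np.log(2.0) * ((wl - center) / fwhm) ** 2)
    v[v < 1e-6 * peak] = 0.0
    return v


def logistic_profile(
    grid: WavelengthGrid, plateau: float, center: float, width: float, rising: bool
) -> np.ndarray:
    """Smooth quantum-yield transition between 0 and ``plateau``."""
    wl = grid.wavelengths.astype(float)
    s = 1.0 / (1.0 + np.exp(-(wl - center) / width))
    return plateau * (s if rising else 1.0 - s)


@dataclass(frozen=True)
class BandSpec:
    """Gaussian absorption band: center (nm), FWHM (nm), peak (M^-1 cm^-1)."""

    center: float
    fwhm: float
    peak: float


@dataclass(frozen=True)
class PhiSpec:
    """Quantum-yield profile: a constant plateau or a logistic transition."""

    plateau: float
    shape: str = "constant"  # constant | rising | falling
    center: float = 0.0
    width: float = 10.0


@dataclass(frozen=True)
class LampSpec:
    """Lamp emission: broadband/LED Gaussians, a flat band, or a single
    monochromatic line; ``total`` is the summed photon flux."""

    kind: str  # broadband | led | flat | mono
    center: float = 0.0
    fwhm: float = 0.0
    lo: float = 0.0
    hi: float = 0.0
    total: float = DEFAULT_P0_TOTAL


@dataclass(frozen=True)
class SystemSpec:
    """Complete description of a synthetic photosystem."""

    mechanism: str
    bands: tuple[BandSpec | None, ...]  # one per species; None = transparent
    phis: tuple[PhiSpec, ...]  # one per step
    lamp: LampSpec
    c_x0: float = 2e-5
    l_irr: float = 1.0
    l_obs: float = 1.0
    lambda_obs: float | None = None
    grid: WavelengthGrid = DEFAULT_GRID
    seed: int = 0


@dataclass
class PhotoSystem:
    """A generated bundle: mechanism + spectra + setup + initial medium."""

    spec: SystemSpec
    mechanism: Mechanism
    epsilons: list[SpectralCurve]
    setup: IrradiationSetup

    @property
    def grid(self) -> WavelengthGrid:
        return self.spec.grid

    @property
    def c_x0(self) -> float:
        return self.spec.c_x0

    def medium0(self, spm: SpectralCurve | None = None) -> Medium:
        conc = np.zeros(self.mechanism.n_species)
        conc[0] = self.spec.c_x0
        return Medium(conc, spm)

    def with_lamp(self, lamp: SpectralCurve) -> "PhotoSystem":
        setup = IrradiationSetup(
            lamp=lamp,
            l_irr=self.setup.l_irr,
            l_obs=self.setup.l_obs,
            lambda_obs=self.setup.lambda_obs,
        )
        return PhotoSystem(self.spec, self.mechanism, self.epsilons, setup)

    def with_c_x0(self, c_x0: float) -> "PhotoSystem":
        return PhotoSystem(
            replace(self.spec, c_x0=c_x0), self.mechanism, self.epsilons, self.setup
        )


def make_lamp(grid: WavelengthGrid, spec: LampSpec) -> SpectralCurve:
    """Build a lamp curve and rescale it to the requested photon budget."""
    if spec.kind in ("broadband", "led"):
        vals = gaussian_band(grid, spec.center, spec.fwhm, 1.0)
    elif spec.kind == "flat":
        wl = grid.wavelengths
        vals = ((wl >= spec.lo) & (wl <= spec.hi)).astype(float)
    elif spec.kind == "mono":
        vals = np.zeros(len(grid))
        vals[grid.index(spec.center)] = 1.0
    else:
        raise ValueError(f"unknown lamp kind {spec.kind!r}")
    s = vals.sum()
    if s == 0:
        raise ValueError("lamp band lies outside the grid")
    return SpectralCurve(grid, vals * (spec.total / s), "lamp_intensity")


def _phi_curve(grid: WavelengthGrid, spec: PhiSpec) -> SpectralCurve:
    if spec.shape == "constant":
        vals = np.full(len(grid), spec.plateau)
    elif spec.shape in ("rising", "falling"):
        vals = logistic_profile(grid, spec.plateau, spec.center, spec.width, spec.shape == "rising")
    else:
        raise ValueError(f"unknown phi shape {spec.shape!r}")
    return SpectralCurve(grid, vals, "quantum_yield")


def generate(spec: SystemSpec) -> PhotoSystem:
    """Materialize a :class:`SystemSpec` into curves on the shared grid."""
    topo = MECHANISM_TOPOLOGIES.get(spec.mechanism)
    if topo is None:
        raise ValueError(f"unknown mechanism {spec.mechanism!r}")
    if len(spec.bands) != topo["n_species"]:
        raise ValueError("one band spec (or None) per species is required")
    if len(spec.phis) != len(topo["steps"]):
        raise ValueError("one phi spec per step is required")

    grid = spec.grid
    wl = grid.wavelengths
    epsilons = []
    for band in spec.bands:
        if band is None:
            epsilons.append(SpectralCurve.zeros(grid, "absorptivity"))
            continue
        if not (wl[0] <= band.center <= wl[-1]):
            raise ValueError(
                f"band center {band.center} nm outside the grid [{wl[0]}, {wl[-1]}] nm"
            )
        epsilons.append(
            SpectralCurve(
                grid, gaussian_band(grid, band.center, band.fwhm, band.peak), "absorptivity"
            )
        )

    phi_curves = [_phi_curve(grid, p) for p in spec.phis]
    mechanism = build_mechanism(spec.mechanism, phi_curves)
    lamp = make_lamp(grid, spec.lamp)
    lambda_obs = spec.lambda_obs
    if lambda_obs is None:
        # observe at the reactant band maximum when it exists
        band0 = spec.bands[0]
        lambda_obs = float(round(band0.center)) if band0 else float(wl[len(wl) // 2])
    setup = IrradiationSetup(
        lamp=lamp, l_irr=spec.l_irr, l_obs=spec.l_obs, lambda_obs=lambda_obs
    )
    return PhotoSystem(spec, mechanism, epsilons, setup)


# ---------------------------------------------------------------------------
# random benchmark systems
# ---------------------------------------------------------------------------

FAMILIES = ("m1", "m2", "m3", "m4", "m5", "phi_shaped", "cyclic3", "cyclic4")

#: documented draw ranges for the benchmark generator
EPS_PEAK_RANGE = (1e3, 3e4)  # M^-1 cm^-1, log-uniform
PHI_RANGE = (0.05, 0.9)  # uniform
C0_RANGE = (1e-6, 1e-4)  # M, log-uniform, capped so A(0) < 0.45
BAND_CENTER_RANGE = (330.0, 460.0)  # nm
BAND_FWHM_RANGE = (25.0, 60.0)  # nm


def random_system(seed: int, mechanism_family: str | None = None) -> SystemSpec:
    """Draw one benchmark system spec.

    Band centers/widths and quantum-yield plateaus are uniform draws;
    absorptivity peaks and the initial concentration are log-uniform (both
    span two decades).  The initial concentration is capped so that the
    initial reactant absorbance stays inside the rate-law validity zone
    (A < 0.45 over the irradiation path).
    """
    rng = np.random.default_rng(seed)
    family = mechanism_family or FAMILIES[int(rng.integers(len(FAMILIES)))]
    topo = MECHANISM_TOPOLOGIES[family]
    grid = DEFAULT_GRID

    bands: list[BandSpec | None] = []
    for j in range(topo["n_species"]):
        if j in topo["transparent"]:
            bands.append(None)
            continue
        center = rng.uniform(*BAND_CENTER_RANGE)
        fwhm = rng.uniform(*BAND_FWHM_RANGE)
        peak = 10.0 ** rng.uniform(*np.log10(EPS_PEAK_RANGE))
        bands.append(BandSpec(center, fwhm, peak))

    step_regions = topo.get("step_regions")
    phis: list[PhiSpec] = []
    for s, _ in enumerate(topo["steps"]):
        plateau = rng.uniform(*PHI_RANGE)
        if step_regions is not None:
            # m5: UV-driven steps fall off past the band split, the visible
            # back-reaction rises after it
            split = rng.uniform(360.0, 390.0)
            shape = "falling" if step_regions[s] == "uv" else "rising"
            phis.append(PhiSpec(plateau, shape, center=split, width=6.0))
        elif rng.random() < 0.5:
            phis.append(PhiSpec(plateau, "constant"))
        else:
            shape = "rising" if rng.random() < 0.5 else "falling"
            center = rng.uniform(*BAND_CENTER_RANGE)
            phis.append(PhiSpec(plateau, shape, center=center, width=rng.uniform(5.0, 20.0)))

    # lamp centered near the reactant band so the OSIA is never empty
    x_center = bands[0].center
    lamp = LampSpec(
        kind="broadband",
        center=float(np.clip(x_center + rng.uniform(-25.0, 25.0), 320.0, 470.0)),
        fwhm=rng.uniform(40.0, 80.0),
        total=DEFAULT_P0_TOTAL,
    )

    l_irr = 1.0
    c0 = 10.0 ** rng.uniform(*np.log10(C0_RANGE))
    c0 = min(c0, A0_CAP / (bands[0].peak * l_irr))

    return SystemSpec(
        mechanism=family,
        bands=tuple(bands),
        phis=tuple(phis),
        lamp=lamp,
        c_x0=c0,
        l_irr=l_irr,
        l_obs=1.0,
        lambda_obs=float(round(x_center)),
        grid=grid,
        seed=int(seed),
    )


def benchmark_suite(n: int, seed: int) -> list[SystemSpec]:
    """``n`` seeded system specs cycling through all mechanism families."""
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=n)
    return [
        random_system(int(child_seeds[i]), FAMILIES[i % len(FAMILIES)]) for i in range(n)
    ]
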