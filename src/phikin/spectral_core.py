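"""Domain types and basic photophysical quantities.

Everything in this package lives on a shared 1-nm wavelength grid: molar
absorptivities ``eps(lambda)`` (M^-1 cm^-1), quantum-yield profiles
``phi(lambda)`` (dimensionless, <= 1) and lamp emission profiles
``P0(lambda)`` (einstein s^-1 dm^-3 delivered per 1-nm step).  A
photoreaction mechanism is a directed graph of photosteps between species,
each step carrying its own quantum-yield profile.

The quantities computed here are the building blocks of the polychromatic
rate law: the total absorbance of the medium (Beer-Lambert sum over species
plus any inert spectator absorbance), the photokinetic factor
``PKF(A) = (1 - 10^-A)/A``, the fraction of incident photons absorbed by a
given species, and the overlap section of irradiation and absorption
wavelengths (OSIA).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger("phikin.spectral_core")

LN10 = np.log(10.0)

#: total absorbance above which the well-stirred, collimated-beam rate law
#: is considered outside its validity zone (a warning, not an error)
ABSORBANCE_VALIDITY_LIMIT = 0.5

#: below this absorbance the photokinetic factor switches to its series form
PKF_SERIES_THRESHOLD = 1e-6

CURVE_KINDS = ("absorptivity", "quantum_yield", "lamp_intensity", "absorbance")


@dataclass(frozen=True)
class WavelengthGrid:
    """Integer wavelength grid with a fixed 1-nm step, inclusive endpoints."""

    lambda_min: int
    lambda_max: int

    def __post_init__(self) -> None:
        if self.lambda_min >= self.lambda_max:
            raise ValueError(
                f"lambda_min ({self.lambda_min}) must be < lambda_max ({self.lambda_max})"
            )

    @property
    def wavelengths(self) -> np.ndarray:
        return np.arange(self.lambda_min, self.lambda_max + 1)

    def __len__(self) -> int:
        return self.lambda_max - self.lambda_min + 1

    def index(self, lam: float) -> int:
        """Grid index of wavelength ``lam``; raises if off the grid."""
        idx = int(round(lam)) - self.lambda_min
        if lam != round(lam) or idx < 0 or idx >= len(self):
            raise ValueError(
                f"wavelength {lam} nm is not on the grid "
                f"[{self.lambda_min}, {self.lambda_max}] nm (1-nm steps)"
            )
        return idx


@dataclass(frozen=True)
class SpectralCurve:
    """A value-per-wavelength function on a :class:`WavelengthGrid`.

    ``kind`` is one of ``absorptivity`` (M^-1 cm^-1), ``quantum_yield``
    (dimensionless, <= 1), ``lamp_intensity`` (einstein s^-1 dm^-3 per 1-nm
    step) or ``absorbance`` (dimensionless, used for spectator-molecule
    envelopes).
    """

    grid: WavelengthGrid
    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if self.kind not in CURVE_KINDS:
            raise ValueError(f"unknown curve kind {self.kind!r}; expected one of {CURVE_KINDS}")
        if vals.ndim != 1 or vals.size != len(self.grid):
            raise ValueError(
                f"curve has {vals.size} values but the grid has {len(self.grid)} points"
            )
        if np.any(vals < 0):
            raise ValueError(f"{self.kind} curve contains negative values")
        if self.kind == "quantum_yield" and np.any(vals > 1.0):
            raise ValueError("quantum-yield values must not exceed 1")

    def at(self, lam: float) -> float:
        return float(self.values[self.grid.index(lam)])

    def support(self) -> np.ndarray:
        """Boolean mask of grid points where the curve is strictly positive."""
        return self.values > 0

    def scaled(self, factor: float) -> "SpectralCurve":
        return SpectralCurve(self.grid, self.values * factor, self.kind)

    @classmethod
    def zeros(cls, grid: WavelengthGrid, kind: str) -> "SpectralCurve":
        return cls(grid, np.zeros(len(grid)), kind)


@dataclass(frozen=True)
class PhotoStep:
    """One photochemical step ``from_species -> to_species`` with its
    wavelength-dependent quantum yield."""

    from_species: int
    to_species: int
    phi: SpectralCurve

    def __post_init__(self) -> None:
        if self.from_species == self.to_species:
            raise ValueError("a photostep must connect two distinct species")
        if self.phi.kind != "quantum_yield":
            raise ValueError("photostep curve must be of kind 'quantum_yield'")


@dataclass(frozen=True)
class Mechanism:
    """Directed graph of photosteps.  Species 0 is the reactant X."""

    n_species: int
    steps: tuple[PhotoStep, ...]
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "steps", tuple(self.steps))
        for s in self.steps:
            if not (0 <= s.from_species < self.n_species and 0 <= s.to_species < self.n_species):
                raise ValueError("photostep species index out of range")
        if not self.labels:
            labels = ("X",) + tuple(f"Y{j}" for j in range(1, self.n_species))
            object.__setattr__(self, "labels", labels)
        elif len(self.labels) != self.n_species:
            raise ValueError("labels length must equal n_species")

    @property
    def n_phi(self) -> int:
        """Total number of photochemical steps."""
        return len(self.steps)

    def n_phi_j(self, j: int) -> int:
        """Number of steps starting or ending at species ``j``."""
        return sum(1 for s in self.steps if s.from_species == j or s.to_species == j)

    def has_cycle(self) -> bool:
        """True if the step graph contains a directed cycle of length >= 3.

        Simple photoreversible pairs (two-step A<->B loops) are not counted:
        the term-count relaxation for cyclic mechanisms applies to genuine
        multi-species cycles only.
        """
        adj: dict[int, set[int]] = {j: set() for j in range(self.n_species)}
        for s in self.steps:
            adj[s.from_species].add(s.to_species)

        def dfs(start: int, node: int, visited: frozenset[int]) -> bool:
            for nxt in adj[node]:
                if nxt == start and len(visited) >= 3:
                    return True
                if nxt not in visited:
                    if dfs(start, nxt, visited | {nxt}):
                        return True
            return False

        return any(dfs(j, j, frozenset({j})) for j in range(self.n_species))

    def term_bound(self, j: int | None = None) -> int:
        """Upper bound on the number of mono-Phi-order terms for a trace.

        ``j`` selects a species trace (bound ``n_phi_j``, relaxed to ``n_phi``
        for cyclic mechanisms); ``j=None`` selects the total-absorbance trace
        (bound ``n_phi``).
        """
        if j is None:
            return self.n_phi
        if self.has_cycle():
            return self.n_phi
        return self.n_phi_j(j)


@dataclass
class Medium:
    """Composition of the reactive medium: molar concentrations of the
    mechanism species plus an optional aggregated spectator-molecule (SPM)
    absorbance envelope.

    Spectator molecules are thermally and photochemically inert; only their
    summed absorbance enters the rate law, so the ``w`` individual spectator
    species are stored as one curve.
    """

    concentrations: np.ndarray
    spm_absorbance: SpectralCurve | None = None

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be non-negative")
        if self.spm_absorbance is not None and self.spm_absorbance.kind != "absorbance":
            raise ValueError("spm_absorbance must be a curve of kind 'absorbance'")


@dataclass(frozen=True)
class IrradiationSetup:
    """Lamp and reactor geometry: irradiation path length ``l_irr`` (cm),
    observation path length ``l_obs`` (cm) and observation wavelength."""

    lamp: SpectralCurve
    l_irr: float = 1.0
    l_obs: float = 1.0
    lambda_obs: float | None = None

    def __post_init__(self) -> None:
        if self.lamp.kind != "lamp_intensity":
            raise ValueError("setup lamp must be a curve of kind 'lamp_intensity'")
        if self.l_irr <= 0 or self.l_obs <= 0:
            raise ValueError("optical path lengths must be positive")
        if self.lambda_obs is not None:
            self.lamp.grid.index(self.lambda_obs)  # raises if off grid


# ---------------------------------------------------------------------------
# mechanism catalog
# ---------------------------------------------------------------------------

#: Step topologies of the catalog mechanisms.  ``transparent`` lists species
#: generated with zero absorptivity by default (the colourless photoproduct
#: of mechanism m1).  ``m5`` is the diarylethene-like photochrome: a
#: photoreversible pair driven in one wavelength region plus a second,
#: spectrally separate back-reaction channel of the product; its two reverse
#: steps are tagged with the region ("uv"/"vis") their quantum-yield profile
#: occupies.
MECHANISM_TOPOLOGIES: dict[str, dict] = {
    "m1": {"n_species": 2, "steps": [(0, 1)], "transparent": (1,)},
    "m2": {"n_species": 2, "steps": [(0, 1)], "transparent": ()},
    "m3": {"n_species": 2, "steps": [(0, 1), (1, 0)], "transparent": ()},
    "m4": {"n_species": 3, "steps": [(0, 1), (1, 0), (0, 2), (2, 0)], "transparent": ()},
    "m5": {
        "n_species": 2,
        "steps": [(0, 1), (1, 0), (1, 0)],
        "transparent": (),
        "step_regions": ("uv", "uv", "vis"),
    },
    "phi_shaped": {"n_species": 3, "steps": [(0, 1), (0, 2)], "transparent": ()},
    "cyclic3": {"n_species": 3, "steps": [(0, 1), (1, 2), (2, 0)], "transparent": ()},
    "cyclic4": {
        "n_species": 4,
        "steps": [(0, 1), (1, 2), (2, 3), (3, 0), (0, 2), (1, 3)],
        "transparent": (),
    },
}


def build_mechanism(name: str, phi_curves: list[SpectralCurve]) -> Mechanism:
    """Assemble a catalog mechanism from its name and per-step quantum-yield
    curves (ordered as in :data:`MECHANISM_TOPOLOGIES`)."""
    if name not in MECHANISM_TOPOLOGIES:
        raise ValueError(f"unknown mechanism {name!r}; catalog: {sorted(MECHANISM_TOPOLOGIES)}")
    topo = MECHANISM_TOPOLOGIES[name]
    if len(phi_curves) != len(topo["steps"]):
        raise ValueError(
            f"mechanism {name} has {len(topo['steps'])} steps, got {len(phi_curves)} phi curves"
        )
    steps = tuple(
        PhotoStep(f, t, phi) for (f, t), phi in zip(topo["steps"], phi_curves)
    )
    return Mechanism(n_species=topo["n_species"], steps=steps)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def _check_shared_grid(*curves: SpectralCurve) -> WavelengthGrid:
    grids = {c.grid for c in curves if c is not None}
    if len(grids) != 1:
        raise ValueError("all spectral curves in one computation must share one grid")
    return grids.pop()


def pkf(a_tot):
    """Photokinetic factor ``(1 - 10^-A) / A``.

    Continuous at A = 0 through the series limit ``ln10 * (1 - A ln10 / 2 +
    (A ln10)^2 / 6)``, used below ``PKF_SERIES_THRESHOLD`` to avoid 0/0
    cancellation.  Accepts scalars or arrays; strictly decreasing in A.
    """
    a = np.asarray(a_tot, dtype=float)
    if np.any(a < 0):
        raise ValueError("total absorbance must be non-negative")
    small = a < PKF_SERIES_THRESHOLD
    safe = np.where(small, 1.0, a)
    direct = -np.expm1(-safe * LN10) / safe
    x = a * LN10
    series = LN10 * (1.0 - x / 2.0 + x * x / 6.0)
    out = np.where(small, series, direct)
    if np.isscalar(a_tot) or np.ndim(a_tot) == 0:
        return float(out)
    return out


def absorbance_spectrum(
    medium: Medium, epsilons: list[SpectralCurve], path: float
) -> np.ndarray:
    """Total absorbance at every grid wavelength (species + SPM)."""
    grid = _check_shared_grid(*epsilons)
    if len(epsilons) != medium.concentrations.size:
        raise ValueError("one absorptivity curve per species is required")
    eps = np.stack([e.values for e in epsilons])
    a = medium.concentrations @ eps * path
    if medium.spm_absorbance is not None:
        _check_shared_grid(epsilons[0], medium.spm_absorbance)
        a = a + medium.spm_absorbance.values
    return a


def total_absorbance(
    mechanism: Mechanism,
    medium: Medium,
    epsilons: list[SpectralCurve],
    lam: float,
    path: float,
) -> float:
    """Total absorbance of the medium at wavelength ``lam`` over ``path`` cm:
    Beer-Lambert sum over all species plus spectator absorbance."""
    if len(epsilons) != mechanism.n_species:
        raise ValueError("an absorptivity curve must be supplied for every species")
    idx = epsilons[0].grid.index(lam)
    return float(absorbance_spectrum(medium, epsilons, path)[idx])


def absorbed_fraction(
    j: int,
    mechanism: Mechanism,
    medium: Medium,
    epsilons: list[SpectralCurve],
    lamp: SpectralCurve,
    lam: float,
    path: float = 1.0,
) -> float:
    """Photon flux absorbed by species ``j`` at wavelength ``lam``:
    ``Pa_j = A_j * P0 * PKF(Atot)``, in einstein s^-1 dm^-3.

    The competition of all absorbers (including spectators) enters through
    the photokinetic factor of the *total* absorbance; a species with zero
    own absorbance absorbs nothing regardless of the other absorbers.
    """
    if len(epsilons) != mechanism.n_species:
        raise ValueError("an absorptivity curve must be supplied for every species")
    grid = _check_shared_grid(*epsilons, lamp)
    idx = grid.index(lam)
    a_j = epsilons[j].values[idx] * path * medium.concentrations[j]
    if a_j == 0.0:
        return 0.0
    a_tot = float(absorbance_spectrum(medium, epsilons, path)[idx])
    return float(a_j * lamp.values[idx] * pkf(a_tot))


def compute_osia(
    lamp: SpectralCurve, epsilon: SpectralCurve, threshold: float = 0.0
) -> list[tuple[int, int]]:
    """Overlap section of irradiation and absorption (OSIA).

    Returns the interval(s) ``[lambda_a, lambda_b]`` (nm, inclusive) where
    both the lamp emission and the absorptivity exceed ``threshold``.  An
    empty overlap is a valid result (logged as a warning): the lamp then
    cannot drive the species at all.
    """
    grid = _check_shared_grid(lamp, epsilon)
    mask = (lamp.values > threshold) & (epsilon.values > threshold)
    if not mask.any():
        logger.warning("empty OSIA: lamp emission and absorption do not overlap")
        return []
    wl = grid.wavelengths
    intervals: list[tuple[int, int]] = []
    start = None
    for i, m in enumerate(mask):
        if m and start is None:
            start = wl[i]
        elif not m and start is not None:
            intervals.append((int(start), int(wl[i - 1])))
            start = None
    if start is not None:
        intervals.append((int(start), int(wl[-1])))
    return intervals


def osia_mask(lamp: SpectralCurve, epsilon: SpectralCurve, threshold: float = 0.0) -> np.ndarray:
    """Boolean grid mask of the OSIA (union of its intervals)."""
    _check_shared_grid(lamp, epsilon)
    return (lamp.values > threshold) & (epsilon.values > threshold)
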