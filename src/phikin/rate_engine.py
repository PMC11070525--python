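"""The wavelength-summed photokinetic rate law.

For each species ``Yj`` the rate under a polychromatic beam is a sum over
the 1-nm grid wavelengths and over the photosteps touching ``Yj``::

    r_j(t) = sum_lambda sum_{j'} [ -Phi_{j->j'}(l) Pa_j(l,t)
                                   +Phi_{j'->j}(l) Pa_{j'}(l,t) ]

with ``Pa_j = A_j P0 PKF(Atot)`` the photon flux absorbed by ``Yj``.  For
pure interconversion graphs the rates sum to zero (photon-driven mass
conservation).  The initial reactant rate for a pure-X start collapses to
the closed form ``r0_X = -sum_lambda sum_{X->Yj'} Phi P0 (1 - 10^-A_X)``,
which is the largest magnitude the reactant rate ever attains.
"""

from __future__ import annotations

import numpy as np

from .spectral_core import (
    IrradiationSetup,
    Mechanism,
    Medium,
    SpectralCurve,
    _check_shared_grid,
    pkf,
)

__all__ = [
    "RateEvaluator",
    "rate_vector",
    "initial_reactant_rate",
    "theoretical_initial_rates",
]


class RateEvaluator:
    """Precompiled rate-law evaluator for one (mechanism, spectra, setup).

    Folds all time-invariant factors (``Phi(l) * eps_from(l) * l_irr *
    P0(l)`` per step) into one matrix so that a rate evaluation is two
    small matrix-vector products; this is the inner loop of the RK4
    integrator.
    """

    def __init__(
        self,
        mechanism: Mechanism,
        epsilons: list[SpectralCurve],
        setup: IrradiationSetup,
        spm_absorbance: SpectralCurve | None = None,
    ):
        if len(epsilons) != mechanism.n_species:
            raise ValueError("an absorptivity curve must be supplied for every species")
        curves = list(epsilons) + [setup.lamp] + [s.phi for s in mechanism.steps]
        if spm_absorbance is not None:
            curves.append(spm_absorbance)
        self.grid = _check_shared_grid(*curves)
        self.mechanism = mechanism
        self.setup = setup
        self.n_species = mechanism.n_species
        self.eps = np.stack([e.values for e in epsilons])  # (nsp, nl)
        self.l_irr = setup.l_irr
        self.p0 = setup.lamp.values
        self.spm = (
            spm_absorbance.values if spm_absorbance is not None else np.zeros(len(self.grid))
        )
        self.from_idx = np.array([s.from_species for s in mechanism.steps], dtype=int)
        self.to_idx = np.array([s.to_species for s in mechanism.steps], dtype=int)
        if mechanism.n_phi:
            phi = np.stack([s.phi.values for s in mechanism.steps])  # (nstep, nl)
            # per-step weight: Phi * eps_from * l_irr * P0  -> flux = C_from * W @ PKF
            self.w = phi * self.eps[self.from_idx] * self.l_irr * self.p0
        else:
            self.w = np.zeros((0, len(self.grid)))

    def total_absorbance(self, conc: np.ndarray) -> np.ndarray:
        """Atot(lambda) for the given concentration vector."""
        return conc @ self.eps * self.l_irr + self.spm

    def rates(self, conc: np.ndarray) -> np.ndarray:
        """Per-species rates (mol dm^-3 s^-1) at the given state."""
        f = pkf(self.total_absorbance(conc))
        r = np.zeros(self.n_species)
        if self.w.shape[0]:
            flux = (self.w @ f) * conc[self.from_idx]  # per-step M/s, >= 0
            np.subtract.at(r, self.from_idx, flux)
            np.add.at(r, self.to_idx, flux)
        return r


def rate_vector(
    mechanism: Mechanism,
    medium: Medium,
    epsilons: list[SpectralCurve],
    setup: IrradiationSetup,
) -> np.ndarray:
    """Evaluate the polychromatic rate law for every species.

    Sign convention: depletion negative, formation positive.  The entries
    sum to zero for any pure interconversion mechanism.
    """
    ev = RateEvaluator(mechanism, epsilons, setup, medium.spm_absorbance)
    return ev.rates(medium.concentrations)


def initial_reactant_rate(
    mechanism: Mechanism,
    c_x0: float,
    epsilons: list[SpectralCurve],
    setup: IrradiationSetup,
    spm_absorbance: SpectralCurve | None = None,
) -> float:
    """Closed-form initial reactant rate for a pure-X start.

    ``r0_X = -sum_lambda sum_{X->Yj'} Phi(l) P0(l) (1 - 10^-A_X(l,0))``;
    valid only when the reactant is the sole absorbing species at t = 0
    (spectator absorbance, which competes for photons, is folded in through
    the photokinetic factor when present).  For mixed initial states use
    :func:`rate_vector` at t = 0 instead.
    """
    if c_x0 < 0:
        raise ValueError("initial concentration must be non-negative")
    conc0 = np.zeros(mechanism.n_species)
    conc0[0] = c_x0
    medium = Medium(conc0, spm_absorbance)
    return float(rate_vector(mechanism, medium, epsilons, setup)[0])


def theoretical_initial_rates(
    mechanism: Mechanism,
    medium0: Medium,
    epsilons: list[SpectralCurve],
    setup: IrradiationSetup,
) -> dict:
    """Theoretical initial rates of every species and of the observed
    total absorbance.

    Returns a dict with ``species`` (array of r0 per species, M s^-1) and,
    when the setup declares an observation wavelength, ``absorbance``
    (``Theo:r0_A = sum_j eps_j(lambda_obs) l_obs r0_j``, s^-1).
    """
    r0 = rate_vector(mechanism, medium0, epsilons, setup)
    out: dict = {"species": r0}
    if setup.lambda_obs is not None:
        idx = epsilons[0].grid.index(setup.lambda_obs)
        eps_obs = np.array([e.values[idx] for e in epsilons])
        out["absorbance"] = float(eps_obs @ r0 * setup.l_obs)
    return out
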