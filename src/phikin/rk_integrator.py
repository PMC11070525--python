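"""Fixed-step fourth-order Runge-Kutta integration of the rate law.

The integrator is deliberately plain: classic RK4 with a constant step,
no adaptivity, recording the state at uniform intervals.  Traces are pure
data (times + concentrations + provenance); the total-absorbance trace at
the observation wavelength is derived afterwards.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .rate_engine import RateEvaluator
from .spectral_core import (
    ABSORBANCE_VALIDITY_LIMIT,
    IrradiationSetup,
    Mechanism,
    Medium,
    SpectralCurve,
)

logger = logging.getLogger("phikin.rk_integrator")

NEGATIVE_CLAMP = -1e-15  # float noise below this magnitude is zeroed; worse aborts


@dataclass(frozen=True)
class IntegrationSettings:
    """RK4 step controls.

    ``dt`` must be small enough that the per-step concentration change is a
    small fraction of the initial reactant concentration (the default
    chooser targets <= 1e-3 * C_X0 at t = 0).
    """

    dt: float
    t_end: float
    record_every: int = 1
    warn_absorbance: float = ABSORBANCE_VALIDITY_LIMIT

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.t_end <= self.dt:
            raise ValueError("t_end must exceed dt")
        if self.record_every < 1:
            raise ValueError("record_every must be >= 1")


@dataclass
class KineticTrace:
    """Time series of all species concentrations.

    ``conc`` has shape (n_times, n_species).  ``meta`` carries provenance:
    mechanism labels, lamp tag, integration settings.
    """

    times: np.ndarray
    conc: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def n_species(self) -> int:
        return self.conc.shape[1]

    def species(self, j: int) -> np.ndarray:
        return self.conc[:, j]

    def final_state(self) -> np.ndarray:
        return self.conc[-1].copy()


def default_settings(
    mechanism: Mechanism,
    medium0: Medium,
    epsilons: list[SpectralCurve],
    setup: IrradiationSetup,
    *,
    horizon: float = 10.0,
    step_fraction: float = 1e-3,
    n_record: int = 300,
) -> IntegrationSettings:
    """Choose dt and t_end from the initial rates.

    ``dt`` is set so the first step moves no species by more than
    ``step_fraction`` of the total concentration; ``t_end`` spans
    ``horizon`` characteristic times ``C_tot / max|r0|``.  ``n_record``
    evenly spaced states are kept.
    """
    ev = RateEvaluator(mechanism, epsilons, setup, medium0.spm_absorbance)
    r0 = ev.rates(medium0.concentrations)
    rmax = float(np.max(np.abs(r0)))
    c_tot = float(medium0.concentrations.sum())
    if rmax == 0.0 or c_tot == 0.0:
        return IntegrationSettings(dt=1.0, t_end=100.0, record_every=1)
    tau = c_tot / rmax
    dt = step_fraction * tau
    # stability: the initial rates miss fast modes of species absent at
    # t = 0 (a photoproduct can be far more reactive than the reactant).
    # Bound every species' pseudo-first-order depletion constant using
    # PKF <= ln10 and keep dt well inside the fastest one.
    if ev.w.shape[0]:
        kappa_step = np.log(10.0) * ev.w.sum(axis=1)
        kappa = np.zeros(mechanism.n_species)
        np.add.at(kappa, ev.from_idx, kappa_step)
        kappa_max = float(kappa.max())
        if kappa_max > 0:
            dt = min(dt, 0.1 / kappa_max)
    t_end = horizon * tau
    n_steps = int(np.ceil(t_end / dt))
    record_every = max(1, n_steps // n_record)
    return IntegrationSettings(dt=dt, t_end=t_end, record_every=record_every)


def integrate(
    mechanism: Mechanism,
    medium0: Medium,
    epsilons: list[SpectralCurve],
    setup: IrradiationSetup,
    settings: IntegrationSettings,
    stop_projected_change: float | None = None,
) -> KineticTrace:
    """Integrate the polychromatic rate law with classic RK4.

    Emits a single logged warning if the in-OSIA total absorbance reaches
    the validity limit (default 0.5) at any recorded state; aborts with a
    step report on NaN or genuinely negative concentrations.

    When ``stop_projected_change`` is given, integration truncates once the
    remaining change projected from the current rates —
    ``max_j |r_j| * (t_end - t)`` — falls below that fraction of the total
    concentration (the system is stationary for any practical purpose);
    the trace is then marked ``early_stop`` in its meta.
    """
    ev = RateEvaluator(mechanism, epsilons, setup, medium0.spm_absorbance)
    dt = settings.dt
    n_steps = int(np.ceil(settings.t_end / dt))
    rec = settings.record_every
    n_rec = n_steps // rec + 1

    c = medium0.concentrations.astype(float).copy()
    times = np.empty(n_rec)
    conc = np.empty((n_rec, mechanism.n_species))
    times[0] = 0.0
    conc[0] = c

    c_tot = float(medium0.concentrations.sum())
    lamp_on = ev.p0 > 0
    warned = False
    stopped = False
    k = 0
    for step in range(1, n_steps + 1):
        k1 = ev.rates(c)
        k2 = ev.rates(c + 0.5 * dt * k1)
        k3 = ev.rates(c + 0.5 * dt * k2)
        k4 = ev.rates(c + dt * k3)
        c = c + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)

        bad = c < 0
        if bad.any():
            worst = float(c.min())
            if worst < NEGATIVE_CLAMP:
                raise RuntimeError(
                    f"negative concentration {worst:.3e} M at step {step} "
                    f"(t = {step * dt:.6g} s); reduce dt"
                )
            c[bad] = 0.0

        if step % rec == 0:
            k += 1
            times[k] = step * dt
            conc[k] = c
            if np.any(np.isnan(c)):
                raise RuntimeError(f"NaN state at step {step} (t = {step * dt:.6g} s)")
            if not warned:
                a = ev.total_absorbance(c)
                if np.any(a[lamp_on] >= settings.warn_absorbance):
                    logger.warning(
                        "in-OSIA absorbance reached %.3g (validity limit %.2g) at t = %.6g s",
                        float(a[lamp_on].max()),
                        settings.warn_absorbance,
                        step * dt,
                    )
                    warned = True
            if stop_projected_change is not None and c_tot > 0:
                r = ev.rates(c)
                remaining = settings.t_end - step * dt
                if float(np.abs(r).max()) * remaining < stop_projected_change * c_tot:
                    stopped = True
                    break

    meta = {
        "labels": mechanism.labels,
        "dt": dt,
        "t_end": settings.t_end,
        "record_every": rec,
        "l_irr": setup.l_irr,
        "l_obs": setup.l_obs,
        "lambda_obs": setup.lambda_obs,
        "early_stop": stopped,
    }
    return KineticTrace(times=times[: k + 1], conc=conc[: k + 1], meta=meta)


def absorbance_trace(
    trace: KineticTrace,
    epsilons_at_lambda_obs: np.ndarray,
    l_obs: float,
    spm_at_lambda_obs: float = 0.0,
) -> np.ndarray:
    """Total absorbance time series at the observation wavelength:
    ``Atot(t) = sum_j eps_j(l_obs) * l_obs * C_j(t) + A_SPM(l_obs)``."""
    eps = np.asarray(epsilons_at_lambda_obs, dtype=float)
    if eps.size != trace.n_species:
        raise ValueError("one absorptivity value per species is required")
    return trace.conc @ eps * l_obs + spm_at_lambda_obs
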