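"""Kinactinometry: actinometer standardization and yield quantities.

An actinometer is standardized against a lamp by irradiating it at several
intensities, fitting each kinetic trace with the Phi-order equation and
regressing the fitted initial rates on the incident photon flux.  The
through-origin slope alpha is dimensionless and prices photons: an unknown
intensity of the *same* lamp follows as ``P0 = r0 / alpha``.

Two photon counts exist for one lamp: photons inside the actinometer OSIA
(range ``dlam``) and all emitted photons (``dlam+``).  Their ratio is
fixed by the lamp/actinometer pair through ``beta = P0(outside OSIA) /
P0(inside OSIA)``, giving the slope rescaling ``alpha_dlam = alpha_dlam+
* (1 + beta)``.  Every intensity, slope and yield value carries a
(lamp, range) tag and operations refuse to mix tags — a calibration line
standardized for one lamp and range must not price another.

Yield quantities: the photonic yield PHYD (converted amount per incident
photon, time-dependent), the efficiency PY = -r0 / P0 (time-independent;
equal to -alpha across an intensity scan) and the quantum yield of a
single-step depletion, recoverable from a fitted trace via
``Phi = -Fit:r0 / sum_l P0(l) (1 - 10^-A_X(l,0))``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .analysis_toolkit import study_system
from .phi_order_model import MultistartSettings
from .rate_engine import RateEvaluator
from .rk_integrator import IntegrationSettings, default_settings
from .spectral_core import (
    IrradiationSetup,
    LN10,
    Mechanism,
    Medium,
    SpectralCurve,
    compute_osia,
    osia_mask,
    pkf,
)
from .synth_systems import PhotoSystem

logger = logging.getLogger("phikin.kinactinometry")

__all__ = [
    "RangeTag",
    "CalibrationLine",
    "BetaFactor",
    "TaggedYield",
    "standardize",
    "beta_factor",
    "rescale_alpha",
    "unknown_intensity",
    "photonic_yield",
    "efficiency_py",
    "quantum_yield_single_step",
    "quantum_yield_general",
]

CALIBRATION_R2_MIN = 0.999


@dataclass(frozen=True)
class RangeTag:
    """Wavelength-range tag of a photon count: ``dlam`` (inside the
    actinometer OSIA) or ``dlam_plus`` (full lamp emission), with the
    explicit nm interval."""

    kind: str  # dlam | dlam_plus
    interval: tuple[int, int]

    def __post_init__(self) -> None:
        if self.kind not in ("dlam", "dlam_plus"):
            raise ValueError("range tag kind must be 'dlam' or 'dlam_plus'")

    def __str__(self) -> str:
        sym = "Δλ" if self.kind == "dlam" else "Δλ+"
        return f"{sym}:{self.interval[0]}-{self.interval[1]}nm"


@dataclass
class CalibrationLine:
    """Actinometric calibration ``r0 = alpha * P0`` (through the origin)."""

    alpha: float
    lamp_tag: str
    range_tag: RangeTag
    points: list  # (P0_i, r0_i)
    r2: float
    situation: str = ""
    beta: float | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.alpha) or self.alpha == 0.0:
            raise ValueError("calibration slope alpha must be finite and nonzero")


@dataclass(frozen=True)
class BetaFactor:
    """Out-of-OSIA to in-OSIA photon ratio of a lamp; zero iff the lamp
    support lies inside the OSIA."""

    beta: float
    lamp_tag: str
    osia_interval: tuple[int, int]

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be non-negative")


@dataclass(frozen=True)
class TaggedYield:
    """A yield value carrying its mandatory (lamp, range) provenance."""

    value: float
    lamp_tag: str
    range_tag: RangeTag
    kind: str  # phyd_reactant | phyd_product | py


def _support_interval(curve: SpectralCurve) -> tuple[int, int]:
    wl = curve.grid.wavelengths
    on = curve.values > 0
    if not on.any():
        raise ValueError("curve has empty support")
    return int(wl[on][0]), int(wl[on][-1])


def _detect_situation(
    lamp: SpectralCurve,
    act_epsilon: SpectralCurve,
    species_epsilon: SpectralCurve | None,
) -> str:
    """Classify the lamp / actinometer / species overlap.

    sit2: the lamp emits only inside the actinometer OSIA (all counted
    photons serve the reaction).  sit1: the lamp is wider than the
    actinometer OSIA (excess photons counted but unused).  sit3: the
    investigated species absorbs over a wider range than the actinometer —
    counted photons under-represent the photons the species absorbs.
    """
    lamp_lo, lamp_hi = _support_interval(lamp)
    act = compute_osia(lamp, act_epsilon)
    if not act:
        raise ValueError("lamp and actinometer do not overlap: cannot standardize")
    act_lo, act_hi = act[0][0], act[-1][1]
    if species_epsilon is not None:
        sp = compute_osia(lamp, species_epsilon)
        if sp:
            sp_lo, sp_hi = sp[0][0], sp[-1][1]
            if sp_lo < act_lo or sp_hi > act_hi:
                logger.warning(
                    "sit3: species OSIA %d-%d nm exceeds actinometer OSIA %d-%d nm; "
                    "counted photons under-represent the photons absorbed",
                    sp_lo, sp_hi, act_lo, act_hi,
                )
                return "sit3"
    if lamp_lo >= act_lo and lamp_hi <= act_hi:
        return "sit2"
    return "sit1"


def beta_factor(lamp: SpectralCurve, osia_intervals) -> BetaFactor:
    """``beta = sum_{l outside OSIA} P0(l) / sum_{l inside OSIA} P0(l)``.

    ``osia_intervals`` is a list of (lo, hi) nm intervals (inclusive) or a
    single interval.  Scale-invariant in the lamp intensity.
    """
    if isinstance(osia_intervals, tuple) and np.isscalar(osia_intervals[0]):
        osia_intervals = [osia_intervals]
    wl = lamp.grid.wavelengths
    mask = np.zeros(wl.size, dtype=bool)
    for lo, hi in osia_intervals:
        lamp.grid.index(lo), lamp.grid.index(hi)  # raise if off grid
        mask |= (wl >= lo) & (wl <= hi)
    inside = float(lamp.values[mask].sum())
    outside = float(lamp.values[~mask].sum())
    if inside == 0.0:
        raise ValueError("no lamp photons inside the OSIA: beta is undefined")
    lo_all = int(min(i[0] for i in osia_intervals))
    hi_all = int(max(i[1] for i in osia_intervals))
    return BetaFactor(beta=outside / inside, lamp_tag="", osia_interval=(lo_all, hi_all))


def rescale_alpha(alpha: float, beta: float, *, inverse: bool = False) -> float:
    """Slope rescaling between photon-count ranges:
    ``alpha_dlam = alpha_dlam+ * (1 + beta)``; ``inverse=True`` maps
    ``alpha_dlam`` back to ``alpha_dlam+``."""
    if beta < 0:
        raise ValueError("beta must be non-negative")
    return alpha / (1.0 + beta) if inverse else alpha * (1.0 + beta)


def standardize(
    system: PhotoSystem,
    p0_scales,
    *,
    target: str = "absorbance",
    range_kind: str = "dlam_plus",
    lamp_tag: str = "Lp1",
    species_epsilon: SpectralCurve | None = None,
    settings: IntegrationSettings | None = None,
    fit_settings: MultistartSettings | None = None,
) -> CalibrationLine:
    """Standardize an actinometer against its lamp (protocol steps i-viii).

    Simulates the actinometer system at each intensity scale, fits each
    trace (reactant concentration or observed total absorbance, per
    ``target``), extracts the fitted initial rates and regresses them on
    the photon count of the requested range through the origin.

    Raises if fewer than three intensities are given or if the calibration
    is not linear (r^2 < 0.999): nonlinearity signals a broken assumption
    such as absorbance drifting out of the validity range.
    """
    p0_scales = list(p0_scales)
    if len(p0_scales) < 3:
        raise ValueError("at least three intensity levels are required")
    if target not in ("absorbance", "reactant"):
        raise ValueError("target must be 'absorbance' or 'reactant'")
    if range_kind not in ("dlam", "dlam_plus"):
        raise ValueError("range_kind must be 'dlam' or 'dlam_plus'")

    lamp = system.setup.lamp
    act_eps = system.epsilons[0]
    osia = compute_osia(lamp, act_eps)
    if not osia:
        raise ValueError("lamp and actinometer do not overlap: cannot standardize")
    situation = _detect_situation(lamp, act_eps, species_epsilon)
    mask = osia_mask(lamp, act_eps)
    in_osia = float(lamp.values[mask].sum())
    full = float(lamp.values.sum())
    beta = (full - in_osia) / in_osia

    if range_kind == "dlam":
        interval = (osia[0][0], osia[-1][1])
        p0_base = in_osia
    else:
        interval = _support_interval(lamp)
        p0_base = full
    tag = RangeTag(range_kind, interval)

    if settings is None:
        # one shared time grid, set at the median intensity
        mid = system.with_lamp(lamp.scaled(float(np.median(p0_scales))))
        settings = default_settings(mid.mechanism, mid.medium0(), mid.epsilons, mid.setup)

    points = []
    for scale in p0_scales:
        sys_i = system.with_lamp(lamp.scaled(scale))
        study = study_system(sys_i, settings=settings, fit_settings=fit_settings)
        r0 = study.fit_r0_a if target == "absorbance" else float(study.fit_r0[0])
        points.append((p0_base * scale, r0))

    p0 = np.array([p for p, _ in points])
    r0 = np.array([r for _, r in points])
    alpha = float(p0 @ r0 / (p0 @ p0))
    resid = r0 - alpha * p0
    ss_tot = float(((r0 - r0.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(resid @ resid) / ss_tot
    if r2 < CALIBRATION_R2_MIN:
        raise RuntimeError(
            f"calibration is not linear (r^2 = {r2:.6f} < {CALIBRATION_R2_MIN}); "
            "check that the medium stays inside the validity range"
        )
    return CalibrationLine(
        alpha=alpha,
        lamp_tag=lamp_tag,
        range_tag=tag,
        points=points,
        r2=r2,
        situation=situation,
        beta=beta,
    )


def unknown_intensity(
    r0: float,
    line: CalibrationLine,
    *,
    lamp_tag: str | None = None,
    range_tag: RangeTag | None = None,
) -> float:
    """Price an unknown intensity of the calibrated lamp: ``P0 = r0 /
    alpha``.

    The caller's (lamp, range) tags must match the line's: a line
    standardized for one lamp and photon-count range cannot price another
    (actinometric non-transferability).
    """
    if lamp_tag is not None and lamp_tag != line.lamp_tag:
        raise ValueError(
            f"lamp tag mismatch: line was standardized for {line.lamp_tag!r}, "
            f"got {lamp_tag!r}; a calibration is specific to its lamp"
        )
    if range_tag is not None and range_tag != line.range_tag:
        raise ValueError(
            f"range tag mismatch: line prices photons over {line.range_tag}, "
            f"got {range_tag}"
        )
    p0 = r0 / line.alpha
    if p0 < 0:
        raise ValueError("negative intensity: r0 and alpha have inconsistent signs")
    return float(p0)


def photonic_yield(
    c0: float,
    c_t: float,
    p0_total: float,
    t: float,
    *,
    kind: str = "reactant",
    lamp_tag: str = "Lp",
    range_tag: RangeTag | None = None,
) -> TaggedYield:
    """Photonic yield PHYD: converted amount per photon incident over
    ``t`` seconds.

    Reactant variant: ``(C_X(0) - C_X(t)) / (P0 t)``; product variant:
    ``C_Yend(t) / (P0 t)``.  Time-dependent and relative — the photon
    count's range tag (OSIA or full emission) is mandatory provenance.
    """
    if t <= 0:
        raise ValueError("irradiation time must be positive")
    if p0_total <= 0:
        raise ValueError("photon flux must be positive")
    if kind not in ("reactant", "product"):
        raise ValueError("kind must be 'reactant' or 'product'")
    converted = (c0 - c_t) if kind == "reactant" else c_t
    tag = range_tag or RangeTag("dlam", (0, 0))
    return TaggedYield(
        value=float(converted / (p0_total * t)),
        lamp_tag=lamp_tag,
        range_tag=tag,
        kind=f"phyd_{kind}",
    )


def efficiency_py(r0: float, p0_total: float, *, kind: str = "concentration") -> float:
    """Photoreaction efficiency ``PY = -r0 / P0``: time-independent,
    dimensionless.  For absorbance-derived rates the sign is dropped
    (``|r0_A| / P0``) since a growing product band flips it."""
    if p0_total <= 0:
        raise ValueError("photon flux must be positive")
    return abs(r0) / p0_total if kind == "absorbance" else -r0 / p0_total


def quantum_yield_single_step(
    fit_r0_x: float,
    lamp: SpectralCurve,
    epsilon_x: SpectralCurve,
    l_irr: float,
    c_x0: float,
) -> float:
    """Quantum yield of a single-step depletion X -> Y1 from a fitted
    trace: ``Phi = -Fit:r0_X / sum_l P0(l) (1 - 10^-A_X(l,0))``.

    Assumes the declared mechanism is a pure depletion and Phi is
    wavelength-invariant; a result above 1 (logged) flags a violated
    assumption.
    """
    a_x0 = epsilon_x.values * l_irr * c_x0
    denom = float((lamp.values * -np.expm1(-a_x0 * LN10)).sum())
    if denom <= 0:
        raise ValueError("the reactant absorbs no lamp photons at t = 0")
    phi = -fit_r0_x / denom
    if phi > 1.0:
        logger.warning(
            "quantum yield %.4f exceeds 1: the single-step / wavelength-invariant "
            "assumption is likely violated", phi,
        )
    return float(phi)


def quantum_yield_general(
    mechanism: Mechanism,
    medium: Medium,
    epsilons: list[SpectralCurve],
    setup: IrradiationSetup,
    rate_x: float,
    *,
    target_step: int = 0,
) -> float:
    """General quantum-yield expression for a reaction step X -> Yj at a
    stated time (calculation-only: every other quantum-yield profile and
    every absorbed-photon term must be supplied through the mechanism).

    Solves the reactant rate law for the target step's (assumed
    wavelength-invariant) quantum yield: subtracts the other forward
    branches and adds back the reverse contributions, normalized by the
    photons X absorbs.  Reduces to the single-step formula at t = 0 for a
    pure depletion.
    """
    steps = mechanism.steps
    if not (0 <= target_step < len(steps)):
        raise ValueError("target_step out of range")
    if steps[target_step].from_species != 0:
        raise ValueError("the target step must start at the reactant X")
    ev = RateEvaluator(mechanism, epsilons, setup, medium.spm_absorbance)
    conc = medium.concentrations
    f = pkf(ev.total_absorbance(conc))
    # Pa_j(lambda) = eps_j l C_j P0 PKF
    pa = ev.eps * ev.l_irr * conc[:, None] * ev.p0 * f  # (nsp, nl)
    pa_x = float(pa[0].sum())
    if pa_x == 0.0:
        raise ValueError("the reactant absorbs no photons in this state")
    num = -rate_x
    for i, step in enumerate(steps):
        phi = step.phi.values
        if step.from_species == 0 and i != target_step:
            num -= float((phi * pa[0]).sum())
        if step.to_species == 0:
            num += float((phi * pa[step.from_species]).sum())
    return float(num / pa_x)
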