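"""The Phi-order model equation and kinetic-trace fitting.

Photoreaction traces, under monochromatic or polychromatic light, follow
the log-exp "Phi-order" shape::

    y(t) = y_inf + sum_i  omega_i * Log10(1 + cc * exp(-k_i t))

with one shared ``cc`` per trace and one (omega_i, k_i) pair per
mono-Phi-order term.  The analytic rate and the closed-form initial rate

    r(t)  = -sum_i omega_i cc k_i e^{-k_i t} / ((1 + cc e^{-k_i t}) ln10)
    r0    = -sum_i omega_i cc k_i / ((1 + cc) ln10)

make the fitted initial rate the invariant, physically usable metric:
different multistart optima of equal quality (the identifiability issue)
share the same r0 even when their individual (omega, cc, k) values differ.

Fitting uses separable least squares: for fixed (cc, k_1..k_n) the model is
linear in (y_inf, omega_i), which are eliminated by a linear solve inside
the residual.  The nonlinear parameters are optimized by
scipy.optimize.least_squares from a deterministic initial guess plus seeded
random multistarts; ties in SSE are broken toward the smallest sum of rate
constants so results are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .spectral_core import LN10, Mechanism

__all__ = [
    "PhiOrderFit",
    "MultistartSettings",
    "phi_order",
    "model_eval",
    "model_rate",
    "initial_rate_from_fit",
    "fit_trace",
    "rk_initial_rate",
]

# The model itself admits any cc > -1 (log domain).  The *fitter* restricts
# cc to (0, inf) via cc = exp(theta): the trace shapes the model describes
# arise with cc = 10^A - 1 >= 0, and the cc -> -1+ corner admits degenerate
# optima whose value matches the data while the closed-form initial rate
# diverges (a spurious near-singular transient between t = 0 and the first
# sample).  Negative-cc shapes are reachable with positive cc and negated
# omegas, so no expressiveness is lost.


@dataclass(frozen=True)
class MultistartSettings:
    """Multistart protocol: one deterministic start plus ``n_starts - 1``
    seeded log-space perturbations of (cc, k)."""

    n_starts: int = 20
    seed: int = 1234
    perturbation: float = 1.0  # std-dev of the log-space jitter
    #: stop early once the RMSD falls below this fraction of the data range
    rmsd_stop_fraction: float = 1e-7


@dataclass
class PhiOrderFit:
    """Fitted Phi-order parameters and fit-quality metrics.

    ``c_inf`` is the asymptotic value (a concentration for species traces,
    dimensionless for absorbance traces); ``cc`` is shared across terms.
    ``multistart`` records (sse, r0, cc, ks, omegas) for every optimum so
    the identifiability spread can be inspected.
    """

    c_inf: float
    cc: float
    omegas: np.ndarray
    ks: np.ndarray
    target_kind: str = "concentration"
    r2: float = float("nan")
    sse: float = float("nan")
    rmsd: float = float("nan")
    multistart: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.omegas = np.atleast_1d(np.asarray(self.omegas, dtype=float))
        self.ks = np.atleast_1d(np.asarray(self.ks, dtype=float))
        if self.omegas.size != self.ks.size:
            raise ValueError("omegas and ks must have the same length")
        if np.any(self.ks <= 0):
            raise ValueError("rate constants k_i must be positive")
        if self.cc <= -1.0:
            raise ValueError("cc must exceed -1 (log domain)")

    @property
    def n_terms(self) -> int:
        return self.ks.size

    @property
    def r0(self) -> float:
        return initial_rate_from_fit(self)


def phi_order(t, c_inf, cc, omegas, ks):
    """Evaluate ``c_inf + sum_i omega_i Log10(1 + cc e^{-k_i t})``."""
    if cc <= -1.0:
        raise ValueError("cc must exceed -1 (log domain)")
    t = np.asarray(t, dtype=float)
    omegas = np.atleast_1d(omegas)
    ks = np.atleast_1d(ks)
    e = np.exp(-np.multiply.outer(t, ks))
    out = c_inf + np.log10(1.0 + cc * e) @ omegas
    return out if out.ndim else float(out)


def model_eval(fit: PhiOrderFit, t):
    """Model value(s) at time(s) ``t``."""
    return phi_order(t, fit.c_inf, fit.cc, fit.omegas, fit.ks)


def model_rate(fit: PhiOrderFit, t):
    """Analytic time derivative of the Phi-order model."""
    t = np.asarray(t, dtype=float)
    e = np.exp(-np.multiply.outer(t, fit.ks))
    terms = fit.omegas * fit.cc * fit.ks * e / (1.0 + fit.cc * e)
    out = -terms.sum(axis=-1) / LN10
    return out if out.ndim else float(out)


def initial_rate_from_fit(fit: PhiOrderFit) -> float:
    """Closed-form initial rate ``Fit:r0 = -sum_i omega_i cc k_i /
    ((1 + cc) ln10)``."""
    return float(-(fit.omegas * fit.ks).sum() * fit.cc / ((1.0 + fit.cc) * LN10))


def rk_initial_rate(times: np.ndarray, values: np.ndarray) -> float:
    """Initial slope of a numerically integrated trace (``RK:r0``).

    Four-point one-sided finite difference on the first uniformly spaced
    samples: ``(-11 y0 + 18 y1 - 9 y2 + 2 y3) / (6 h)``.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size < 4:
        raise ValueError("at least four samples are needed for RK:r0")
    h = t[1] - t[0]
    if not np.allclose(np.diff(t[:4]), h, rtol=1e-8):
        raise ValueError("the first four samples must be uniformly spaced")
    return float((-11.0 * y[0] + 18.0 * y[1] - 9.0 * y[2] + 2.0 * y[3]) / (6.0 * h))


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _basis(t: np.ndarray, cc: float, ks: np.ndarray) -> np.ndarray:
    b = np.empty((t.size, ks.size + 1))
    b[:, 0] = 1.0
    b[:, 1:] = np.log10(1.0 + cc * np.exp(-np.multiply.outer(t, ks)))
    return b


def _projected_residual(theta: np.ndarray, t: np.ndarray, y: np.ndarray, log_k_cap: float):
    # clip the log-space parameters so wild multistart jitter cannot
    # overflow exp() and poison the linear solve; k is capped relative to
    # the sampling rate because a term that decays entirely before the
    # second sample is unidentifiable from the data yet can absorb the
    # t = 0 sample alone and corrupt the closed-form initial rate
    cc = np.exp(np.clip(theta[0], -700.0, 50.0))
    ks = np.exp(np.clip(theta[1:], -700.0, log_k_cap))
    b = _basis(t, cc, ks)
    coef, *_ = np.linalg.lstsq(b, y, rcond=None)
    res = b @ coef - y
    return res, cc, ks, coef


def _half_life_guess(t: np.ndarray, y: np.ndarray) -> float:
    """Time at which the trace has covered half of its total excursion."""
    dy = np.abs(y - y[-1])
    if dy[0] == 0.0:
        return t[-1] / 2 if t[-1] > 0 else 1.0
    idx = np.argmax(dy <= 0.5 * dy[0])
    t_half = t[idx] if idx > 0 else t[1] if t.size > 1 else 1.0
    return float(max(t_half, t[1] if t.size > 1 else 1e-6))


def fit_trace(
    times: np.ndarray,
    values: np.ndarray,
    n_terms: int = 1,
    settings: MultistartSettings | None = None,
    *,
    target_kind: str = "concentration",
    mechanism: Mechanism | None = None,
    species: int | None = None,
    cc_guess: float | None = None,
) -> PhiOrderFit:
    """Fit a kinetic trace with the Phi-order model equation.

    Parameters
    ----------
    times, values
        The trace.  At least ``5 * (2 * n_terms + 2)`` points are required.
    n_terms
        Number of mono-Phi-order terms.  When ``mechanism`` is given the
        count is checked against the mechanistic bound: the number of steps
        touching the species (or the total step count for the absorbance
        trace and for cyclic mechanisms).
    settings
        Multistart protocol; defaults to 20 starts seeded at 1234.
    cc_guess
        Optional starting value for ``cc``; for absorbance traces the
        default is ``10^A(0) - 1``, for concentration traces 1.

    Returns
    -------
    PhiOrderFit with the best-SSE optimum; all multistart optima are kept
    on the fit for identifiability inspection.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.ndim != 1 or t.shape != y.shape:
        raise ValueError("times and values must be 1-D arrays of equal length")
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    if t.size < 5 * (2 * n_terms + 2):
        raise ValueError(
            f"need at least {5 * (2 * n_terms + 2)} points to fit {n_terms} term(s), "
            f"got {t.size}"
        )
    if mechanism is not None:
        bound = mechanism.term_bound(species)
        if n_terms > bound:
            raise ValueError(
                f"n_terms = {n_terms} exceeds the mechanistic bound {bound} "
                f"for {'the absorbance trace' if species is None else f'species {species}'}"
            )
    settings = settings or MultistartSettings()

    scale = float(np.ptp(y))
    if scale == 0.0:
        # flat trace: the model degenerates to a constant
        fit = PhiOrderFit(
            c_inf=float(y[0]), cc=0.0, omegas=np.zeros(n_terms),
            ks=np.ones(n_terms), target_kind=target_kind,
            r2=1.0, sse=0.0, rmsd=0.0,
        )
        return fit

    if cc_guess is None:
        cc_guess = 10.0 ** float(y[0]) - 1.0 if target_kind == "absorbance" else 1.0
        cc_guess = min(max(cc_guess, 0.05), 1e3)
    k0 = np.log(2.0) / _half_life_guess(t, y)
    if n_terms == 1:
        k_guess = np.array([k0])
    else:
        k_guess = k0 * np.logspace(-0.5 * (n_terms - 1), 0.5 * (n_terms - 1), n_terms, base=3.0)

    theta0 = np.concatenate(([np.log(cc_guess)], np.log(k_guess)))
    rng = np.random.default_rng(settings.seed)
    # fastest identifiable decay: a few e-folds within the first interval
    log_k_cap = float(np.log(5.0 / (t[1] - t[0]))) if t[1] > t[0] else 50.0

    best = None
    results = []
    for start in range(settings.n_starts):
        theta_init = theta0 if start == 0 else theta0 + rng.normal(
            0.0, settings.perturbation, theta0.size
        )
        try:
            sol = least_squares(
                lambda th: _projected_residual(th, t, y, log_k_cap)[0],
                theta_init,
                method="lm",
                xtol=1e-15,
                ftol=1e-15,
                gtol=1e-15,
                max_nfev=400 * theta0.size,
            )
        except (ValueError, np.linalg.LinAlgError):
            continue
        res, cc, ks, coef = _projected_residual(sol.x, t, y, log_k_cap)
        sse = float(res @ res)
        omegas = coef[1:]
        r0 = float(-(omegas * ks).sum() * cc / ((1.0 + cc) * LN10))
        results.append({"sse": sse, "r0": r0, "cc": cc, "ks": ks, "omegas": omegas,
                        "c_inf": float(coef[0])})
        if (
            best is None
            or sse < best["sse"] * (1.0 - 1e-12)
            or (abs(sse - best["sse"]) <= 1e-12 * max(sse, best["sse"])
                and ks.sum() < best["ks"].sum())
        ):
            best = results[-1]
        if best is not None and np.sqrt(best["sse"] / t.size) < settings.rmsd_stop_fraction * scale:
            break

    if best is None:
        raise RuntimeError(
            "Phi-order fit failed to converge from any multistart "
            f"({settings.n_starts} starts, {n_terms} term(s))"
        )

    fitted = _basis(t, best["cc"], best["ks"]) @ np.concatenate(
        ([best["c_inf"]], best["omegas"])
    )
    sse = best["sse"]
    rmsd = float(np.sqrt(sse / t.size))
    sf = float(np.std(fitted))
    if sf == 0.0 or np.std(y) == 0.0:
        r2 = 1.0 if rmsd <= 1e-12 * scale else 0.0
    else:
        r2 = float(np.corrcoef(fitted, y)[0, 1] ** 2)

    return PhiOrderFit(
        c_inf=best["c_inf"],
        cc=best["cc"],
        omegas=best["omegas"],
        ks=best["ks"],
        target_kind=target_kind,
        r2=r2,
        sse=sse,
        rmsd=rmsd,
        multistart=results,
    )
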