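"""Derived studies: concentration scans, spectator competition, WROR
location, LED series and photostationary ratios."""

import numpy as np
import pytest

from phikin.analysis_toolkit import (
    REFERENCE_C0_GRID,
    c0_scan,
    led_scan,
    pss_ratios,
    spm_scan,
    wror_profile,
)
from phikin.rate_engine import initial_reactant_rate
from phikin.rk_integrator import IntegrationSettings, default_settings, integrate
from phikin.spectral_core import SpectralCurve, WavelengthGrid, build_mechanism
from phikin.synth_systems import (
    BandSpec,
    LampSpec,
    PhiSpec,
    PhotoSystem,
    SystemSpec,
    gaussian_band,
    generate,
)

GRID = WavelengthGrid(300, 500)


@pytest.fixture(scope="module")
def m2_system():
    """Absorbing-product depletion under a broadband lamp."""
    return generate(
        SystemSpec(
            mechanism="m2",
            bands=(BandSpec(380, 40, 1e4), BandSpec(430, 40, 6e3)),
            phis=(PhiSpec(0.4, "constant"),),
            lamp=LampSpec(kind="broadband", center=390, fwhm=60, total=1e-6),
            c_x0=3e-5,
            lambda_obs=380.0,
        )
    )


@pytest.fixture(scope="module")
def divergent_system():
    """Two separately-addressable reactant bands feeding different
    products (chromatic orthogonality layout): the blue band drives
    X -> Y1, the red band drives X -> Y2."""
    wl = GRID.wavelengths
    eps_x = SpectralCurve(
        GRID,
        gaussian_band(GRID, 335, 30, 9e3) + gaussian_band(GRID, 390, 30, 9e3),
        "absorptivity",
    )
    eps_y1 = SpectralCurve(GRID, gaussian_band(GRID, 450, 30, 4e3), "absorptivity")
    eps_y2 = SpectralCurve(GRID, gaussian_band(GRID, 460, 30, 4e3), "absorptivity")
    phi_blue = SpectralCurve(
        GRID, 0.4 / (1.0 + np.exp((wl - 362.0) / 4.0)), "quantum_yield"
    )
    phi_red = SpectralCurve(
        GRID, 0.4 / (1.0 + np.exp(-(wl - 362.0) / 4.0)), "quantum_yield"
    )
    mech = build_mechanism("phi_shaped", [phi_blue, phi_red])
    spec = SystemSpec(
        mechanism="phi_shaped",
        bands=(None, None, None),
        phis=(None, None),
        lamp=LampSpec(kind="flat", lo=310, hi=420, total=1e-6),
        c_x0=2e-5,
        lambda_obs=335.0,
    )
    from phikin.synth_systems import make_lamp
    from phikin.spectral_core import IrradiationSetup

    lamp = make_lamp(GRID, spec.lamp)
    setup = IrradiationSetup(lamp=lamp, lambda_obs=335.0)
    return PhotoSystem(spec, mech, [eps_x, eps_y1, eps_y2], setup)


class TestC0Scan:
    def test_default_grid_is_the_reference_seven_points(self):
        assert REFERENCE_C0_GRID == (1.3e-6, 1.3e-5, 3e-5, 5e-5, 7e-5, 9e-5, 1e-4)

    def test_auto_photostabilization_signature(self, m2_system):
        res = c0_scan(m2_system, (1.3e-6, 1e-5, 4e-5, 1e-4))
        assert res.extras["auto_photostabilization"]
        r0 = np.abs(res.table["fit_r0_X"].to_numpy())
        conv = res.table["conversion"].to_numpy()
        assert np.all(np.diff(r0) > 0)
        assert np.all(np.diff(conv) < 0)

    def test_monochromatic_initial_rate_ratio(self, mono_m1):
        """r0 between A0 = 1 and A0 = 0.01 follows (1-10^-1)/(1-10^-0.01)."""
        s = mono_m1
        r_hi = initial_reactant_rate(s.mechanism, 1e-4, s.epsilons, s.setup)
        r_lo = initial_reactant_rate(s.mechanism, 1e-6, s.epsilons, s.setup)
        expected = (1 - 10**-1) / (1 - 10**-0.01)
        assert r_hi / r_lo == pytest.approx(expected, rel=1e-10)
        assert r_hi / r_lo == pytest.approx(39.5, rel=2e-3)

    def test_dilute_limit_half_time_concentration_independent(self, mono_m1):
        """As A -> 0 the photokinetic factor saturates at ln10 and the
        kinetics become first order: the half-time loses its c0 dependence."""
        halves = []
        for c0 in (1e-7, 2e-7):
            s = mono_m1.with_c_x0(c0)
            settings = IntegrationSettings(dt=2.0, t_end=1200.0, record_every=1)
            tr = integrate(s.mechanism, s.medium0(), s.epsilons, s.setup, settings)
            idx = np.argmax(tr.conc[:, 0] <= c0 / 2)
            halves.append(tr.times[idx])
        assert halves[0] == pytest.approx(halves[1], rel=5e-3)


class TestSpmScan:
    def test_zero_spm_baseline_has_zero_reduction(self, m2_system, flat_curve):
        spm = flat_curve(0.0, "absorbance")
        res = spm_scan(m2_system, [spm])
        row = res.table.iloc[1]
        for lab in ("X", "Y1", "A"):
            assert row[f"pct_reduction_{lab}"] == pytest.approx(0.0, abs=1e-6)

    def test_spm_outside_osia_changes_nothing(self, m2_system, flat_curve):
        # absorber far to the blue of both the lamp band and the species
        spm = flat_curve(0.8, "absorbance", lo=300, hi=310)
        res = spm_scan(m2_system, [spm])
        row = res.table.iloc[1]
        for lab in ("X", "Y1"):
            assert row[f"pct_reduction_{lab}"] == pytest.approx(0.0, abs=1e-3)

    def test_in_osia_spm_reduces_every_rate(self, m2_system, flat_curve):
        spm = flat_curve(0.4, "absorbance", lo=350, hi=430)
        res = spm_scan(m2_system, [spm])
        row = res.table.iloc[1]
        for lab in ("X", "Y1"):
            assert row[f"pct_reduction_{lab}"] > 5.0

    def test_chromatic_orthogonality_selectivity(self, divergent_system):
        """A spectator shading only the red reactant band suppresses the
        red-driven product far more than the blue-driven one."""
        spm = SpectralCurve(GRID, gaussian_band(GRID, 390, 25, 0.6), "absorbance")
        res = spm_scan(divergent_system, [spm])
        row = res.table.iloc[1]
        assert row["pct_reduction_Y2"] > 3 * row["pct_reduction_Y1"]
        assert row["pct_reduction_Y2"] > 20.0


class TestWror:
    def test_constant_phi_centers_window_on_absorption_maximum(self):
        eps = SpectralCurve(GRID, gaussian_band(GRID, 400, 40, 1e4), "absorptivity")
        phi = SpectralCurve(GRID, np.full(len(GRID), 0.5), "quantum_yield")
        prof = wror_profile(eps, [phi])
        assert prof.peak_wavelength == 400
        lo, hi = prof.window
        assert lo < 400 < hi
        assert (400 - lo) == pytest.approx(hi - 400, abs=1)

    def test_zero_phi_subregion_excluded(self):
        """Absorption without quantum yield drives nothing: that region
        falls outside the reactivity window."""
        wl = GRID.wavelengths
        eps = SpectralCurve(GRID, gaussian_band(GRID, 360, 60, 1e4), "absorptivity")
        phi = SpectralCurve(
            GRID, 0.5 / (1.0 + np.exp(-(wl - 360.0) / 5.0)), "quantum_yield"
        )
        prof = wror_profile(eps, [phi])
        lo, hi = prof.window
        assert lo > 330  # the blue absorption flank (phi ~ 0) is excluded
        assert prof.peak_wavelength > 360

    def test_all_zero_score_reports_no_active_region(self, caplog):
        eps = SpectralCurve(GRID, gaussian_band(GRID, 400, 40, 1e4), "absorptivity")
        phi = SpectralCurve(GRID, np.zeros(len(GRID)), "quantum_yield")
        with caplog.at_level("WARNING"):
            prof = wror_profile(eps, [phi])
        assert prof.window is None

    def test_score_tracks_single_wavelength_initial_rates(self, mono_m1):
        """At low absorbance, per-wavelength r0 under equal photons is
        proportional to eps(l) * Phi(l)."""
        s = mono_m1.with_c_x0(1e-6)
        prof = wror_profile(s.epsilons[0], [s.mechanism.steps[0].phi])
        wls = [int(w) for w in range(350, 451, 10)]
        r0 = []
        for lam in wls:
            vals = np.zeros(len(GRID))
            vals[GRID.index(lam)] = 1e-6
            lamp = SpectralCurve(GRID, vals, "lamp_intensity")
            r0.append(-initial_reactant_rate(s.mechanism, 1e-6, s.epsilons, s.with_lamp(lamp).setup))
        score = [prof.score[GRID.index(w)] for w in wls]
        r = np.corrcoef(r0, score)[0, 1]
        assert r**2 > 0.999


class TestLedScan:
    def test_led_outside_band_support_is_inert(self):
        s = generate(
            SystemSpec(
                mechanism="m2",
                bands=(BandSpec(400, 25, 1e4), BandSpec(350, 25, 5e3)),
                phis=(PhiSpec(0.4, "constant"),),
                lamp=LampSpec(kind="broadband", center=400, fwhm=40, total=1e-6),
                c_x0=2e-5,
                lambda_obs=400.0,
            )
        )
        res = led_scan(s, [400.0, 490.0], led_fwhm=10.0)
        r_on = abs(res.table.loc[0, "fit_r0_X"])
        r_off = abs(res.table.loc[1, "fit_r0_X"])
        assert r_off < 1e-6 * r_on

    def test_symmetric_leds_give_equal_rates(self):
        s = generate(
            SystemSpec(
                mechanism="m2",
                bands=(BandSpec(400, 40, 1e4), BandSpec(400, 40, 5e3)),
                phis=(PhiSpec(0.4, "constant"),),
                lamp=LampSpec(kind="broadband", center=400, fwhm=40, total=1e-6),
                c_x0=2e-5,
                lambda_obs=400.0,
            )
        )
        res = led_scan(s, [380.0, 420.0], led_fwhm=20.0)
        r1, r2 = np.abs(res.table["fit_r0_X"].to_numpy())
        assert r1 == pytest.approx(r2, rel=1e-3)

    def test_best_led_matches_score_argmax(self):
        """The empirical WROR center (argmax LED) lands within one LED
        half-width of the intrinsic eps*Phi argmax."""
        s = generate(
            SystemSpec(
                mechanism="m2",
                bands=(BandSpec(400, 40, 1e4), BandSpec(460, 30, 4e3)),
                phis=(PhiSpec(0.5, "rising", 400, 12),),
                lamp=LampSpec(kind="broadband", center=400, fwhm=60, total=1e-6),
                c_x0=2e-5,
                lambda_obs=400.0,
            )
        )
        prof = wror_profile(s.epsilons[0], [s.mechanism.steps[0].phi])
        centers = [360.0, 380.0, 400.0, 420.0, 440.0]
        res = led_scan(s, centers, led_fwhm=20.0)
        assert abs(res.extras["best_center"] - prof.peak_wavelength) <= 10.0 + 1.0


class TestPssRatios:
    def test_monochromatic_reversible_ratio(self, mono_m3):
        s = mono_m3
        settings = default_settings(
            s.mechanism, s.medium0(), s.epsilons, s.setup,
            horizon=80.0, step_fraction=5e-3,
        )
        tr = integrate(s.mechanism, s.medium0(), s.epsilons, s.setup, settings)
        res = pss_ratios(tr)
        assert res["ratios"]["Y1/X"] == pytest.approx(4.0, rel=1e-4)

    def test_full_conversion_flagged_infinite(self, mono_m1):
        s = mono_m1
        settings = default_settings(
            s.mechanism, s.medium0(), s.epsilons, s.setup,
            horizon=200.0, step_fraction=5e-3,
        )
        tr = integrate(s.mechanism, s.medium0(), s.epsilons, s.setup, settings)
        res = pss_ratios(tr)
        assert "X" in res["fully_converted"]
        assert res["ratios"]["Y1/X"] == float("inf")

    def test_non_stationary_trace_rejected(self, mono_m3):
        s = mono_m3
        settings = default_settings(
            s.mechanism, s.medium0(), s.epsilons, s.setup, horizon=0.5
        )
        tr = integrate(s.mechanism, s.medium0(), s.epsilons, s.setup, settings)
        with pytest.raises(ValueError, match="stationar"):
            pss_ratios(tr)

    def test_ratios_invariant_across_c0_grid(self, mono_m3):
        """Final-state composition ratios do not depend on C_X0."""
        ratios = []
        for c0 in REFERENCE_C0_GRID:
            s = mono_m3.with_c_x0(c0)
            settings = default_settings(
                s.mechanism, s.medium0(), s.epsilons, s.setup,
                horizon=80.0, step_fraction=5e-3,
            )
            tr = integrate(s.mechanism, s.medium0(), s.epsilons, s.setup, settings)
            ratios.append(pss_ratios(tr)["ratios"]["Y1/X"])
        ratios = np.array(ratios)
        assert np.ptp(ratios) / ratios.mean() <= 1e-3
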