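# Methods

## Model and assumptions

`phikin` models unimolecular photoreactions in a well-stirred, slab-shaped
medium under a collimated polychromatic beam.  The state is the vector of
species concentrations; each photostep `Yj → Yj'` converts one species into
another with a wavelength-dependent quantum yield, driven by the photons
the *source* species absorbs at each wavelength.  All spectral quantities
live on a shared integer grid with a fixed 1-nm step, and the wavelength
integral of the rate law is evaluated as a plain sum over that grid — lamp
values are photons-per-step, so no Δλ weight appears.

Assumptions inherited from this formulation:

* Beer–Lambert additivity of absorbances, valid only inside the linearity
  range of each species (total absorbance below ≈ 0.5 within the overlap
  of lamp and absorption; the integrator logs a warning when a trace
  leaves this zone but does not stop);
* no reflection, scattering, emission or radiative-transfer geometry;
* no thermal (dark) reaction steps and no bimolecular chemistry —
  mechanisms are pure interconversion graphs, so total concentration is
  conserved exactly;
* spectator molecules are thermally and photochemically inert: only their
  summed absorbance enters, as a constant competition term in the
  photokinetic factor.

## Key quantities

* **Photokinetic factor** `PKF(A) = (1 − 10^−A)/A`, the shape factor that
  converts absorbance into absorbed-photon fraction; `→ ln10` as `A → 0`.
  Below `A = 10⁻⁶` a three-term series is used to avoid 0/0 cancellation
  (the switch is continuous to better than 1e-12 relative).
* **OSIA** — the overlap section of irradiation and absorption: grid
  wavelengths where lamp and absorptivity are both strictly positive.  No
  numeric threshold defines the edges; strictly-positive support is the
  convention, and the synthetic generator truncates Gaussian tails below
  1e-6 of peak to zero so supports are finite.
* **Initial rates** are computed three ways and cross-checked: from the
  rate law at t = 0 (`Theo`), by a four-point one-sided finite difference
  on step-resolution early samples of the integration (`RK`), and from the
  closed form of the fitted Φ-order parameters (`Fit`).

## Numerical integration

Classic fixed-step RK4 (no adaptivity — reproducibility over cleverness).
The automatic step chooser sets

* `dt = 1e-3 · C_tot / max_j |r_j(0)|` (≤ 0.1% of the total concentration
  moves per step at the start), further bounded by `dt ≤ 0.1/κ_max`, where
  `κ_j = ln10 · Σ_steps-from-j Σ_λ Φ ε_j l P0` bounds each species'
  pseudo-first-order depletion constant.  The second bound matters when a
  photoproduct is far more reactive than the reactant: the t = 0 rates
  cannot see that mode, and without the bound the first step can go
  unstable.
* `t_end = 10 · C_tot / max|r(0)|`, with ~300 evenly recorded states.
* When the projected remaining change `max_j|r_j|·(t_end − t)` falls below
  `1e-7·C_tot`, the run is truncated as stationary and re-recorded over
  the truncated window.  This matters for nearly photostable systems whose
  dynamics finish orders of magnitude before the nominal window; recording
  them on the nominal grid would miss the entire transient.

Concentrations in `[−1e-15, 0)` are clamped to zero (float noise); larger
negatives abort with a step report.  Mass conservation along catalog
traces holds to ~1e-15 relative, comfortably inside the 1e-10 target.

## Φ-order fitting

`C(t) = C∞ + Σᵢ ωᵢ·Log10(1 + cc·e^(−kᵢt))`, one shared `cc` per trace.
The number of terms per species trace defaults to the mechanistic bound:
the number of photosteps touching the species, relaxed to the total step
count for mechanisms containing a directed cycle of length ≥ 3;
total-absorbance traces use the total step count.  Callers may request
fewer terms; more than the bound is rejected.

The fit is separable least squares (variable projection): for fixed
`(cc, k₁..kₙ)` the model is linear in `(C∞, ωᵢ)`, which are eliminated by
a linear solve inside the residual, leaving a small nonlinear problem over
`(log cc, log kᵢ)` solved by Levenberg–Marquardt.  Design choices:

* `kᵢ = exp(θᵢ)` enforces positivity; `cc = exp(θ_cc)` enforces `cc > 0`.
  The model itself is defined for any `cc > −1`, but the fitter restricts
  to positive `cc`: physical Φ-order traces have `cc = 10^A − 1 ≥ 0`,
  negative-`cc` shapes are reachable by negating ω, and the `cc → −1⁺`
  corner admits degenerate optima that match the samples while the
  closed-form initial rate diverges through the `1/(1+cc)` factor.
* `kᵢ` is capped at `5 / (first sampling interval)`: a term decaying
  entirely before the second sample is unidentifiable from the data, yet
  can absorb the t = 0 sample alone and corrupt the initial rate.
* Initial guesses: `k` log-spaced around `ln2 / t_half` of the trace,
  `cc = 10^{A(0)} − 1` for absorbance traces and 1 for concentration
  traces; 20 multistarts (one deterministic + 19 seeded log-space
  perturbations, default seed 1234).  Ties in SSE break toward the
  smallest `Σk` for determinism.  The multistart loop stops early once
  the RMSD falls below 1e-7 of the data range.
* Metrics: `r²` is the squared Pearson correlation of fitted vs simulated
  series; SSE and RMSD are in data units.

Identifiability: distinct optima of equal quality differ in their
individual `(ω, cc, k)` values, but share the initial rate — the fit
object retains every multistart optimum so this spread can be inspected.

## Synthetic systems

The generator emulates realistic spectra with Gaussian absorptivity bands
(peak 10³–3·10⁴ M⁻¹cm⁻¹), constant or logistic (sigmoid) quantum-yield
profiles (plateaus 0.05–0.9), and broadband/LED Gaussian, flat or
monochromatic lamps normalized to a stated photon budget (default total
10⁻⁶ einstein s⁻¹ dm⁻³ over a 300–500 nm grid — a low-irradiance
photostability setup).  Catalog mechanisms: single-step depletion with
transparent (`m1`) or absorbing (`m2`) product, photoreversible `m3`,
doubly photoreversible `m4` (Y1 ⇌ X ⇌ Y2), the diarylethene-like
photochrome `m5` (UV-driven reversible pair plus a spectrally separate
visible back-channel), the divergent branch `phi_shaped` (Y3 ← X → Y1) and
tri-/tetra-cyclic graphs (the tetracycle carries six steps: the ring plus
two cross-links).

Random draws use one explicitly passed seeded generator: band centers
330–460 nm and FWHM 25–60 nm uniform, absorptivity peaks and initial
concentrations (10⁻⁶–10⁻⁴ M) log-uniform over their two-decade ranges,
lamp centered near the reactant band so the OSIA is never empty.  The
drawn concentration is capped so that the initial reactant absorbance
stays at or below 0.45 over the irradiation path — the model's validity
zone; without the cap the upper corner of the concentration × absorptivity
ranges would start the simulation outside the regime the rate law
describes.

What the generator does **not** emulate: measurement noise, baseline
drift, instrument bandwidth, vibronic structure, overlapping impurity
bands, or Beer–Lambert deviations at high concentration.  Passing tests
therefore demonstrate correctness of the numerics and the internal
consistency of the framework on idealized smooth systems, not robustness
to real instrument data.

## Analyses

* **Concentration scans** use the seven-point grid 1.3·10⁻⁶ … 10⁻⁴ M and
  one shared time grid chosen at the largest (slowest-converting)
  concentration, so fractional conversions are comparable.  The
  auto-photostabilization signature — |r0_X| strictly increasing while
  conversion strictly decreases — is flagged on the scan result.
* **Spectator scans** report percent reductions of each fitted initial
  rate against the spectator-free baseline run under identical settings.
* **WROR**: the reactivity score is `ε_X(λ)·Σ_j Φ_X→Yj(λ)`; the reported
  window is the contiguous region around the global maximum where the
  score stays within 95% of the peak (the fraction is a package
  convention, adjustable by argument).  The LED scan estimates the same
  quantity empirically with Gaussian LED bands rescaled to a common
  photon budget.
* **Photostationary ratios** require terminal relative slopes below 1e-6
  (`|dC/dt|·t_end/C_tot`); fully converted species are flagged rather
  than divided by.
* **Actinometry**: through-origin weighted least squares for the
  calibration line (the proportional model has no intercept); the
  standardization refuses nonlinear calibrations (r² < 0.999) since these
  signal a broken assumption such as absorbance drifting out of range.
  Every slope, intensity and yield carries a (lamp, range) tag and
  operations refuse to mix tags.  The lamp/actinometer/species overlap is
  classified automatically (sit1 — lamp wider than the actinometer OSIA;
  sit2 — lamp inside it; sit3 — species absorbing beyond the actinometer,
  which triggers an undercounting warning).
* The "zeroth-order" high-concentration estimator sometimes used to
  extract quantum yields is numerically the reactant photonic yield
  (PHYD) and is not exposed as a separate operation.

## Known limitations

* The Φ-order equation is an excellent but not exact description of
  polychromatic traces.  The residual is relative: fits reach ~10⁻⁴–10⁻⁶
  of the trace amplitude (squared correlations above 0.9999, SSE below
  10⁻¹² M²), so the *absolute* RMSD scales with the initial
  concentration.  Multi-step mechanisms near the top of the concentration
  range (amplitudes ~10⁻⁴ M) floor at RMSD ~10⁻⁸ M under their
  mechanistic term bounds; raising the term count beyond the bound would
  fit tighter but is rejected by design.
* For nearly photostable systems (reactivity score ≈ 0 over the lamp
  band) the initial rate is a ~10⁻¹² M/s signal on a ~10⁻¹⁰ M amplitude
  trace; the fitted initial rate of such traces is unreliable even though
  the fit itself is numerically excellent, and the theoretical and
  finite-difference estimates should be used instead.
* Fixed-step RK4 is not a stiff solver; the stability bound on dt makes
  stiff systems slow rather than wrong.
* High-concentration Beer–Lambert deviations, uncollimated reactors and
  radiative transfer are out of scope.
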