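# Methods

## Scattering model

The incoherent scattering function of hydration water is modelled per
wavenumber q as three populations plus a flat background:

    S(q,E) = DW(q) { [A_i + A_r j0²(qb)] R(q,E)
             + A_t L(E; Γ_t(q)) ⊗ R
             + A_r Σ_{l=1..5} (2l+1) j_l²(qb) L(E; l(l+1) Γ_r) ⊗ R } + k(q)

* **Debye–Waller factor** DW(q) = exp(−q²⟨u²⟩), with ⟨u²⟩ in Å². The
  convention carries no 1/3 factor; `elastic.msd_from_elastic` offers a
  `convention="third"` switch for comparison with work using exp(−q²⟨u²⟩/3),
  labelled in output.
* **Translation**: a Lorentzian of half-width Γ_t(q) = ħ·D_t·q^λ with
  ħ = 658.2119 µeV·ps, so q stays in Å⁻¹ and E in µeV. For λ = 2 this is
  Brownian diffusion with D_t in Å²/ps; for λ < 2 the motion is
  sub-diffusive and D_t carries units Å^λ/ps (recorded in output metadata).
* **Rotation**: the isotropic rotational-diffusion expansion on a sphere of
  radius b = 0.98 Å (the water H–O distance; configurable). The elastic
  factor j0²(qb) is the rotational EISF; the l-th quasi-elastic line has
  weight (2l+1)j_l²(qb) and half-width l(l+1)·Γ_r, i.e. Γ_r ≡ ħ·D_R; the
  rotational diffusion coefficient D_R = Γ_r/ħ is reported alongside. The
  model keeps the l ≤ 5 terms: at the largest instrument q (1.66 Å⁻¹) they
  retain 99.99997% of the total quasi-elastic rotational weight, so the
  truncation error is far below measurement noise. Where the single
  broadening unit sits in the l-ladder is a modelling choice; the
  l(l+1)-scaling is what the isotropic rotational-diffusion model
  prescribes, and the alternative (a single shared width) is recovered by
  reading Γ_r as that width at l = 1 up to the factor 2.
* **Elastic line**: a delta convolved with the resolution is the
  resolution, so elastic terms ride on R directly — no numerical spike.
* **Background** k(q) is fitted per q, neither convolved nor DW-attenuated.

**Variants.** In the default *additive* form translation and rotation are
separate terms. In the *convolved* form the rotational term is convolved
with the translational Lorentzian: widths add, and the rotational elastic
line acquires width Γ_t. The two coincide as Γ_t → 0. The families are not
symmetric: an additive surface cannot be reproduced by the convolved model
(its rotational lines are forced broader), whereas the additive family can
absorb a convolved surface almost exactly by re-tuning widths and
amplitudes. On synthetic data this shows up as a χ² ratio ≈ 1.17 when
fitting the convolved model to additive-generated spectra, against ≈ 1.00
in the reverse direction (`analysis/03`).

## Numerics

* **Channel-integrated Lorentzians.** Quasi-elastic lines are evaluated as
  exact per-channel integrals, (arctan((E+ΔE/2)/Γ) − arctan((E−ΔE/2)/Γ))/(πΔE),
  not point samples. Point sampling misrepresents lines narrower than the
  0.04 µeV channel; the bin integral is accurate for every width and tends
  to the correct single-channel delta as Γ → 0.
* **Convolution.** Discrete linear convolution on the uniform energy grid,
  multiplied by the channel width; profiles are built on an axis padded by
  at least ten resolution FWHM per side and cropped back, so edge effects
  and area loss are negligible within the window. The resolution profile is
  kept unit-area (numerically, to 1e-6).
* **Degenerate regimes.** D_t = 0 reduces the translational term to the
  elastic line exactly. If the fitted Γ_t at the lowest q falls below 5% of
  the resolution FWHM, translation is statistically indistinguishable from
  elastic scattering and the fit result carries a warning rather than
  failing.

## Global fit

All q slices at one temperature are fitted simultaneously. Shared
parameters: ⟨u²⟩, A_i, A_t, A_r, D_t, λ, Γ_r; per-q: k(q). The model is
linear in (A_i, A_t, A_r, k), so these are profiled out at each step by
non-negative least squares on the σ-weighted design matrix, leaving a
four-dimensional bounded least-squares problem in (⟨u²⟩, D_t, λ, Γ_r)
solved by a trust-region reflective method. This separable (variable
projection) formulation makes the search dimension independent of the
number of q slices and removes the amplitude/background degeneracy from
the nonlinear step.

* **Bounds** (defaults): ⟨u²⟩ ∈ [0, 5] Å², D_t ∈ [0, 1], λ ∈ [0.301, 2],
  Γ_r ∈ [0.01, 50] µeV; amplitudes and k non-negative via the linear solver.
* **Multistart**: the (λ, Γ_r) grid {1.0, 1.5, 2.0} × {0.2, 1, 5} µeV plus
  seed-controlled random starts; best χ² wins, ties broken toward smaller λ.
* **Uncertainties** from the Gauss–Newton curvature of χ² at the optimum
  (Δχ² = 1 contour) over the full free-parameter vector, via a numerical
  Jacobian; fraction errors by the delta method on the amplitude block.
  Doubling the noise doubles these uncertainties (verified on matched noise
  realizations). Parameters landing on bounds are flagged.
* **Fractions** are reported as A_x/(A_i+A_t+A_r) at reporting time; no sum
  constraint is imposed during fitting because the overall intensity scale
  is absorbed by the low-temperature area normalization of the spectra.

Recovery at instrument conditions (10 q in 0.46–1.66 Å⁻¹, ±15.8 µeV, 0.04
µeV channels, 0.7 µeV FWHM Gaussian resolution, 2% counting-like noise,
truth f = 0.3/0.2/0.5, D_t = 0.01, λ = 1.6, Γ_r = 0.5): fractions to
better than 0.01, D_t and λ within a few percent, reduced χ² ≈ 1. The
acceptance truth set does not pin ⟨u²⟩ or k; the package fixes them once
at 0.1 Å² and 1e-3 — representative hydrated-powder values.

## Elastic scans and the dynamical transition

⟨u²⟩(T) is the negative slope of ln I versus q² by weighted linear
regression (variance of ln I taken as (σ/I)²), by default over q² ≤ 2 Å⁻²
where the Gaussian approximation holds. The hydrated-minus-dry difference
(dry interpolated linearly when grids differ; errors in quadrature) is
smoothed with a cubic smoothing spline and the transition temperature is
the interior argmax of its second derivative, evaluated by central
differences on a 1 K grid; the quoted uncertainty is half the local spacing
of the measured temperature grid.

Two choices matter here:

* **Smoothing penalty.** When per-point errors are available the penalty is
  chosen by the discrepancy principle — the strongest smoothing whose
  weighted residual χ² still equals the number of points. Generalized
  cross-validation, the usual default for function estimation, undersmooths
  badly for *second-derivative* estimation and mislocated the hinge in
  roughly 8 of 20 noisy trials; with the discrepancy penalty detection is
  20/20 at the synthetic study conditions (10 K grid, 1% noise, slope
  change 0.004 Å²/K at 240 K).
* **No-transition guard.** A curve is declared transition-free when its
  detrended amplitude is below 1e-8 of its overall variation (affine- and
  scale-invariant, so adding any straight line or rescaling the curve
  cannot create or move a detection), or when the curvature peak does not
  exceed three times the median interior curvature magnitude.

## Hydrogen-bond kinetics

* **Criterion**: d(D–A) < 3.5 Å and D–H–A angle > 150° with the vertex at
  the hydrogen, any hydrogen of the donor; minimum-image convention for
  orthorhombic boxes. Donors/acceptors are declared explicitly in a
  topology sidecar — no force-field inference.
* **Estimators**: for each lag, numerator and normalization ⟨h(0)⟩ are
  accumulated over the same origin window (every frame is an origin; stride
  configurable), pooled over pairs. This guarantees S(0) = C(0) = 1,
  values in [0, 1] and C ≥ S pointwise. Strict monotonicity of S holds for
  the ensemble function and provably for single-pair series; the pooled
  finite-sample estimator can violate it on contrived multi-pair inputs.
  Per-lag origin counts are reported so statistical errors are computable.
  S uses a run-length histogram (O(pairs × frames)); C uses FFT
  autocorrelation with exact integer rounding — both match brute-force
  enumeration exactly on small series.
* **Dual sampling**: coarse (1 ps) histories for C_HB, a fine (8 fs)
  segment for S_HB, both through the same engine.
* **Relaxation times**: 1/e crossing by linear interpolation; if the curve
  does not reach 1/e inside the window (default 4 ns), a stretched
  exponential A·exp[−(t/τ_s)^β] is fitted to the tail (from the first lag
  below 0.95, weights √counts, β ∈ (0.2, 1]) and the analytic crossing
  τ = τ_s(ln A + 1)^{1/β} is returned; A ≤ 1/e is a diagnosed failure, as
  is a curve that never leaves 0.95.
* **Water MSD**: all-origin average of squared displacements at a given
  lag (default 100 ps), after minimum-image unwrapping when a box is
  stored; invariant under global rotation and translation.

## Synthetic generators

All generators are deterministic given their integer seed, which is
recorded in every output.

* **QENS**: forward model plus Gaussian noise with counting-like
  σ = c·√max(S, floor) (c = 0.02, floor = 1e-3 by default — the Gaussian
  approximation to Poisson counting at long-acquisition count levels; the
  floor keeps σ positive in empty wings). The σ surface is stored as the
  dataset errors and the full truth in its metadata.
* **Resolution**: Gaussian (or pseudo-Voigt) of 0.7 µeV FWHM, unit area,
  FWHM verified numerically to one channel.
* **Elastic scans**: I = exp(−q²⟨u²⟩(T))(1+noise) for a piecewise-linear
  MSD profile with an optional hinge (default at 240 K), relative to the
  base temperature.
* **Two-state bond histories**: the exact frame-sampled continuous-time
  two-state process — per-step probabilities (1−p_eq)(1−e^{−KΔt}) and
  p_eq(1−e^{−KΔt}) with K = k_on+k_off and p_eq = k_on/K (equal to
  1−e^{−kΔt} to first order in Δt). This discretization has exactly the
  equilibrium bonded fraction p_eq and exactly the intermittent
  correlation p_eq + (1−p_eq)e^{−Kt}; a naive per-rate discretization
  biases the stationary fraction by ~3% at Δt = 1 ps and the naive chain
  was measurably (4–7σ) off its own closed form. The frame-resolution
  survival rate differs from k_off by O(KΔt): 1.1% at 1 ps, negligible at
  8 fs. Initial states are drawn from equilibrium (all-bonded when
  k_on = 0, where no re-formation can occur).
* **Water trajectories**: free space (no protein atoms), three
  populations — immobile molecules with independent Gaussian jitter
  (0.1 Å) about lattice sites; rotors with fixed oxygen and a rigid
  H–O–H frame (b = 0.98 Å, 104.5°) under random-axis rotational Brownian
  motion of angular variance 2·D_R·Δt per step; translators as rigid
  molecules on Brownian walks with D_t. A separate helper realizes a
  prescribed bond on/off sequence geometrically (acceptor at 2.8 Å/180°
  when bonded, 5 Å otherwise) to round-trip detection against Markov truth.

**What the generators do not emulate** — powder structure and protein
atoms, detector geometry, multiple scattering, true Poisson statistics,
correlated noise between channels, heterogeneous per-pair kinetics, and
rotational–translational coupling. Passing recovery tests therefore
demonstrates the correctness of the estimators and fits under the stated
idealizations, not instrument-level systematics on real samples.

## Preprocessing and bookkeeping

Energy re-binning averages channels with inverse-variance weights
(errors 1/√Σσ⁻²); the bin width must be an integer multiple of the native
spacing and edges are trimmed to keep the grid symmetric — the integral is
conserved exactly for uniform weights when no trimming occurs. Low-T
normalization divides each q slice by the energy-integrated area of the
reference with error propagation; re-binning and normalization commute
when the reference is error-free. The incoherent cross-section budget
swaps a stated fraction of exchangeable protein deuterons with water
protons (mass-balanced) and sums σ_inc·count per species with σ_H = 80.27
barn and σ_D = 2.05 barn (tabulated values, overridable); fractions sum to
1 and are invariant under uniform scaling of all counts.

## Problem sizes

The test and acceptance runs use the full instrument grid (10 q × 791
channels) for the headline recovery fit and a reduced grid (5 q × 317
channels at 0.1 µeV) for repeated-fit studies; bond-history studies use
500 pairs × 4000 frames (coarse) and 500 × 50000 (fine); MSD studies 300–
1000 molecules over ~400 frames — sizes at which the statistical
tolerances quoted above are comfortably resolved.

## Known limitations

* Uncertainties come from the local quadratic approximation; no bootstrap
  or posterior sampling (a config hook exists for the former).
* Multi-temperature fits share no parameters across temperatures.
* The fast-water background k(q) is treated as a free nuisance per q; its
  physical content is not modelled.
* Binary trajectory formats are out of scope; XYZ plus the topology
  sidecar is the interchange format (readers for other formats can be
  slotted behind the same `Trajectory` contract).
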