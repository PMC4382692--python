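# aquadyn — hydration-water dynamics analysis

`aquadyn` analyzes the picosecond–nanosecond dynamics of protein hydration
water from three complementary measurements, with seeded synthetic
generators providing known ground truth for every stage:

1. **Quasi-elastic neutron scattering (QENS).** A backscattering
   spectrometer resolves the broadening of the elastic line by diffusive
   water motion on a (q, E) grid. The scattering function is modelled as
   three water populations plus a flat background,

   S(q,E) = e^{−q²⟨u²⟩} { [A_i + A_r j₀²(qb)] R(q,E)
            + A_t L(E; Γ_t(q)) ⊗ R
            + A_r Σ_{l=1..5} (2l+1) j_l²(qb) L(E; l(l+1)Γ_r) ⊗ R } + k(q),

   with Γ_t(q) = ħ·D_t·q^λ (λ = 2 is Brownian diffusion, λ < 2
   sub-diffusion), j_l the spherical Bessel functions of the rotational
   diffusion expansion at the H–O radius b = 0.98 Å, R the measured
   resolution, and k(q) a flat background. Translational terms have
   q-dependent widths and q-independent intensities; rotational terms the
   opposite — which is why all q slices are fitted **globally** by χ²
   minimization, yielding the translational / rotational / immobile
   intensity fractions f_t, f_r, f_i per temperature.

2. **Elastic scans.** Elastic intensities I(q,T) give apparent mean-squared
   displacements via the Debye–Waller factor, ⟨u²⟩(T) = −d ln I/dq². The
   protein **dynamical transition** is located from the hydrated-minus-dry
   ΔMSD(T): a smoothing spline is fitted and the transition temperature is
   the peak of its second derivative (near 240 K for a programmed hinge).

3. **Trajectory hydrogen-bond kinetics.** A donor–acceptor pair is bonded
   when d(D–A) < 3.5 Å and the D–H–A angle exceeds 150°. From the bond
   history h(t), the continuous survival S_HB(t) = ⟨h(0)H(t)⟩/⟨h⟩ (intact
   at every intermediate frame) and the intermittent correlation
   C_HB(t) = ⟨h(0)h(t)⟩/⟨h⟩ are averaged over pairs and time origins.
   Their 1/e times τ_HBC and τ_HBI separate fast bond breakage from the
   slower relaxation of the hydrogen-bond network; slow decays are
   extrapolated with a stretched exponential A·exp[−(t/τ_s)^β]. Water
   translational mobility is summarized by the oxygen MSD at a 100 ps lag.

## Layout

- `src/aquadyn/` — the library: `qens_model` (forward model),
  `qens_fit` (global χ² fitting), `elastic` (MSD and transition),
  `hbonds` (bond detection, correlations, relaxation times, MSD),
  `synthetic` (ground-truth generators), `io` (tab-separated formats,
  binning, low-T normalization, incoherent cross-section budget),
  `pipeline`/`cli` (declarative runner, `aquadyn` command).
- `analysis/01…06_*.py` — numbered drivers that run each study and write
  tables under `results/`.
- `scripts/acceptance.py` — recomputes the headline numbers (below).

## Worked example

```python
import aquadyn as aq
from aquadyn import synthetic as syn

grid = syn.default_qens_grid(n_q=10)                 # 0.46–1.66 1/Å, ±15.8 µeV
resolution = syn.generate_resolution(grid, fwhm=0.7) # 0.7 µeV FWHM
truth = syn.default_qens_truth(n_q=10)               # f_t=0.3, f_r=0.2, f_i=0.5
data = syn.generate_qens_dataset(truth, grid, resolution,
                                 syn.NoiseSpec(c=0.02, seed=20260101))
result = aq.global_fit(data, aq.FitConfig(seed=20260101))
print(result.fractions, result.params.D_t, result.params.lam,
      result.chi2_reduced)
```

which prints (run via `analysis/02_qens_parameter_recovery.py`):

```
fractions  f_t=0.298 f_r=0.204 f_i=0.497
D_t=0.0103 (truth 0.01)  lam=1.659 (truth 1.6)  Gamma_r=0.586 ueV (truth 0.5)
chi2_reduced=1.032
```

i.e. the global fit recovers the programmed population fractions to better
than 0.01, the anomalous diffusion parameters within their statistical
uncertainty, and a reduced χ² consistent with the injected 2% noise.

The other drivers print, for example, that five terms of the rotational
expansion retain ≥ 99.99997% of the quasi-elastic weight at q = 1.66 Å⁻¹
(`01`), that a programmed translational-fraction step at 240 K reappears in
the fitted f_t(T) (`02`), that the convolved model variant fits
additive-generated spectra with a χ² ratio of ≈ 1.17 while the reverse
comparison stays at ≈ 1.00 (`03`), a hinge programmed at 240 K detected at
240 ± 5 K (`04`), hydrogen-bond rates 1/τ_HBC ≈ 0.099 ps⁻¹ and a C_HB
decay rate ≈ 0.120 ps⁻¹ against programmed k_off = 0.1, k_on+k_off = 0.12
(`05`), and a pure-translator MSD(100 ps) ≈ 6.26 Å² against the Einstein
value 6 Å² (`06`).

## Command line

Each verb runs the matching stages of a declarative YAML config:

```bash
aquadyn report  -c config.yml          # everything
aquadyn fit     -c config.yml          # simulate → preprocess → fit
aquadyn hbonds  -c config.yml          # bond histories → correlations → τ
aquadyn elastic -c config.yml          # scans → MSD → transition
```

Every run directory contains a `run.log` recording the parameters and
seeds needed to regenerate its outputs.
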