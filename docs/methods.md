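# Methods

## Model

The package computes gas-phase photoabsorption cross-sections with the
nuclear ensemble approach (NEA). The ground-state nuclear probability
density of each conformer is approximated by the harmonic Wigner
distribution defined by its equilibrium geometry, vibrational
frequencies ω_k and unit-norm mass-weighted normal-mode vectors L_k.
Its position marginal factorizes over modes; each mass-weighted normal
coordinate is Gaussian with

    Var(Q_k) = (ħ / 2ω_k) · coth(ħω_k / 2k_B T),

the zero-point value ħ/2ω_k at T = 0. Momenta are Gaussian with
Var(P_k) = (ħω_k/2)·coth(ħω_k/2k_BT); they are sampled on request
(useful as initial conditions for excited-state dynamics) but unused by
the spectrum pipeline, which needs positions only.

N_p geometries are drawn, vertical excitation energies ΔE_0I and
transition dipoles μ_0I (or oscillator strengths f_0I) are evaluated at
each, and the cross-section is the ensemble average of broadened
transitions

    σ(E) = C · (1/N_p) Σ_j Σ_I f_0I(R_j) · g_δ(E − ΔE_0I(R_j)),

with g_δ a unit-area lineshape and C = πe²ħ/(2m_e c ε₀) the integrated
cross-section of a unit-f transition. The normative contract is the
band-area sum rule ∫σ dE = C·⟨Σ_I f⟩: whatever the broadening, the
integrated band carries the ensemble-mean oscillator strength. Conformer
spectra are combined as σ_total = Σ_i w_i σ_i with Boltzmann weights
w_i ∝ exp(−ΔE_i/RT); no symmetry/degeneracy numbers are applied (user
energies can absorb them if needed).

The photolysis rate coefficient is J = ∫φ(λ)σ(λ)F(λ)dλ over the actinic
window 280–400 nm, with φ the (constant or tabulated) quantum yield and
F the actinic flux.

### Assumptions and known limitations

- **Harmonic ground state.** The Wigner density is exact only for a
  harmonic surface. Soft modes (< 200 cm⁻¹) are typically anharmonic;
  sampling them harmonically can produce unphysically distorted
  geometries and spurious spectral tails. The sampler logs a warning
  when such modes are active and `freq_cutoff` can exclude them (masked
  modes contribute zero displacement).
- **No vibronic structure.** The NEA broadens vertical lines; it cannot
  reproduce vibronic progressions, and the low-energy tail of the band
  tends to be too intense. The tail bias is documented, not corrected —
  note it inflates J when the tail enters the actinic window.
- **Frequency records must describe a minimum**: any imaginary frequency
  is rejected at construction.
- Cross-sections are point functions of photon energy: converting the
  axis to nm relabels abscissae only, with no Jacobian (σ is not a
  density over wavelength).

## Parameters

| parameter | unit | default | rationale |
|---|---|---|---|
| `n_samples` (N_p) | — | 500 | lower end of the usual 500–10 000 range; Monte-Carlo error of the band mean ~ band-width/√N_p |
| `sampling_temperature` | K | 0 | zero-point Wigner sampling, the common NEA practice; thermal coth-scaled sampling is an option |
| `temperature` | K | 298.15 | conformer Boltzmann weighting at ambient conditions |
| `freq_cutoff` | cm⁻¹ | 0 | no modes removed by default; the < 200 cm⁻¹ risk is surfaced as a warning instead |
| `delta` (δ) | eV | 0.05 | common NEA broadening; δ is the Gaussian std-dev and the Lorentzian HWHM (one convention had to be fixed; it is stamped into the spectrum metadata) |
| lineshape | — | gaussian | Lorentzian available; both unit-area |
| grid | — | 4096 pts over [min ΔE − 6δ, max ΔE + 6δ] | resolves δ with ≳ 8 points and keeps truncation of band area < 0.5 % |
| `phi` (φ) | — | 1.0 | upper bound for J; user-supplied, constant or tabulated |
| window | nm | 280–400 | tropospheric actinic region |
| near-zero-frequency drop threshold | cm⁻¹ | 1 | separates translations/rotations from vibrations in real program output |
| conformer RMSD dedup threshold | Å | 0.1 | heavy-atom RMSD after Kabsch alignment; prunes re-optimized duplicates |

Unit system: internal sampling arithmetic is in atomic units
(1 cm⁻¹ = 4.556335×10⁻⁶ Hartree, 1 amu = 1822.888486 m_e,
1 Hartree = 27.211386 eV); the energy/wavelength axis uses a fixed
hc = 1239.841984 eV·nm so written spectra are bit-reproducible.
C is computed from CODATA constants (1.09761×10⁻¹⁶ cm²·eV).

## Synthetic data: the mock backend

The mock electronic-structure backend emulates a harmonic ground state
with one active mode ω and a single excited state whose gap varies
linearly along the mass-weighted coordinate, ΔE(Q) = ΔE₀ + κQ, with a
constant transition dipole (or constant f). Under Wigner sampling Q ~
N(0, σ_Q²), so the exact N_p → ∞, δ → 0 band is Gaussian with mean ΔE₀
and std-dev |κ|σ_Q — the reflection-principle closed form. This is the
package's end-to-end oracle: tests verify the sampled band moments
against it within Monte-Carlo standard errors.

What the mock captures: the geometry → excitation → spectrum data flow,
absolute intensity scaling, ensemble statistics, determinism. What it
does not: multi-state spectra with state crossings, non-Condon intensity
variation (beyond the `from_tdm` option), anharmonicity, and real
electronic-structure error — so passing tests demonstrate correctness of
the NEA machinery, not accuracy of any quantum-chemistry level. Gaps
driven nonpositive by extreme samples are floored at 0.01 eV with a
warning rather than raising, keeping large-κ stress tests runnable.

The packaged glycolaldehyde conformer fixture
(`data/synthetic_conformers.json`) is likewise synthetic: constructed
coordinates and a relative energy chosen to give a ~0.6 % minor
population at 298 K, for exercising the conformer plumbing offline.

## Flux presets

The three standardized actinic fluxes (high: zenith 0°, 200 DU ozone;
medium: 60°, 350 DU; low: 90°, 500 DU; all at 0 km elevation) ship as
replaceable CSV tables generated once by an analytic surrogate
(`scripts/make_flux_tables.py`): Planck photon irradiance at 5772 K
scaled by the solar solid angle, attenuated by Beer–Lambert ozone
absorption (Gaussian Hartley-band model, peak 1.13×10⁻¹⁷ cm² at 255 nm)
and half the Rayleigh optical depth along a Kasten–Young airmass path.
The surrogate reproduces the physically required pointwise ordering
high ≥ medium ≥ low and realistic magnitudes (~3×10¹⁴
photons·cm⁻²·s⁻¹·nm⁻¹ at 400 nm overhead), but it is not
radiative-transfer output: supply a flux CSV (`flux: file:PATH`) for
authoritative J values.

## Numerical choices

- **Quadrature**: trapezoidal throughout (band areas, J); flux tables
  are tabulated data, so higher-order rules buy nothing.
- **Interpolation**: σ is resampled onto the flux grid linearly and is
  zero outside its computed grid — conservative for J and consistent
  with the known over-tall tail. Window endpoints are inserted exactly
  so J is additive over sub-windows.
- **Boltzmann weights** subtract the minimum energy before
  exponentiation (overflow-safe).
- **RNG**: one `numpy.random.default_rng(seed)` stream per sampling
  call; all position deviates are drawn first (sample-by-sample,
  mode-major), then momenta, so ensembles are bit-reproducible. Workflow
  runs derive per-conformer child seeds from the configured seed via
  `SeedSequence`.
- **Band moments** (used by the reflection-principle checks) are
  intensity-weighted trapezoidal moments of σ(E); for Gaussian
  broadening δ² is subtracted from the variance (a Gaussian convolution
  adds variances) to recover the underlying excitation distribution.
- **Degenerate inputs**: all-masked distributions raise ("nothing to
  sample"); zero-variance sampling returns the equilibrium geometry;
  empty tables, empty grids and non-rectangular excitation tables raise
  with the offending geometry named.
- **Orthogonality tolerance** for mass-weighted modes is 1e-6 (unit norm
  and pairwise dot products); the Molden-style reader renormalizes and
  records the factors, and rejects non-orthogonal (i.e. plain Cartesian)
  mode vectors with an instruction to supply mass-weighted ones.

## Design decisions on genuinely open points

- The frequency-file dialect consumed internally is our own neutral JSON
  record; the Molden-style reader is a convenience normalized into it.
  Quantum-chemistry outputs vary too much for one scraped format to be
  canonical.
- Whether Wigner sampling is thermal or zero-point is not fixed by
  common usage; both are provided, default 0 K, and the choice is
  recorded in run provenance.
- Problem sizes in the test-suite and acceptance checks (N_p = 300–5000,
  10⁵ variance samples) were chosen so Monte-Carlo errors are a few
  per-mille to percent — comfortably inside the tolerances being
  checked — while keeping the whole suite interactive.
- External electronic-structure engines are integration points, not
  dependencies: they enter either through the excitation-backend
  contract or by supplying excitation tables in the conformer manifest
  (whose energies can also carry refined, post-force-field conformer
  energetics).
- Workflow provenance is a flat JSON sidecar per run directory rather
  than a database; stage artifacts are plain files so any stage can be
  inspected or resumed.
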