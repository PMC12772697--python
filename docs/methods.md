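# Methods

This note documents the physics models, numerical choices and known
limitations of the solver, at the level a maintainer or reviewer needs to
judge what a passing test does and does not demonstrate.

## Transport model

The solver treats a monoenergetic, monodirectional (or 2-D Gaussian) proton
source incident normally on a semi-infinite water phantom. Three
one-dimensional families of distributions are propagated independently in
depth and combined at scoring time:

* **Energy spectra** `Φ(z, E)` (per MeV per incident proton), propagated by
  the total-expectation iteration with single-step energy-loss kernels.
* **Angular distributions** `Φ(z, θ)` (per steradian, azimuthally
  symmetric), propagated by spherical convolution with Molière kernels on a
  50-node log grid from 0.01° to 10°.
* **Radial profiles** `Φ(z, ρ)` (per cm²), reconstructed from the
  scattering history (see "Lateral model" below).

Factorizing energy from the lateral variables neglects the correlation
between a proton's energy and its lateral position at fixed depth (slower
protons have scattered more); the same approximation is inherent in the
step-wise formulation being implemented. The path-length/depth
identification `t = z` is accurate to the detour factor (0.998–0.999 for
protons in water).

## Energy-loss straggling

The Vavilov distribution is evaluated by direct quadrature of its
oscillatory inversion integral; the envelope `exp(k f₁(y))` decays like
`exp(−πky/2)`, which fixes the truncation point (envelope < 1e−12), and the
sampling density follows the fastest phase. The implementation reproduces
the printed Gaussian-limit variance `ξ Δt (ΔE)max (1 − β²/2)` analytically
and passes normalization/mean quadrature checks at the 1e−3/1% level. Note
that under the thin-slab condition (mean loss below 20% of the energy) the
straggling parameter k cannot exceed ≈ 10 in water, where the residual skew
still leaves a ~4% sup-norm distance to the Gaussian; the familiar "large-k
Gaussian limit" is approached but not attained within the model's domain of
validity. Because the Vavilov evaluation is comparatively slow, it is used
for the first step only by default (`kernel="vavilov-first"`); subsequent
steps use the Gaussian kernel. `vavilov-all` and `normal-only` are
available as configuration switches.

### Anchored composition

Applying a binned kernel at every depth step adds roughly `w²/12` of
spurious variance per re-binning (w = local bin width) — enough, over the
many clamped terminal steps, to flatten the Bragg peak by several percent
and to make the result depend on the step fraction f. The propagation
therefore composes Gaussian steps analytically from an *anchor* spectrum:
the mean follows the CSDA map over the whole composed thickness, the
variance is the thick-target straggling integral
`σ²(E→E_f) = S(E_f)² ∫ ξ (ΔE)max (1 − β²/2) / S³ dε`
(each step's width carried through the linearized slowing-down map), and
nuclear attenuation uses the exact CSDA survival integral
`exp(−[G(E) − G(E_f)])` with `G = ∫ σ_N / S dε`. The spectrum is re-binned
(re-anchored) only when the composed kernel is at least 2.5 local bin
widths wide, where binning noise is negligible. Source bins are treated as
uniform within the bin, subdivided adaptively where the slowing-down map is
strongly nonlinear (near the range-out threshold), with two-point Gauss
nodes providing the mapped mean and spread per sub-interval. Validation
against the shared-kernel Monte Carlo shows bin-wise agreement at the
statistics level (2e4 histories) at 30/60/85% of the range for 40 and
100 MeV beams.

## Multiple Coulomb scattering

Molière parameters follow the screened-Rutherford formulation with Z²
nuclear scattering per element and the Fano inelastic (atomic-electron)
correction `F_j / Z_j` subtracted from the log screening angle; the
compound average of `ln χ_a²` is weighted by each element's share of χ_c².
The Thomas–Fermi screening angle carries the `1.13 + 3.76 (αZ/β)² k_HF`
factor with the Hartree–Fock coefficients set to 1.0 (their effect is
logarithmic). `B − ln B = b` is solved by safeguarded Newton iteration on
the B > 1 branch; steps with b ≤ 1.2 (too few collisions for the
multiple-scattering expansion) raise an error advising a larger step. The
universal functions f⁽⁰⁾, f⁽¹⁾, f⁽²⁾ are pre-tabulated to a reduced angle
of 20 by direct quadrature (f⁽⁰⁾ matches its closed form 2e^(−ϑ²) to
1e−10); beyond the table f⁽¹⁾ continues as the Rutherford tail 2ϑ⁻⁴.
Single-step kernels at therapeutic energies agree with the Highland
parameterization at the few-percent level in the Gaussian core, with the
single-scattering tail carrying roughly 40% additional mean-square angle
inside the 10° grid cutoff.

The quadrature orders (64-point Legendre in θ′, 64-point Chebyshev in φ′)
were fixed by doubling-order convergence; distributions are renormalized to
unit solid-angle integral after each convolution to control quadrature
drift. The 10° angular cutoff truncates the large-angle tail near the end
of range; the truncated mass is folded back by the renormalization, which
slightly sharpens deep angular distributions relative to an uncapped
calculation.

## Lateral model

Two constructions are provided. The classic step-wise Molière technique —
mean radius accumulated as the trapezoid of tan(θ̄) over depth and the
radial shape obtained by rescaling the angular distribution — is exposed as
`mean_radius_update` / `angular_to_radial`. Validation against the
shared-kernel Monte Carlo shows that the tangent recurrence with the mean
polar angle overestimates the true mean radius by 15–25% (it ignores the
azimuthal decorrelation between direction and position), so the driver uses
two exact constructions instead:

* the **mean radius** from Fermi–Eyges moment accumulation of the same step
  kernels (position variance, position–angle covariance, angle variance),
  which matches the Monte Carlo mean radius to ~2% at all depths;
* the **radial profile** from the product of per-step characteristic
  functions `∏ A_i(s_i q)` with lever arms `s_i` (exact for independent
  small-angle deflections), inverted by a Hankel transform. The Gaussian
  source multiplies in as `exp(−σ²q²/2)`, so the beam convolution is
  performed in Fourier–Bessel space and matches a brute-force Cartesian
  convolution to better than 1%.

The spec-level Legendre/Chebyshev real-space convolution
(`gaussian_beam_convolve`) remains available and is cross-checked against a
direct 2-D Cartesian sum.

## Nuclear model

Cross-section tables (p–p elastic, p–16O elastic, p–16O nonelastic) are a
smooth compilation of literature-typical values shipped as replaceable text
tables; the paper-level formulas (Ranft differential cross section,
relativistic two-body kinematics, surface-crossing tally with 1/μ weights
and CSDA transport of the scattered proton) are implemented exactly.
Secondary generation is single-pass: secondaries do not spawn tertiaries,
and their radial spread is assigned to the primary profile at the tally
depth. The p–H channel uses 16-point Legendre quadrature in μ_cm (isotropic
CM density), the forward-peaked p–A channel 32-point Gauss–Laguerre in
1 − μ_cm; the collision-depth line integral is subdivided threefold within
each coarse nuclear interval. The nonelastic channel transports no
secondary protons by default (configuration switch `nuclear="all"` with a
user-supplied single-differential emission table); the removed energy is
deposited locally scaled by `local_deposit_fraction` (default 0.65 — the
approximate charged-particle plus recoil share for p+16O at therapeutic
energies, with neutrons and photons escaping the phantom). Local nuclear
deposits are ramped from zero at the surface (the entrance node remains
primary-only dose), mirroring the secondary build-up a full transport would
produce.

## Scoring

Dose at the stored depths is the fluence integral `ρ⁻¹ Σ Φ_j S̄_j w_j` with
the range-consistent bin stopping power `S̄_j = ΔE_j / ΔR_j` (the harmonic
bin mean, exact for the 1/S slowing-down shape within a bin). Sub-grid
terminal deposition is closed by exact energy balance: each segment's local
deposit is the step operator's energy difference minus the share the
trapezoidal fluence-dose integral already assigns. With nuclear channels
off, the depth-integrated dose returns the incident energy to better than
0.1%. Off-node dose is evaluated by re-propagating from the nearest stored
anchor (no interpolation error); the energy-shifted spectrum interpolation
is used for the coarse-grid secondary spectra, whose quasi-primary
(forward-elastic) component retains its Bragg structure under the shift.

Entrance normalization scales the solver's own z = 0 central-axis dose to
the requested value. The γ-index is the standard global criterion with an
exhaustive search within a 3×DTA radius on a 5× linearly refined grid,
verified against an all-pairs brute-force oracle.

## Default parameters

| parameter | 40 MeV | 220 MeV | meaning |
|---|---|---|---|
| f | 0.05 | 0.05 | fractional energy loss per Coulomb step |
| Δt_min | 0.005 cm | 0.2 cm | terminal step clamp |
| ΔE_max / ΔE_min | 0.3 / 0.02 MeV | 0.5 / 0.1 MeV | energy-bin widths (low/high E) |
| E_s | 31 MeV | 175 MeV | grid switching energy |
| Δτ_max / Δτ_min | 0.1 / 0.1 cm | 2.4 / 0.8 cm | nuclear tally steps |
| r_max | 2 cm | 3 cm | radial grid extent |

Intermediate energies interpolate linearly; every value is overridable per
run. The plan extends ~5% past the CSDA range so the distal falloff is
fully covered.

## What the Monte Carlo oracle shows — and what it does not

The condensed-history oracle samples the *same* per-step kernels, the same
step plan and the same tables as the solver, so agreement isolates
transport-mathematics errors (convolution, binning, composition) from
physics-data uncertainty. It says nothing about the fidelity of the
underlying models themselves (Bethe–Bloch with I = 75 eV, Molière with the
10° cutoff, the compiled nuclear cross sections, single-generation
secondaries). Equivalence tests run with 2–4×10⁴ histories at a handful of
depths; comparisons allow the Monte Carlo statistics plus a few percent of
systematic headroom for the finite grids.

## Known limitations

* Water only; heterogeneous/voxelized media are out of scope.
* The energy–lateral correlation is neglected (both in the solver and its
  validation oracle).
* Nonelastic secondary protons are not transported by default; their energy
  is deposited locally with an energy-independent retained fraction.
* Treating forward p–A elastic scattering as removal plus single-generation
  tally re-injection (with full σ_N attenuation of the secondaries)
  discards part of the Bragg-peak contribution that multiple generations
  would retain; at 220 MeV, where ~11% of protons scatter elastically off
  oxygen over the track, this depresses the computed narrow-beam peak dose
  by O(10%) relative to a full Monte Carlo treatment.
* Grid-refinement self-convergence of the depth dose (halving f and
  ΔE_min) is ≈0.8% of the maximum at 40 MeV but degrades to ≈2.5% on the
  distal falloff at 100 MeV, driven by the coarse low-energy bins of the
  prescribed energy grid.
* The γ tool compares 1-D curves and cylindrical (z, r) maps only.
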