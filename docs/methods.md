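# Methods

This note documents the physical model behind `menpi`, the calibrations and
numerical choices, and what the synthetic scenarios do and do not establish.

## Head phantom and conduction model

The head is a uniform voxel grid (default 1 mm) of nested ellipsoidal
compartments — WM core, GM shell, CSF shell — each with a uniform isotropic
conductivity: WM 0.14 S/m, GM 0.33 S/m, CSF 1.79 S/m. A structured grid was
chosen over a tetrahedral FE mesh: it supports the same quasi-static
conduction physics at desk scale, aligns exactly with NIfTI volumes, and
makes the imaging step a convolution. Skull and scalp are not modeled; the
outer tissue surface is treated as insulating (zero normal current), which
is the appropriate idealization when all sources and observation points are
intracranial. No anisotropic WM tensors.

Neuronal firing is a 2-mm-diameter sphere of tissue carrying a volumetric
current density `J_v = (70 pA/pF) × c_m`, where `c_m` (pF/mm³) is the
effective membrane capacitance per tissue volume. `c_m` is an explicit
calibration constant because a per-capacitance current fixes no volumetric
source by itself; the default, 8.5×10⁵ pF/mm³, places the peak |E| of the
default firing spot at ≈95 V/m, the top of the 5–100 V/m range of
endogenous cortical fields the particle model addresses. The return current
flows through an identical sphere offset by one voxel (the offset-monopole
source/sink pair), rescaled so the net injected current is exactly zero — a
requirement for solvability under insulating boundaries.

The potential solves `∇·(σ∇φ) = −J_v` by a finite-volume discretization
with harmonic-mean face conductivities (the conservative choice for
discontinuous σ), Jacobi-preconditioned conjugate gradients, and a
mean-zero gauge. The default tolerance bounds the max-norm residual of the
discrete current balance at 10⁻⁸ of the largest injected voxel current.
`E = −∇φ` uses central differences, falling back to one-sided differences
at the tissue boundary.

Validation: against the closed-form potential of a point-source pair,
`I/(4πσr)`, superposed with its mirror images across the insulating box
faces (method of images, reflections to second order), the solver agrees
pointwise within 5% at voxels ≥3 from the sources — excluding the dipole
null surface, where pointwise relative error is undefined — and within 5%
of the peak value everywhere qualifying. |E| decays with the expected
exponent −2.0 ± 0.1, and grid refinement converges with observed order ≈1.8.

## Particle model

A particle of diameter d (default 50 nm) has volume `V = πd³/6` and moment
`m = M_S V`. At temperature T (default 300 K) the thermal-equilibrium
relative magnetization is the Langevin function `L(ξ) = coth ξ − 1/ξ`,
`ξ = mH/k_BT`, evaluated by series below |ξ| < 10⁻³ for stability. MENs add
an electric-field term: `ΔM = α E` with α in G·cm/V and E in V/cm
(1 G ≡ 1 emu/cc), so `M_rel = clip(L(ξ) + ΔM/M_S, −1, 1)`. The shift is
additive in magnetization, not an effective field, and an MN is exactly the
α = 0 special case. Magnetics are CGS-Gaussian throughout (Oe, emu/cc,
erg); fields enter in V/m and are converted only inside the ME coupling.

Defaults: MEN `M_S` = 10 emu/cc, α = 0.1 G·cm/V, `H_c` = 100 Oe, density
5 g/cc; MN `M_S` = 100 emu/cc, α = 0. Two caveats on the source values are
deliberately left visible rather than silently reconciled:

- `M_S` is interpreted in emu/cc (the value also used by the dissipation
  estimate); quotations in emu/g differ by the ×5 mass density. The config
  accepts both with an explicit unit tag.
- the literal product α·E at 1 V/cm is 0.1 emu/cc, although the motivating
  10%-change argument quotes 1 emu/cc for the same inputs; the code always
  computes the literal product.

Hysteresis is excluded from the imaging response (the MPI operating point
keeps selected particles in their reversible linear zone); `H_c` enters
only the per-cycle dissipation, `4 H_c M_S` erg/cc for a rectangular loop
(π H_c M_S elliptical), an order-of-magnitude estimator. Collective
behavior is summarized by the nearest-neighbor axial dipole field
`2m/r³ = 2m·density`; spacings under 5 nm (quantum-interaction regime) are
flagged, not modeled. Néel/Brown relaxation dynamics and frequency-dependent
α are out of scope.

## MPI image formation

Operating point: a 500 Oe background field saturates all particles; the
opposed selection field (−500 ± 50 Oe, linear gradient, default 25 Oe/mm)
cancels it at the field-free point. Voxels whose net static field stays
within the ±50 Oe linear zone (a 2-mm-radius ball at the default gradient)
respond to the small a.c. drive; all others are saturated and contribute no
modulated signal.

The per-voxel signal is the proportionality `S ∝ density × M_rel`, with
`M_rel` evaluated at the drive amplitude `H_d` — in-zone particles sit near
zero static field and are probed by the drive. Rastering the FFP over the
grid and summing in-zone voxels is exactly a convolution with the zone
ball, which is how it is computed. Optional Gaussian noise (config sd,
fixed seed) is added to the aggregated signal; images are normalized by
their maximum, or by a shared reference constant when scans must remain
mutually comparable (pre/post-firing pairs).

**Drive-amplitude calibration.** The one free constant of the image model
is `H_d`. It is fixed at 2 Oe so that, for the default MEN, the structural
response `L(mH_d/k_BT) ≈ 0.0105` matches the ME modulation `ΔM/M_S = 0.01`
at E = 100 V/m — i.e. a firing spot at the top of the endogenous field
range doubles the local signal, the contrast level the approach is designed
around. With the simulated firing spot (whose zone-averaged field is well
below its 95 V/m peak) the post/pre ROI contrast comes out ≈1.3, within
the ±50% band around 2 that the unspecified reconstruction details warrant.
The ROI is the firing sphere dilated by one voxel; the metric is the ratio
of raw (shared-normalization) ROI means.

**Density/resolution study.** A point density impulse is imaged by a fine
1-D FFP sweep. Peak signal grows linearly with density; the dipole field
adds to the linear-zone half-width, so the FWHM, `2(50 Oe + 2m·density)/G`,
is non-decreasing and degrades sharply at high density. This reproduces the
qualitative signal/resolution trade-off; the absolute resolution floor of a
real scanner depends on an interaction model beyond this estimator.

## Demodulation and field recovery

Demodulation divides the MEN image voxelwise by the *equivalent-MN* image —
same `M_S`, `V`, `T`, α = 0 — where the MN signal exceeds an epsilon guard
(10⁻⁶ of its maximum). Raw, de-normalized signals are used so that display
normalization cancels; with uniform density the ratio is exactly
`1 + αE/(100 M_S L(ξ_d))`, hence

    |E| = (ratio − 1) · L(ξ_d) · M_S · 100 / α   [V/m],

clipped at zero. This is the exact inverse of the forward model in the
noise-free, unclipped, uniform-density case: a 40 V/m plateau recovers to
machine precision in its interior (voxels whose linear zone sees only
plateau), and to within a few percent of ROI mean at image SNR 20. The
recovered map is |E| only; the scalar signal model discards direction.
Structure cancels only where particle density is (locally) uniform — a real
biodistribution would leave density gradients imprinted on the ratio.

## Dosimetry

Dose (default 0.1 mmol/kg, comparable to clinical Gd contrast agents) ×
bodyweight × molar mass gives total mass; the default molar mass, 467.8
g/mol, is one BaTiO₃ + CoFe₂O₄ formula-unit pair (233.19 + 234.62), the
assumed core–shell composition — for 50 kg this is 2.34 g. Mass / (ρV) per
particle gives the count (~7×10¹⁵) and, spread uniformly over the phantom
tissue (no biodistribution model; a GM-weighted mode is a config option),
the number density used in imaging. Dissipated power is energy-per-cycle ×
drive frequency, flagged against the 50 W limit below which no steady
brain-temperature rise above ~2 K is expected; the default scenario sits
near 2 W. Pharmacokinetics and clearance are not modeled.

## Determinism and problem sizes

One global seed derives per-stage seeds through `SeedSequence.spawn` in a
fixed stage order; reruns are bit-identical, and every image records its
config hash and seed. The shipped scenarios — 64³ voxels at 1 mm for the
head phantom and firing study, 32³ for the demodulation round trips, three
resolutions from 1.5 to 0.375 mm for the convergence study — were chosen as
the smallest grids on which the compartment geometry, the 2-mm spot and the
2-mm linear zone are all well resolved; the full pipeline runs in about a
second on one core.

## What the synthetic scenarios do not show

The ellipsoidal phantom has no gyri, skull or scalp; conductivities are
isotropic; the firing source is a single static snapshot (pre/post), not an
EPSP/alpha-rhythm time series; particle density is uniform; the image model
is the stated `S ∝ M_rel` aggregation, not a harmonic-space MPI
reconstruction with relaxation blurring. Passing tests therefore certify
the internal consistency of the physics chain and its parameter-recovery
guarantee, not the absolute contrast or resolution of a physical scanner on
a real head.
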