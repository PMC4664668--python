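# Methods

This note documents the physics model, the parameters that matter, the
numerical choices, and the limits of validity of the `minibeams` package.

## Scope and assumptions

The package models fully stripped light ions (p, d, He-4, Li-7, C-12) in
liquid water between 1 and 500 MeV/u. Water stands in for soft tissue
throughout ("tissue-equivalent depth"). Three physical processes are
modelled: electronic stopping, multiple Coulomb scattering (MCS), and range
straggling. Deliberately **not** modelled: nuclear interactions (fluence
loss, fragmentation tails, secondary-particle halo), large-angle single
scattering, energy-straggling contributions to lateral spread, LET-dependent
RBE, and any tissue biology beyond a scalar sparing factor.

## Stopping power and range

Electronic stopping is the plain Bethe formula with water's mean excitation
energy fixed at 75 eV, density 1 g/cm³, 3.3428·10²³ electrons/g. Shell,
Barkas and density-effect corrections are omitted: they are sub-percent over
the therapeutic window and irrelevant at the precision of minibeam design
numbers. The CSDA range integrates a·dE′/S(E′) from a 1 MeV/u cutoff on an
800-point log-spaced grid; the residual range below the cutoff (< 0.1 mm) is
dropped. Range and energy-for-range are mutual inverses through the same
monotone (PCHIP) spline, so round trips close far below the 0.01 cm
tolerance. Per-nucleon rest energies are taken from the shipped species
table (`data/species.tsv`, nuclear rest energy / A; e.g. 938.272 MeV for the
proton, 931.238 MeV/u for C-12).

Useful scaling built into these formulas: at equal E/A, stopping scales as
z², ranges as A/z², and the Highland scattering angle as z/pβc — which is
why He-4 tracks the proton range exactly (A/z² = 1) while broadening half as
much, and why C-12 both stops sooner and stays narrow.

## Lateral broadening

The transported state is the Fermi–Eyges second-moment triple
A₀ = ⟨θ²⟩ (rad²), A₁ = ⟨xθ⟩, A₂ = ⟨x²⟩ (mm²), advanced as
dA₀ = T dz, dA₁ = A₀ dz, dA₂ = 2A₁ dz, with the incident profile variance
and angular divergence (default 0 mrad — collimator optics are not modelled)
as initial conditions. The scattering power is the differential Highland
form

    T(x) = (14.1 MeV · z / pβc(x))² / X₀ · f(x),
    f(x) = clip[(1 + log10(x/X₀)/9)², 0.25, 1.0],

with X₀ = 36.08 g/cm² for water and the logarithmic correction evaluated at
the **cumulative** thickness x. Evaluating the Highland correction on each
thin step in isolation is a known way to underestimate widths (the log term
sees only dz); tying it to the cumulative path restores the single-slab
Highland numbers. The clamp keeps f finite in the first few microns. The
residual energy entering pβc comes from the range-energy relation, which is
exact under CSDA.

Transport refuses to go beyond 95% of the CSDA range: near the Bragg peak
the Gaussian small-angle picture (and the moment truncation) breaks down.

**Width convention.** "Width" is always the FWHM of the lateral dose
profile — the film-measurement observable. The incident slit/pinhole profile
is approximated by a Gaussian of equal FWHM and folded in quadrature:
FWHM(z)² = FWHM_incident² + (2.3548)²·A₂_mcs(z). A top-hat incident profile
is available (`incident_profile: tophat`, FWHM of the erf-convolution found
by root finding); it differs from the Gaussian form by under 5% at
merge-relevant widths. Planar (1-D) and pencil (radial) beams have the same
transverse FWHM because the scattering kernel is isotropic; they differ only
at the array level.

**Step sizes.** Transport uses 0.1-mm steps by default; halving the step
changes widths by < 0.2% (tested). Width-versus-depth curves are monotone,
so depth-for-width and the FWHM-rule merge depth are monotone root finds
with residuals below 1 µm.

## Monte Carlo oracle

`mc_transport` is a condensed-history random walk in (x, θ) sharing the same
scattering power: per step the angular kick has variance T dz, and the
correlated position increment is sampled from the exact within-step
Fermi–Eyges covariance (⟨δxδθ⟩ = T dz²/2, ⟨δx²⟩ = T dz³/3), so the walk
reproduces the moment solution at any step size and the comparison tests
only the moment bookkeeping, not the step discretisation. It is
seed-reproducible bit for bit (numpy `default_rng`). At 10⁵ histories the
empirical FWHM agrees with the moment model within 3 standard errors of the
Gaussian width estimator (σ/√(2n)) on all tested planes.

## Arrays, PVDR and merge depth

Array profiles superpose per-beam Gaussian kernels at comb (planar) or
square-lattice (pencil) sites, on a lateral grid (default 0.01 mm) centred
on the central beam; pencil profiles are evaluated along a lattice row,
summing all rows within 6σ. Kernels are area-normalised so a single beam has
unit surface peak dose; the laterally integrated dose of a planar array
profile is then depth-independent to < 0.5% (scattering redistributes, it
does not absorb). PVDR is the mean dose at the three central beam sites over
the mean at the interior valley midpoints — edge periods are excluded — and
a profile whose peak-valley contrast falls below 10⁻⁹ is reported as merged
(PVDR 1).

"Fully merged" has no universal definition, so both rules are always
computed and reported together:

* **valley rule** (default): smallest depth with valley/peak ≥ 0.95, by
  root finding on the monotone valley/peak(z);
* **fwhm rule**: depth where the beam FWHM equals the on-center spacing.

The two agree within ~7% on the 10-cm-range fixtures (15% is the documented
ceiling). Pencil lattices merge no earlier than planar combs of equal
geometry because their 2-D valleys are deeper.

## Collimator and dose bookkeeping

Collimator yield is geometric: width/spacing for a multislit (planar),
π(width/2)²/spacing² for pinholes on a square lattice (the square lattice is
validated by the closed-form yields 28.3% at 0.3/0.5 mm and 14.4% at
0.3/0.7 mm). The incident-dose factor is exactly 1/yield; bookkeeping
reports quote it to one decimal, and the estimated biological entrance ratio
divides that rounded factor by the scalar tissue-sparing factor (default
7.0, a literature-anchored estimate exposed as user input; 2.3/7.0 = 0.33).

## Bragg curves and SOBP

A pristine Bragg curve is the stopping power at the residual energy,
convolved with a Gaussian range-straggling kernel
σ_R = 0.012·R⁰·⁹³⁵ cm (a standard water parameterisation for protons),
scaled by 1/√A for heavier ions, and zeroed beyond the straggled range.
Without nuclear fluence loss the entrance-to-peak ratio comes out lower than
measured curves (≈ 0.14 for a 109-MeV proton) — acceptable here because only
depth structure and normalised comparisons are used downstream.

SOBP layer ranges are spaced uniformly from the proximal depth to the distal
depth **plus 2σ_R**: without that overshoot the last plateau points ride the
distal falloff and no weighting can flatten them (the plain stack leaves a
~30% ripple; with the overshoot the achieved flatness is ~0.1–0.2%,
comfortably below the 3% goal). Weights are solved by non-negative least
squares against a unit plateau (deterministic), default one layer per mm of
span, and the curve is normalised to unit plateau mean. A single layer
degenerates to the pristine curve.

The 10-MV photon comparison curve is D(z) = (1 − e^(−βz))·e^(−μz) with
μ = 0.003/mm and β solved so the maximum sits at 25 mm, giving ~64% of
maximum at 150 mm — textbook values, present only as a baseline.

**Three-curve comparison.** All curves share unit SOBP-plateau-mean
normalisation (the plateau is the clinically prescribed quantity; an
entrance normalisation would be an equally defensible alternative). The
minibeam "estimated biological" curve multiplies the solid SOBP by a factor
that is incident_dose_factor/sparing_factor at the surface and 1 from the
merge depth on; only those endpoints are constrained, and the ramp between
them is linear — a documented choice, not a modelled transition.

## Interleaved arrays

The composed slice spans the ±x beam axis and the plane-stacking axis v; the
±y arrays of the orthogonal pair intersect that slice only inside the
target. Conventions: within a 90° pair the partner array is offset by half
the on-center spacing (so the pair's planes stack every spacing/2 in the
target); the second pair is offset a further quarter spacing; the beam
energy is chosen so the range equals the target's distal edge; the phantom
is symmetric unless an extent is given. Coverage at the target-proximal edge
(where beams are narrowest inside the target) requires the stacked planes to
abut — width within ±10% of the half-spacing counts as abutting on the gap
side, widths more than 10% beyond flag an over-dose seam — and the width not
to exceed the 0.7-mm sparing limit. Exact abutment is a measure-zero
condition, hence the tolerance band; ±10% mirrors the overlap allowance.

Inside the target each full pair contributes pedestal × (pedestal→SOBP
ratio) — the two arrays of a pair do not sum, their planes fill alternate
slots — and pairs add; the map paints the solid composite there and each
array's own comb (at the transported width) outside. The pedestal→SOBP ratio
(20/14 for the canonical carbon case) depends on the accelerator's SOBP
weighting and is a plan input, not a computed quantity. GyE = physical dose
× scalar RBE (carbon default 3.0), everywhere.

The maximum allowable proximal depth re-chooses the energy at every
candidate depth d (range = d + 20 mm default target margin) and bisects for
FWHM(d) = width limit.

The incident-dose factor bracket for two-pair carbon delivery is
(2 × spacing/width) at the upper end (pair non-additivity × surface comb
dilution). The lower end uses 2.0 × spacing/width_at_target as the dilution
— the 2.0 scale reproduces the conventionally quoted lower endpoint, whose
derivation is not documented in the literature; the unscaled alternative
(spacing/width_at_target) would give half this. The lower value is clamped
to the upper one.

## Fixtures: what they emulate and what they do not

The five canonical configurations regenerate byte-identically and encode the
published study geometries: the 109-MeV proton pencil film measurement, the
10-cm-range proton and Li-7 planar arrays (1.0-mm on-center), a He-4 pencil
lattice as the pencil-array representative, and the four-directional
interleaved-carbon rabbit plan (0.3 mm / 1.05 mm, target proximal edge at
36 mm, 14-Gy pedestal, RBE 3.0). They emulate geometry and beam parameters
only: clean monoenergetic beams, perfect collimation, homogeneous water. No
film response, positioning error, beamline energy spread or anatomy. Tests
passing on these fixtures validate the model arithmetic and its internal
consistency — not agreement with tissue measurements.

## Known limitations

* The Fermi–Eyges/Highland model carries the **Gaussian core** of the MCS
  distribution. Full Monte Carlo dose profiles additionally contain
  non-Gaussian MCS tails, large-angle single scattering and nuclear
  secondaries, which both widen film-observable FWHMs at depth and fill
  inter-beam valleys faster. Consequently this model reproduces
  incident-width-dominated observables closely (the carbon width at 36 mm
  agrees within ~2%) but reaches target widths and especially merge
  conditions systematically deeper than published Monte Carlo figures — by
  roughly 20–35% for the proton and Li-7 geometries. Merge depths from this
  package should be read as upper bounds.
* No fragmentation tail beyond the carbon distal edge; carbon SOBPs are
  optimistic distally.
* Transport stops at 95% of range; nothing near or past the Bragg peak is
  said about lateral spread.
* The sparing factor, RBE and pedestal→SOBP ratio are scalar inputs; the
  package propagates, it does not predict them.
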