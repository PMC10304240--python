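# Methods

`mitolens` simulates light transport through a *lens mitochondrion*: a
sphere of radius R ≈ 1 µm, found in tree-shrew cone inner segments,
filled with a cubic membrane of the gyroid type — twelve lipid bilayers
stacked into a wall that follows a triply periodic surface and divides
the interior into two interpenetrating labyrinth compartments. The
package asks what such an organelle does to visible and near-UV light:
where it focuses, what it filters, and how robust that behaviour is to
orientation.

## Geometry

The gyroid mid-surface is the zero level set of

    g(u, v, w) = sin u cos v + sin v cos w + sin w cos u,
    u = 2π x / a  (etc.)

in rotated, phase-shifted lattice coordinates, clipped to the sphere.
The lattice constant defaults to `a = 400 nm`, so the default sphere
spans five unit cells (≈ 65 whole cells by the volume ratio). Space is
labelled compartment A where g > 0 (tie resolved to A) and compartment
B where g < 0; the level set bisects space, so each labyrinth holds
half the interior volume.

The twelve physical bilayers are collapsed onto this single mid-surface
(a *center approximation*): collisions are detected on g = 0 only,
while the full layered optics of the wall enters through the
scattering amplitudes (below). Consequences of this choice: the wall
has zero geometric volume (it cannot shadow itself), and a 131.6 nm
stack is represented at a surface whose sheet-to-sheet spacing is
~200 nm — acceptable because the stack is thin compared to the
wavelength, which is the same regime that justifies treating it as
locally flat.

Ray/surface intersections are found by marching along the ray in steps
of a/50 (8 nm) and refining each bracketed sign change by bisection to
0.1 nm — far below the smallest layer thickness (1.8 nm). A ray
tangent to the surface can graze a zero of g without a sign change;
such contacts transmit no event, which is the correct measure-zero
limit. After every scattering event the children are nudged 0.2 nm off
the surface along the normal so the next march starts on the correct
side (phase error ≲ 0.003 rad per event).

## Wall optics

The wall between the compartments is a stratified stack of 25 media:
the two bounding compartments plus 12 lipid films (n = 1.70,
d = 1.8 nm) alternating with 11 cytosolic gaps (n = 1.38, d = 10 nm).
Indices are bulk values at the sodium D line; material dispersion is
unknown for these constituents and is not modelled, so every
wavelength dependence the simulator produces is structural
(interference), not material.

Each film contributes the standard characteristic matrix

    M = [[cos δ, i sin δ / γ], [i γ sin δ, cos δ]],   δ = k₀ n d cos θ

with admittance γ = n cos θ (s polarization) or n / cos θ (p); the
vacuum admittance cancels in every amplitude ratio and is set to 1.
The stack response is the ordered matrix product; r and t follow from
tangential-field continuity against the bounding media, with the
conventions fixed so that a bare 1.0→1.5 interface at normal incidence
gives r = −0.2 and the p-state transmission carries the cos θᵢ/cos θₜ
factor. Transmittance is the Poynting flux ratio
T = Re(nₛ cos θₛ)/(n₀ cos θ₀)·|t|², which guarantees R + T = 1 for
lossless stacks; the suite verifies this on 10⁴ random stacks and
checks the full complex amplitudes against an independent Airy
(recursive Fresnel) summation. Evanescent layers inside the stack are
carried with complex cosines (frustrated TIR is exact); total internal
reflection is declared only when the substrate wave is evanescent,
tested by the exact Snell criterion at the bounding compartments, and
then the reflection is forced to unit modulus with its phase retained.
Grazing incidence (90°) is evaluated one-sided (90° − 10⁻⁶ rad).

During transport the wall response is pre-tabulated per wavelength on
a 2048-point incidence-angle grid for both crossing directions and
both polarizations, linearly interpolated, and re-normalized per
lookup so each scattering event is exactly lossless; the energy ledger
then closes to float accumulation (~10⁻¹⁵ relative).

## Equivalent closed bilayer

For coarse-grained modelling the wall can be replaced by a
four-parameter "closed bilayer" X = {na, nb, da, db}, fitted by
minimising the L1 distance between polarized reflectance grids
(λ = 400–800 nm in 5 nm steps, θ = 0–90° in 1° steps):

    min_X Σᵢⱼ |R⊥ − R̂⊥| + |R∥ − R̂∥|

Two topologies are supported. The default is the closed symmetric
sandwich [na, da][nb, db][na, da] (an outer leaflet of thickness da on
each face of a core), which is both the natural reading of a "closed"
bilayer and the variant whose optimum reproduces the published
equivalent parameters; the minimal two-layer stack [na, da][nb, db] is
available behind a switch, but its global optimum is simply a
mean-index slab. Optimizer bounds default to the material range
n ∈ [1.33, 1.70] (cytosol to pure lipid): allowing indices below
cytosol lets the core drift to a value no membrane constituent has.
The optimization is a multi-start (≥ 8 scrambled-Sobol points plus any
user init) bound-constrained Powell search with a Nelder–Mead polish —
the objective has a long curved valley in which Powell's line searches
stall. The fitted core index equals the surrounding cytosol, which
makes the core thickness db only weakly identified: the objective
changes by < 5 % across db ± 5 nm at the optimum. The fit preserves
the wall's outer-film character (na ≈ 1.55, da ≈ 30 nm) much more
sharply than its total thickness.

## Monte Carlo transport

A plane wave is represented by unit-energy ray packets on a square y–z
grid restricted to the disc of radius R (every ray meets the sphere),
launched along +x one radius upstream. Each packet carries complex s-
and p-amplitudes in a transverse basis; energy is |A_s|² + |A_p|².
Between events the basis is rotated minimally into each new plane of
incidence (at exact normal incidence the previous basis is kept), and
the optical phase 2π n ℓ / λ of the traversed segment is folded into
the amplitudes. At a wall crossing the children's amplitudes are the
parent's times the complex r or t per polarization, with t pre-scaled
by √(T/|t|²) so squared amplitude remains energy; the sphere envelope
is a bare Fresnel interface between the inner compartment and the
exterior. Refraction across the collapsed wall uses the compartment
indices (the interior layers cancel in the Snell invariant).

Splitting strategies:

* **i — Russian roulette.** One child survives with probability equal
  to its energy share and is rescaled by 1/√p; unbiased, needs many
  rays. Uses the seeded RNG.
* **ii — branch pursuit (default).** Both children are followed; a
  child below ε times the per-ray input energy (default ε = 10⁻⁹) is
  dropped into the discard ledger. Fully deterministic and independent
  of packet processing order; the engine processes whole generations
  as arrays.
* **iii — diffraction fan.** As (ii), with each transmitted child fanned
  into three rays (weights ¼ ½ ¼) spread ±λ/(π·spacing) in the plane
  of incidence. The fan is applied only for the first six generations —
  an unconditional fan grows the tree as 3^depth — and the strategy is
  retained for completeness, off by default.

The generation depth is capped at 60 (discards logged separately and a
warning raised if they exceed 0.1 % of the input). Packets exiting
backward are recorded as back-scattered energy, not discarded; the
ledger identity input = exited + discarded holds to ~10⁻¹⁵ for
strategies i–iii. For the default model ~96 % of the input exits
forward, ~4 % back-scatters, and the discard at ε = 10⁻⁹ is below
10⁻⁵ of the input.

## Near-field integration

Two integration models turn exit packets into intensity maps on planes
behind the rear pole (the axial datum for all reported distances):

* **First order (wave).** Forward packets fly straight to a virtual
  capture plane tangent to the rear pole and are deposited as complex
  field samples (cloud-in-cell; amplitudes scaled by
  source-spacing/pixel so an extended field's summed intensity equals
  its energy). The captured field is carried to any image plane by the
  exact scalar angular-spectrum propagator (evanescent components
  dropped), which conserves power and needs no tunable kernel. A
  legacy per-plane variant (geometric landing + Airy PSF whose NA is
  the sphere's opening angle) is available as `method="geometric"`.
* **Patch (Huygens).** Forward packets are binned coherently onto
  ~100 nm angular patches of the sphere (phases referred to patch
  centres along each packet's direction); each patch re-emits a
  1/(iλ)·cos χ obliquity-weighted spherical wavelet integrated onto
  the plane.

A fundamental limitation shared by any ray decomposition of this
structure: neighbouring rays that take different split sequences lose
mutual coherence, so at finite sampling only part of the exit field
(1–3 % of the energy for the default model at 10 nm ray spacing)
survives as a deterministic coherent field; the remainder is a diffuse
speckle background. The focal curves are converged in sampling between
5 and 10 nm spacing, and the two integration models place the best
plane within one step of each other, but absolute map power is not
energy-complete. For this reason all *energy* observables — flux
ratios and the rotation-sweep metrics — are computed geometrically
(full packet energies landing in the target disk), which is exact
bookkeeping and sampling-robust, while *focus* observables use the
coherent field maps, where interference is the phenomenon of interest.

Observable definitions:

* **find_focus** — plane of maximum peak intensity over a 0.5–6 µm scan
  (0.1 µm step; extended to 12 µm at 800 nm); "centred" requires the
  peak within 2 pixels (λ/2) of the axis, and "found" requires it to
  exceed 1.05× the uniform-background level of the forward energy.
* **flux_ratio_spectrum** — energy through the mitochondrion-diameter
  disk divided by the free-propagation flux (analytically the input
  power, since undisturbed rays all cross the disk).
* **rotation_sweep** — lattice rotated about an axis ⊥ propagation;
  reports (max − min)/mean of total forward energy and of the central
  beam (disk of radius R/4 at the zero-angle focus plane). The R/4
  radius and the variation metric are this package's definitions.
* **waveguide_diagnostics** — high-index-compartment share of the exit
  energy on the rear polar cap (cos > 0.75, where the axis-aligned
  channels terminate) versus its share of the cap area. Over the full
  hemisphere the share is *depressed* (~2 pp) because high-index exits
  also face the stronger boundary reflection and TIR; on the cap it is
  enhanced by ~3 pp, and in this model the enhancement is flat in
  wavelength.

## Study conditions and problem sizes

Defaults are the study conditions: R = 1000 nm, a = 400 nm,
n_A = n_exterior = 1.33 (cytosol), n_B = 1.48 (upper end of the
plausible 1.38–1.48 range, where the chromatic effects are clearest),
the 25-medium wall, source along +x. The discard
criterion runs at ~4000 rays (28 nm spacing) with ε = 10⁻⁹; focal
scans use 10 nm spacing (~31 000 rays) with ε = 10⁻⁵ (the two ε values
give identical focal curves; the looser one halves the branch tree);
rotation and spectral sweeps use ~4000 rays per condition. These sizes
give sampling-converged focal positions and sub-percent energy
statistics while keeping a full analysis within tens of minutes on one
core.

## Known limitations

* Geometric ray chaos limits the coherent fraction of the exit field;
  map-based absolute intensities are lower bounds (see above).
* Direction scrambling at membrane crossings is wavelength-independent
  in a ray model, so the UV flux reduction is dominated by angular
  dispersal rather than by a spectral bandgap; the reduction grows
  with plane distance as the scattered cone outruns the reference
  disk.
* No material dispersion, no absorption, no deformation of the
  envelope; the wall is everywhere the same stack.
* The center approximation removes wall volume; volume-fraction
  reports estimate the wall band by |g|/|∇g| distance and cannot
  reproduce compartment fractions derived from electron-microscopy
  segmentations with a 131.6 nm wall in a 400 nm cell (the band would
  fill the cell).
* The patch integrator's plane-wave reconstruction carries ~30 %
  ripple at 100 nm patches with ~5 rays per patch; it serves as a
  cross-check of *where* light goes, not as a precision field solver.
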