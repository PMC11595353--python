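# Methods

`retistim` simulates extracellular electrical stimulation of retinal
ganglion cells (RGCs) by epiretinal prostheses and predicts two things:
the footprint of the evoked phosphene for a 2D hexagonal surface array,
and whether a 3D penetrating linear-carrier pair can activate a *single*
cell.  This note records the models, the parameters that matter, the
numerical choices, and the limits of what the simulations show.

## Volume-conductor field model

The retina is a stack of plane-parallel slabs (vitreous, ganglionic layer,
inner nuclear layer where applicable, photoreceptor layer, pigment
epithelium), each with a bulk conductivity; the ~22 mm curvature of the
eye wall is negligible at the sub-millimetre scale of arrays and cells and
is dropped (nominal eye diameters are kept as stack metadata).  Injected
currents establish a quasi-static potential obeying ∇·(σ∇V) = 0.
Capacitive tissue currents are neglected: the stimuli have spectral
content in the 100 Hz–10 kHz range where retinal tissue is predominantly
resistive, and a purely resistive field *factorizes in time* — one
unit-current solve per electrode pair, scaled by the waveform, serves
every cell position and stimulus amplitude.  This solve-once/scale-many
structure is what makes the cell-shifting percept search tractable.

Discretization: 7-point finite differences on a regular voxel grid with
harmonic-mean face conductivities, solved by Jacobi-preconditioned
conjugate gradients to a relative residual of 1e-8.  The active electrode
injects its current uniformly over the disc face (ideal current source);
the ground electrode is an ideal conductor held at 0 V.  A pure
two-source formulation (`ground_mode="source"`) is available and is used
to verify reciprocity exactly.  Insulating solids (polyimide substrate
and carrier shanks, σ = 1e-17 S/m) are excluded from the linear system;
the outer boundary is insulating, with optional Dirichlet values used for
manufactured-solution verification against the monopole closed form
(≤ 2 % error for r ≥ 10h, decreasing under refinement).

Grid spacings: 10 µm for hexagonal-array scenes (resolves the 100 µm
electrodes and 500 µm pitch).  For the linear-carrier scene the spacing
is λ/10 ≈ 1.075 µm, chosen so that the two electrode faces at x = ±λ/2
fall exactly on voxel boundaries and the inter-carrier gap resolves into
ten cells; a uniform "round" spacing cannot align both faces and would
stagger the two electrodes differently.  Each hexagonal pair is solved on
a subdomain extending 1 mm beyond the pair's bounding box; percepts at
the smallest proximity can exceed that subdomain and are then truncated
by the search radius, which is reported via the boundary's `clipped`
flag.

## Field-to-membrane coupling

The membrane model is driven by the *boundary current density* J_c: the
current density on the cell's spherical surface, averaged over a
deterministic 128-point Fibonacci covering and scaled by the waveform.
The forward solve treats the cell as transparent (the membrane does not
perturb the field), so a choice must be made about which component of the
undisturbed field stands in for the membrane drive of a real cell.  The
default is the surface-averaged **magnitude** |J|.  Rationale: a real
cell is effectively insulating at these frequencies and deflects the
current around itself; for uniform flow the surface-average of the
current-density magnitude on an insulating sphere is 1.18·|J∞|, which the
transparent-sphere |J| average (= |J∞|) approximates closely, whereas the
normal-component average |J·n̂| (= |J∞|/2) undercounts the drive by the
flow-around factor of ≈ 2.4.  The normal-component variant remains
available (`component="normal"`), as does an explicit resistive-inclusion
solve in which the cell sphere is painted with the membrane conductivity.

The sign convention linking the extracellular drive to depolarization is
not determined by the field solution alone; the model takes the leading
lobe of the pulse as depolarizing (switchable by negating the drive).

## RGC membrane model

Single-compartment current balance with the five voltage-gated
conductances of the classic published RGC parameterization — fast Na,
Ca, delayed-rectifier K, A-type K, Ca-activated K — plus ohmic leak:

    C_m dV/dt = −(I_Na + I_Ca + I_K + I_A + I_KCa + I_L) + J_c(t)

with C_m = 1 µF/cm², ḡ = 50 / 2.2 / 12 / 36 / 0.05 / 0.05 mS/cm²,
E_Na = +35 mV, E_K = −75 mV, E_Ca Nernstian from intracellular calcium
([Ca]_o = 1.8 mM, resting [Ca]_i = 0.1 µM, removal τ = 1.5 ms, shell
radius 5 µm), K_Ca half-activation at [Ca]_i = 1 µM, room temperature.
The leak reversal is set to −65 mV so the model rests at its published
value (−64.95 mV here); all parameters live in a versioned JSON document
(`data/membrane_fohlmeister.json`) so alternative printed sets can be
swapped without code changes.  J_c enters directly as an areal current
(1 A/m² = 100 µA/cm²), depolarizing for positive drive.

Integration uses LSODA with a fixed output grid (default 2 µs during the
pulse), relative tolerance 1e-8; there is no randomness anywhere.
*Activation* means a membrane excursion of at least +30 mV above rest,
inclusive at the boundary for determinism.  *Threshold search* raises the
peak amplitude from 0.1 nA in 0.1 nA steps until activation, reusing the
unit field across steps; a bisection-refined threshold density
(`threshold_density`) provides the membrane-side threshold for a pulse
shape independent of geometry.

Measured membrane-side thresholds with the default parameters:
2.66 A/m² for the 100 µs linear-decrease pulse and 3.20 A/m² for the
94 µs-per-phase biphasic pulse.  A caveat found in testing: after a
spike the model shows a slow afterhyperpolarization of ≈ 3 mV that has
not fully decayed 10 ms after the pulse.  The functional independence
assumed when percepts from separately pulsed pairs are unioned still
holds — a second identical pulse 10 ms later fires normally — and that
is the property the test suite asserts.

## Percept mapping (stimulus criterion)

The percept of one electrode pair is the retinal region where a model
cell is activated.  The search places the cell concentric with the
active electrode at a fixed depth (cell top at the retinal surface),
marches outward along 16 radial rays in 5 µm steps, and bisects each
activation transition to 0.5 µm.  A silent centre with an activated
annulus yields a ring percept (inner and outer boundary); a completely
silent field within the 1.5 mm search radius yields a no-stimulation
signal, upon which the injected current may be escalated (factor 2, cap
4× the base amplitude).  Because activation is monotone in amplitude
(property-tested against the full membrane integration), the default
predicate compares the position's J_c at the stimulus peak against the
pulse shape's threshold density — exact, and thousands of times cheaper
than re-integrating the membrane at every probe position.  Percepts from
several pairs are combined as a geometric union (shapely), reflecting
shapes rather than brightness; cell counts are union area × areal
density (31,300 mm⁻²), floored.

The 16-gon formed by the ray vertices underestimates a disc's area by
the inscribed-polygon factor (n/2π)·sin(2π/n) ≈ 2.6 % at n = 16; tests
compare against the polygon closed form and use 32 rays where the 2 %
union-area checks apply.

Tilt: rotating the array about a width-parallel axis through its near
edge (the pivot keeps the minimum proximity fixed) displaces each
electrode toward the retina by (x − x_pivot)·sinθ.  Mirror asymmetry of
a percept is quantified as symmetric-difference area over union area
under reflection across the pair's perpendicular bisector.  The untilted
baseline is not exactly zero (≈ 0.03): the active and ground electrodes
obey different boundary conditions (current source vs equipotential), and
the sphere covering is not reflection-symmetric; at 2° and 4° the metric
rises to ≈ 0.08 and ≈ 0.20.

## 3D carrier selectivity

The volumetric density profile ρ_v(z) through the 60 µm ganglion layer is
a cubic polynomial normalized so its integral reproduces the areal
density; the shipped operating point uses the peak density
ρ_v = 8.05×10⁻⁴ µm⁻³ (the polynomial behind it is regenerable from
photomicrograph samples via `fit_density_profile`).  The criterion:
v = ρ_v⁻¹ ≈ 1242 µm³ is the volume statistically enclosed by one cell,
treated as a cube of edge λ = v^{1/3} ≈ 10.75 µm; λ is also the
face-to-face separation of the 7.5 µm electrodes on adjacent carriers,
placed at the peak-density depth (mid-layer) with a 10 µm cell midway.
A pair is *selective* when the |J| ≥ J_c(threshold) region at the found
threshold fits within v and the mid-placed cell fires.  With the default
scene the threshold search gives 0.4 nA (one 0.1 nA step below the
reference operating point), a cell-boundary peak drive of 2.9 A/m², a
suprathreshold volume of ≈ 435 µm³ — selective — and a charge density of
4.5×10⁻⁵ mC/cm² at the found threshold, far below the conservative 0.1 mC/cm²
platinum bound.

## Electrochemical safety

Charge per phase (|i| integrated over one phase; the whole pulse for the
monophasic shape) divided by the flat disc area, in mC/cm², compared
inclusively against per-material charge-injection limits (platinum
0.1–0.35, platinum gray 1.0, titanium nitride 0.9 mC/cm²; coated
materials default to the conservative lower platinum bound).  Heating is
reported only as ohmic dissipated power P(t) = i(t)²·R_access with the
access resistance from the unit field (equal to ∫σ|∇V|² dV by energy
balance, verified to 3 %); no tissue-temperature model is attached, so no
temperature numbers are invented.

## What the synthetic scenes do and do not capture

The scenes encode the published geometry and materials: Table-style layer
stacks, the 25-electrode hexagonal array (100 µm discs, 500 µm pitch,
5×5 hexagonal packing on a 2×4 mm substrate), the carrier pair, and the
clinical stimulus (13 µA, 94 µs/phase, 100 Hz, charge-balanced biphasic).
Subject stimulation patterns are shipped as editable JSON pair lists
*reconstructed from figure panels* and are approximations, not printed
data.  Passing tests therefore show that the pipeline reproduces the
study's quantitative operating point and qualitative percept behaviors
(shrinkage with proximity, growth with amplitude, tilt-induced
asymmetry) under these idealized conditions — not that it predicts any
individual patient's drawings.  Known idealizations: homogeneous layer
conductivities; spherical single-compartment cells with no axon (so no
axon-of-passage streaks); no retinal network cells; no brightness or
fading dynamics; percept truncation at the solved subdomain for the
largest percepts.

## Degenerate inputs and tie-breaks

Zero-amplitude waveforms propagate as identically zero drives and empty
percepts.  Activation exactly at +30 mV counts as activated; charge
density exactly at a material limit counts as safe.  A cell whose sphere
would leave the ganglion layer raises a placement error (the cell-shifting
loop's stop signal); a cell surface leaving the solved subdomain is
treated as silent during boundary marching.  Boundaries with fewer than
three activated rays are reported as no stimulation.
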