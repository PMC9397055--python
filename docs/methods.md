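# Methods

## Scaffold geometry

A design is a `ScaffoldSpec`: bounding dimensions, layer count, fibre
diameter, pore size(s), and the 0/90 lay-down rule. "Pore size" is the
clear edge-to-edge spacing between adjacent parallel filaments in a
layer, so the centre-to-centre spacing is `pore + fibre_diameter` — the
standard convention for extrusion scaffolds. Per layer, as many
filaments as fit are placed at that spacing, `floor(W / s) + 1`, centred
so the two margins are equal. Consecutive layers alternate between the
x and y directions and are stacked at a vertical pitch (default
`height / n_layers`, 0.31 mm for the catalogue designs) smaller than the
fibre diameter (0.33 mm), so neighbouring layers interpenetrate by
0.02 mm and fuse into one body. The bottom layer is tangent to the base
plane and the stack is cut flush at the nominal height; filament ends
are cut flush with the envelope (no end caps protrude).

The catalogue parameters follow the consolidated design record (10
layers, 0.33 mm fibre, 3.1 mm height); where a prose description
disagrees with that record the record wins, because only it is
consistent with the height/pitch arithmetic.

Porosity is reported as the void fraction 1 − V_material/V_domain. Note
the material-volume ratio sometimes written as "porosity" in design
tables is only consistent with catalogue values when read as the void
fraction; that reading is implemented.

**Volume integration.** The union volume of the fused filament stack is
computed semi-analytically, not from a mesh: each filament contributes
its z-clipped circular cross-section (circular-segment formula) times
its span length; perpendicular filaments of vertically adjacent layers
overlap only inside the thin height window where both layer circles are
active (width `2r − pitch` = 0.02 mm), and those pairwise overlaps are
integrated by midpoint quadrature (400 points per window) and
subtracted. Same-orientation layers are two pitches apart (> one
diameter) and never intersect. For the graded-ring family, filaments
are chords of elliptical annuli (boundaries at equal radial increments
by default — the ring radii are not part of the design record);
parallel-band slivers at ring boundaries are neglected, and segments
shorter than one fibre diameter are dropped. Agreement with a
brute-force voxel integration is first order in voxel size and the
semi-analytic result is converged to < 10⁻⁴ relative.

**Surface area.** Lateral filament surfaces are integrated by
quadrature (128 azimuthal × 40 axial samples per mm); points buried in
a crossing filament or outside the envelope are discarded. Flat cuts at
ring boundaries count as surface; cuts flush with the envelope boundary
face the enclosure wall and do not. Specific surface area SA/V_domain
is reported for information only — published values for these designs
are not reproducible under any surface/volume convention we could
identify and are asserted nowhere.

**Resulting void fractions.** 1A 56.11 %, 1B 58.85 %, 1C 64.32 %,
design 2 ≈ 75.4 %. The first two agree with the published design record
to < 0.5 percentage points. Design 1C is the exception: its published
porosity (61.19 %) implies ≈ 28 filaments per layer, but only 26 fit a
20 mm footprint at the stated 0.45 + 0.33 mm spacing, and no single
pore/spacing convention reproduces all three published values at once.
The constructive value is reported as computed.

## Voxel domains

Domains are isotropic voxel lattices (occupancy by centre-point test),
flow along z (face-on inflow through the scaffold thickness, consistent
with the reported top-surface shear maxima), with open entry/exit pads
(default 1 mm at desk scale) and the scaffold's own footprint as the
duct cross-section. An enclosure radius quoted in the source material
(1 mm) is dimensionally inconsistent with a 20 mm scaffold and is not
used. Resolution floors: spacing ≤ fibre/3, and ≥ 3 voxels across the
smallest pore. Fluid not 6-connected to the inlet is flagged, removed
and counted (idempotent filter).

For the in-plane-periodic rectangular designs, the default flow domain
is one unit cell — a `(pore + fibre)²` period through the full layer
stack with periodic lateral boundaries; the spacing is snapped so the
period is an integer number of voxels. The directly built cell centres
its filament in the window (the phase differs from a cell cropped out
of a full-scaffold raster by a fraction of a voxel; cropping is also
provided and matches the full-domain interior porosity within 2
percentage points). The elliptical graded design has no period; it runs
on its footprint, by default the x ≥ 0, y ≥ 0 quarter with symmetry
planes — exact for this mirror-symmetric lay-down — at a quarter of the
cost.

## Flow solver

Marker-and-cell staggered finite differences: face-normal velocities,
cell-centred pressure. Steady state is reached by
artificial-compressibility pseudo-time marching
(dp/dt = −ρc²∇·u): at convergence the discrete divergence vanishes
identically, so the artificial sound speed c (set from the grid:
max(5ν/h, 15·u_in)) affects only the transient. The explicit update
uses CFL 0.7 against the viscous, acoustic and advective limits. The
advective term (conservative, centred) is retained by default; at the
modelled conditions it shifts the pressure drop by well under 1 %.
Boundary handling: solid walls lie exactly on voxel faces (normal
velocity zero there; tangential ghosts mirrored through the wall,
first-order at staircase corners, second-order on aligned walls);
uniform plug inlet; zero-gradient outlet with pressures reported
relative to the outlet-plane mean (zero-resistance outlet); lateral
walls, periodic images or symmetry planes as labelled.

The inlet is switched on over a half-cosine ramp lasting about two
pseudo-acoustic transits; an impulsive start excites weakly damped
sloshing modes in the open pads that otherwise dominate the convergence
tail. Convergence requires both an RMS momentum residual below 10⁻⁴
(normalised by the viscous scale µu_in/h²) and a relative velocity-field
change below 10⁻⁶ between checks (every 200 steps). On large coarse
domains (the quarter-footprint design-2 run) a residual-level sloshing
mode with relative amplitude ~10⁻⁴ never decays below the strict change
band; those runs use a 5 × 10⁻⁴ change band, where the integral
quantities (ΔP, k₀) are already stable to four significant digits.

The solver is deterministic: zero initial fields, no random state.
Velocity sweeps warm-start each solve from the previous velocity's
solution scaled by the velocity ratio (the Stokes part is exactly
linear), which the converged state does not depend on. Two
implementations share the identical stencil: a vectorised numpy
reference and fused numba kernels; a test holds them to round-off
agreement, and a second test holds the solver's pressure drop on a tiny
duct to 10⁻⁶ relative against an independently assembled sparse Stokes
system.

**Validation accuracy** (converged runs): plane-channel centreline
velocity within 0.5 % of 1.5·U at 20 voxels per gap and ΔP within 0.3 %
of 12µUL/h²; circular-tube permeability within 1.5 % of R²/8 at 30
voxels per diameter (the staircase boundary biases the effective radius
at first order — 20 voxels per diameter gives ≈ 4 %); global mass
imbalance ~10⁻⁵.

Turbulence modelling is deliberately absent: every modelled condition
has interstitial Re ≤ 0.95, two orders below the Re ≈ 8.6 Darcy bound
and far below any transition, and the wall-shear formula itself assumes
laminar flow. Isothermal, rigid walls, Newtonian rheology; molar mass
and heat capacity of the perfusate are irrelevant to this physics and
unused.

## Wall shear stress and viability

Wall elements are voxel faces between fluid and scaffold material
(enclosure walls excluded unless requested). τ_w = µ|u_t|/(h/2) from
the tangential velocity at the adjacent cell centre — one-sided,
first-order, consistent with walls on faces; a two-sample second-order
variant `(9u₁ − u₂)/(3h)` is available behind a switch. Element areas
are the voxel face areas; they sum exactly to the domain's voxel
interface area. On curved surfaces the voxel surface exceeds the smooth
surface by up to 4/π, so local τ values are correspondingly lower while
the integrated shear force is accurate (the tube validation compares
force per unit cylinder area, within 5 % of 4µU/R).

The viability indicator is the area-weighted percentage of scaffold
surface with τ_w strictly below the threshold (default 30 mPa,
configurable). It is a *surface-area* fraction: a "volume" fraction of
a surface field is not well defined, and area weighting is the only
self-consistent reading. Histograms are area-weighted with half-open
bins `[lo, hi)`, final bin closed.

Absolute viability percentages from the voxel model are not comparable
to values obtained with body-fitted meshes and per-mesh-cell weighting;
only their monotone structure (non-increasing in inlet velocity, by
Stokes linearity) and the cross-design ordering are asserted. The
published per-velocity percentages for the four catalogue designs are
carried as external reference data for the summary arithmetic (their
per-design means and pairwise differences), never as solver output.

## Perfusion metrics

ΔP is the difference of plane-averaged pressures one voxel upstream and
downstream of the scaffold slab (plane averages suppress voxel noise).
k₀ = uµL/ΔP with u the superficial inlet velocity and L the slab
thickness. Re = ρud/µ uses the pore size; for the graded design every
ring pore is checked and the maximum reported — a conservative validity
bound. Darcy validity is Re ≤ 8.6 inclusive.

## Problem sizes

Defaults are desk-scale: unit cells at 6 voxels per fibre (~10⁴ cells,
seconds per velocity), duct fixtures at 20–30 voxels across (~10⁵
cells, about a minute), and the design-2 quarter footprint at 0.1 mm
voxels (~8.5 × 10⁵ cells, a few minutes). The design-ordering
comparison runs all four designs near 0.1 mm — the only spacing band
satisfying both resolution floors for every design; the rectangular
cells snap to 0.085–0.09 mm for periodicity. Full-footprint rectangular
domains are supported through the same API for users who want them.

## Known limitations

Staircase walls limit WSS to first-order accuracy and bias
per-element stress low on curved filaments; ring boundaries in the
graded design are approximated by equal radial increments; the
parallel-band slivers there are neglected in the analytic volume;
entrance effects make whole-duct WSS averages exceed developed-flow
values (validation restricts to the developed section); and the
published 1C porosity and all published specific surface areas are
internally inconsistent with the stated design parameters, so they are
reported but not matched.
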