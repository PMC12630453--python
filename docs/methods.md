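# Methods

This note describes the models and numerical procedures implemented in
`leafarch`, the choices made where several reasonable designs existed, and
what the synthetic phantoms do and do not establish about real data.

## Labelled volumes and spatial conventions

A leaf tomogram is a 3D grid of integer class codes over seven classes
(outside, adaxial/abaxial pavement, vein, internal air, palisade, spongy).
"Mesophyll" is the union of palisade and spongy; "leaf" is everything but
outside. Two axes are explicit metadata rather than inferred: the *depth
axis* runs through the lamina, oriented adaxial → abaxial (all depth
profiles iterate along it), and the *rotation axis* is the tomographic
rotation axis. Orientation is metadata because slice naming in tomography
stacks is not standardised; for foreign files it must be supplied, never
guessed. Coordinates are 0-based and voxel-centred; physical lengths come
from the isotropic voxel pitch in μm (1.3 μm for a factor-4 downsampling
of a 0.325 μm acquisition, the regime the defaults emulate).

Analyses are restricted to the *valid cylinder*: the maximal cylinder about
the rotation axis inscribed in the in-plane bounding rectangle, i.e. radius
`min(extents)/2` about the plane centre. Only the reconstruction inside it
is trustworthy in real data; phantoms respect the same restriction so that
measured and truth quantities are counted over identical supports.

Label downsampling uses majority (mode) pooling per `factor³` block —
interpolation has no meaning for categorical data — with ties broken by a
fixed class-priority order (air > palisade > spongy > vein > pavements >
outside), so results do not depend on code numbering. Non-divisible
dimensions are padded by edge replication and recorded in metadata.

## Synthetic phantoms

The generator family is the package's ground-truth machinery; every
quantity it reports is recomputable by exhaustive voxel counting.

**Layered leaf.** Solid pavement slabs; palisade as a jittered square grid
of vertical cylinders whose staggered bottoms reach a few voxels into the
spongy slab (a planar layer transition would create an artificial porosity
spike); spongy mesophyll as two layers of spheroids whose radii are
perturbed by random low-order (l = 3, 4) real spherical harmonics, with
the perturbation amplitude set by a `lobedness` knob in [0, 1] (0.35·R at
lobedness 1). The lateral cell spacing follows from the target porosity at
the nominal cell radius; a bisection on a global radius scale then drives
the realised air-to-tissue ratio of the spongy slab (inside the valid
cylinder) to the target within ±0.02. Defaults: 80×96×96 voxels at 1.3 μm,
30-voxel palisade, 28-voxel spongy slab, 9-voxel spongy cell radius,
lobedness 0.5, spongy porosity 0.50 — the scale and porosity regime of a
mature rosette leaf. Porosity here, as everywhere in the package, is the
air-to-tissue *ratio* (not the air fraction).

**Channel phantoms** pierce a tissue slab with an air channel following an
axis-aligned waypoint polyline: straight (true tortuosity 1), serpentine
switchback (polyline length a chosen multiple of the slab thickness),
or blocked (two dead-end stubs; every start unreachable). The channel is
kept narrow (default width 3.5 voxels; 3 is the accuracy floor) and its
mouths narrower still, because a geodesic in a wide tube undercuts the
polyline by roughly the tube radius at each corner; at the default
geometry the residual undercut is ≈2.5%, well inside the 5% accuracy band
claimed for the tortuosity solver. The lateral excursion runs along the
rotation axis so the valid cylinder never clips the channel.

**Inclusion phantoms** place air spheres in tissue or tissue balls in air.
By default each sphere is joined by a thin bridge to an anchor slab of its
own phase at the bottom face, mimicking the connectedness of a real
airspace (air bodies then merge *within* the air phase, giving
negative-death persistence pairs) and the contact between neighbouring
cells (voids then separate within tissue, giving positive-birth pairs).
Without the anchors every feature would be of the "disconnected" kind.

**Gas-exchange simulator.** Steady states couple FvCB demand to the two
diffusive supplies:

    An = (1 − Γ*/cc) · min(wc, wj) − RL
    wc = Vcmax·cc / (cc + Kc(1 + O/Ko)),   wj = Jpot(Q)·cc / (4cc + 8Γ*)
    An = gsc(ca − ci) = gm(ci − cc),        gsc = gsw/1.6

solved for cc by bracketed root finding (the demand–supply difference is
strictly increasing). The minimum is taken over carboxylation velocities,
not net rates, so light limitation stays operative below the compensation
point. Γ* scales with the oxygen mole fraction (Γ*(O) = Γ*_ref·O/O_ref),
which is what makes the low-O2 calibration protocol informative. Jpot(Q)
is a rectangular hyperbola supplied directly (the fluorescence method
measures J; it does not model Jmax kinetics). Fluorescence is emitted from
the *realised* electron transport rate — the rate consistent with the
achieved assimilation — because PSII operating efficiency tracks actual
linear electron flow whichever limitation is engaged; this is precisely
the premise of the variable-J method. Default truth: gm = 0.20,
Vcmax = 60, RL = 1.0, Γ* = 42.5 (at 21% O2), s = 0.45, gsw = 0.25,
Kc = 404.9 μmol mol⁻¹ and Ko = 278.4 mmol mol⁻¹ (the canonical C3 values
near 25 °C; the estimation API deliberately ships no kinetic defaults —
they are user configuration, temperature- and species-dependent).

Measurement noise is multiplicative Gaussian on the *primary* instrument
channels — An, gsw and PSII yield — with the reported ci re-derived from
the noisy An and gsw as ci = ca − An/gsc, exactly as a gas-exchange
instrument computes it. Adding independent noise to ci would break the
internal consistency every real record has and roughly triples the
effective noise on ci − cc.

What the phantoms do **not** emulate: reconstruction and segmentation
artefacts, partial-volume mixing at interfaces, vascular architecture,
anisotropic cell walls, chloroplast positioning, and leakage/temperature
drift in gas exchange. Passing tests therefore establish correctness of
the measurement chain on clean geometry and clean steady states, not
robustness to segmentation error.

## Tissue metrics

Class volume fractions are voxel counts normalised to the leaf volume
inside the valid cylinder. Their uncertainty is a slice bootstrap: the
resampling unit is the depth-axis slice (matching the per-slice
construction of all profile statistics), 1000 resamples, with the
replicate statistics trimmed symmetrically to the central 95% mass before
taking the SD. Leaf thickness is twice the mean over slices (along the
rotation axis) of the maximum of the 2D Euclidean distance transform of
the leaf mask — the EDT maximum marks the mid-plane. The porosity profile
is the per-depth-slice air/tissue ratio; the air-surface profile counts
the air pixels 4-adjacent (in-plane) to tissue — the discrete zero level
of the air mask's signed EDT — divided by the slice's tissue pixel count.
Slices without tissue report zero. The porosity denominator is leaf∖air
(veins and pavements included); a mesophyll-only denominator is a
reasonable alternative reading and can be obtained by masking first.

Palisade cell length is the Feret diameter via inertia alignment: the
voxel coordinates of an instance are rotated into the eigenbasis of their
second-moment tensor and the largest bounding-box side (+1 voxel for the
voxel extent) is scaled to μm. Cells not touching the adaxial pavement or
not entirely inside the valid cylinder are incomplete and excluded.
Instances under 4 voxels have a degenerate tensor and are rejected. Note
this is the eigen-aligned box convention, not the global caliper maximum:
for elongated convex cells the two coincide; for a box the caliper
maximum is its diagonal and is deliberately not what is measured.

## Air-path tortuosity

For every airspace entry point p on the abaxial side (air voxels
face-adjacent to the abaxial pavement), τ(p) = d_air/d_direct, where both
distances are first-arrival solutions of the eikonal equation |∇T| = 1
from the same source front — the adaxial pavement boundary exposed to
internal air — d_air marching through the air phase only and d_direct
through the whole leaf interior. Pairing the two through the same solver
and source keeps the ratio free of the source-discretisation bias either
distance carries alone.

The solver is a first-order upwind fast-marching method (6-neighbour
stencil, binary heap with lazy deletion, frozen-only upwind values),
compiled with numba. First order is the default and the accuracy claims
(straight channel τ = 1 ± 0.02; serpentine within 5% of the polyline
ratio; open-cube point-source diagonal within 2% with exact initialisation
in a small ball around point sources) are stated for it. τ is clamped
below at 1 after division, as discretisation can make d_air fall short of
d_direct by a fraction of a voxel. Unreachable starts are excluded from
the density and maxima but their fraction is always reported.

The summary reports the density (Gaussian KDE, Scott's rule), the strict
maximum, and the 99th percentile `tau_q99`. On small phantoms the strict
maximum is an extreme statistic dominated by single deep pockets; the
percentile is the operational maximum used in the cross-group correlation
study. Both are reported so the pooling convention is never hidden.

## Persistent homology of the spongy airspace

The spongy subvolume (bounding box of the spongy class inside the valid
cylinder, padded along depth) is binarised to air vs not-air, with
out-of-cylinder voxels and crop faces treated as tissue, and converted to
a signed EDT: negative in air, positive in tissue, magnitude = Euclidean
distance to the opposite phase. Sublevel filtration of this field sweeps
from the deepest air to the deepest tissue.

The complex is the full cubical complex with voxels as top cells and face
values induced as the minimum over incident voxels. Consequently sublevel
components connect by 26-adjacency and their complement by 6-adjacency,
and the three homological dimensions admit specialised algorithms:

* dim 0 by union-find over voxels in increasing value order
  (26-connectivity; elder rule by birth value, then processing order);
* dim 2 by the dual: union-find over voxels in *decreasing* order
  (6-connectivity) with a virtual outside node adjoined to every boundary
  voxel, so complement components reaching the boundary are never voids;
  a component with maximum M merging at level m yields the pair (m, M);
* dim 1 by boundary-matrix reduction with clearing: cube columns first,
  their square pivots cleared, then square columns, whose pivots are the
  loop-creating edges.

Zero-persistence pairs are dropped; the remaining multiset is invariant
to tie-breaking order. Essential classes (one dim-0 class per connected
component of the grid) carry death = +∞ and take no quadrant. The whole
pipeline is validated against an independent naive full reduction (no
clearing, no union-find) on random volumes, as exact multisets.

Quadrants classify finite pairs by sign: Q3 (−,−) dim-0 pairs are
connected air bodies, |birth| the maximal inscribed air radius; Q2 (−,+)
are air bodies that only merge through tissue (disconnected); Q1 (+,+)
dim-2 pairs are cells separating from their neighbours within tissue,
death the inscribed cell radius. Noise features with |birth| < 1 voxel sit
on the phase boundary and are removed by default, symmetrically for both
signs. Air radii use Q3 only (Q2 optionally includable); β1 pairs are
computed and exported but not analysed. Radius distributions are
summarised by the mode of a Gaussian KDE (Scott's rule, 512-point grid).

Group comparison conventions: Welch's t-test compares per-scan modes
between groups; the two-sample KS test compares pooled radii.

## Variable-J conductance estimation

The chain is: (1) Yin calibration — OLS of An on Qin·((Fm′−F′)/Fm′)/4
over a low-O2, high-CO2 light-response series; slope = s, intercept =
−RL. (2) Apparent compensation point — per sub-saturating light, OLS of
An on ci over the low-ca steps; regressing intercepts on slopes across
lights gives the common intersection: ci* = −β, RL = −α (the
slope–intercept form of the regression-intercept approach). (3) Per
record, J = Qin·s·(Fm′−F′)/Fm′, the Harley inversion
cc = Γ*(J + 8(An+RL))/(J − 4(An+RL)), and gm = An/(ci − cc). Records with
J ≤ 4(An+RL) or non-positive gm are flagged invalid, excluded from
aggregates, and counted — never silently dropped. (4) Γ* is either fixed
(42.5 μmol mol⁻¹, inside the 40–45 normal C3 range) or iterated to the
fixed point Γ* = ci* + RL/gm_agg (tolerance 1e-6 μmol mol⁻¹, ≤100
iterations), with gm aggregated over valid records by mean (default) or
median. (5) Vcmax is the OLS slope of An on (cc − Γ*)/(cc + Kc(1+O/Ko)),
with −RL as intercept; a concave An–x relation triggers a warning that
RuBP-regeneration-limited records are biasing the slope low.

Two estimator properties deserve explicit statement, both verified by the
acceptance studies rather than assumed:

* Given exact calibration inputs, the J → cc → gm chain inverts the
  simulator exactly (machine precision), and the iterative Γ* fixed point
  is the true Γ* by construction. This isolates implementation
  correctness from method bias.
* The calibration steps carry intrinsic method biases even at zero noise.
  The Yin regression is exact only in the O2 → 0 limit; at 2% O2 the
  residual photorespiration biases s by ≈1%, which propagates to ≈6% in
  gm. The regression-intercept ci* fits straight lines to a hyperbolic
  An–ci response and lands within ≈0.3% of truth at the standard low-ca
  protocol; through Γ* this propagates to ≈0.6% in gm. Zero-noise
  recovery studies therefore run the calibration phase in its exactness
  limit, and the residual full-chain errors quoted are the method's, not
  the code's.

Under 2% multiplicative instrument noise the per-record gm is strongly
right-skewed (1/(ci − cc) is convex in the noisy gap), so mean
aggregation inflates gm by several percent; the Monte-Carlo robustness
study uses the median aggregation option (median bias ≈ −0.2% over 200
simulated datasets of 20 survey records each).

## Comparison statistics and pipeline

Welch's unequal-variance t-test (Welch–Satterthwaite df), the two-sample
KS test (asymptotic p) and Pearson correlation come from scipy behind the
module surface, each cross-checked in the tests against permutation or
longhand oracles. `bootstrap_se` resamples with replacement, trims the
replicates to the central confidence mass (0.95) and reports their SD —
the same convention as the slice bootstrap. Growth-plateau detection
computes the median per-leaf relative growth per consecutive week pair
and finds the first interval below 10% that is confirmed by the following
interval ("two-step"); the reported week linearly interpolates the
threshold crossing from the preceding interval, and a series that never
plateaus reports +∞.

The pipeline driver runs profiles → fractions → tortuosity → persistence
per volume and calibration → gm → Vcmax per gas-exchange CSV, isolates
failures per input, and writes tidy CSVs plus a manifest with versions,
seed and per-input status. Reruns with the same seed are byte-identical.

## Cross-group correlation study

The acceptance-level study builds six leaf groups — three architecture
archetypes (strongly lobed/porous, intermediate, spheroidal/dense) at two
ages each, spanning spongy porosity 0.52 → 0.26 and lobedness 0.8 → 0.15
— with three replicate phantoms per group, and correlates the per-group
mean maximum porosity against the per-group mean operational maximum
tortuosity (`tau_q99`). The inverse relation (r ≈ −0.8 at these problem
sizes) reproduces the porous-media pattern: denser spongy packing forces
air to wind around cells. Group-to-group lobedness differences partially
offset the porosity effect (lobes lengthen paths at fixed porosity),
which is why the synthetic |r| sits below the near-perfect correlations
reported for real leaf groups measured at much larger volumes.

## Problem sizes and determinism

Default study sizes: leaf phantoms 80×96×96, channel phantoms
112×160×112, inclusion phantoms 64×80×88, persistence oracle volumes
≤ 6³ (50 of them), Monte-Carlo 200 simulated datasets. All randomness
flows from explicit integer seeds through `numpy.random.default_rng`;
phantom construction, simulation, bootstraps and the whole pipeline are
bit-reproducible for a fixed seed.

## Known limitations

* The valid cylinder assumes the lamina is oriented with its depth axis
  inside the cylinder cross-section; leaves mounted obliquely would need
  resampling first.
* First-order fast marching over-estimates distances by O(h); the stated
  tolerances hold at the default geometries and degrade in channels
  narrower than ~3 voxels.
* The dim-1 persistence path (boundary-matrix reduction) is exact but not
  optimised for large volumes; radius analyses need only dims 0 and 2,
  which scale to full subvolumes.
* The Feret convention measures the eigen-aligned bounding box, which
  under-reads the caliper maximum for strongly non-convex or cubical
  shapes.
* The gas-exchange simulator has no temperature dependence and a single
  mesophyll compartment; kinetic constants are user inputs by design.
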