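# Methods

## Scope and modeling assumptions

The package implements a quasi-static, fixed-conduction-velocity model of
cardiac electrical activity:

* **Activation** is purely geometric ("fastest route"): the wavefront
  travels in straight lines inside each uniform tissue volume at that
  tissue's conduction speed, and the activation time of a node is the
  shortest travel time from any source. There is no reaction–diffusion or
  ionic dynamics, no fiber-orientation anisotropy, and no mechanical
  deformation.
* **Potentials** are a single standard action-potential waveform shifted
  by the local activation time — no repolarization heterogeneity, APD
  restitution or T-wave modeling.
* **Volume conduction** is quasi-static Laplace in piecewise-homogeneous
  compartments with zero current flux through the body surface; the
  epicardial surface potential is the source (Dirichlet) boundary.

All lengths are mm, times ms, conductivities S/m. Conduction speeds
quoted in m/s are used unchanged as mm/ms (numerically equal).

## Tissue topology

A model is a set of *hulls* (uniform tissue volumes), each bounded by one
outer *shell* and optional inner shells (holes); shells are sets of
*patches* (facet sets carrying a unique integer color index, the link to
mesh cell data). Compilation validates, in order: every facet belongs to
exactly one patch; every shell is a closed, consistently wound 2-manifold
(each edge in exactly two facets, traversed in opposite directions);
shells are normalized to outward winding (positive enclosed volume);
every inner shell lies strictly inside its hull's outer shell and inner
shells are pairwise disjoint; hull volumes are positive. Violations are
collected and reported together.

Point-in-hull queries use the generalized winding number (van
Oosterom–Strackee solid angles). Points within `1e-9 ×` the mesh
bounding-box diagonal of a boundary facet count as inside: mesh nodes lie
exactly on facets and must belong to their hull(s). Interface nodes on a
facet shared by two hulls are members of both — this is the only
conduction pathway between tissues.

## Phantoms

* **Slab** — a regular lattice split into six Kuhn tetrahedra per cell;
  one myocardial hull, a corner source at onset 0. Distances are analytic,
  which is what makes the velocity-recovery checks exact.
* **Concentric spheres** — nested icospheres (20·4^level triangles each);
  innermost surface is the epicardium, outermost the body surface with
  electrode candidate sites; compartment conductivities default to lungs
  0.04 S/m and thorax 0.2 S/m.
* **Two-chamber heart** — two overlapping spherical chambers (atrium
  radius 12 mm above a ventricle of 16 mm, wall 4 mm, lattice 3 mm)
  joined by a one-cell-layer band containing a muscular septal rim
  (myocardium) and a central insulating valve-plane disc (60 % of the
  band radius). A sinus-node source sits on the supero-lateral atrial
  wall (the superior-vena-cava border analog); one bundle branch runs
  from the septal base down the inner ventricular wall at 2 mm/ms with
  0 ms onset delay. The printed bundle "delay" unit in the source
  material is treated as a typo for ms.
* **Lesions** — edema (0.2 mm/ms, 0.0325 S/m) and scar (0, 0) regions are
  realized by re-labeling tetrahedra whose centroid falls in a box or
  sphere, without re-meshing: generation is instant and total volume is
  conserved exactly, at the cost of stair-cased lesion boundaries. A hull
  split into disconnected pieces becomes several hulls.

Voxelized curved regions can leave "pinch" edges where a label's boundary
touches itself (an edge shared by four boundary facets). A repair pass
reassigns the tetrahedron fan around each pinch to the fan's majority
label, jointly for every hull and for the outer envelope, iterating to a
fixed point; non-convergence is a generation error suggesting finer
spacing.

What the phantoms deliberately do **not** emulate: patient-specific
anatomy (crista terminalis, moderator band, real valve planes), realistic
torso shape, atrial/ventricular wall thickness variation, and the
spatial heterogeneity of real epicardial potentials. Passing tests
therefore demonstrate correctness of the algorithms under controlled
geometry, not clinical fidelity.

## Activation simulator

The visibility graph connects every node pair within a conducting hull
whose open segment crosses no boundary facet of that hull. Segments are
shrunk by `1e-6` (relative) at both endpoints before Möller–Trumbore
testing, because endpoints lie exactly on boundary facets; a determinant
below `1e-12` × the facet edge-length scale is treated as parallel (miss).
Edges never straddle hulls, so each edge's speed is well defined; parallel
edges from two hulls sharing an interface keep the fastest. Zero-speed
hulls contribute no edges, and their interior nodes are reported
*blocked* (+inf sentinel), never as a large finite time. Bundle polylines
add consecutive-node edges at bundle speed.

Shortest paths: Floyd–Warshall (dense, the reference solver) up to a
2000-node cap, with scipy's single-source Dijkstra as the mode for larger
graphs; the two agree bitwise on graphs whose weights make path sums
exactly representable, and to floating-point roundoff otherwise. Source
ties resolve to the lowest source index (metadata only).

Effective speeds are recovered as the least-squares slope of
distance-from-source against activation time. Inside a lesion the
regression uses the distance along the propagation axis referenced to the
first-activated lesion node, since the front enters through discrete
interface nodes; the residual quantization bias on the default slab is
about 0.6 % of the edema speed.

## Forward model (BEM)

Constant collocation at facet centroids on the nested closed surfaces.
For each compartment, Green's representation

`2π V(x) = ∮ (1/r) q dS + ∮ V dΩ`

is collocated on both bounding surfaces; interface conditions (potential
continuity, conductivity-weighted flux continuity) couple compartments,
and only conductivity ratios enter — scaling all conductivities leaves
the transfer matrix unchanged. Double-layer terms are analytic solid
angles (with the coplanar case explicitly zeroed — the arctangent form is
sign-unstable there); single-layer terms use the analytic uniform-source
triangle integral (edge-log formula minus `|h·Ω|`). Eliminating the
interface current densities yields the facet-level transfer operator;
node potentials are related to facet values by vertex averaging, and rows
are restricted to electrode nodes (snapped to the nearest distinct
body-surface node, tolerance two mean edge lengths). A constant epicardial
potential transfers exactly, so rows sum to 1 to solver precision. The
assembled system's reciprocal condition number is checked (error below
1e-13).

Verification: per-degree transfer gains on concentric spheres match the
analytic annulus solution `g_l = (2l+1)q^(l+1) / (l + (l+1)q^(2l+1))`,
`q = a/b` (derived from the radial Laplace solution with insulated outer
boundary and cross-checked against a finite-difference radial solve);
at icosphere subdivision level 3 the facet-level gains agree within 1.3 %
for degrees up to 4.

## Inverse mapping and activation estimation

BSPs are mean-referenced per sample (multichannel hardware records
against a reference, and the common-mode resting level carries no spatial
information), then inverted per sample by Tikhonov regularization with
λ = 0.01 in the matrix's natural units (no column scaling). The SVD
filter-factor variant (`σ/(σ²+λ²)`) is the cross-check for the
normal-equations solver.

Activation times are estimated per node from the reconstructed traces.
The default marker is a 50 % amplitude-threshold crossing of the 5-sample
smoothed trace (edge-padded moving average; baseline taken from the trace
tail, where every trace has repolarized; sub-sample linear
interpolation). The long post-upstroke plateau makes this marker robust
on noisy regularized reconstructions, where single-sample derivative
markers are dominated by noise. Nodes whose deflection amplitude is below
0.3 of the maximum node amplitude are flagged blocked — the regularized
inverse suppresses poorly observed nodes toward zero, and their timing is
meaningless. Derivative markers (max |dV/dt|; classical steepest-negative
slope for electrogram-shaped data) remain available.

Noise injection is white Gaussian scaled to a requested SNR over the
whole (referenced) recording RMS, seeded.

## Default problem sizes

The shipped configurations are desk-scale by design: slab phantoms use a
5 mm lattice (117 nodes), the two-chamber heart a 3 mm lattice
(~1100 nodes, ~1460 epicardial facets), the torso sphere icosphere level
2 (320 facets) with 62+3 electrodes, and the annulus-gain check level 3
(1280 facets per sphere). These sizes keep every analysis reproducible in
seconds to a few minutes on one CPU while leaving the algorithms
unchanged for larger meshes (caps are configurable).

## Known limitations

* Stair-cased phantom boundaries slightly bias boundary-element accuracy
  for the heart-in-torso geometry compared to smooth surfaces.
* The visibility graph is O(pairs × facets); the node cap (2000) reflects
  that cost, and the single-source mode only removes the all-pairs
  matrix, not the graph construction cost.
* λ is fixed, not L-curve-selected; the end-to-end localization accuracy
  is resolution-limited by the 65-electrode montage.
* The GEO geometry-script emitter writes one plane surface per triangle —
  faithful but verbose; it targets programmatic re-meshing, not manual
  editing.
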