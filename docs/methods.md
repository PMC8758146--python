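# Methods

This note documents the models, conventions and design choices behind
`diskconnect`, in the order the pipeline runs them.

## Conventions

Volumes are indexed `(z, y, x)`, 0-based, with the physical coordinate of a
voxel equal to `index * voxel_size_nm` at the voxel center. All internal
lengths are nm; MRC headers carry Angstroms and are converted at the I/O
boundary. Only isotropic voxels are supported (the 4x-binned tomographic data
this pipeline addresses has 1.048 nm isotropic voxels). Raw tomograms are
*density-dark* (protein = low gray value); profile analysis and
subvolume-average-style data are *density-bright*, and density-dark input is
negated on profile extraction.

## Membrane masks and between-regions

Membrane central-plane segmentations (one integer label per membrane, paired
by a `(pair_id, label_a, label_b)` table) are grown by 3 iterations of
face-adjacent (6-connected) binary dilation per side, giving ~7-voxel-thick
masks that cover the ~6.8 nm apparent membrane thickness. Pairing is an
input; automatic pairing of arbitrary segmentations is out of scope.

The cytosolic between-region of a pair contains the voxels outside both masks
for which (i) the sum of Euclidean distances to the two masks (distance
transforms, in nm) is at most `gap_max + voxel`, with `gap_max` defaulting to
the 14 nm cytosolic gap plus two voxels, and (ii) the nearest points of the
two masks lie on opposite sides of the voxel (the displacement vectors to the
two masks have non-positive dot product). Condition (ii) restricts the region
to the slab strictly between the pair; without it a generous `gap_max` would
also admit voxels behind a mask. The distance-transform formulation remains
valid for gently curved membranes.

Each between-region is normalized separately to mean 0 and standard deviation
1 (population convention, i.e. divide by N — the difference from the sample
convention is negligible at these voxel counts but must be fixed for
reproducibility). Per-pair normalization removes tomogram-scale gray-value
gradients caused by variable lamella thickness: each pair region is thin
along the gradient axis, so the gradient enters as a per-pair offset that the
normalization cancels. It does not (and is not meant to) flatten gradients
*within* a single region; the standardized values keep their spatial shape.

## Hierarchical connectivity segmentation

The threshold ramp `g_i = g_min + (i-1) g_step` runs over the normalized gray
values with defaults `(-2, -0.68, 0.02)` (67 levels). At each level the
candidate set `{v in region : gray(v) <= g_i}` is decomposed into 6-connected
components, and components face-adjacent to at least one voxel of *both*
membrane masks are "bridging". The output is the set of bridging components
with no ancestor: a component is excluded if any bridging component from a
lower level is a subset of it. Because components at increasing thresholds
are nested, a component has an ancestor exactly when it overlaps a
previously emitted root, which is what the implementation tests; an
independent brute-force oracle in the test suite verifies the equivalence by
explicit subset containment on hundreds of random instances. Non-bridging
fragments at lower levels do not create ancestry. Output connectors carry the
level `g_first` at which they first bridged, are pairwise voxel-disjoint, and
are sorted by `(g_first, lexicographically smallest voxel)` for determinism.
Threshold comparisons are inclusive (`<= g_i`) throughout, including the
binary mask at `g_max`; the one-sided choice only affects voxels exactly at
the ramp end.

### Watershed pre-mask

Connectors that touch laterally are segmented as one first-appearance group
by the plain sweep. The pre-mask splits them: a binary mask
`B = {region : gray <= g_max}` is flooded with a marker-based watershed
(Meyer-style flooding as implemented in scikit-image), with markers taken as
the connected components of `B` intersected with the medial surface — the
region voxels whose distances to the two masks differ by at most one voxel
("filled from the center between the two membranes"). Voxels on boundaries
between distinct basins are removed from the between-region before the
sweep. The flooding relief is the normalized gray value itself (default), so
basins split at the density ridge between two connector cores; a
distance-transform relief (`-EDT(B)`) is available behind the `landscape`
flag for purely geometric splitting, since the source procedure does not pin
down the relief. If no marker exists the region is returned unchanged with a
warning. Removing line voxels can only split components, never merge them;
on pathological noise a marginal bridge can lose its only path, so the
"never fewer connectors" property is guaranteed only for separated-core
geometries like the shipped fixtures, and the recovery experiments quantify
the net effect at realistic contrast.

## Connector measurements and classification

Contact points `P_mb1`/`P_mb2` are the centroids (in nm) of the connector
voxels face-adjacent to each mask. The central coordinate `C_con` is the
centroid of the connector voxels on the medial surface between the masks —
"the center between the two neighboring membranes" — falling back to the
`P_mb1`–`P_mb2` midpoint for connectors that skip the medial layer. A whole-
blob center of mass is deliberately avoided: bulky, asymmetric segmentations
would bias it toward one membrane and corrupt the spatial statistics. The
length is `L_con = ||C_con - P_mb1|| + ||C_con - P_mb2||`, which equals the
contact-to-contact chord for straight connectors and exceeds it for bent
ones. The mean gray value is taken over all connector voxels in normalized
units.

Classification: a connector is *rim* iff the 3D Euclidean distance from
`C_con` to the rim-periphery point set is <= 40 nm (inclusive), else
*interior*. The periphery is ground truth for phantoms or a user-supplied
point table for real data. Whether the 40 nm should be measured within the
membrane plane instead of in 3D is not determinable from the source
procedure; 3D is used. Nearest-neighbor distances are computed between
`C_con` coordinates within the same class. The class comparison uses the
two-sample Kolmogorov–Smirnov test with the asymptotic p-value (effective
n = n_x n_y/(n_x+n_y)); sample sizes here are hundreds to thousands, where
the asymptotic form is accurate.

### Densities and the disk-area model

Per-fraction densities are `rho = n / A` with `A` the analyzed membrane area
of that fraction, and per-disk densities `rho_tot = rho * f / 2`; the factor
2 accounts for each connector being counted from both membranes it links.
Area fractions come from the geometric disk model (defaults
`r_out = 0.65 um`, `r_in = 0.61 um`, `d_cleft = 0.02 um`, `d_rim = 0.04 um`,
i.e. a 1.3 um diameter disk with a 40 nm rim zone and a 20 nm incisure
cleft): `A_tot = pi r_out^2 - r_in d_cleft`,
`A_rim = pi(r_out^2 - r_in^2) + 2 d_rim r_in`,
`A_interior = pi r_in^2 - r_in(d_cleft + 2 d_rim)`; the three formulas
satisfy `A_tot = A_rim + A_interior` identically. The analyzed-area
denominator is estimated from the central-plane voxels with a tilt
correction: each voxel contributes `voxel^2 / cos(theta)`, where `theta` is
the angle between the local total-least-squares plane normal (5×5×5
neighborhood, windowed moments) and its nearest axis. This estimator is a
package design choice — it is exact for axis-aligned planes and accurate to
a few percent for tilted and gently curved surfaces represented as thin
one-voxel-per-column rasters.

## Profile metrics

`extract_profile` averages a square cuboid (default base 21×21 voxels) along
an arbitrary segment with trilinear sampling; averaging 441 voxels per
sample suppresses profile noise by ~21x relative to a single-voxel line.
Membrane edges are detected at 50 % of the peak height above baseline with
sub-sample linear interpolation; the baseline is the profile median, which is
robust against the cytosolic plateau (the source procedure states only "50 %
of the maximum intensity"; median baseline and linear interpolation are
package choices). The median baseline assumes the profile window is
background-dominated — measurements should window a single membrane or a
sparse stack, not a dense one. FWHM of the dominant peak gives d_PM or d_DR;
successive rising-edge spacings give stacking repeats. `d_Shift` (the offset
from a rim-subvolume center to the rim periphery) is an input here: deriving
it from real subvolume averages requires alignment, which is out of scope,
and phantoms provide it exactly. The derived distances are
`d_IN = d_1 - 2 d_Shift` and `d_PR = d_2 - d_Shift - d_PM/2`; negative
results flag inconsistent geometry on the record rather than raising.
Point-to-surface distances (`d_1`, `d_2`) use a total-least-squares plane
through the k nearest points of the opposing group (default k = 9; degenerate
collinear neighborhoods raise — with phantom centers arranged on per-disk
lines, k must be large enough to span several disks).

## Rim scaffold periodicity

Row profiles are fit by unconstrained nonlinear least squares to
`y0 + A sin(w0 x + p)` (x in samples), with `w0` seeded from the dominant
discrete-Fourier frequency and the phase/amplitude seeded from that Fourier
coefficient. A negative fitted amplitude is folded into the phase; phases are
wrapped to (-pi, pi]. The repeat length is `lambda = Ps 2 pi / w0` with
`Ps = 0.262 nm`; fits violating the Nyquist limit or shorter than two
periods raise. The inter-row offset `Delta = wrap(p2 - p1)/2 pi` is reported
in `[0, 1)` as a dimensionless fraction of one repeat — converting to nm is
left to the caller, since the defining formula is dimensionless. Whether the
original fits were weighted or amplitude-constrained is unknown;
unconstrained least squares with sign normalization is used.

Distance cleaning is greedy by descending cross-correlation score (ties to
the lower index): a coordinate is kept iff it lies >= 4 nm from every
previously kept one. This reduces to per-lattice-point argmax when clusters
are separated, always keeps the best-scoring particle and guarantees the
4 nm minimum spacing globally. Spline seeding interpolates a natural cubic
spline through the picked rim contour, re-parameterizes by arc length (10x
oversampling) and emits seeds at 1 nm spacing; Theta/Psi orient the seed
z-axis along the local tangent (ZXZ convention, rotations applied Phi then
Theta then Psi) and Phi is drawn uniformly from a seeded generator.

## Synthetic phantoms

The generator renders the study conditions: disks stacked along z with
membrane center planes separated by `lumen_gap + thickness` within a disk
(4 + 6.8 nm) and `cytosolic_gap + thickness` across the gap (14 + 6.8 nm),
i.e. a 31.6 nm stacking repeat; hairpin rims as elliptical arcs bulging
`rim_radius = 12 nm` beyond the membrane footprint; a plasma membrane with
its proximal half-max face 25 nm from the rim periphery; an optional incisure
cleft lined by rims on both sides. All membranes have Gaussian cross-sections
with FWHM equal to the 6.8 nm apparent thickness, truncated at 3 sigma so
that mid-gap voxels are exactly background. Default contrast: membrane
amplitude 1.0 (arbitrary raw units), rim connectors 0.7, interior 0.5,
additive white Gaussian noise sd 0.1, and a linear gray ramp of amplitude
0.3 peak-to-peak along z emulating variable lamella thickness (z so that the
gradient varies *across* membrane pairs, which is the situation per-pair
normalization addresses; real patches are laterally small, full-field
phantom pairs are not). After per-pair normalization the planted connector
amplitudes are several times the noise sd, matching the visibility of
connectors in phase-plate data.

Connectors are solid cylinders (radius 1.6 nm) spanning membrane center to
membrane center, so mask contact is guaranteed. Ground-truth endpoints sit at
the contact planes (4 voxel layers from the central plane, i.e. the first
cytosolic layer outside the grown mask), making `true_length_nm` directly
comparable to `L_con`. Rim connectors are vertical (contact-to-contact
~12 nm) and confined to a strip whose 3D distance to the rim periphery is
within 40 nm by construction; interior connectors are tilted to a target
length (default mean 16 nm) and placed > 40 nm from the periphery. Placement
is dart-throwing with per-class minimum spacing (6 nm rim, 14 nm interior),
which produces the planted class contrasts: rim connectors shorter, darker
and more closely spaced. Counts default to 48 rim + 72 interior per ~300^3
volume. Everything is a pure function of (spec, connector specs, seed).

What the phantoms do *not* emulate: contrast transfer, missing-wedge
anisotropy (an optional separable axial blur exists but is off by default —
the analyzed quantities are threshold- and geometry-based, not
Fourier-based), macromolecular crowding, curved or wavy membranes, and
segmentation errors in the membrane input. Passing recovery tests therefore
demonstrates the correctness of the computation chain under known geometry
and realistic noise, not performance on adversarial real tomograms; on real
data the membrane segmentation quality and the crowded cytosol dominate the
error budget.

## Problem sizes in the shipped experiments

The recovery experiment uses three 300^3 phantoms (1.048 nm voxels, ~8
membrane pairs, 120 planted connectors each); recall is the fraction of
planted midpoints with a segmented `C_con` within 4 nm, and the coordinate
error is averaged over matched pairs. Class-statistics replication uses 20
smaller phantoms (110×96×160) pooled. Oracle equivalence runs on random
instances up to ~14×10×10 voxels with a coarsened 14-level ramp, where the
set-based enumeration is exact and fast. These sizes are the package's
standard verification configuration.

## Known limitations

* The watershed relief choice (gray value vs. distance transform) changes
  where touching connectors split; both are provided, gray-value is default.
* `C_con` of strongly oblique connectors is the centroid of a one-to-two
  voxel medial band and can be off the geometric axis by a fraction of a
  voxel.
* The analyzed-area estimator assumes thin central-plane rasters; thick or
  multi-voxel membrane segmentations would double-count area.
* The asymptotic KS p-value is inaccurate below ~25 samples per group; an
  exact test is not provided because the intended sample sizes are large.
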