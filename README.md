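# diskconnect

Quantitative analysis of the membrane architecture of rod outer segments
(ROS) in cryo-electron tomograms. The ROS — the light-sensing cilium of rod
photoreceptor cells — contains a stack of flattened membrane disks held at a
precise ~14 nm spacing, and Volta-phase-plate tomograms resolve molecular
**connectors** that bridge the cytosolic gap between adjacent disks: short,
dense, clustered connectors near the highly curved disk rims and longer,
sparser ones between the parallel membranes of the disk interior.

`diskconnect` implements the full image-analysis chain needed to find and
characterize these connectors, together with the ultrastructure distance
measurements and the periodicity analysis of the protein scaffold that lines
the disk rim — and a phantom generator that plants all of this with known
ground truth, so every stage is testable without any microscope data.

## What it computes

**Hierarchical connector segmentation.** Membrane central-plane segmentations
are grown by 3 voxels per side into ~7 nm masks; the cytosolic between-region
of each membrane pair is normalized to mean 0 / sd 1 (removing gray-value
gradients from variable lamella thickness). A threshold ramp

    g_i = g_min + (i - 1) g_step,   (g_min, g_max, g_step) = (-2, -0.68, 0.02)

sweeps the normalized gray values; at each level the 6-connected voxel groups
that touch both membrane masks are collected, and the output keeps exactly
the *first-appearance* groups — those containing no bridging group from any
lower level. An optional marker-based watershed pre-mask (Meyer flooding from
the medial surface between the masks) removes basin-boundary voxels first, so
that laterally touching connectors are split.

**Connector morphometry and statistics.** Each connector gets membrane
contact points `P_mb1`, `P_mb2` (centroids of the mask-adjacent voxels), a
central coordinate `C_con` on the medial surface, a length
`L_con = ||C_con - P_mb1|| + ||C_con - P_mb2||`, its mean normalized gray
value, a rim/interior class (within 40 nm of the disk-rim periphery,
inclusive), within-class nearest-neighbor distances, two-sample
Kolmogorov–Smirnov comparisons, and surface densities
`rho = n / A` scaled to per-disk densities `rho_tot = rho * f / 2` through a
geometric disk-area model

    A_tot      = pi r_out^2 - r_in d_cleft
    A_rim      = pi (r_out^2 - r_in^2) + 2 d_rim r_in
    A_interior = pi r_in^2 - r_in (d_cleft + 2 d_rim)

**Distance measurements.** Averaged 1D intensity profiles (21×21-voxel cuboid
base) with 50 %-of-maximum edge detection give membrane thickness d_PM, disk
rim diameter d_DR and stacking repeats; the derived distances are
`d_IN = d_1 - 2 d_Shift` (incisure gap) and `d_PR = d_2 - d_Shift - d_PM/2`
(plasma-membrane-to-rim distance).

**Rim scaffold periodicity.** Row profiles of the disk-rim scaffold are fit
with `y(x) = y0 + A sin(w0 x + p)`; the repeat length is
`lambda = Ps 2 pi / w0` (pixel size Ps = 0.262 nm) and the inter-row offset
`Delta_lambda = (p2 - p1)/2 pi` in repeat units. Lattice utilities provide
minimum-distance cleaning of subvolume coordinates (4 nm, keep highest
cross-correlation) and oriented seed placement along rim splines (1 nm
spacing, ZXZ Euler angles, randomized Phi).

**Synthetic phantoms.** `diskconnect.synthdata` renders disk stacks with the
measured geometry (6.8 nm apparent membrane thickness, 14 nm cytosolic gap,
12 nm rim radius, ~25 nm plasma-membrane offset, 1.048 nm voxels), plants
rim/interior connector populations with class contrasts, adds a
lamella-thickness gray gradient plus Gaussian noise, and exports the full
ground truth.

## Worked example

```python
from diskconnect import synthdata, pipeline

spec = synthdata.StackSpec(volume_shape=(110, 96, 160), seed=7)
conn = synthdata.default_connector_specs(n_rim=8, n_interior=10)
volume, membranes, truth = synthdata.generate_disk_stack(spec, conn)

measurements, pairs, connectors = pipeline.segment_volume(
    volume, membranes, truth.pair_table)
pipeline.classify_and_annotate(measurements, truth.rim_periphery_nm)
stats = pipeline.class_statistics(measurements)
rec = pipeline.recovery_metrics(measurements, truth)
print(stats["n_rim"], stats["n_interior"], stats["n_total"])
print(round(rec["recall_percent"], 1), round(rec["mean_c_con_error_nm"], 2))
```

prints

```
8 10 18
100.0 0.24
```

i.e. the two planted membrane pairs yield 18 segmented connectors, 8
classified as rim and 10 as interior; all 18 planted connectors are recovered
(100 % recall) with a mean central-coordinate error of 0.24 nm.

The same pipeline runs from the shell:

```bash
diskconnect simulate --config cfg.json --out vol.mrc --truth truth.csv \
    --membranes mem.mrc --pairs pairs.csv
diskconnect segment --volume vol.mrc --membranes mem.mrc --pairs pairs.csv \
    --ramp -2:-0.68:0.02 --table connectors.csv
diskconnect run --config pipeline.json --out results/
```

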