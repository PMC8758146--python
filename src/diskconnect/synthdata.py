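"""Phantom disk-stack tomograms with planted, exported ground truth.

The generator emulates the geometry of a rod outer segment (ROS) disk stack as
seen in 4x-binned cryo-electron tomograms: pairs of parallel membrane slabs
(apparent thickness ~6.8 nm FWHM) separated by a ~14 nm cytosolic gap and a
thin disk lumen, hairpin disk rims bulging by the rim radius of curvature
(~12 nm) beyond the membrane footprint, a plasma membrane ~25 nm from the rim
periphery, an optional disk incisure, and cylindrical connectors of two
classes bridging the cytosolic gap:

* rim connectors — short, dense (dark) and confined to within 40 nm of the
  outer rim periphery;
* interior connectors — longer (tilted), sparser and less dense.

A low-order gray-value gradient along z emulates variable lamella thickness
and additive white Gaussian noise is applied last. Density is rendered DARK
(low gray value) as in raw tomograms. Output is a pure function of
(spec, connector specs, seed).

Axes: (z, y, x); the stack axis is z, the rim/plasma-membrane side is +x.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import DENSITY_DARK, GrayVolume, LabelVolume
from .metrics import IntensityProfile

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

RIM = "rim"
INTERIOR = "interior"

#: Voxel layers between a membrane central plane and the first cytosolic voxel
#: once the plane is grown by 3 voxels on either side (mask halfwidth + 1).
MASK_CONTACT_LAYERS = 4


@dataclass
class IncisureSpec:
    """A cleft interrupting the disks, running across the full disk footprint.

    ``position_y_nm`` is the cleft center line; ``cleft_width_nm`` is the
    cytosolic gap between the two facing rim peripheries (the measurable
    incisure gap d_IN).
    """

    position_y_nm: float
    cleft_width_nm: float = 25.0


@dataclass
class StackSpec:
    """Geometry and contrast of a phantom disk stack.

    Lengths in nm; gray levels in arbitrary raw units (background 0, density
    negative). Defaults reproduce the measured ROS ultrastructure: membrane
    apparent thickness 6.8 nm, cytosolic inter-disk gap 14 nm, rim radius of
    curvature 12 nm, plasma membrane 25 nm beyond the rim periphery, voxel
    size 1.048 nm (4x binned data).
    """

    volume_shape: tuple[int, int, int] = (300, 300, 300)
    voxel_size_nm: float = 1.048
    membrane_thickness_nm: float = 6.8
    cytosolic_gap_nm: float = 14.0
    lumen_gap_nm: float = 4.0
    rim_radius_nm: float = 12.0
    pm_offset_nm: float = 25.0
    incisure: Optional[IncisureSpec] = None
    membrane_amplitude: float = 1.0
    noise_sd: float = 0.1
    gradient_amplitude: float = 0.3
    #: Optional separable axial (z) Gaussian blur emulating missing-wedge
    #: anisotropy; 0 disables it.
    axial_blur_sigma_nm: float = 0.0
    seed: int = 0
    edge_margin_nm: float = 18.0

    def __post_init__(self) -> None:
        for name in (
            "voxel_size_nm", "membrane_thickness_nm", "cytosolic_gap_nm",
            "lumen_gap_nm", "rim_radius_nm", "pm_offset_nm", "membrane_amplitude",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    # Derived geometry -----------------------------------------------------
    @property
    def intra_disk_separation_nm(self) -> float:
        """Center-to-center distance of the two membranes of one disk."""
        return self.lumen_gap_nm + self.membrane_thickness_nm

    @property
    def inter_disk_separation_nm(self) -> float:
        """Center-to-center distance across the cytosolic gap."""
        return self.cytosolic_gap_nm + self.membrane_thickness_nm

    @property
    def pitch_nm(self) -> float:
        return self.intra_disk_separation_nm + self.inter_disk_separation_nm

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2, sort_keys=True)


@dataclass
class ConnectorSpec:
    """A class of planted connectors.

    ``length_nm`` is the mean contact-to-contact length; connectors longer
    than the axial mask-to-mask span are rendered tilted. ``count`` is the
    total number planted in the volume; alternatively ``surface_density_um2``
    (per um^2 of membrane-pair area) may be given.
    """

    class_label: str
    count: Optional[int] = None
    surface_density_um2: Optional[float] = None
    length_nm: float = 12.0
    length_sd_nm: float = 0.8
    radius_nm: float = 1.6
    amplitude: float = 0.7
    min_spacing_nm: float = 6.0

    def __post_init__(self) -> None:
        if self.class_label not in (RIM, INTERIOR):
            raise ValueError(f"class_label must be 'rim' or 'interior', got {self.class_label!r}")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")
        if (self.count is None) == (self.surface_density_um2 is None):
            raise ValueError("give exactly one of count or surface_density_um2")


def default_connector_specs(n_rim: int = 48, n_interior: int = 72) -> list[ConnectorSpec]:
    """Study-condition connector classes: rim short/dense/clustered, interior
    longer/sparser/fainter."""
    return [
        ConnectorSpec(class_label=RIM, count=n_rim, length_nm=12.0, amplitude=0.7,
                      min_spacing_nm=6.0),
        ConnectorSpec(class_label=INTERIOR, count=n_interior, length_nm=16.0,
                      amplitude=0.5, min_spacing_nm=14.0),
    ]


@dataclass
class GroundTruth:
    """Planted geometry exported for recovery tests.

    ``connectors`` columns: id, pair_id, class_label, z0/y0/x0, z1/y1/x1
    (axis endpoints at the mask contact planes, nm), mz/my/mx (midpoint, nm),
    true_length_nm, amplitude.
    """

    connectors: pd.DataFrame
    pair_table: pd.DataFrame          # pair_id, label_a, label_b
    membrane_planes_z_nm: dict        # label -> central-plane z (nm)
    rim_periphery_nm: np.ndarray      # (N, 3) points on the outer rim periphery
    rim_periphery_normals: np.ndarray  # (N, 3) outward unit normals
    incisure_periphery_nm: dict       # side (-1/+1) -> (N, 3) points, if incisure
    d_shift_nm: float                 # rim center to rim periphery offset
    planted_density_um2: dict         # class -> planted per-area density
    spec: StackSpec


def _fit_stack_z(spec: StackSpec) -> np.ndarray:
    """Disk center z positions (nm) that fit the volume with margins."""
    lz = spec.volume_shape[0] * spec.voxel_size_nm
    margin = spec.edge_margin_nm + spec.intra_disk_separation_nm / 2.0
    usable = lz - 2.0 * margin
    n_disks = int(np.floor(usable / spec.pitch_nm)) + 1
    if n_disks < 2:
        raise ValueError("volume too small to hold >= 2 disk pairs at the given spacings")
    start = (lz - (n_disks - 1) * spec.pitch_nm) / 2.0
    return start + np.arange(n_disks) * spec.pitch_nm


def _geometry(spec: StackSpec):
    vox = spec.voxel_size_nm
    nz, ny, nx = spec.volume_shape
    z_centers = _fit_stack_z(spec)
    lx = nx * vox
    # Disk footprint runs from x=margin to x_rim; rim bulges by rim_radius
    # beyond that; the PM proximal half-max face sits pm_offset further out.
    x_pm_center = lx - spec.edge_margin_nm - spec.membrane_thickness_nm / 2.0
    x_periphery = x_pm_center - spec.membrane_thickness_nm / 2.0 - spec.pm_offset_nm
    x_rim = x_periphery - spec.rim_radius_nm
    if x_rim < spec.edge_margin_nm + 20.0:
        raise ValueError("volume too small in x for rim + plasma membrane layout")
    return z_centers, x_rim, x_periphery, x_pm_center


def _footprint_mask(spec: StackSpec) -> np.ndarray:
    """(y, x) boolean mask of the disk membrane footprint."""
    vox = spec.voxel_size_nm
    _, ny, nx = spec.volume_shape
    _, x_rim, _, _ = _geometry(spec)
    x = np.arange(nx) * vox
    y = np.arange(ny) * vox
    fp = np.ones((ny, nx), dtype=bool)
    fp &= (x <= x_rim)[None, :]
    if spec.incisure is not None:
        half = spec.incisure.cleft_width_nm / 2.0 + spec.rim_radius_nm
        fp &= (np.abs(y - spec.incisure.position_y_nm) >= half)[:, None]
    return fp


def _membrane_z_planes(spec: StackSpec):
    """(label, z_nm) per membrane plus the facing-pair table."""
    z_centers, _, _, _ = _geometry(spec)
    s_in = spec.intra_disk_separation_nm
    planes = []  # (label, disk index, 'top'/'bottom', z_nm)
    label = 1
    for i, zc in enumerate(z_centers):
        planes.append((label, i, "top", zc - s_in / 2.0))
        label += 1
        planes.append((label, i, "bottom", zc + s_in / 2.0))
        label += 1
    pairs = []
    for i in range(len(z_centers) - 1):
        label_a = 2 * i + 2        # bottom membrane of disk i
        label_b = 2 * (i + 1) + 1  # top membrane of disk i+1
        pairs.append({"pair_id": i + 1, "label_a": label_a, "label_b": label_b})
    return planes, pd.DataFrame(pairs)


GAUSSIAN_CUTOFF_SIGMAS = 3.0  # rendered membranes vanish beyond 3 sigma


def _trunc_gauss(dist, sigma):
    """Gaussian cross-section truncated to exact zero beyond the cutoff."""
    out = np.exp(-(np.asarray(dist) ** 2) / (2.0 * sigma ** 2))
    return np.where(np.abs(dist) <= GAUSSIAN_CUTOFF_SIGMAS * sigma, out, 0.0)


def _gaussian_line_field(grid_a, grid_b, pts_a, pts_b, sigma):
    """2D field of truncated-Gaussian distance to a sampled curve."""
    from scipy.spatial import cKDTree

    cutoff = GAUSSIAN_CUTOFF_SIGMAS
    aa, bb = np.meshgrid(grid_a, grid_b, indexing="ij")
    flat = np.column_stack([aa.ravel(), bb.ravel()])
    tree = cKDTree(np.column_stack([pts_a, pts_b]))
    d, _ = tree.query(flat, distance_upper_bound=(cutoff + 0.5) * sigma)
    d[~np.isfinite(d)] = (cutoff + 0.5) * sigma
    return _trunc_gauss(d, sigma).reshape(aa.shape)


def _rim_arc_points(spec: StackSpec, z_center: float, attach: float, bulge_sign: float):
    """Sample the hairpin rim arc (an ellipse half) in a 2D cross-section.

    Returns (axial, lateral) samples: axial spans z_center +- a_z, lateral
    bulges from ``attach`` by ``bulge_sign * rim_radius``.
    """
    a_z = spec.intra_disk_separation_nm / 2.0
    a_l = spec.rim_radius_nm
    t = np.linspace(-np.pi / 2.0, np.pi / 2.0, 64)
    return z_center + a_z * np.sin(t), attach + bulge_sign * a_l * np.cos(t)


def _render_membranes(spec: StackSpec, dens: np.ndarray) -> None:
    vox = spec.voxel_size_nm
    nz, ny, nx = spec.volume_shape
    z = np.arange(nz) * vox
    sigma = spec.membrane_thickness_nm * _FWHM_TO_SIGMA
    planes, _ = _membrane_z_planes(spec)
    zprof = np.zeros(nz)
    for _, _, _, z_m in planes:
        zprof += _trunc_gauss(z - z_m, sigma)
    fp = _footprint_mask(spec)
    dens -= spec.membrane_amplitude * zprof[:, None, None] * fp[None, :, :]


def _render_outer_rims(spec: StackSpec, dens: np.ndarray) -> None:
    vox = spec.voxel_size_nm
    nz, ny, nx = spec.volume_shape
    z_centers, x_rim, x_periphery, _ = _geometry(spec)
    sigma = spec.membrane_thickness_nm * _FWHM_TO_SIGMA
    x = np.arange(nx) * vox
    z = np.arange(nz) * vox
    xi0 = max(0, int((x_rim - 3 * sigma) / vox))
    xi1 = min(nx, int((x_periphery + 3 * sigma) / vox) + 2)
    pts_z, pts_x = [], []
    for zc in z_centers:
        az, ax_ = _rim_arc_points(spec, zc, x_rim, +1.0)
        pts_z.append(az)
        pts_x.append(ax_)
    field = _gaussian_line_field(z, x[xi0:xi1], np.concatenate(pts_z),
                                 np.concatenate(pts_x), sigma)
    # Rows carrying a disk (outside the incisure cleft).
    fp = _footprint_mask(spec)
    rows = fp[:, 0] if fp.shape[1] else np.ones(ny, dtype=bool)
    contrib = spec.membrane_amplitude * field[:, None, :] * rows[None, :, None]
    dens[:, :, xi0:xi1] -= contrib


def _render_incisure_rims(spec: StackSpec, dens: np.ndarray) -> None:
    if spec.incisure is None:
        return
    vox = spec.voxel_size_nm
    nz, ny, nx = spec.volume_shape
    z_centers, x_rim, _, _ = _geometry(spec)
    sigma = spec.membrane_thickness_nm * _FWHM_TO_SIGMA
    y = np.arange(ny) * vox
    z = np.arange(nz) * vox
    y0 = spec.incisure.position_y_nm
    half = spec.incisure.cleft_width_nm / 2.0 + spec.rim_radius_nm
    xi1 = min(nx, int(x_rim / vox) + 1)
    for side in (-1.0, +1.0):
        attach = y0 + side * half
        pts_z, pts_y = [], []
        for zc in z_centers:
            az, ay = _rim_arc_points(spec, zc, attach, -side)
            pts_z.append(az)
            pts_y.append(ay)
        yi0 = max(0, int((min(map(np.min, pts_y)) - 3 * sigma) / vox))
        yi1 = min(ny, int((max(map(np.max, pts_y)) + 3 * sigma) / vox) + 2)
        field = _gaussian_line_field(z, y[yi0:yi1], np.concatenate(pts_z),
                                     np.concatenate(pts_y), sigma)
        dens[:, yi0:yi1, :xi1] -= spec.membrane_amplitude * field[:, :, None]


def _render_pm(spec: StackSpec, dens: np.ndarray) -> None:
    vox = spec.voxel_size_nm
    nx = spec.volume_shape[2]
    _, _, _, x_pm = _geometry(spec)
    sigma = spec.membrane_thickness_nm * _FWHM_TO_SIGMA
    x = np.arange(nx) * vox
    xprof = _trunc_gauss(x - x_pm, sigma)
    dens -= spec.membrane_amplitude * xprof[None, None, :]


def _sample_positions(rng, n, bounds_y, bounds_x, min_spacing, forbidden_y=None,
                      max_tries=4000):
    """Dart-throwing placement with a minimum pairwise spacing (nm)."""
    placed = []
    tries = 0
    while len(placed) < n and tries < max_tries:
        tries += 1
        yy = rng.uniform(*bounds_y)
        xx = rng.uniform(*bounds_x)
        if forbidden_y is not None and forbidden_y[0] <= yy <= forbidden_y[1]:
            continue
        if all((yy - p[0]) ** 2 + (xx - p[1]) ** 2 >= min_spacing ** 2 for p in placed):
            placed.append((yy, xx))
    return placed


def _render_cylinder(dens, spec, e0, e1, radius, amplitude):
    """Paint a solid cylinder (segment e0-e1, nm coords z,y,x) as dark density."""
    vox = spec.voxel_size_nm
    nz, ny, nx = dens.shape
    lo = np.minimum(e0, e1) - radius - vox
    hi = np.maximum(e0, e1) + radius + vox
    i0 = np.maximum(np.floor(lo / vox).astype(int), 0)
    i1 = np.minimum(np.ceil(hi / vox).astype(int) + 1, [nz, ny, nx])
    if np.any(i0 >= i1):
        return
    zz, yy, xx = np.meshgrid(
        np.arange(i0[0], i1[0]) * vox,
        np.arange(i0[1], i1[1]) * vox,
        np.arange(i0[2], i1[2]) * vox,
        indexing="ij",
    )
    p = np.stack([zz, yy, xx], axis=-1)
    d = e1 - e0
    ll = float(np.dot(d, d))
    t = np.clip(np.einsum("...k,k->...", p - e0, d) / ll, 0.0, 1.0)
    closest = e0[None, None, None, :] + t[..., None] * d[None, None, None, :]
    dist = np.linalg.norm(p - closest, axis=-1)
    inside = dist <= radius
    dens[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]][inside] -= amplitude


def generate_disk_stack(
    spec: StackSpec,
    connectors: Sequence[ConnectorSpec] | None = None,
) -> tuple[GrayVolume, LabelVolume, GroundTruth]:
    """Render a phantom disk stack with planted connectors.

    Returns the gray volume (density dark), the membrane central-plane label
    volume (one label per membrane) and the planted ground truth.
    """
    if connectors is None:
        connectors = default_connector_specs()
    rng = np.random.default_rng(spec.seed)
    vox = spec.voxel_size_nm
    nz, ny, nx = spec.volume_shape
    z_centers, x_rim, x_periphery, x_pm = _geometry(spec)
    planes, pair_table = _membrane_z_planes(spec)
    s_out = spec.inter_disk_separation_nm

    dens = np.zeros(spec.volume_shape, dtype=np.float64)
    _render_membranes(spec, dens)
    _render_outer_rims(spec, dens)
    _render_incisure_rims(spec, dens)
    _render_pm(spec, dens)

    # --- membrane central-plane labels ---
    labels = np.zeros(spec.volume_shape, dtype=np.int32)
    fp = _footprint_mask(spec)
    plane_z_nm = {}
    for label, _, _, z_m in planes:
        zi = int(round(z_m / vox))
        labels[zi][fp] = label
        plane_z_nm[label] = z_m

    # --- connector placement per membrane pair ---
    n_pairs = len(pair_table)
    y_lo, y_hi = spec.edge_margin_nm, ny * vox - spec.edge_margin_nm
    forbidden_y = None
    if spec.incisure is not None:
        half = spec.incisure.cleft_width_nm / 2.0 + spec.rim_radius_nm + 6.0
        forbidden_y = (spec.incisure.position_y_nm - half,
                       spec.incisure.position_y_nm + half)
    # Zones chosen so the 40 nm rim rule holds by construction (periphery sits
    # rim_radius beyond x_rim; interior midpoints stay > 40 nm from it in 3D).
    rim_zone = (x_rim - 22.0, x_rim - 4.0)
    int_zone = (spec.edge_margin_nm + 6.0, x_rim - 57.0)
    if int_zone[1] <= int_zone[0]:
        raise ValueError("volume too small in x for an interior connector zone")

    records = []
    conn_id = 1
    pair_area_um2 = ((y_hi - y_lo) * (x_rim - spec.edge_margin_nm)) * 1e-6
    for cs in connectors:
        if cs.radius_nm * 2.0 >= spec.cytosolic_gap_nm:
            raise ValueError(f"connector spec {cs} too thick for the {spec.cytosolic_gap_nm} nm gap")
        axial_span = s_out  # plane center to plane center
        contact_span_vox = None  # computed per pair below
        total = cs.count
        if total is None:
            total = int(round(cs.surface_density_um2 * pair_area_um2 * n_pairs))
        base = total // n_pairs
        extra = total - base * n_pairs
        per_pair = [base + (1 if i < extra else 0) for i in range(n_pairs)]
        zone = rim_zone if cs.class_label == RIM else int_zone
        for pi, row in pair_table.iterrows():
            n_here = per_pair[pi]
            if n_here == 0:
                continue
            za = plane_z_nm[row["label_a"]]
            zb = plane_z_nm[row["label_b"]]
            zia, zib = int(round(za / vox)), int(round(zb / vox))
            # Contact planes: first cytosolic voxel layer outside the grown masks.
            zc0 = (zia + MASK_CONTACT_LAYERS) * vox
            zc1 = (zib - MASK_CONTACT_LAYERS) * vox
            contact_span = zc1 - zc0
            pos = _sample_positions(rng, n_here, (y_lo, y_hi), zone,
                                    cs.min_spacing_nm, forbidden_y)
            if len(pos) < n_here:
                raise ValueError(
                    f"could not place {n_here} {cs.class_label} connectors in pair "
                    f"{row['pair_id']} at min spacing {cs.min_spacing_nm} nm"
                )
            for yy, xx in pos:
                length = max(contact_span,
                             rng.normal(cs.length_nm, cs.length_sd_nm))
                max_len = contact_span / np.cos(np.deg2rad(55.0))
                if length > max_len:
                    raise ValueError(
                        f"connector length {length:.1f} nm cannot fit the gap (spec {cs})"
                    )
                lat = np.sqrt(max(length ** 2 - contact_span ** 2, 0.0))
                phi = rng.uniform(0.0, 2.0 * np.pi)
                dy, dx = lat * np.sin(phi), lat * np.cos(phi)
                # Contact-plane endpoints (ground truth).
                e0 = np.array([zc0, yy - dy / 2.0, xx - dx / 2.0])
                e1 = np.array([zc1, yy + dy / 2.0, xx + dx / 2.0])
                # Render beyond the contacts into both masks so the cylinder is
                # guaranteed face-adjacent to each grown membrane mask.
                scale = (zb - za) / contact_span
                mid = (e0 + e1) / 2.0
                r0 = mid + (e0 - mid) * scale
                r1 = mid + (e1 - mid) * scale
                amp = max(cs.amplitude + rng.normal(0.0, 0.04), 0.3 * cs.amplitude)
                _render_cylinder(dens, spec, r0, r1, cs.radius_nm, amp)
                records.append({
                    "id": conn_id, "pair_id": int(row["pair_id"]),
                    "class_label": cs.class_label,
                    "z0": e0[0], "y0": e0[1], "x0": e0[2],
                    "z1": e1[0], "y1": e1[1], "x1": e1[2],
                    "mz": mid[0], "my": mid[1], "mx": mid[2],
                    "true_length_nm": float(np.linalg.norm(e1 - e0)),
                    "amplitude": amp,
                })
                conn_id += 1

    # --- axial blur, gradient (along z: lamella thickness), noise ---
    if spec.axial_blur_sigma_nm > 0:
        from scipy.ndimage import gaussian_filter1d

        dens = gaussian_filter1d(dens, spec.axial_blur_sigma_nm / vox, axis=0)
    if spec.gradient_amplitude != 0.0:
        ramp = spec.gradient_amplitude * (np.arange(nz) / max(nz - 1, 1) - 0.5)
        dens += ramp[:, None, None]
    if spec.noise_sd > 0:
        dens += rng.normal(0.0, spec.noise_sd, size=dens.shape)

    # --- ground truth periphery points ---
    yv = np.arange(ny) * vox
    row_ok = (yv >= y_lo) & (yv <= y_hi)
    if forbidden_y is not None:
        row_ok &= ~((yv >= forbidden_y[0]) & (yv <= forbidden_y[1]))
    per_pts, per_nrm = [], []
    for zc in z_centers:
        ys = yv[row_ok][::2]
        for yy in ys:
            per_pts.append([zc, yy, x_periphery])
            per_nrm.append([0.0, 0.0, 1.0])
    incisure_pts = {}
    if spec.incisure is not None:
        y0 = spec.incisure.position_y_nm
        gap_half = spec.incisure.cleft_width_nm / 2.0
        xs = np.arange(spec.edge_margin_nm, x_rim - 2.0, 8.0 * vox)
        for side in (-1, +1):
            pts = [[zc, y0 + side * gap_half, xx] for zc in z_centers for xx in xs]
            incisure_pts[side] = np.asarray(pts)

    df = pd.DataFrame(
        records,
        columns=["id", "pair_id", "class_label", "z0", "y0", "x0", "z1", "y1",
                 "x1", "mz", "my", "mx", "true_length_nm", "amplitude"],
    )
    density = {}
    for cls in (RIM, INTERIOR):
        n_cls = int((df["class_label"] == cls).sum()) if len(df) else 0
        density[cls] = n_cls / (pair_area_um2 * n_pairs) if n_pairs else 0.0

    gt = GroundTruth(
        connectors=df,
        pair_table=pair_table,
        membrane_planes_z_nm=plane_z_nm,
        rim_periphery_nm=np.asarray(per_pts),
        rim_periphery_normals=np.asarray(per_nrm),
        incisure_periphery_nm=incisure_pts,
        d_shift_nm=spec.rim_radius_nm,
        planted_density_um2=density,
        spec=spec,
    )
    vol = GrayVolume(data=dens, voxel_size_nm=vox, polarity=DENSITY_DARK)
    return vol, LabelVolume(labels=labels, voxel_size_nm=vox), gt


def mock_rim_subvolume_centers(gt: GroundTruth, group: str) -> np.ndarray:
    """Emulated rim-subvolume center coordinates for the distance formulas.

    Centers sit ``d_shift_nm`` inward of the periphery along the outward
    normal. ``group`` is ``"incisure-"``, ``"incisure+"`` (the two sides of
    the incisure) or ``"pm"`` (the outer periphery facing the plasma membrane).
    """
    if group == "pm":
        return gt.rim_periphery_nm - gt.d_shift_nm * gt.rim_periphery_normals
    if group in ("incisure-", "incisure+"):
        side = -1 if group.endswith("-") else +1
        pts = gt.incisure_periphery_nm.get(side)
        if pts is None or len(pts) == 0:
            raise ValueError("phantom has no incisure")
        nrm = np.zeros_like(pts, dtype=float)
        nrm[:, 1] = -side  # outward = toward the cleft center
        return pts - gt.d_shift_nm * nrm
    raise ValueError(f"unknown group {group!r}")


def generate_membrane_profile(
    thickness_nm: float,
    separation_nm: float,
    spacing_nm: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_peaks: int = 2,
) -> IntensityProfile:
    """Density-bright 1D profile of Gaussian membrane peaks of known FWHM.

    ``separation_nm`` is the center-to-center peak distance; the inner
    half-max edges are then ``separation - thickness`` apart.
    """
    if not spacing_nm > 0:
        raise ValueError("spacing_nm must be > 0")
    if n_peaks > 1 and separation_nm < thickness_nm:
        raise ValueError("separation smaller than membrane thickness")
    sigma = thickness_nm * _FWHM_TO_SIGMA
    # Generous flat padding keeps the profile median (the edge-detection
    # baseline) at the background level.
    pad = 4.0 * thickness_nm + separation_nm
    length = pad * 2.0 + separation_nm * max(n_peaks - 1, 0)
    n = int(np.floor(length / spacing_nm)) + 1
    x = np.arange(n) * spacing_nm
    y = np.zeros(n)
    for k in range(n_peaks):
        c = pad + k * separation_nm
        y += np.exp(-((x - c) ** 2) / (2.0 * sigma ** 2))
    if noise_sd > 0:
        y += np.random.default_rng(seed).normal(0.0, noise_sd, size=n)
    return IntensityProfile(samples=y, spacing_nm=spacing_nm)


def generate_lattice_profiles(
    lambda_nm: float,
    offset_fraction: float,
    Ps_nm: float = 0.262,
    n_samples: int = 256,
    noise_sd: float = 0.0,
    seed: int = 0,
    amplitude: float = 1.0,
    phase0: float = 0.3,
) -> tuple[IntensityProfile, IntensityProfile]:
    """Two sinusoidal row profiles with period ``lambda_nm`` and a relative
    phase of ``2*pi*offset_fraction`` (central vs peripheral row)."""
    if Ps_nm <= 0:
        raise ValueError("Ps_nm must be > 0")
    if n_samples * Ps_nm < 3.0 * lambda_nm:
        raise ValueError("profile too short: need n_samples*Ps_nm >= 3*lambda_nm")
    rng = np.random.default_rng(seed)
    x = np.arange(n_samples) * Ps_nm
    w = 2.0 * np.pi / lambda_nm
    y_cd = amplitude * np.sin(w * x + phase0)
    y_pr = amplitude * np.sin(w * x + phase0 + 2.0 * np.pi * offset_fraction)
    if noise_sd > 0:
        y_cd = y_cd + rng.normal(0.0, noise_sd, n_samples)
        y_pr = y_pr + rng.normal(0.0, noise_sd, n_samples)
    prof_cd = IntensityProfile(samples=y_cd, spacing_nm=Ps_nm)
    prof_pr = IntensityProfile(samples=y_pr, spacing_nm=Ps_nm)
    return prof_cd, prof_pr
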