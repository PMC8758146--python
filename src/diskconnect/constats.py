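"""Per-connector measurements, rim/interior classification, disk-area model
and class-comparison statistics.

Each segmented connector gets a central coordinate C_con on the medial zone
between the two membranes, two membrane contact points P_mb1/P_mb2 (centroids
of the mask-adjacent connector voxels) and a length
L_con = ||C_con - P_mb1|| + ||C_con - P_mb2||. Connectors within 40 nm of the
outer disk-rim periphery are rim connectors, the rest interior connectors.
Surface densities per membrane fraction follow the geometric disk-area model
(disk = annular rim zone + interior, with an incisure cleft correction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats
from scipy.spatial import cKDTree

from .connectors import Connector
from .membranes import STRUCT_6, MembranePair

RIM = "rim"
INTERIOR = "interior"


@dataclass
class ConnectorMeasurement:
    connector_id: int
    pair_id: int
    c_con_nm: np.ndarray          # central coordinate (z, y, x), nm
    p_mb1_nm: np.ndarray          # contact point on mask A, nm
    p_mb2_nm: np.ndarray          # contact point on mask B, nm
    l_con_nm: float               # |C-P1| + |C-P2|
    mean_gray: float              # mean normalized gray over connector voxels
    n_voxels: int
    g_first: float
    class_label: str | None = None
    nn_dist_nm: float | None = None

    def as_record(self) -> dict:
        return {
            "id": self.connector_id,
            "pair_id": self.pair_id,
            "class": self.class_label,
            "Ccon_z_nm": self.c_con_nm[0],
            "Ccon_y_nm": self.c_con_nm[1],
            "Ccon_x_nm": self.c_con_nm[2],
            "L_con_nm": self.l_con_nm,
            "mean_gray": self.mean_gray,
            "nn_dist_nm": self.nn_dist_nm,
        }


def measure_connector(
    connector: Connector,
    pair: MembranePair,
    gray: np.ndarray,
) -> ConnectorMeasurement:
    """Contact points, central coordinate, length and mean gray of a connector.

    ``gray`` is the pair's cropped normalized array. Contact points are the
    centroids of the connector voxels face-adjacent to each mask; C_con is the
    centroid of the connector voxels on the medial zone between the masks
    (center between the two membranes), falling back to the P_mb1-P_mb2
    midpoint when the connector does not sample the medial zone.
    """
    vox = pair.voxel_size_nm
    offset = pair.offset_vox
    local = connector.voxels - offset
    conn_mask = np.zeros(pair.region.shape, dtype=bool)
    conn_mask[tuple(local.T)] = True

    adj_a = conn_mask & ndimage.binary_dilation(pair.mask_a, structure=STRUCT_6)
    adj_b = conn_mask & ndimage.binary_dilation(pair.mask_b, structure=STRUCT_6)
    if not adj_a.any() or not adj_b.any():
        raise ValueError(
            f"connector {connector.id} has no contact voxels on one side "
            "(bridging invariant violated)"
        )
    p1 = (np.argwhere(adj_a).mean(axis=0) + offset) * vox
    p2 = (np.argwhere(adj_b).mean(axis=0) + offset) * vox

    medial = conn_mask & pair.medial_zone()
    if medial.any():
        c = (np.argwhere(medial).mean(axis=0) + offset) * vox
    else:
        c = (p1 + p2) / 2.0
    l_con = float(np.linalg.norm(c - p1) + np.linalg.norm(c - p2))
    mean_gray = float(gray[tuple(local.T)].mean())
    return ConnectorMeasurement(
        connector_id=connector.id, pair_id=connector.pair_id,
        c_con_nm=c, p_mb1_nm=p1, p_mb2_nm=p2, l_con_nm=l_con,
        mean_gray=mean_gray, n_voxels=connector.n_voxels,
        g_first=connector.g_first,
    )


def nn_distances(points_nm) -> np.ndarray:
    """Euclidean distance from each point to its nearest other point."""
    pts = np.asarray(points_nm, dtype=float)
    if pts.ndim != 2 or len(pts) < 2:
        raise ValueError("need >= 2 points for nearest-neighbor distances")
    tree = cKDTree(pts)
    d, _ = tree.query(pts, k=2)
    return d[:, 1]


def classify_rim_interior(c_con_nm, rim_periphery_nm, threshold_nm: float = 40.0) -> str:
    """Rim iff the 3D distance to the rim periphery is <= threshold (inclusive)."""
    periph = np.asarray(rim_periphery_nm, dtype=float)
    if periph.size == 0:
        raise ValueError("empty rim periphery point set")
    d = np.min(np.linalg.norm(periph - np.asarray(c_con_nm, dtype=float), axis=1))
    return RIM if d <= threshold_nm else INTERIOR


@dataclass
class DiskGeometry:
    """Geometric disk model (all lengths in um).

    r_out/r_in: outer disk radius and inner (interior-fraction) radius, with
    r_out - r_in the rim-zone width; d_cleft: incisure cleft width; d_rim:
    width of the rim zone flanking the cleft. Defaults reproduce a ~1.3 um^2
    mouse disk with a 40 nm rim fraction.
    """

    r_out: float = 0.65
    r_in: float = 0.61
    d_cleft: float = 0.02
    d_rim: float = 0.04

    def __post_init__(self) -> None:
        if not (0 < self.r_in < self.r_out):
            raise ValueError("need 0 < r_in < r_out")
        if self.d_cleft < 0 or self.d_rim < 0:
            raise ValueError("d_cleft and d_rim must be >= 0")


def disk_area_model(geom: DiskGeometry):
    """Total, rim and interior disk membrane areas (um^2) and area fractions.

    A_tot = pi r_out^2 - r_in d_cleft
    A_rim = pi (r_out^2 - r_in^2) + 2 d_rim r_in
    A_interior = pi r_in^2 - r_in (d_cleft + 2 d_rim)

    A_tot = A_rim + A_interior holds as an algebraic identity.
    """
    a_tot = np.pi * geom.r_out ** 2 - geom.r_in * geom.d_cleft
    a_rim = np.pi * (geom.r_out ** 2 - geom.r_in ** 2) + 2.0 * geom.d_rim * geom.r_in
    a_interior = np.pi * geom.r_in ** 2 - geom.r_in * (geom.d_cleft + 2.0 * geom.d_rim)
    if a_tot <= 0:
        raise ValueError("non-positive total disk area")
    return a_tot, a_rim, a_interior, a_rim / a_tot, a_interior / a_tot


@dataclass
class DensityEstimate:
    fraction: str
    n_fraction: int
    area_um2: float
    rho_um2: float = field(init=False)      # connectors per um^2 of analyzed membrane
    f_fraction: float = 0.0
    rho_tot_um2: float = field(init=False)  # per-disk density

    def __post_init__(self) -> None:
        if self.area_um2 <= 0:
            raise ValueError("zero or negative membrane area")
        self.rho_um2 = self.n_fraction / self.area_um2
        # Divide by two: a connector links two membranes, so the segmentation
        # counts it once per membrane pair face.
        self.rho_tot_um2 = self.rho_um2 * self.f_fraction / 2.0


def density_estimates(
    counts: dict[str, int],
    areas_um2: dict[str, float],
    geom: DiskGeometry | None = None,
) -> list[DensityEstimate]:
    """Per-fraction surface densities for one tomogram/volume."""
    if geom is None:
        geom = DiskGeometry()
    _, _, _, f_rim, f_interior = disk_area_model(geom)
    f = {RIM: f_rim, INTERIOR: f_interior}
    out = []
    for fraction in (RIM, INTERIOR):
        out.append(DensityEstimate(
            fraction=fraction,
            n_fraction=int(counts.get(fraction, 0)),
            area_um2=float(areas_um2[fraction]),
            f_fraction=f[fraction],
        ))
    return out


def membrane_area(plane: np.ndarray, voxel_size_nm: float) -> float:
    """Tilt-corrected area (um^2) of a central-plane voxel set.

    Each plane voxel contributes voxel_size^2 / cos(theta), where theta is
    the angle between the local plane normal (total-least-squares fit over a
    5x5x5 neighborhood) and its nearest coordinate axis. Reduces to
    voxel_size^2 * N for flat axis-aligned planes.
    """
    plane = np.asarray(plane, dtype=bool)
    if not plane.any():
        raise ValueError("empty plane")
    m = plane.astype(np.float64)
    coords = np.indices(plane.shape, dtype=np.float64)
    size = 5
    # Windowed moments via uniform filters -> local covariance of occupied voxels.
    s0 = ndimage.uniform_filter(m, size)
    s1 = [ndimage.uniform_filter(m * c, size) for c in coords]
    s2 = {}
    for i in range(3):
        for j in range(i, 3):
            s2[(i, j)] = ndimage.uniform_filter(m * coords[i] * coords[j], size)
    idx = np.argwhere(plane)
    sel = tuple(idx.T)
    n = s0[sel]
    cov = np.empty((len(idx), 3, 3))
    for i in range(3):
        mi = s1[i][sel] / n
        for j in range(i, 3):
            mj = s1[j][sel] / n
            cov[:, i, j] = cov[:, j, i] = s2[(i, j)][sel] / n - mi * mj
    evals, evecs = np.linalg.eigh(cov)
    normals = evecs[:, :, 0]  # smallest-eigenvalue direction
    cos_theta = np.max(np.abs(normals), axis=1)
    cos_theta = np.clip(cos_theta, 1.0 / np.sqrt(3.0), 1.0)
    area_nm2 = np.sum(voxel_size_nm ** 2 / cos_theta)
    return float(area_nm2) * 1e-6


def ks_two_sample(x, y) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test (asymptotic p-value).

    D is the supremum distance between the two empirical CDFs; the p-value
    comes from the asymptotic Kolmogorov distribution with effective sample
    size n_x n_y / (n_x + n_y).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(x, y, method="asymp")
    return float(res.statistic), float(res.pvalue)
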