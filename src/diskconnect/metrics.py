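"""1D intensity-profile extraction and ultrastructure distance measurements.

Profiles are always analyzed density-bright (membranes appear as maxima);
density-dark source volumes are negated on extraction. Membrane edges are
located where the signal reaches 50 % of the peak height above the profile
baseline, with sub-sample precision by linear interpolation. The baseline is
the profile median, which is robust to the cytosolic plateau.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.ndimage import map_coordinates
from scipy.spatial import cKDTree

from .io import DENSITY_BRIGHT, DENSITY_DARK, GrayVolume


@dataclass
class IntensityProfile:
    """An ordered 1D profile with its sampling geometry.

    ``samples[k]`` sits at arc position ``k * spacing_nm`` from ``origin_nm``
    along ``direction`` (a unit vector in (z, y, x) order).
    """

    samples: np.ndarray
    spacing_nm: float
    origin_nm: np.ndarray = field(default_factory=lambda: np.zeros(3))
    direction: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    polarity: str = DENSITY_BRIGHT

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 3:
            raise ValueError("profile needs >= 3 ordered samples")
        if not self.spacing_nm > 0:
            raise ValueError("spacing_nm must be > 0")

    @property
    def positions_nm(self) -> np.ndarray:
        return np.arange(self.samples.size) * self.spacing_nm


@dataclass
class DistanceSet:
    """Derived ultrastructure distances (all nm).

    d_IN = d_1 - 2*d_Shift   (cytosolic gap at the disk incisure)
    d_PR = d_2 - d_Shift - d_PM/2   (plasma membrane to disk rim)
    """

    d_1: float
    d_2: float
    d_shift: float
    d_pm: float
    d_in: float = field(init=False)
    d_pr: float = field(init=False)
    geometry_consistent: bool = field(init=False)

    def __post_init__(self) -> None:
        if min(self.d_1, self.d_2, self.d_shift, self.d_pm) < 0:
            raise ValueError("distance inputs must be >= 0")
        self.d_in = self.d_1 - 2.0 * self.d_shift
        self.d_pr = self.d_2 - self.d_shift - self.d_pm / 2.0
        self.geometry_consistent = self.d_in >= 0 and self.d_pr >= 0


def derived_distances(d_1: float, d_2: float, d_shift: float, d_pm: float) -> DistanceSet:
    """Apply the incisure-gap and PM-rim distance formulas."""
    return DistanceSet(d_1=d_1, d_2=d_2, d_shift=d_shift, d_pm=d_pm)


def extract_profile(
    volume: GrayVolume,
    p0_nm,
    p1_nm,
    base_edge_vox: int = 21,
    spacing_nm: float | None = None,
) -> IntensityProfile:
    """Average a square cuboid along the segment ``p0 -> p1`` into a 1D profile.

    Each sample is the mean gray value over a ``base_edge_vox`` x
    ``base_edge_vox`` voxel square slice perpendicular to the segment. The
    default sample spacing is one voxel. Density-dark volumes are negated so
    the returned profile is density-bright.
    """
    p0 = np.asarray(p0_nm, dtype=float)
    p1 = np.asarray(p1_nm, dtype=float)
    vox = volume.voxel_size_nm
    if spacing_nm is None:
        spacing_nm = vox
    seg = p1 - p0
    length = float(np.linalg.norm(seg))
    if length <= 0:
        raise ValueError("p0 and p1 coincide")
    u = seg / length
    # Orthonormal frame for the square base.
    helper = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    v = np.cross(u, helper)
    v /= np.linalg.norm(v)
    w = np.cross(u, v)

    n_samples = int(np.floor(length / spacing_nm + 1e-9)) + 1
    half = (base_edge_vox - 1) / 2.0
    offsets = (np.arange(base_edge_vox) - half) * vox
    # Base grid of in-plane offsets, shape (base^2, 3).
    gv, gw = np.meshgrid(offsets, offsets, indexing="ij")
    base = gv.ravel()[:, None] * v[None, :] + gw.ravel()[:, None] * w[None, :]

    arc = np.arange(n_samples) * spacing_nm
    pts = p0[None, None, :] + arc[:, None, None] * u[None, None, :] + base[None, :, :]
    coords = pts.reshape(-1, 3).T / vox
    upper = np.array(volume.shape, dtype=float) - 1.0
    if np.any(coords < -1e-9) or np.any(coords > upper[:, None] + 1e-9):
        raise ValueError("profile cuboid exits the volume")
    vals = map_coordinates(np.asarray(volume.data, dtype=float), coords, order=1)
    samples = vals.reshape(n_samples, -1).mean(axis=1)
    if volume.polarity == DENSITY_DARK:
        samples = -samples
    return IntensityProfile(
        samples=samples, spacing_nm=spacing_nm, origin_nm=p0, direction=u,
        polarity=DENSITY_BRIGHT,
    )


def _find_peaks(samples: np.ndarray, baseline: float, min_prominence: float | None):
    span = samples.max() - baseline
    if span <= 0:
        return np.array([], dtype=int)
    if min_prominence is None:
        min_prominence = 0.5 * span
    peaks, _ = signal.find_peaks(samples, height=baseline, prominence=min_prominence)
    return peaks


def _half_crossings(samples: np.ndarray, peak: int, level: float, spacing: float):
    """Linear-interpolated positions where the profile crosses ``level`` around peak."""
    left = None
    for i in range(peak, 0, -1):
        if samples[i - 1] <= level <= samples[i]:
            frac = (samples[i] - level) / (samples[i] - samples[i - 1])
            left = (i - frac) * spacing
            break
    right = None
    for i in range(peak, samples.size - 1):
        if samples[i + 1] <= level <= samples[i]:
            frac = (samples[i] - level) / (samples[i] - samples[i + 1])
            right = (i + frac) * spacing
            break
    return left, right


def half_max_positions(
    profile: IntensityProfile, min_prominence: float | None = None
) -> list[tuple[float, float]]:
    """50 %-of-maximum edge positions for each membrane peak.

    Returns one ``(left_nm, right_nm)`` pair per detected peak, ordered by
    position. The 50 % level for a peak is ``baseline + 0.5*(peak - baseline)``
    with the profile median as baseline. Equivariant under affine gray
    rescaling ``g -> a*g + b`` with ``a > 0``.
    """
    samples = profile.samples
    baseline = float(np.median(samples))
    peaks = _find_peaks(samples, baseline, min_prominence)
    if peaks.size == 0:
        raise ValueError("no membrane peak above the baseline noise floor")
    out = []
    for p in peaks:
        level = baseline + 0.5 * (samples[p] - baseline)
        left, right = _half_crossings(samples, p, level, profile.spacing_nm)
        if left is None or right is None:
            continue
        out.append((left, right))
    if not out:
        raise ValueError("no peak with two half-maximum crossings")
    return out


def fwhm_thickness(profile: IntensityProfile, min_prominence: float | None = None) -> float:
    """Full width at half maximum of the dominant peak (d_PM or d_DR)."""
    samples = profile.samples
    baseline = float(np.median(samples))
    peaks = _find_peaks(samples, baseline, min_prominence)
    if peaks.size == 0:
        raise ValueError("no peak above baseline")
    heights = samples[peaks]
    order = np.argsort(heights)[::-1]
    if peaks.size > 1 and np.isclose(heights[order[0]], heights[order[1]], rtol=1e-6, atol=1e-12):
        raise ValueError(
            "multiple equally high maxima; call on a windowed sub-profile instead"
        )
    p = peaks[order[0]]
    level = baseline + 0.5 * (samples[p] - baseline)
    left, right = _half_crossings(samples, p, level, profile.spacing_nm)
    if left is None or right is None:
        raise ValueError("dominant peak has no two half-maximum crossings")
    return right - left


def repeat_distances(
    profile: IntensityProfile, min_prominence: float | None = None
) -> list[float]:
    """Spacings between like (rising) half-max edges of consecutive peaks."""
    pairs = half_max_positions(profile, min_prominence=min_prominence)
    if len(pairs) < 2:
        raise ValueError("need >= 2 membrane peaks for repeat distances")
    lefts = sorted(p[0] for p in pairs)
    return [b - a for a, b in zip(lefts[:-1], lefts[1:])]


def local_plane_distance(point_nm, cloud_nm, k_neighbors: int = 9) -> float:
    """Distance from a point to the total-least-squares plane of its k nearest
    cloud neighbors."""
    point = np.asarray(point_nm, dtype=float)
    cloud = np.asarray(cloud_nm, dtype=float)
    if k_neighbors < 3:
        raise ValueError("k_neighbors must be >= 3")
    if cloud.shape[0] < k_neighbors:
        raise ValueError(f"cloud has {cloud.shape[0]} points, need >= {k_neighbors}")
    tree = cKDTree(cloud)
    _, idx = tree.query(point, k=k_neighbors)
    nb = cloud[np.atleast_1d(idx)]
    centroid = nb.mean(axis=0)
    centered = nb - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    # Collinear neighborhoods have (near-)zero second singular value.
    if s[1] <= 1e-9 * max(s[0], 1e-30):
        raise ValueError("degenerate (collinear) neighborhood, plane undefined")
    normal = vt[2]
    return float(abs(np.dot(point - centroid, normal)))
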