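"""Periodicity analysis of the disk-rim scaffold rows and lattice utilities.

The scaffold repeats are measured by fitting y(x) = y0 + A sin(w0 x + p) to a
1D row profile (x in samples); the repeat length is lambda = Ps * 2*pi / w0
with Ps the pixel size of the average (0.262 nm for the unbinned data). The
offset between two rows is Delta_lambda = wrap(p2 - p1) / 2*pi, a
dimensionless fraction of one repeat. Distance cleaning enforces a minimal
spacing between subvolume coordinates, keeping the highest-scoring particle;
spline seeding places oriented subvolume extraction points along picked rim
contours at fixed arc-length spacing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import least_squares
from scipy.spatial import cKDTree

from .io import GrayVolume
from .metrics import IntensityProfile


@dataclass
class SineFit:
    """Parameters of y(x) = y0 + A sin(w0 x + p), x in samples.

    Phase p is wrapped to (-pi, pi] with A normalized positive;
    lambda_nm = Ps_nm * 2*pi / w0.
    """

    y0: float
    A: float
    w0: float
    p: float
    Ps_nm: float
    residual_rms: float

    def __post_init__(self) -> None:
        if not self.w0 > 0:
            raise ValueError("w0 must be > 0")
        if self.lambda_nm <= 2.0 * self.Ps_nm:
            raise ValueError(
                f"repeat length {self.lambda_nm:.3g} nm violates the Nyquist "
                f"limit 2*Ps = {2 * self.Ps_nm:.3g} nm"
            )

    @property
    def lambda_nm(self) -> float:
        return self.Ps_nm * 2.0 * np.pi / self.w0


def _wrap_phase(p: float) -> float:
    """Wrap to (-pi, pi]."""
    w = (p + np.pi) % (2.0 * np.pi) - np.pi
    if w == -np.pi:
        w = np.pi
    return float(w)


def row_average(volume: GrayVolume, cuboid: tuple, long_axis: int) -> IntensityProfile:
    """Average an axis-aligned cuboid perpendicular to ``long_axis``.

    ``cuboid`` is ((z0, z1), (y0, y1), (x0, x1)) in voxels, half-open.
    """
    data = np.asarray(volume.data)
    for (lo, hi), n in zip(cuboid, data.shape):
        if lo < 0 or hi > n or lo >= hi:
            raise ValueError(f"cuboid {cuboid} outside volume of shape {data.shape}")
    sl = tuple(slice(lo, hi) for lo, hi in cuboid)
    box = data[sl]
    axes = tuple(i for i in range(3) if i != long_axis)
    samples = box.mean(axis=axes)
    return IntensityProfile(
        samples=samples, spacing_nm=volume.voxel_size_nm,
        polarity=volume.polarity,
    )


def fit_sine(profile: IntensityProfile, Ps_nm: float = 0.262) -> SineFit:
    """Nonlinear least-squares sine fit; w0 seeded from the dominant
    discrete-Fourier frequency. Requires >= 2 full periods in the profile."""
    y = np.asarray(profile.samples, dtype=float)
    n = y.size
    x = np.arange(n, dtype=float)
    yc = y - y.mean()
    if np.allclose(yc, 0.0):
        raise ValueError("constant profile: no periodic component to fit")
    spec = np.abs(np.fft.rfft(yc))
    if spec[1:].max() <= 0:
        raise ValueError("no periodic component in the profile")
    k0 = int(np.argmax(spec[1:])) + 1
    w_init = 2.0 * np.pi * k0 / n
    a_init = float(np.sqrt(2.0) * yc.std())
    # Linear phase/amplitude estimate at the seed frequency.
    c = np.fft.rfft(yc)[k0]
    p_init = float(np.angle(c) + np.pi / 2.0)

    def resid(theta):
        y0, a, w, p = theta
        return y0 + a * np.sin(w * x + p) - y

    res = least_squares(
        resid, x0=[y.mean(), a_init, w_init, p_init],
        bounds=([-np.inf, -np.inf, 1e-6, -2.0 * np.pi],
                [np.inf, np.inf, np.pi, 2.0 * np.pi]),
    )
    if not res.success:
        raise ValueError(f"sine fit failed to converge: {res.message}")
    y0, a, w0, p = res.x
    if a < 0:  # fold the sign of A into the phase
        a, p = -a, p + np.pi
    p = _wrap_phase(p)
    rms = float(np.sqrt(np.mean(res.fun ** 2)))
    if n * Ps_nm < 2.0 * (Ps_nm * 2.0 * np.pi / w0):
        raise ValueError("profile shorter than two periods of the fitted repeat")
    return SineFit(y0=float(y0), A=float(a), w0=float(w0), p=p, Ps_nm=Ps_nm,
                   residual_rms=rms)


def row_offset(fit_row1: SineFit, fit_row2: SineFit) -> float:
    """Inter-row offset Delta_lambda = wrap(p2 - p1)/2pi in [0, 1) repeats."""
    rel = abs(fit_row1.lambda_nm - fit_row2.lambda_nm) / fit_row1.lambda_nm
    if rel >= 0.1:
        raise ValueError(
            f"incompatible periods: {fit_row1.lambda_nm:.3g} vs "
            f"{fit_row2.lambda_nm:.3g} nm ({100 * rel:.1f}% apart)"
        )
    frac = ((fit_row2.p - fit_row1.p) / (2.0 * np.pi)) % 1.0
    return float(frac)


def distance_clean(coords_nm, scores, min_dist_nm: float = 4.0) -> np.ndarray:
    """Greedy minimum-spacing selection, by descending score.

    Accept a point iff it lies >= min_dist_nm from every previously accepted
    point; ties in score break toward the lower index. The highest-scoring
    point is always kept and all pairwise output distances are >= min_dist_nm.
    Returns the accepted indices (ascending).
    """
    coords = np.atleast_2d(np.asarray(coords_nm, dtype=float))
    scores = np.asarray(scores, dtype=float)
    if len(coords) != len(scores):
        raise ValueError(f"coords ({len(coords)}) and scores ({len(scores)}) differ in length")
    order = np.lexsort((np.arange(len(scores)), -scores))
    accepted: list[int] = []
    for i in order:
        p = coords[i]
        if all(np.linalg.norm(p - coords[j]) >= min_dist_nm for j in accepted):
            accepted.append(int(i))
    return np.array(sorted(accepted), dtype=int)


@dataclass
class OrientedSeed:
    """A subvolume extraction point with ZXZ Euler angles (degrees).

    Convention: rotations are applied as Phi (about z, in-plane, randomized),
    then Theta (about the new x), then Psi (about the new z); Theta and Psi
    orient the seed z-axis along the local spline tangent.
    """

    position_nm: np.ndarray
    euler_phi: float
    euler_theta: float
    euler_psi: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.euler_theta <= 180.0):
            raise ValueError("theta must be in [0, 180]")
        for a in (self.euler_phi, self.euler_psi):
            if not (-180.0 <= a < 180.0):
                raise ValueError("phi and psi must be in [-180, 180)")

    def rotation_matrix(self) -> np.ndarray:
        """Matrix mapping seed-frame vectors to tomogram (x, y, z) vectors."""
        return (
            _rot_z(self.euler_psi) @ _rot_x(self.euler_theta) @ _rot_z(self.euler_phi)
        )

    def z_axis(self) -> np.ndarray:
        """Seed z-axis direction in tomogram (x, y, z) components."""
        return self.rotation_matrix() @ np.array([0.0, 0.0, 1.0])


def _rot_z(deg: float) -> np.ndarray:
    c, s = np.cos(np.deg2rad(deg)), np.sin(np.deg2rad(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rot_x(deg: float) -> np.ndarray:
    c, s = np.cos(np.deg2rad(deg)), np.sin(np.deg2rad(deg))
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def _tangent_to_euler(tangent_xyz: np.ndarray) -> tuple[float, float]:
    """(theta, psi) in degrees such that Rz(psi) Rx(theta) maps z to the tangent."""
    dx, dy, dz = tangent_xyz
    theta = float(np.rad2deg(np.arccos(np.clip(dz, -1.0, 1.0))))
    psi = float(np.rad2deg(np.arctan2(dx, -dy))) if theta > 1e-9 else 0.0
    if psi >= 180.0:
        psi -= 360.0
    return theta, psi


def spline_seed(
    control_points_nm,
    spacing_nm: float = 1.0,
    rng_seed: int = 0,
    oversample: int = 10,
) -> list[OrientedSeed]:
    """Oriented seeds along a natural cubic spline through the control points.

    The spline is re-parameterized by arc length (``oversample`` x denser
    sampling); seeds sit at arc-length multiples of ``spacing_nm``, the seed
    z-axis equals the local tangent (via Theta/Psi) and Phi is uniform in
    [-180, 180) from ``rng_seed``. Deterministic given rng_seed.
    """
    pts = np.asarray(control_points_nm, dtype=float)
    if pts.ndim != 2 or len(pts) < 2:
        raise ValueError("need >= 2 control points")
    if np.any(np.linalg.norm(np.diff(pts, axis=0), axis=1) < 1e-12):
        raise ValueError("duplicate consecutive control points")
    chord = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
    spline = CubicSpline(chord, pts, axis=0, bc_type="natural")
    # Arc-length re-parameterization on an oversampled grid.
    n_dense = max(int(np.ceil(chord[-1] / spacing_nm)) * oversample, 2 * oversample)
    t_dense = np.linspace(0.0, chord[-1], n_dense + 1)
    p_dense = spline(t_dense)
    seg = np.linalg.norm(np.diff(p_dense, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    n_seeds = int(np.floor(total / spacing_nm + 1e-9)) + 1
    targets = np.arange(n_seeds) * spacing_nm
    t_at = np.interp(targets, arc, t_dense)

    rng = np.random.default_rng(rng_seed)
    seeds = []
    for t in t_at:
        pos = spline(t)
        tan = spline(t, 1)
        tan = tan / np.linalg.norm(tan)
        # Spline points are (z, y, x); Euler angles act on (x, y, z).
        theta, psi = _tangent_to_euler(tan[::-1])
        phi = float(rng.uniform(-180.0, 180.0))
        seeds.append(OrientedSeed(position_nm=pos, euler_phi=phi,
                                  euler_theta=theta, euler_psi=psi))
    return seeds
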