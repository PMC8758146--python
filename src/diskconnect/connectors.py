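"""Hierarchical connectivity segmentation of inter-membrane connectors.

A gray-value threshold ramp runs from g_min to g_max in steps of g_step over
the normalized between-region of a membrane pair. At each level the
6-connected components of {voxels <= level} that are face-adjacent to both
membrane masks ("bridging components") are collected; the output contains the
first-appearance (root) components only — those that contain no bridging
component from any lower level. An optional watershed pre-mask, flooded from
markers on the medial surface between the two masks, removes basin-boundary
voxels first so that laterally touching connectors are split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.segmentation import watershed

from .membranes import STRUCT_6, MembranePair


@dataclass
class ThresholdRamp:
    """Gray-value ramp g_i = g_min + (i - 1) * g_step, i = 1..n, g_i <= g_max.

    Defaults (-2, -0.68, 0.02) are the normalized-gray working range for
    density-dark tomograms standardized to mean 0 / sd 1.
    """

    g_min: float = -2.0
    g_max: float = -0.68
    g_step: float = 0.02

    def __post_init__(self) -> None:
        if not self.g_min < self.g_max:
            raise ValueError("g_min must be < g_max")
        if not self.g_step > 0:
            raise ValueError("g_step must be > 0")

    def levels(self) -> np.ndarray:
        n = int(np.floor((self.g_max - self.g_min) / self.g_step + 1e-9)) + 1
        return self.g_min + np.arange(n) * self.g_step


@dataclass
class Connector:
    """A first-appearance bridging voxel group.

    ``voxels`` are (N, 3) integer (z, y, x) indices in full-volume
    coordinates; ``g_first`` is the ramp level at which the group first
    bridged both masks.
    """

    id: int
    pair_id: int
    voxels: np.ndarray
    g_first: float

    @property
    def n_voxels(self) -> int:
        return len(self.voxels)


def _touch_maps(region: np.ndarray, mask_a: np.ndarray, mask_b: np.ndarray):
    """Region voxels face-adjacent to each mask."""
    touch_a = region & ndimage.binary_dilation(mask_a, structure=STRUCT_6)
    touch_b = region & ndimage.binary_dilation(mask_b, structure=STRUCT_6)
    return touch_a, touch_b


def bridging_components(
    gray: np.ndarray,
    region: np.ndarray,
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    g: float,
) -> list[np.ndarray]:
    """6-connected components of {region voxels with gray <= g} that touch
    (face-adjacency) both masks. Returns (N, 3) index arrays."""
    bw = region & (gray <= g)
    labels, n = ndimage.label(bw, structure=STRUCT_6)
    if n == 0:
        return []
    touch_a, touch_b = _touch_maps(region, mask_a, mask_b)
    la = np.unique(labels[bw & touch_a])
    lb = np.unique(labels[bw & touch_b])
    bridging = np.intersect1d(la, lb)
    bridging = bridging[bridging > 0]
    out = []
    slices = ndimage.find_objects(labels)
    for lab in bridging:
        sl = slices[lab - 1]
        local = np.argwhere(labels[sl] == lab)
        local += np.array([s.start for s in sl])
        out.append(local)
    return out


def watershed_premask(
    gray: np.ndarray,
    pair: MembranePair,
    g_max: float = -0.68,
    landscape: str = "gray",
) -> np.ndarray:
    """Remove watershed-line voxels from the between-region.

    The binary mask B = {region voxels <= g_max} is flooded (Meyer algorithm)
    from markers on the medial surface between the two membrane masks; voxels
    on boundaries between distinct basins are dropped from the region so that
    touching connectors separate. ``landscape`` selects the flooding relief:
    ``"gray"`` (normalized gray values, default — splits at the density ridge
    between two cores) or ``"distance"`` (negated distance transform of B).
    """
    region = pair.region
    b = region & (gray <= g_max)
    markers_src = pair.medial_zone() & b
    markers, n_markers = ndimage.label(markers_src, structure=STRUCT_6)
    if n_markers == 0:
        warnings.warn("watershed pre-mask: no marker voxels on the medial surface; "
                      "region returned unchanged", stacklevel=2)
        return region.copy()
    if landscape == "gray":
        relief = gray
    elif landscape == "distance":
        relief = -ndimage.distance_transform_edt(b)
    else:
        raise ValueError(f"unknown landscape {landscape!r}")
    ws = watershed(relief, markers=markers, mask=b, connectivity=STRUCT_6,
                   watershed_line=True)
    lines = b & (ws == 0)
    return region & ~lines


def segment_pair(
    gray: np.ndarray,
    pair: MembranePair,
    ramp: ThresholdRamp | None = None,
    use_watershed: bool = True,
    id_start: int = 1,
) -> list[Connector]:
    """Hierarchical threshold-sweep segmentation of one membrane pair.

    ``gray`` is the pair's (cropped) normalized gray-value array. The output
    holds exactly the bridging components without ancestors (first-appearance
    rule), with their first-appearance level recorded, sorted by
    (g_first, lexicographic minimum voxel) and voxel-disjoint.
    """
    if ramp is None:
        ramp = ThresholdRamp()
    gray = np.asarray(gray, dtype=float)
    region = pair.region
    if not region.any():
        raise ValueError(f"pair {pair.pair_id}: empty between-region")
    if use_watershed:
        region = watershed_premask(gray, pair, g_max=ramp.g_max)
    touch_a, touch_b = _touch_maps(region, pair.mask_a, pair.mask_b)

    taken = np.zeros(region.shape, dtype=bool)
    offset = pair.offset_vox
    found: list[tuple[float, tuple, np.ndarray]] = []
    for g in ramp.levels():
        bw = region & (gray <= g)
        labels, n = ndimage.label(bw, structure=STRUCT_6)
        if n == 0:
            continue
        la = np.unique(labels[bw & touch_a])
        lb = np.unique(labels[bw & touch_b])
        bridging = np.intersect1d(la, lb)
        bridging = bridging[bridging > 0]
        if bridging.size == 0:
            continue
        # A bridging component has an ancestor iff it contains a previously
        # output root (components across levels are nested), i.e. overlaps it.
        with_ancestor = np.unique(labels[taken])
        new = np.setdiff1d(bridging, with_ancestor)
        if new.size == 0:
            continue
        slices = ndimage.find_objects(labels)
        for lab in new:
            sl = slices[lab - 1]
            comp = labels[sl] == lab
            local = np.argwhere(comp) + np.array([s.start for s in sl])
            taken[sl] |= comp
            vox_global = local + offset
            key = tuple(vox_global[np.lexsort(vox_global.T[::-1])][0])
            found.append((float(g), key, vox_global))
    found.sort(key=lambda t: (t[0], t[1]))
    return [
        Connector(id=id_start + i, pair_id=pair.pair_id, voxels=vox, g_first=g)
        for i, (g, _, vox) in enumerate(found)
    ]
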