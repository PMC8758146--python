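"""Independent brute-force oracle for the hierarchical threshold-sweep
segmentation, built on explicit python sets.

For every ramp level it enumerates the 6-connected components of the
sub-threshold region voxels, tests bridging by explicit face-neighbor lookup
against the mask voxel sets, and applies the first-appearance (no-ancestor)
rule by explicit subset containment across all lower levels. Deliberately
naive and independent of the array-based implementation it checks.
"""

from __future__ import annotations

import numpy as np

_FACES = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]


def _components(voxels: set) -> list[set]:
    """6-connected components via BFS over a voxel set."""
    remaining = set(voxels)
    comps = []
    while remaining:
        seed = next(iter(remaining))
        comp = {seed}
        frontier = [seed]
        remaining.remove(seed)
        while frontier:
            z, y, x = frontier.pop()
            for dz, dy, dx in _FACES:
                nb = (z + dz, y + dy, x + dx)
                if nb in remaining:
                    remaining.remove(nb)
                    comp.add(nb)
                    frontier.append(nb)
        comps.append(comp)
    return comps


def _touches(comp: set, mask: set) -> bool:
    for z, y, x in comp:
        for dz, dy, dx in _FACES:
            if (z + dz, y + dy, x + dx) in mask:
                return True
    return False


def oracle_segment(gray, region, mask_a, mask_b, levels):
    """First-appearance bridging components by exhaustive enumeration.

    Returns a list of (g_first, frozenset of voxel tuples), unordered.
    """
    gray = np.asarray(gray)
    region_set = {tuple(v) for v in np.argwhere(np.asarray(region, dtype=bool))}
    set_a = {tuple(v) for v in np.argwhere(np.asarray(mask_a, dtype=bool))}
    set_b = {tuple(v) for v in np.argwhere(np.asarray(mask_b, dtype=bool))}

    bridging_by_level = []
    for g in levels:
        sub = {v for v in region_set if gray[v] <= g}
        bridging = [c for c in _components(sub)
                    if _touches(c, set_a) and _touches(c, set_b)]
        bridging_by_level.append(bridging)

    out = []
    for li, bridging in enumerate(bridging_by_level):
        for comp in bridging:
            has_ancestor = any(
                earlier <= comp
                for lj in range(li)
                for earlier in bridging_by_level[lj]
            )
            if not has_ancestor:
                out.append((float(levels[li]), frozenset(comp)))
    return out
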