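import numpy as np
import pytest

from diskconnect.connectors import (Connector, ThresholdRamp, bridging_components,
                                    segment_pair, watershed_premask)
from conftest import make_slab_pair
from _oracle import oracle_segment


def as_sets(conns):
    return {(c.g_first, frozenset(map(tuple, c.voxels))) for c in conns}


def put_column(gray, pair, y, x, value, z_range=None):
    """Fill a vertical column through the between-region with a gray value."""
    zs = np.unique(np.argwhere(pair.region)[:, 0]) if z_range is None else z_range
    for z in zs:
        gray[z, y, x] = value


def background_gray(pair, value=0.0):
    return np.full(pair.region.shape, value)


class TestThresholdRamp:
    def test_default_levels(self):
        levels = ThresholdRamp().levels()
        assert len(levels) == 67
        assert levels[0] == pytest.approx(-2.0)
        assert levels[-1] == pytest.approx(-0.68)
        assert np.allclose(np.diff(levels), 0.02)

    def test_invalid_ramps(self):
        with pytest.raises(ValueError):
            ThresholdRamp(g_min=-0.5, g_max=-1.0)
        with pytest.raises(ValueError):
            ThresholdRamp(g_step=0.0)


class TestBridgingComponents:
    def test_nothing_below_threshold(self):
        pair = make_slab_pair()
        gray = background_gray(pair)
        assert bridging_components(gray, pair.region, pair.mask_a, pair.mask_b,
                                   -0.68) == []

    def test_single_spanning_column(self):
        pair = make_slab_pair()
        gray = background_gray(pair)
        put_column(gray, pair, 5, 7, -1.0)
        comps = bridging_components(gray, pair.region, pair.mask_a, pair.mask_b, -1.0)
        assert len(comps) == 1
        zs = np.unique(np.argwhere(pair.region)[:, 0])
        assert {tuple(v) for v in comps[0]} == {(z, 5, 7) for z in zs}

    def test_column_above_threshold_excluded(self):
        pair = make_slab_pair()
        gray = background_gray(pair)
        put_column(gray, pair, 5, 7, -1.0)
        assert bridging_components(gray, pair.region, pair.mask_a, pair.mask_b,
                                   -1.02) == []

    def test_non_bridging_stub_excluded(self):
        pair = make_slab_pair()
        gray = background_gray(pair)
        zs = np.unique(np.argwhere(pair.region)[:, 0])
        put_column(gray, pair, 5, 7, -1.0, z_range=zs[:3])  # touches A only
        assert bridging_components(gray, pair.region, pair.mask_a, pair.mask_b,
                                   -1.0) == []


class TestSegmentPairFixtures:
    def test_single_column_first_appearance_level(self):
        pair = make_slab_pair()
        gray = background_gray(pair)
        put_column(gray, pair, 5, 7, -1.0)
        conns = segment_pair(gray, pair, use_watershed=False)
        assert len(conns) == 1
        # -1.0 is ramp level i=51: g = -2 + 50*0.02
        assert conns[0].g_first == pytest.approx(-1.0)
        zs = np.unique(np.argwhere(pair.region)[:, 0])
        assert {tuple(v) for v in conns[0].voxels} == {(z, 5, 7) for z in zs}

    @pytest.mark.parametrize("use_watershed", [False, True])
    def test_two_columns_with_weak_bridge_stay_split(self, use_watershed):
        """A faint lateral bridge merges two dark columns only at a higher
        ramp level; the merged component has ancestors and is excluded."""
        pair = make_slab_pair()
        gray = background_gray(pair)
        put_column(gray, pair, 5, 4, -1.5)
        put_column(gray, pair, 5, 10, -1.5)
        for x in range(5, 10):  # weak bridge at mid-gap
            gray[9, 5, x] = -0.8
        conns = segment_pair(gray, pair, use_watershed=use_watershed)
        assert len(conns) == 2
        assert all(c.g_first == pytest.approx(-1.5) for c in conns)

    def test_u_shape_split_only_by_watershed(self):
        """Two arms joined by an equally dark lateral bridge at one membrane
        surface form a single first-appearance component; the watershed
        pre-mask separates the two density cores."""
        pair = make_slab_pair()
        gray = background_gray(pair)
        put_column(gray, pair, 5, 4, -1.5)
        put_column(gray, pair, 5, 10, -1.5)
        zs = np.unique(np.argwhere(pair.region)[:, 0])
        for x in range(5, 10):  # bridge on the mask-B side, same gray
            gray[zs[-1], 5, x] = -1.5
        plain = segment_pair(gray, pair, use_watershed=False)
        split = segment_pair(gray, pair, use_watershed=True)
        assert len(plain) == 1
        assert len(split) == 2

    def test_empty_region_errors(self):
        pair = make_slab_pair()
        pair.region[:] = False
        with pytest.raises(ValueError, match="between-region"):
            segment_pair(background_gray(pair), pair)

    def test_output_disjoint_and_sorted(self):
        rng = np.random.default_rng(11)
        pair = make_slab_pair()
        gray = rng.normal(-0.6, 0.7, pair.region.shape)
        conns = segment_pair(gray, pair, use_watershed=False)
        seen = set()
        for c in conns:
            vox = set(map(tuple, c.voxels))
            assert not vox & seen
            seen |= vox
        g_firsts = [c.g_first for c in conns]
        assert g_firsts == sorted(g_firsts)

    def test_connector_invariants(self):
        rng = np.random.default_rng(13)
        pair = make_slab_pair()
        gray = rng.normal(-0.6, 0.7, pair.region.shape)
        from scipy import ndimage
        from diskconnect.membranes import STRUCT_6

        for c in segment_pair(gray, pair, use_watershed=False):
            mask = np.zeros(pair.region.shape, dtype=bool)
            mask[tuple(c.voxels.T)] = True
            _, n = ndimage.label(mask, structure=STRUCT_6)
            assert n == 1  # one 6-connected component
            assert gray[tuple(c.voxels.T)].max() <= c.g_first <= -0.68 + 1e-12
            dil = ndimage.binary_dilation(mask, structure=STRUCT_6)
            assert (dil & pair.mask_a).any() and (dil & pair.mask_b).any()


class TestRampRefinement:
    def test_halving_step_preserves_output_on_ramp_aligned_gray(self):
        rng = np.random.default_rng(5)
        pair = make_slab_pair()
        levels = ThresholdRamp().levels()
        gray = rng.choice(levels, size=pair.region.shape) - 1e-9
        coarse = segment_pair(gray, pair, ramp=ThresholdRamp(), use_watershed=False)
        fine = segment_pair(gray, pair, ramp=ThresholdRamp(g_step=0.01),
                            use_watershed=False)
        assert {frozenset(map(tuple, c.voxels)) for c in coarse} == \
               {frozenset(map(tuple, c.voxels)) for c in fine}


class TestWatershedPremask:
    def test_single_column_single_basin_region_unchanged_on_b(self):
        pair = make_slab_pair()
        gray = background_gray(pair)
        put_column(gray, pair, 5, 7, -1.0)
        out = watershed_premask(gray, pair)
        b = pair.region & (gray <= -0.68)
        np.testing.assert_array_equal(out & b, pair.region & b)

    def test_two_distant_columns_no_removed_voxels(self):
        pair = make_slab_pair()
        gray = background_gray(pair)
        put_column(gray, pair, 2, 2, -1.2)
        put_column(gray, pair, 8, 12, -1.2)
        out = watershed_premask(gray, pair)
        np.testing.assert_array_equal(out, pair.region)

    def test_no_markers_warns_and_returns_region(self):
        pair = make_slab_pair()
        gray = background_gray(pair)  # nothing below g_max anywhere
        with pytest.warns(UserWarning, match="no marker"):
            out = watershed_premask(gray, pair)
        np.testing.assert_array_equal(out, pair.region)

    def test_watershed_never_merges_connectors(self):
        """Removing watershed-line voxels can only split components, so no
        two plain-sweep connectors may end up inside one pre-masked one."""
        rng = np.random.default_rng(21)
        for _ in range(10):
            pair = make_slab_pair()
            gray = rng.normal(-0.5, 0.6, pair.region.shape)
            plain = segment_pair(gray, pair, use_watershed=False)
            split = segment_pair(gray, pair, use_watershed=True)
            plain_sets = [set(map(tuple, c.voxels)) for c in plain]
            for s in split:
                vox = set(map(tuple, s.voxels))
                overlapping = sum(1 for p in plain_sets if p <= vox)
                assert overlapping <= 1

    def test_watershed_does_not_decrease_counts_on_fixtures(self):
        pair = make_slab_pair()
        zs = np.unique(np.argwhere(pair.region)[:, 0])
        for bridge_z, bridge_gray in [(zs[-1], -1.5), (9, -0.8)]:
            gray = background_gray(pair)
            put_column(gray, pair, 5, 4, -1.5)
            put_column(gray, pair, 5, 10, -1.5)
            for x in range(5, 10):
                gray[bridge_z, 5, x] = bridge_gray
            plain = segment_pair(gray, pair, use_watershed=False)
            split = segment_pair(gray, pair, use_watershed=True)
            assert len(split) >= len(plain)


def random_instance(rng):
    nz = int(rng.integers(8, 14))
    ny = int(rng.integers(5, 11))
    nx = int(rng.integers(5, 11))
    za = 1
    zb = nz - 2
    pair = make_slab_pair(nz=nz, ny=ny, nx=nx, za=za, zb=zb, halfwidth=1)
    gray = rng.normal(-0.4, 0.75, (nz, ny, nx))
    if rng.random() < 0.5:  # plant 1-2 spanning columns
        for _ in range(int(rng.integers(1, 3))):
            y, x = int(rng.integers(0, ny)), int(rng.integers(0, nx))
            gray[:, y, x] = rng.uniform(-1.8, -0.9)
    return pair, gray


class TestOracleEquivalence:
    @pytest.mark.parametrize("batch", range(4))
    def test_matches_brute_force_on_random_instances(self, batch):
        """The array-based sweep equals an exhaustive set-based enumeration of
        every ramp level with explicit subset-containment ancestry."""
        rng = np.random.default_rng(100 + batch)
        ramp = ThresholdRamp(g_min=-2.0, g_max=-0.7, g_step=0.1)
        for _ in range(15):
            pair, gray = random_instance(rng)
            got = as_sets(segment_pair(gray, pair, ramp=ramp, use_watershed=False))
            expected = oracle_segment(gray, pair.region, pair.mask_a,
                                      pair.mask_b, ramp.levels())
            exp_plain = {(round(g, 9), comp) for g, comp in expected}
            got_plain = {(round(g, 9), comp) for g, comp in got}
            assert got_plain == exp_plain
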