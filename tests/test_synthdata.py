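import numpy as np
import pytest

from diskconnect import synthdata
from diskconnect.io import DENSITY_DARK
from diskconnect.metrics import fwhm_thickness, half_max_positions
from diskconnect.synthdata import (ConnectorSpec, IncisureSpec, StackSpec,
                                   generate_disk_stack, generate_lattice_profiles,
                                   generate_membrane_profile)

SMALL = dict(volume_shape=(110, 96, 160), seed=3)


def small_specs(n_rim=8, n_interior=10):
    return synthdata.default_connector_specs(n_rim=n_rim, n_interior=n_interior)


class TestGenerateDiskStack:
    def test_counts_and_classes_bookkeeping(self):
        spec = StackSpec(**SMALL)
        specs = [ConnectorSpec(class_label="rim", count=6, length_nm=12.0,
                               amplitude=0.7),
                 ConnectorSpec(class_label="interior", count=10, length_nm=16.0,
                               amplitude=0.5, min_spacing_nm=10.0)]
        _, _, gt = generate_disk_stack(spec, specs)
        assert len(gt.connectors) == 16
        counts = gt.connectors["class_label"].value_counts()
        assert counts["rim"] == 6 and counts["interior"] == 10

    def test_determinism_and_seed_sensitivity(self):
        spec = StackSpec(**SMALL)
        v1, l1, _ = generate_disk_stack(spec, small_specs())
        v2, l2, _ = generate_disk_stack(StackSpec(**SMALL), small_specs())
        np.testing.assert_array_equal(v1.data, v2.data)
        np.testing.assert_array_equal(l1.labels, l2.labels)
        v3, _, _ = generate_disk_stack(StackSpec(**{**SMALL, "seed": 4}), small_specs())
        assert not np.array_equal(v1.data, v3.data)

    def test_noiseless_background_is_flat_between_membranes(self):
        spec = StackSpec(**SMALL, noise_sd=0.0, gradient_amplitude=0.0)
        vol, labels, gt = generate_disk_stack(spec, [])
        # Mid-gap voxels far from membranes, rims and PM: exactly background.
        row = gt.pair_table.iloc[0]
        za = gt.membrane_planes_z_nm[row["label_a"]]
        zb = gt.membrane_planes_z_nm[row["label_b"]]
        zi = int(round((za + zb) / 2.0 / spec.voxel_size_nm))
        mid = vol.data[zi, 20:40, 30:60]
        assert np.abs(mid).max() < 1e-6
        assert vol.polarity == DENSITY_DARK

    def test_rendered_membrane_fwhm_matches_spec(self):
        """The plasma membrane (rendered like every slab) has the apparent
        thickness as its 1D-profile full width at half maximum."""
        spec = StackSpec(**SMALL, noise_sd=0.0, gradient_amplitude=0.0)
        vol, _, gt = generate_disk_stack(spec, [])
        from diskconnect.metrics import extract_profile

        # Profile along x at a cytosolic mid-gap z: only the PM peak remains.
        row = gt.pair_table.iloc[0]
        za = gt.membrane_planes_z_nm[row["label_a"]]
        zb = gt.membrane_planes_z_nm[row["label_b"]]
        z_nm = (za + zb) / 2.0
        y_nm = 30 * spec.voxel_size_nm
        x1 = (spec.volume_shape[2] - 1) * spec.voxel_size_nm
        prof = extract_profile(vol, [z_nm, y_nm, 0.0], [z_nm, y_nm, x1],
                               base_edge_vox=3)
        assert fwhm_thickness(prof) == pytest.approx(
            spec.membrane_thickness_nm, abs=spec.voxel_size_nm)

    def test_rim_connectors_respect_the_40nm_zone(self):
        spec = StackSpec(**SMALL)
        _, _, gt = generate_disk_stack(spec, small_specs())
        from scipy.spatial import cKDTree

        tree = cKDTree(gt.rim_periphery_nm)
        mids = gt.connectors[["mz", "my", "mx"]].to_numpy()
        d, _ = tree.query(mids)
        rim = gt.connectors["class_label"] == "rim"
        assert (d[rim] <= 40.0).all()
        assert (d[~rim] > 40.0).all()

    def test_midpoint_is_mean_of_endpoints(self):
        spec = StackSpec(**SMALL)
        _, _, gt = generate_disk_stack(spec, small_specs())
        df = gt.connectors
        for a, m in (("z", "mz"), ("y", "my"), ("x", "mx")):
            np.testing.assert_allclose(df[m], (df[a + "0"] + df[a + "1"]) / 2.0,
                                       atol=1e-9)
        lengths = np.linalg.norm(
            df[["z1", "y1", "x1"]].to_numpy() - df[["z0", "y0", "x0"]].to_numpy(),
            axis=1)
        np.testing.assert_allclose(df["true_length_nm"], lengths, atol=1e-9)

    def test_interior_connectors_planted_longer_than_rim(self):
        spec = StackSpec(**SMALL)
        _, _, gt = generate_disk_stack(spec, small_specs())
        df = gt.connectors
        med_rim = df.loc[df.class_label == "rim", "true_length_nm"].median()
        med_int = df.loc[df.class_label == "interior", "true_length_nm"].median()
        assert med_rim < med_int

    def test_volume_too_small_errors(self):
        with pytest.raises(ValueError, match="2 disk pairs"):
            generate_disk_stack(StackSpec(volume_shape=(40, 40, 150)))

    def test_oversized_connector_errors(self):
        spec = StackSpec(**SMALL)
        fat = [ConnectorSpec(class_label="rim", count=1, radius_nm=8.0)]
        with pytest.raises(ValueError, match="too thick"):
            generate_disk_stack(spec, fat)
        long = [ConnectorSpec(class_label="interior", count=1, length_nm=40.0,
                              length_sd_nm=0.0)]
        with pytest.raises(ValueError, match="cannot fit"):
            generate_disk_stack(spec, long)

    def test_incisure_carves_a_cleft(self):
        y0 = 32 * 1.048
        spec = StackSpec(volume_shape=(110, 96, 150), seed=3,
                         incisure=IncisureSpec(position_y_nm=y0,
                                               cleft_width_nm=24.0))
        vol, labels, gt = generate_disk_stack(spec, [])
        yi = int(round(y0 / spec.voxel_size_nm))
        assert not (labels.labels[:, yi, :]).any()  # no membrane in the cleft
        assert (labels.labels[:, 90, :]).any()
        assert set(gt.incisure_periphery_nm) == {-1, 1}


class TestMembraneProfileGenerator:
    def test_inner_edge_gap_matches_analytic_geometry(self):
        prof = generate_membrane_profile(6.8, 14.0, spacing_nm=0.2)
        (l1, r1), (l2, r2) = sorted(half_max_positions(prof))
        assert l2 - r1 == pytest.approx(14.0 - 6.8, abs=0.2)
        assert r1 - l1 == pytest.approx(6.8, abs=0.2)

    def test_single_peak_symmetry(self):
        prof = generate_membrane_profile(6.8, 14.0, spacing_nm=0.1, n_peaks=1)
        p = int(np.argmax(prof.samples))
        w = min(p, prof.samples.size - 1 - p)
        np.testing.assert_allclose(prof.samples[p - w:p],
                                   prof.samples[p + w:p:-1], atol=1e-9)

    def test_reproducible_noise(self):
        a = generate_membrane_profile(6.8, 14.0, 0.5, noise_sd=0.1, seed=5)
        b = generate_membrane_profile(6.8, 14.0, 0.5, noise_sd=0.1, seed=5)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_separation_below_thickness_errors(self):
        with pytest.raises(ValueError, match="separation"):
            generate_membrane_profile(6.8, 5.0, 0.5)


class TestLatticeProfileGenerator:
    def test_antiphase_offset(self):
        cd, pr = generate_lattice_profiles(4.1, 0.5)
        a = cd.samples - cd.samples.mean()
        b = pr.samples - pr.samples.mean()
        assert np.dot(a, b) < 0

    def test_fft_peak_at_planted_frequency(self):
        cd, _ = generate_lattice_profiles(4.1, 0.0, Ps_nm=0.262, n_samples=512)
        spec = np.abs(np.fft.rfft(cd.samples - cd.samples.mean()))
        freqs = np.fft.rfftfreq(512, d=0.262)
        peak_freq = freqs[np.argmax(spec)]
        expected = 1.0 / 4.1
        assert abs(peak_freq - expected) <= freqs[1] / 2 + 1e-12 + abs(
            freqs[np.abs(freqs - expected).argmin()] - expected)

    def test_zero_offset_identical(self):
        cd, pr = generate_lattice_profiles(4.1, 0.0)
        np.testing.assert_allclose(cd.samples, pr.samples, atol=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError, match="Ps_nm"):
            generate_lattice_profiles(4.1, 0.0, Ps_nm=0.0)
        with pytest.raises(ValueError, match="too short"):
            generate_lattice_profiles(4.1, 0.0, n_samples=10)


class TestGroundTruthConsistency:
    def test_noiseless_planted_length_recovered_within_one_voxel(
            self, noiseless_phantom):
        """Rendering then re-measuring a noiseless planted connector's length
        through the full segmentation chain reproduces true_length_nm."""
        from diskconnect import pipeline
        from scipy.spatial import cKDTree

        spec, volume, labels, gt = noiseless_phantom
        meas, _, _ = pipeline.segment_volume(volume, labels, gt.pair_table)
        found = np.array([m.c_con_nm for m in meas])
        lengths = np.array([m.l_con_nm for m in meas])
        tree = cKDTree(found)
        mids = gt.connectors[["mz", "my", "mx"]].to_numpy()
        d, j = tree.query(mids)
        matched = d <= 4.0
        assert matched.mean() > 0.9
        err = np.abs(lengths[j[matched]]
                     - gt.connectors["true_length_nm"].to_numpy()[matched])
        assert np.median(err) <= spec.voxel_size_nm


class TestAxialBlur:
    def test_blur_widens_axial_but_not_lateral_profiles(self):
        sharp = StackSpec(**SMALL, noise_sd=0.0, gradient_amplitude=0.0)
        blurred = StackSpec(volume_shape=SMALL["volume_shape"], seed=3,
                            noise_sd=0.0, gradient_amplitude=0.0,
                            axial_blur_sigma_nm=2.0)
        v1, _, _ = generate_disk_stack(sharp, [])
        v2, _, _ = generate_disk_stack(blurred, [])
        col1 = v1.data[:, 30, 40]
        col2 = v2.data[:, 30, 40]
        # Blur conserves integral but lowers the membrane peak depth.
        assert col2.min() > col1.min()
        assert np.sum(col2) == pytest.approx(np.sum(col1), rel=0.01)
        # Lateral (x) structure at a fixed z is left untouched by z-only blur
        # apart from mixing across z; the PM slab (constant in z) is identical.
        pm_x = int(np.argmin(v1.data[5, 30, :]))
        assert v2.data[5, 30, pm_x] == pytest.approx(v1.data[5, 30, pm_x],
                                                     abs=1e-6)
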