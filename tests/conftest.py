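import numpy as np
import pytest

from diskconnect import synthdata
from diskconnect.membranes import build_pair


@pytest.fixture(scope="session")
def small_phantom():
    """A small disk-stack phantom with planted connectors (2 membrane pairs)."""
    spec = synthdata.StackSpec(volume_shape=(110, 96, 160), seed=7)
    specs = synthdata.default_connector_specs(n_rim=8, n_interior=10)
    volume, labels, gt = synthdata.generate_disk_stack(spec, specs)
    return spec, volume, labels, gt


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Same geometry without noise or gradient, for exact-recovery checks."""
    spec = synthdata.StackSpec(volume_shape=(110, 96, 160), seed=7,
                               noise_sd=0.0, gradient_amplitude=0.0)
    specs = synthdata.default_connector_specs(n_rim=8, n_interior=10)
    volume, labels, gt = synthdata.generate_disk_stack(spec, specs)
    return spec, volume, labels, gt


def make_slab_pair(nz=20, ny=11, nx=15, za=2, zb=16, halfwidth=3, voxel=1.0):
    """A membrane pair of two flat z-planes with everything between in-region."""
    plane_a = np.zeros((nz, ny, nx), dtype=bool)
    plane_b = np.zeros((nz, ny, nx), dtype=bool)
    plane_a[za] = True
    plane_b[zb] = True
    gap_nm = (zb - za - 2 * halfwidth) * voxel + 2 * voxel
    return build_pair(plane_a, plane_b, voxel_size_nm=voxel,
                      halfwidth_vox=halfwidth, gap_max_nm=gap_nm)
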