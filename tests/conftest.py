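import numpy as np
import pytest

import icodiff as ic


@pytest.fixture(scope="session")
def group():
    return ic.build_icosahedral_group()


@pytest.fixture(scope="session")
def small_spec():
    """A 64-cube phantom scaled to fit: everything ~0.66x the default radii."""
    return ic.PhantomSpec(
        box_size=64, voxel_size=2.9, shell_radius=64.0, shell_thickness=7.0,
        p2=ic.BlobSpec(sigma=6.0, radius=48.0, amplitude=2.0, occupancy=0.5),
        p4=ic.BlobSpec(sigma=6.0, radius=72.0, amplitude=1.0, occupancy=1.0),
        p7=ic.BlobSpec(sigma=6.0, radius=51.0, amplitude=1.6, occupancy=0.57),
        central_diffuse_sigma=20.0, noise_sigma=0.1, seed=11)


@pytest.fixture(scope="session")
def default_triple():
    """Default-spec mutant triple plus its ground truth (seed fixed)."""
    spec = ic.PhantomSpec(seed=5)
    maps, truth = ic.generate_mutant_triple(spec)
    return spec, maps, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def normalize_triple(spec, maps):
    """Filter + threshold + standardize a phantom triple (shared helper)."""
    filtered = {k: ic.low_pass_filter(m, 16.0) for k, m in maps.items()}
    target = ic.shell_volume_fwhm(spec)
    p1 = {k: ic.p1_shell_mask(m, ic.threshold_for_volume(m, target).threshold)
          for k, m in filtered.items()}
    any_map = next(iter(filtered.values()))
    edge = any_map.n * any_map.voxel_size
    bg = ic.background_annulus_mask(any_map, 0.40 * edge, 0.47 * edge)
    return ic.normalize_set(filtered, p1, bg)
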