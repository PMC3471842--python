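"""Volume budget, volume-matched thresholds, masks, and joint scaling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import icodiff as ic
from icodiff.density_map import radial_average
from icodiff.normalization import p1_radial_profiles

from conftest import normalize_triple


class TestExpectedVolume:
    def test_shell_protein_budget(self):
        # 84 kDa x 120 copies at 1.41 g/cm^3 -> ~1.187e4 nm^3
        v = ic.expected_protein_volume(84.0, 120, 1.41)
        assert v == pytest.approx(1.187e4, rel=1e-3)

    def test_linear_in_copies(self):
        assert ic.expected_protein_volume(84, 240, 1.41) == pytest.approx(
            2 * ic.expected_protein_volume(84, 120, 1.41))

    @pytest.mark.parametrize("args", [(0, 120, 1.41), (84, 0, 1.41), (84, 120, 0)])
    def test_rejects_non_positive(self, args):
        with pytest.raises(ValueError):
            ic.expected_protein_volume(*args)

    def test_volume_budget_dataclass(self):
        b = ic.VolumeBudget(84.0, 120, 1.41)
        assert b.expected_volume == pytest.approx(1.187e4, rel=1e-3)


class TestThresholdForVolume:
    def test_two_level_map_exact(self):
        data = np.zeros((16,) * 3)
        data[:4, :4, :4] = 1.0  # 64 voxels high
        m = ic.Map3D(data, 10.0)  # voxel volume 1000 A^3 = 1 nm^3
        res = ic.threshold_for_volume(m, 64.0)
        assert 0 < res.threshold <= 1.0
        assert res.achieved_volume == pytest.approx(64.0 * 1e3)

    def test_half_grid_target_hits_median(self, rng):
        m = ic.Map3D(rng.normal(size=(32,) * 3), 10.0)
        total_nm3 = 32**3 * 1.0
        res = ic.threshold_for_volume(m, total_nm3 / 2)
        med = np.median(m.data)
        step = np.diff(np.sort(m.data.ravel())).max()
        assert abs(res.threshold - med) <= 2 * step + 1e-12

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_matches_sort_and_index_oracle(self, seed):
        """Exact agreement with brute-force descending sort indexing."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 33))
        m = ic.Map3D(rng.normal(size=(n,) * 3), 4.0)
        vv_nm3 = m.voxel_volume / 1e3
        k = int(rng.integers(1, n**3))
        res = ic.threshold_for_volume(m, k * vv_nm3)
        oracle = np.sort(m.data.ravel())[::-1][k - 1]
        assert res.threshold == oracle
        assert int(np.count_nonzero(m.data >= res.threshold)) == k

    def test_monotone_in_target(self, rng):
        m = ic.Map3D(rng.normal(size=(16,) * 3), 4.0)
        vv_nm3 = m.voxel_volume / 1e3
        targets = [100 * vv_nm3, 500 * vv_nm3, 2000 * vv_nm3]
        thr = [ic.threshold_for_volume(m, t).threshold for t in targets]
        assert thr[0] >= thr[1] >= thr[2]

    def test_target_exceeding_grid_raises(self):
        m = ic.Map3D(np.zeros((8,) * 3), 1.0)
        with pytest.raises(ValueError):
            ic.threshold_for_volume(m, 1e9)


class TestMasks:
    def test_two_level_shell_mask_selects_high_voxels(self):
        data = np.zeros((12,) * 3)
        data[2:5] = 1.0
        m = ic.Map3D(data, 2.0)
        mask = ic.p1_shell_mask(m, 0.5)
        assert np.array_equal(mask.data, data >= 0.5)

    def test_degenerate_radial_band_is_empty(self):
        m = ic.Map3D(np.ones((12,) * 3), 2.0)
        with pytest.warns(UserWarning):
            mask = ic.p1_shell_mask(m, 0.5, radial_band=(0.0, 0.0))
        assert mask.count == 0

    def test_phantom_shell_mask_volume_matches_analytic(self):
        import dataclasses
        spec = ic.PhantomSpec(noise_sigma=0.0, vertex_recess_depth=0.0,
                              central_diffuse_amplitude=0.0)
        spec = dataclasses.replace(
            spec, p2=dataclasses.replace(spec.p2, occupancy=0.0),
            p4=dataclasses.replace(spec.p4, occupancy=0.0),
            p7=dataclasses.replace(spec.p7, occupancy=0.0))
        m, _ = ic.generate_procapsid(spec)
        target = ic.shell_volume_fwhm(spec)
        res = ic.threshold_for_volume(m, target)
        mask = ic.p1_shell_mask(m, res.threshold)
        assert mask.volume / 1e3 == pytest.approx(target, rel=0.05)
        # FWHM budget on a Gaussian shell puts the threshold at half max
        assert res.threshold == pytest.approx(0.5 * spec.shell_amplitude, abs=0.05)

    def test_annulus_volume_matches_analytic(self):
        m = ic.Map3D(np.zeros((48,) * 3), 2.9)
        r_in, r_out = 45.0, 65.0
        mask = ic.background_annulus_mask(m, r_in, r_out)
        analytic = 4.0 / 3.0 * np.pi * (r_out**3 - r_in**3)
        assert mask.count == pytest.approx(analytic / m.voxel_volume, rel=0.02)

    @pytest.mark.parametrize("r_in,r_out", [(50.0, 50.0), (60.0, 40.0),
                                            (0.0, 40.0), (10.0, 1e4)])
    def test_invalid_annulus_radii_raise(self, r_in, r_out):
        m = ic.Map3D(np.zeros((32,) * 3), 2.9)
        with pytest.raises(ValueError):
            ic.background_annulus_mask(m, r_in, r_out)

    def test_annulus_disjoint_from_interior_particle(self):
        m = ic.Map3D(np.zeros((48,) * 3), 2.9)
        particle = ic.spherical_mask(np.zeros(3), 40.0, m)
        annulus = ic.background_annulus_mask(m, 45.0, 65.0)
        assert not (particle.data & annulus.data).any()


class TestNormalizeSet:
    def _simple_setup(self, rng, n=24):
        data = rng.normal(size=(n,) * 3)
        m = ic.Map3D(data, 2.9)
        p1 = ic.Mask(m.radius_grid() < 15.0, 2.9)
        bg = ic.background_annulus_mask(m, 20.0, 30.0)
        return m, p1, bg

    def test_already_standardized_map_is_fixed_point(self, rng):
        m, p1, bg = self._simple_setup(rng)
        region = p1.data | bg.data
        vals = m.data[region]
        pre = ic.Map3D((m.data - vals.mean()) / vals.std(), 2.9)
        out = ic.normalize_set({"a": pre}, {"a": p1}, bg)
        assert out.scale_report["a"]["gain"] == pytest.approx(1.0, abs=1e-9)
        assert out.scale_report["a"]["offset"] == pytest.approx(0.0, abs=1e-9)

    def test_affine_inputs_normalize_identically(self, rng):
        m, p1, bg = self._simple_setup(rng)
        m2 = ic.Map3D(3.0 * m.data + 5.0, 2.9)
        out = ic.normalize_set({"a": m, "b": m2}, {"a": p1, "b": p1}, bg)
        assert np.abs(out["a"].data - out["b"].data).max() < 1e-9

    def test_postconditions_on_phantom_triple(self, default_triple):
        spec, maps, _ = default_triple
        norm = normalize_triple(spec, maps)
        for name in maps:
            region = norm.union_region(name)
            vals = norm[name].data[region]
            assert abs(vals.mean()) < 1e-6
            assert abs(vals.std() - 1.0) < 1e-6

    def test_triple_shell_means_agree(self, default_triple):
        """The three phantoms share one shell, so scaled shell means match.

        Scaled and compared over the intersection of the three shell
        masks — the voxels every map agrees belong to the shell — since
        each map's own mask additionally catches its own protein blobs.
        """
        spec, maps, _ = default_triple
        filtered = {k: ic.low_pass_filter(m, 16.0) for k, m in maps.items()}
        target = ic.shell_volume_fwhm(spec)
        p1 = {k: ic.p1_shell_mask(m, ic.threshold_for_volume(m, target).threshold)
              for k, m in filtered.items()}
        edge = filtered["P1247"].n * filtered["P1247"].voxel_size
        bg = ic.background_annulus_mask(filtered["P1247"], 0.40 * edge,
                                        0.47 * edge)
        norm = ic.normalize_set(filtered, p1, bg, union_mode="intersection")
        shared = np.logical_and.reduce([p1[n].data for n in maps])
        means = [norm[name].data[shared].mean() for name in maps]
        spread = (max(means) - min(means)) / abs(np.mean(means))
        assert spread < 0.02

    def test_zero_variance_region_raises(self):
        m = ic.Map3D(np.zeros((16,) * 3), 2.9)
        p1 = ic.Mask(m.radius_grid() < 10.0, 2.9)
        bg = ic.background_annulus_mask(m, 12.0, 20.0)
        with pytest.raises(ValueError):
            ic.normalize_set({"a": m}, {"a": p1}, bg)

    def test_full_pipeline_affine_invariance(self, small_spec):
        """Threshold + normalize is invariant to per-input affine rescaling."""
        maps, _ = ic.generate_mutant_triple(small_spec)
        gains = {"P1247": 2.0, "P124": 0.5, "P147": 7.0}
        offsets = {"P1247": -1.0, "P124": 3.0, "P147": 0.2}
        warped = {k: ic.Map3D(gains[k] * m.data + offsets[k], m.voxel_size)
                  for k, m in maps.items()}
        norm_a = normalize_triple(small_spec, maps)
        norm_b = normalize_triple(small_spec, warped)
        for k in maps:
            assert np.abs(norm_a[k].data - norm_b[k].data).max() < 1e-6


class TestRadialScale:
    def test_identical_profiles_leave_map_unchanged(self, rng):
        m = ic.Map3D(rng.normal(size=(24,) * 3), 2.9)
        prof = radial_average(m)
        out = ic.radial_scale(m, prof, prof)
        assert np.abs(out.data - m.data).max() < 1e-9

    def test_recovers_reference_profile_after_shellwise_scaling(self, rng):
        m = ic.Map3D(rng.normal(size=(24,) * 3) + 5.0, 2.9)
        prof = radial_average(m)
        # warp per shell by a known factor g(r), using the same binning
        r_vox = m.radius_grid() / m.voxel_size
        idx = np.floor(r_vox).astype(int)
        g = 1.0 + 0.05 * np.arange(len(prof.means))
        warped = ic.Map3D(m.data * g[idx], 2.9)
        out = ic.radial_scale(warped, prof, radial_average(warped))
        prof_out = radial_average(out)
        defined = ~np.isnan(prof.means)
        assert np.abs(prof_out.means[defined] - prof.means[defined]).max() < 1e-6

    def test_shell_grid_mismatch_raises(self, rng):
        m = ic.Map3D(rng.normal(size=(24,) * 3), 2.9)
        p1 = radial_average(m, shell_width=1.0)
        p2 = radial_average(m, shell_width=2.0)
        with pytest.raises(ValueError):
            ic.radial_scale(m, p1, p2)

    def test_radial_scaling_does_not_move_detected_sites(self, default_triple):
        """Difference maps change negligibly with or without radial factors."""
        spec, maps, truth = default_triple
        norm = normalize_triple(spec, maps)
        profiles = p1_radial_profiles(norm.maps, norm.p1_masks)
        rescaled = {k: ic.radial_scale(norm[k], profiles["P1247"], profiles[k])
                    for k in norm.maps}
        d_plain = ic.subtract(norm["P1247"], norm["P147"])
        d_scaled = ic.subtract(rescaled["P1247"], rescaled["P147"])
        bg_sigma = d_plain.data.data[norm.background_mask.data].std()
        c = d_plain.data.center_index
        vs = d_plain.data.voxel_size
        idx = np.rint(truth.positions("p2") / vs + c).astype(int)
        delta = np.abs(d_plain.data.data[idx[:, 0], idx[:, 1], idx[:, 2]]
                       - d_scaled.data.data[idx[:, 0], idx[:, 1], idx[:, 2]])
        assert delta.max() < bg_sigma
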