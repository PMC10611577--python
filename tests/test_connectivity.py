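"""Denoising chain, seeds, connectivity maps, and group inference."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from mbnf import connectivity as conn
from mbnf import synth
from mbnf.config import SeedSpec
from mbnf.connectivity import ConnectivityMap
from mbnf.errors import DegenerateDataError, ShapeMismatchError
from mbnf.images import VolumeSeries

AFFINE_2MM = np.diag([2.0, 2.0, 2.0, 1.0])


def _flat_confounds(T):
    return conn.ConfoundSet(
        motion_params=np.zeros((T, 6)),
        fd=np.zeros(T),
        global_signal_z=np.zeros(T),
        outlier_flags=np.zeros(T, dtype=bool),
    )


class TestFramewiseDisplacement:
    def test_constant_parameters_give_zero(self):
        assert conn.framewise_displacement(np.ones((10, 6)) * 3).max() == 0.0

    def test_translation_jump_arithmetic(self):
        p = np.zeros((5, 6))
        p[2, 0], p[2, 1] = 0.3, 0.4
        fd = conn.framewise_displacement(p)
        assert fd[0] == 0.0
        assert fd[2] == pytest.approx(0.7)
        assert fd[3] == pytest.approx(0.7)  # the return to baseline also moves

    def test_rotation_converted_on_50mm_sphere(self):
        p = np.zeros((3, 6))
        p[1, 3] = 0.01  # radians
        assert conn.framewise_displacement(p)[1] == pytest.approx(0.5)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=hst.integers(0, 10_000))
    def test_axis_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.standard_normal((20, 6)) * 0.1
        perm = p[:, [2, 0, 1, 5, 3, 4]]  # permute within translations/rotations
        np.testing.assert_allclose(
            conn.framewise_displacement(p), conn.framewise_displacement(perm)
        )

    def test_wrong_column_count_rejected(self):
        with pytest.raises(ShapeMismatchError):
            conn.framewise_displacement(np.zeros((10, 5)))


class TestOutlierFlags:
    def _spiky_series(self):
        maps = synth.make_network_maps((10, 10, 8), 2, 2, seed=0)
        series, _ = synth.simulate_run(maps, noise_sd=1.0, n_vols=100, seed=0)
        motion, spikes = synth.simulate_motion(100, spike_prob=0.08,
                                               spike_scale=2.0, seed=5)
        return series, motion, spikes

    def test_clean_run_has_no_flags(self):
        maps = synth.make_network_maps((10, 10, 8), 2, 2, seed=0)
        series, _ = synth.simulate_run(maps, noise_sd=1.0, n_vols=100, seed=0)
        motion, _ = synth.simulate_motion(100, spike_prob=0.0, seed=1)
        fd = conn.framewise_displacement(motion)
        flags, _ = conn.flag_outliers(series, fd)
        assert flags.sum() == 0

    def test_planted_spike_flagged_under_both_presets(self):
        series, motion, spikes = self._spiky_series()
        fd = conn.framewise_displacement(motion)
        lenient, _ = conn.flag_outliers(series, fd, gs_thresh=5, fd_thresh=0.9)
        strict, _ = conn.flag_outliers(series, fd, gs_thresh=3, fd_thresh=0.5)
        assert len(spikes) > 0
        for i in spikes:
            assert lenient[i] and strict[i]

    def test_intermediate_frame_only_flagged_by_stringent_preset(self):
        series, motion, _ = self._spiky_series()
        fd = conn.framewise_displacement(motion)
        # a frame with FD 0.6: above 0.5, below 0.9
        fd2 = fd.copy()
        fd2[50] = 0.6
        lenient, _ = conn.flag_outliers(series, fd2, gs_thresh=5, fd_thresh=0.9)
        strict, _ = conn.flag_outliers(series, fd2, gs_thresh=3, fd_thresh=0.5)
        assert not lenient[50] and strict[50]


class TestCompCor:
    def test_shared_latents_recovered_and_orthonormal(self, rng):
        T, grid = 200, (6, 6, 4)
        lat = rng.standard_normal((T, 2))
        W = rng.standard_normal((2, 144))
        data = (lat @ W).T.reshape(grid + (T,)) + 0.01 * rng.standard_normal(grid + (T,))
        cc = conn.compcor_components(VolumeSeries(data, tr=1.2), np.ones(grid, bool), 2)
        assert np.abs(cc.T @ cc - np.eye(2)).max() < 1e-10
        q1, _ = np.linalg.qr(cc)
        design = np.column_stack([np.ones(T), np.arange(T)])
        latd = lat - design @ np.linalg.lstsq(design, lat, rcond=None)[0]
        q2, _ = np.linalg.qr(latd)
        canon = np.linalg.svd(q1.T @ q2, compute_uv=False)
        assert canon.min() > 0.99

    def test_mask_too_small_rejected(self):
        series = VolumeSeries(np.random.default_rng(0).random((4, 4, 2, 30)), tr=1.2)
        tiny = np.zeros((4, 4, 2), bool)
        tiny[0, 0, 0] = True
        with pytest.raises(ValueError):
            conn.compcor_components(series, tiny, n_components=5)


class TestDenoise:
    TR = 1.2

    def test_confounds_removed_target_preserved(self, rng):
        T, grid = 250, (5, 5, 3)
        t = np.arange(T)
        motion, _ = synth.simulate_motion(T, seed=1)
        fd = conn.framewise_displacement(motion)
        cs = conn.ConfoundSet(motion, fd, np.zeros(T), np.zeros(T, dtype=bool))
        # band-limited target orthogonal to the filtered confound design
        raw = np.sin(2 * np.pi * 0.03 * self.TR * t) + 0.5 * np.sin(2 * np.pi * 0.05 * self.TR * t + 1)
        Xf = conn.bandpass_projection(cs.design_matrix(), (0.008, 0.09), self.TR)
        target = conn.bandpass_projection(raw[:, None], (0.008, 0.09), self.TR)[:, 0]
        target -= Xf @ np.linalg.lstsq(Xf, target, rcond=None)[0]
        conf_mix = motion @ rng.standard_normal(6)
        data = np.zeros(grid + (T,))
        data += (target + 2 * conf_mix + 3.0 + 0.01 * t)[None, None, None, :]
        data += 0.05 * rng.standard_normal(grid + (T,))
        out = conn.denoise(VolumeSeries(data, tr=self.TR), cs)
        r = np.corrcoef(out.data[2, 2, 1], target)[0, 1]
        assert r > 0.95

    def test_constant_series_maps_to_zero(self):
        T = 100
        series = VolumeSeries(np.full((4, 4, 2, T), 7.0), tr=self.TR)
        out = conn.denoise(series, _flat_confounds(T))
        assert np.abs(out.data).max() < 1e-10

    def test_out_of_band_sinusoid_attenuated(self):
        T = 250
        t = np.arange(T)
        s = np.sin(2 * np.pi * 0.2 * self.TR * t)  # 0.2 Hz, above the band
        series = VolumeSeries(np.tile(s, (4, 4, 2, 1)), tr=self.TR)
        out = conn.denoise(series, _flat_confounds(T))
        assert (out.data[0, 0, 0] ** 2).sum() < 0.1 * (s**2).sum()

    def test_idempotent(self, rng):
        T = 200
        data = rng.standard_normal((4, 4, 2, T))
        motion, _ = synth.simulate_motion(T, spike_prob=0.02, seed=4)
        fd = conn.framewise_displacement(motion)
        flags = fd > 0.9
        cs = conn.ConfoundSet(motion, fd, np.zeros(T), flags)
        d1 = conn.denoise(VolumeSeries(data, tr=self.TR), cs)
        d2 = conn.denoise(d1, cs)
        rel = np.linalg.norm(d2.data - d1.data) / np.linalg.norm(d1.data)
        assert rel < 1e-6

    def test_confound_row_mismatch_rejected(self):
        series = VolumeSeries(np.zeros((4, 4, 2, 50)), tr=self.TR)
        with pytest.raises(ShapeMismatchError):
            conn.denoise(series, _flat_confounds(40))


class TestSphereSeed:
    def test_8mm_sphere_on_2mm_grid_has_257_voxels(self):
        # brute-force lattice count of {v : |2v - c| <= 8} with c on a center
        spec = SeedSpec("s", (20.0, 20.0, 10.0), 8.0)
        mask = conn.make_sphere_seed(spec, AFFINE_2MM, (21, 21, 11))
        assert mask.sum() == 257

    def test_tiny_radius_selects_single_voxel(self):
        spec = SeedSpec("s", (20.0, 20.0, 10.0), 0.5)
        mask = conn.make_sphere_seed(spec, AFFINE_2MM, (21, 21, 11))
        assert mask.sum() == 1

    def test_translation_by_whole_voxel_preserves_cardinality(self):
        a = conn.make_sphere_seed(SeedSpec("s", (20.0, 20.0, 10.0), 8.0),
                                  AFFINE_2MM, (25, 25, 15))
        b = conn.make_sphere_seed(SeedSpec("s", (22.0, 20.0, 10.0), 8.0),
                                  AFFINE_2MM, (25, 25, 15))
        assert a.sum() == b.sum()

    def test_sphere_outside_grid_rejected(self):
        with pytest.raises(ValueError):
            conn.make_sphere_seed(SeedSpec("s", (500.0, 0.0, 0.0), 8.0),
                                  AFFINE_2MM, (10, 10, 10))


class TestSeedConnectivity:
    def test_voxel_identical_to_seed_capped_and_flagged(self, rng):
        T, grid = 60, (4, 4, 2)
        data = rng.standard_normal(grid + (T,))
        seed = np.zeros(grid, bool)
        seed[0, 0, 0] = True
        data[1, 1, 1] = data[0, 0, 0]  # exact copy of the 1-voxel seed mean
        cm = conn.seed_connectivity(VolumeSeries(data, tr=1.2), seed)
        assert np.isfinite(cm.fisher_z_field).all()
        assert cm.degenerate[1, 1, 1]
        assert cm.fisher_z_field[1, 1, 1] > 5  # atanh near the cap

    def test_known_attenuation_with_added_noise(self, rng):
        T, grid = 5000, (4, 4, 2)
        base = rng.standard_normal(T)
        data = 0.001 * rng.standard_normal(grid + (T,))
        seed = np.zeros(grid, bool)
        seed[0, 0, 0] = True
        data[0, 0, 0] = base
        data[2, 2, 1] = base + rng.standard_normal(T)  # expected r = 1/sqrt(2)
        cm = conn.seed_connectivity(VolumeSeries(data, tr=1.2), seed)
        assert cm.fisher_z_field[2, 2, 1] == pytest.approx(np.arctanh(1 / np.sqrt(2)), abs=0.05)

    def test_planted_network_in_network_z_exceeds_background(self, planted_maps):
        series, _ = synth.simulate_run(planted_maps, within_network_r=0.5,
                                       n_vols=250, seed=3)
        support = synth.top_fraction_mask(planted_maps[0], 0.5)
        seed = np.zeros(series.grid_shape, bool)
        # seed at the peak-loading voxel, as a seed region would be placed
        seed[np.unravel_index(np.argmax(planted_maps[0]), series.grid_shape)] = True
        cm = conn.seed_connectivity(series, seed)
        out = ~support & ~synth.top_fraction_mask(planted_maps[1], 0.5)
        assert cm.fisher_z_field[support].mean() > cm.fisher_z_field[out].mean() + 0.2

    def test_zero_variance_voxel_flagged_zero(self, rng):
        T, grid = 50, (4, 4, 2)
        data = rng.standard_normal(grid + (T,))
        data[3, 3, 1] = 0.0
        seed = np.zeros(grid, bool)
        seed[0, 0, 0] = True
        cm = conn.seed_connectivity(VolumeSeries(data, tr=1.2), seed)
        assert cm.fisher_z_field[3, 3, 1] == 0.0
        assert cm.degenerate[3, 3, 1]

    def test_too_few_volumes_rejected(self, rng):
        data = rng.standard_normal((4, 4, 2, 5))
        seed = np.ones((4, 4, 2), bool)
        with pytest.raises(ValueError):
            conn.seed_connectivity(VolumeSeries(data, tr=1.2), seed)


def _change_maps(grid, region, delta, n, seed, noise_sd=0.1):
    """Per-subject pre/post Fisher-z map pairs with a planted regional change."""
    pre_maps, post_maps = [], []
    sm = np.zeros(grid, bool)
    sm[0, 0, 0] = True
    for s in range(n):
        r = np.random.default_rng(seed + s)
        pre = noise_sd * r.standard_normal(grid)
        post = pre + delta * region + noise_sd * r.standard_normal(grid)
        pre_maps.append(ConnectivityMap(pre, sm, 250))
        post_maps.append(ConnectivityMap(post, sm, 250))
    return pre_maps, post_maps


class TestPrepostChange:
    GRID = (8, 8, 6)

    @pytest.fixture()
    def region(self):
        region = np.zeros(self.GRID, bool)
        region[2:6, 2:6, 2:4] = True
        return region

    def test_planted_reduction_survives_fdr(self, region, rng):
        pre, post = _change_maps(self.GRID, region, -0.3, 9, seed=0)
        res = conn.prepost_change(pre, post, region,
                                  covariate=rng.standard_normal(9), q=0.05)
        assert res.surviving.any()
        assert res.stat_map[res.surviving].mean() < 0
        assert res.clusters[0]["size"] > 0

    def test_single_voxel_mask_reduces_to_paired_t(self, rng):
        grid = (4, 4, 2)
        region = np.zeros(grid, bool)
        region[1, 1, 1] = True
        pre, post = _change_maps(grid, region.astype(float), -0.3, 9, seed=3)
        res = conn.prepost_change(pre, post, region, q=0.05)
        delta = np.array([po.fisher_z_field[1, 1, 1] - pr.fisher_z_field[1, 1, 1]
                          for pr, po in zip(pre, post)])
        from mbnf.stats import one_sample_t

        ref = one_sample_t(delta, 0.0, "two-sided")
        assert res.stat_map[1, 1, 1] == pytest.approx(ref.t)
        assert res.p_map[1, 1, 1] == pytest.approx(ref.p)
        # with m = 1, BH at q is the raw-p decision
        assert bool(res.surviving[1, 1, 1]) == (ref.p < 0.05)

    def test_empty_region_rejected(self):
        pre, post = _change_maps(self.GRID, np.zeros(self.GRID), 0.0, 4, seed=1)
        with pytest.raises(ValueError):
            conn.prepost_change(pre, post, np.zeros(self.GRID, bool))


class TestBrainBehavior:
    GRID = (8, 8, 6)

    def test_score_readout_region_found(self):
        region = np.zeros(self.GRID, bool)
        region[2:5, 2:5, 2:4] = True
        rng = np.random.default_rng(0)
        maps, scores = [], []
        sm = np.zeros(self.GRID, bool)
        sm[0, 0, 0] = True
        for s in range(12):
            level = rng.standard_normal()
            field = 0.05 * rng.standard_normal(self.GRID) + level * region
            maps.append(ConnectivityMap(field, sm, 250))
            scores.append(2.0 * level + 0.1 * rng.standard_normal())
        res = conn.brain_behavior_map(maps, scores, covariate=rng.standard_normal(12))
        assert res.surviving[region].mean() > 0.5
        assert res.surviving[~region].mean() < 0.05

    def test_null_suprathreshold_fraction_calibrated(self):
        rng = np.random.default_rng(1)
        sm = np.zeros(self.GRID, bool)
        sm[0, 0, 0] = True
        frac = []
        for rep in range(60):
            maps = [ConnectivityMap(rng.standard_normal(self.GRID), sm, 250)
                    for _ in range(12)]
            res = conn.brain_behavior_map(maps, rng.standard_normal(12),
                                          p_thresh=0.01)
            frac.append(res.surviving.mean())
        assert np.mean(frac) == pytest.approx(0.01, abs=0.005)

    def test_three_subjects_rejected(self):
        sm = np.zeros(self.GRID, bool)
        sm[0, 0, 0] = True
        maps = [ConnectivityMap(np.zeros(self.GRID), sm, 250) for _ in range(3)]
        with pytest.raises(ValueError):
            conn.brain_behavior_map(maps, [1.0, 2.0, 3.0])

    def test_constant_scores_rejected(self):
        sm = np.zeros(self.GRID, bool)
        sm[0, 0, 0] = True
        maps = [ConnectivityMap(np.random.default_rng(s).random(self.GRID), sm, 250)
                for s in range(5)]
        with pytest.raises(DegenerateDataError):
            conn.brain_behavior_map(maps, [1.0] * 5)


class TestWithinNetwork:
    def test_independent_rois_average_near_zero(self, rng):
        grid, T = (6, 6, 4), 2000
        data = rng.standard_normal(grid + (T,))
        rois = []
        for k in range(4):
            m = np.zeros(grid, bool)
            m[k, :, :] = True
            rois.append(m)
        z = conn.within_network_connectivity(VolumeSeries(data, tr=1.2), rois)
        assert abs(z) < 0.05

    def test_identical_roi_series_capped(self):
        grid, T = (4, 4, 2), 50
        base = np.random.default_rng(0).standard_normal(T)
        data = np.zeros(grid + (T,))
        data[0, 0, 0] = base
        data[3, 3, 1] = base
        m1 = np.zeros(grid, bool); m1[0, 0, 0] = True
        m2 = np.zeros(grid, bool); m2[3, 3, 1] = True
        z = conn.within_network_connectivity(VolumeSeries(data, tr=1.2), [m1, m2])
        assert np.isfinite(z) and z > 5

    def test_fewer_than_two_rois_rejected(self):
        with pytest.raises(ValueError):
            conn.within_network_connectivity(
                VolumeSeries(np.zeros((4, 4, 2, 20)), tr=1.2),
                [np.ones((4, 4, 2), bool)],
            )
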