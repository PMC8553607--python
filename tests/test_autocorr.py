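"""Masked autocorrelation against a brute-force oracle, and the
spacing/size/self-similarity estimators on generator ground truth."""

import numpy as np
import pytest

from volgrid import synthetic
from volgrid.autocorr import (anisotropy_correct, autocorrelation,
                              central_crop, central_peak_radius,
                              grid_spacing, midline_profiles,
                              vertical_self_similarity)
from volgrid.containers import Autocorr3D, RateMap


def _mk_map(rate, visited=None, voxel=1.0):
    visited = np.ones_like(rate, dtype=bool) if visited is None else visited
    return RateMap(rate=rate, occupancy=visited.astype(float),
                   spikes=np.zeros_like(rate), voxel_size=voxel,
                   origin=np.zeros(rate.ndim), visited=visited)


def brute_force_autocorr(rate, visited, min_overlap=20):
    """Direct per-lag Pearson correlation over overlapping visited voxels."""
    shape = rate.shape
    out_shape = tuple(2 * s - 1 for s in shape)
    out = np.full(out_shape, np.nan)
    lags = np.stack(np.meshgrid(*[np.arange(-s + 1, s) for s in shape],
                                indexing="ij"), axis=-1)
    for idx in np.ndindex(out_shape):
        tau = lags[idx]
        sl1, sl2 = [], []
        for k, t in enumerate(tau):
            if t >= 0:
                sl1.append(slice(t, shape[k]))
                sl2.append(slice(0, shape[k] - t))
            else:
                sl1.append(slice(0, shape[k] + t))
                sl2.append(slice(-t, shape[k]))
        a = rate[tuple(sl1)]
        b = rate[tuple(sl2)]
        m = visited[tuple(sl1)] & visited[tuple(sl2)]
        if m.sum() < min_overlap:
            continue
        x, y = a[m], b[m]
        vx = len(x) * (x ** 2).sum() - x.sum() ** 2
        vy = len(y) * (y ** 2).sum() - y.sum() ** 2
        if vx <= 0 or vy <= 0:
            continue
        out[idx] = (len(x) * (x * y).sum() - x.sum() * y.sum()) / \
            np.sqrt(vx * vy)
    return out


class TestAutocorrelation:
    def test_matches_brute_force_oracle_on_random_maps(self):
        rng = np.random.default_rng(7)
        for trial in range(3):
            rate = rng.random((9, 9, 9))
            visited = rng.random((9, 9, 9)) > 0.15
            ac = autocorrelation(_mk_map(rate, visited))
            oracle = brute_force_autocorr(rate, visited)
            both = np.isfinite(ac.r) & np.isfinite(oracle)
            assert np.isnan(ac.r).sum() == np.isnan(oracle).sum()
            assert np.nanmax(np.abs(ac.r[both] - oracle[both])) < 1e-10

    def test_zero_lag_is_one_and_symmetric(self):
        rng = np.random.default_rng(1)
        ac = autocorrelation(_mk_map(rng.random((7, 7, 7))))
        assert ac.r[ac.center] == pytest.approx(1.0)
        flipped = ac.r[::-1, ::-1, ::-1]
        both = np.isfinite(ac.r) & np.isfinite(flipped)
        assert np.allclose(ac.r[both], flipped[both], atol=1e-10)

    def test_cosine_map_has_cosine_autocorrelation(self):
        L = 16
        x = np.arange(96)
        rate = np.cos(2 * np.pi * x / L)[:, None, None] * np.ones((1, 9, 9))
        ac = autocorrelation(_mk_map(rate))
        c = ac.center
        taus = np.arange(-10, 11)
        vals = ac.r[c[0] + taus, c[1], c[2]]
        # finite overlap windows hold non-integer period counts, so the
        # per-lag Pearson deviates slightly from the ideal cosine
        assert np.allclose(vals, np.cos(2 * np.pi * taus / L), atol=0.05)

    def test_constant_map_raises(self):
        with pytest.raises(ValueError):
            autocorrelation(_mk_map(np.ones((6, 6, 6))))

    def test_2d_maps_supported(self):
        rng = np.random.default_rng(3)
        ac = autocorrelation(_mk_map(rng.random((12, 12))))
        assert ac.r.shape == (23, 23)
        assert ac.r[ac.center] == pytest.approx(1.0)


class TestCentralPeak:
    def test_spherical_region_radius(self):
        shape = (21, 21, 21)
        c = (np.asarray(shape) - 1) / 2
        g = np.stack(np.meshgrid(*[np.arange(s) for s in shape],
                                 indexing="ij"), axis=-1)
        dist = np.linalg.norm(g - c, axis=-1)
        r = np.where(dist <= 5.0, 1.0, 0.0)
        ac = Autocorr3D(r=r, n_overlap=np.full(shape, 100), voxel_size=2.0)
        vol = (dist <= 5.0).sum()
        expected = (3 * vol / (4 * np.pi)) ** (1 / 3) * 2.0
        assert central_peak_radius(ac) == pytest.approx(expected)
        assert expected == pytest.approx(5.0 * 2.0, rel=0.05)

    def test_radius_grows_with_field_width(self):
        radii = []
        for sigma in (1.5, 3.0):
            spec = synthetic.ArrangementSpec("FCC", S=400.0, sigma=sigma,
                                             seed=2)
            rm = synthetic.arrangement_ratemap(
                synthetic.make_arrangement(spec), spec)
            radii.append(central_peak_radius(autocorrelation(rm)))
        assert radii[1] > radii[0]

    def test_radius_insensitive_to_arrangement_kind(self):
        vals = []
        for kind in ("HCP", "FCC", "RND"):
            spec = synthetic.ArrangementSpec(kind, S=400.0, sigma=2.0, seed=4)
            rm = synthetic.arrangement_ratemap(
                synthetic.make_arrangement(spec), spec)
            vals.append(central_peak_radius(autocorrelation(rm)))
        assert np.ptp(vals) / np.mean(vals) < 0.2


class TestAnisotropyCorrect:
    def test_isotropic_input_unchanged(self, fcc_ratemap):
        ac = central_crop(autocorrelation(fcc_ratemap[0]), 20)
        out = anisotropy_correct(ac)
        both = np.isfinite(ac.r) & np.isfinite(out.r)
        assert np.corrcoef(ac.r[both], out.r[both])[0, 1] > 0.98

    def test_stretched_volume_is_restored(self, fcc_ratemap):
        from scipy import ndimage as ndi
        ac = central_crop(autocorrelation(fcc_ratemap[0]), 20)
        stretched = ndi.zoom(np.nan_to_num(ac.r), (1, 1, 1.5), order=1)
        s = stretched.shape
        ac2 = Autocorr3D(r=stretched[:, :, (s[2] - 41) // 2:(s[2] - 41) // 2 + 41],
                         n_overlap=np.full((41, 41, 41), 100), voxel_size=1.0)
        out = anisotropy_correct(ac2)
        from volgrid.autocorr import central_peak_region
        reg = central_peak_region(out)
        idx = np.argwhere(reg)
        ext = idx.max(axis=0) - idx.min(axis=0) + 1
        assert ext.max() / ext.min() < 1.4

    def test_idempotent_within_tolerance(self, fcc_ratemap):
        ac = central_crop(autocorrelation(fcc_ratemap[0]), 20)
        once = anisotropy_correct(ac)
        twice = anisotropy_correct(once)
        both = np.isfinite(once.r) & np.isfinite(twice.r)
        assert np.corrcoef(once.r[both], twice.r[both])[0, 1] > 0.95


class TestGridSpacing:
    @pytest.mark.parametrize("kind", ["FCC", "HCP"])
    def test_recovers_generator_spacing(self, kind):
        spec = synthetic.ArrangementSpec(kind, S=400.0, sigma=2.0, seed=5)
        rm = synthetic.arrangement_ratemap(synthetic.make_arrangement(spec),
                                           spec)
        est = grid_spacing(autocorrelation(rm))
        assert est.d is not None
        assert abs(est.d * 10.0 - 400.0) / 400.0 < 0.10

    def test_rotation_leaves_estimate_within_one_shell(self):
        base = synthetic.ArrangementSpec("FCC", S=400.0, sigma=2.0, seed=6)
        rot = synthetic.ArrangementSpec(
            "FCC", S=400.0, sigma=2.0, seed=6,
            rotation=(np.array([0.3, 0.5, 0.81]), 30.0))
        ds = []
        for spec in (base, rot):
            rm = synthetic.arrangement_ratemap(
                synthetic.make_arrangement(spec), spec)
            ds.append(grid_spacing(autocorrelation(rm)).d)
        voxel = 2.425 * 400.0 / 41 / 10
        assert abs(ds[0] - ds[1]) <= 1.5 * voxel

    def test_single_blob_yields_undefined_spacing(self):
        shape = (31, 31, 31)
        c = (np.asarray(shape) - 1) / 2
        g = np.stack(np.meshgrid(*[np.arange(s) for s in shape],
                                 indexing="ij"), axis=-1)
        rate = np.exp(-0.5 * (np.linalg.norm(g - c, axis=-1) / 3) ** 2)
        est = grid_spacing(autocorrelation(_mk_map(rate)))
        assert est.d is None


class TestSelfSimilarity:
    def test_columnar_midline_and_shift_profile(self):
        spec = synthetic.ArrangementSpec("COL", S=400.0, sigma=2.0, seed=7)
        rm = synthetic.arrangement_ratemap(synthetic.make_arrangement(spec),
                                           spec)
        ac = autocorrelation(rm)
        prof = midline_profiles(ac)
        zc = prof["z"][np.isfinite(prof["z"])]
        assert np.min(zc) > 0.8
        xc = prof["x"]
        c = ac.center[0]
        assert xc[c] == pytest.approx(1.0)
        assert np.nanmin(xc) < 0.5
        sim = vertical_self_similarity(rm, d=40.0)
        assert np.nanmin(sim["correlation"][:20]) > 0.9

    def test_profiles_peak_at_one_in_center_and_are_symmetric(self,
                                                              fcc_ratemap):
        ac = autocorrelation(fcc_ratemap[0])
        prof = midline_profiles(ac)
        for p in prof.values():
            c = (len(p) - 1) // 2
            assert p[c] == pytest.approx(1.0)
            both = np.isfinite(p) & np.isfinite(p[::-1])
            assert np.allclose(p[both], p[::-1][both], atol=1e-6)

    def test_hcp_layer_period_at_two_x_0816_d(self):
        spec = synthetic.ArrangementSpec("HCP", S=400.0, sigma=2.0, seed=8)
        rm = synthetic.arrangement_ratemap(synthetic.make_arrangement(spec),
                                           spec)
        d_cm = 40.0
        sim = vertical_self_similarity(rm, d=d_cm)
        # identical layers recur at 2 x (sqrt6/3) = 1.633 in units of d
        target = 2 * np.sqrt(6) / 3
        peaks = sim["peak_shifts_over_d"]
        assert len(peaks) > 0
        assert np.min(np.abs(peaks - target)) < 0.15

    def test_zero_shift_correlation_is_one(self, fcc_ratemap):
        sim = vertical_self_similarity(fcc_ratemap[0], d=40.0)
        assert sim["correlation"][0] == pytest.approx(1.0)

    def test_undefined_spacing_raises(self, fcc_ratemap):
        with pytest.raises(ValueError):
            vertical_self_similarity(fcc_ratemap[0], d=None)
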