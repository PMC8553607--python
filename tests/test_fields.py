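"""Field detection, shape statistics and field-level null models."""

import numpy as np
import pytest

from volgrid import synthetic
from volgrid.containers import RateMap, SpikeTrain
from volgrid.fields import (detect_fields, elongation_index,
                            elongation_shuffle, equivalent_diameter,
                            field_axes, field_shuffle, field_size_cv,
                            fields_per_m3, interfield_cv,
                            layer_distribution_test, orientation_axis_test,
                            vmf_density, _nn3_cv)
from volgrid.ratemaps import adaptive_ratemap


def _blob_map(centers, sigmas, peaks, shape=(39, 39, 39), voxel=2.5):
    ax = [(np.arange(s) + 0.5) * voxel for s in shape]
    gx, gy, gz = np.meshgrid(*ax, indexing="ij")
    pts = np.stack([gx, gy, gz], axis=-1)
    rate = np.zeros(shape)
    for c, s, p in zip(centers, sigmas, peaks):
        rate += p * np.exp(-0.5 * np.sum((pts - c) ** 2, axis=-1) / s ** 2)
    return RateMap(rate=rate, occupancy=np.ones(shape),
                   spikes=np.zeros(shape), voxel_size=voxel,
                   origin=np.zeros(3), visited=np.ones(shape, dtype=bool))


class TestDetectFields:
    def test_single_blob_gives_one_field(self):
        m = _blob_map([[40.0, 50.0, 45.0]], [8.0], [5.0])
        fs = detect_fields(m, traj=None, min_visits=0)
        assert len(fs) == 1
        assert np.linalg.norm(fs[0].centroid - [40.0, 50.0, 45.0]) < 4.0

    def test_subhertz_second_blob_excluded(self):
        m = _blob_map([[30.0, 30.0, 30.0], [70.0, 70.0, 70.0]],
                      [8.0, 8.0], [5.0, 0.5])
        fs = detect_fields(m, traj=None, min_visits=0)
        assert len(fs) == 1

    def test_empty_map_gives_no_fields(self):
        m = _blob_map([[40.0, 40.0, 40.0]], [8.0], [0.0])
        assert len(detect_fields(m, traj=None)) == 0

    def test_visit_criterion_filters(self, volume_session):
        traj, spikes, _, centers = volume_session
        m = adaptive_ratemap(traj, spikes, voxel=2.5,
                             bounds=(np.zeros(3), np.full(3, 97.0)))
        with_visits = detect_fields(m, traj=traj)
        assert 1 <= len(with_visits) <= 4
        impossible = detect_fields(m, traj=traj, min_visits=10 ** 6)
        assert len(impossible) == 0

    def test_recovers_generator_field_count(self):
        spec = synthetic.ArrangementSpec("HCP", S=500.0, sigma=2.0, seed=3)
        lat = synthetic.make_arrangement(spec)
        rm = synthetic.arrangement_ratemap(lat, spec)
        rm2 = RateMap(rate=rm.rate * 5.0, occupancy=rm.occupancy,
                      spikes=rm.spikes, voxel_size=rm.voxel_size,
                      origin=rm.origin, visited=rm.visited)
        fs = detect_fields(rm2, traj=None, min_voxels=8, min_visits=0)
        assert abs(len(fs) - lat.n) <= 1


class TestFieldShape:
    def test_sphere_axes_nearly_equal(self):
        g = np.stack(np.meshgrid(*[np.arange(21)] * 3, indexing="ij"), axis=-1)
        vox = np.argwhere(np.linalg.norm(g[..., :] - 10.0, axis=-1)[..., None]
                          .squeeze(-1) <= 7.0)
        p, vecs = field_axes(vox, voxel_size=1.0)
        assert p[0] / p[2] < 1.05
        assert np.allclose(vecs.T @ vecs, np.eye(3), atol=1e-8)

    def test_two_to_one_ellipsoid_axis_ratio(self):
        g = np.stack(np.meshgrid(*[np.arange(41)] * 3, indexing="ij"), axis=-1)
        d = ((g[..., 0] - 20) / 14.0) ** 2 + ((g[..., 1] - 20) / 7.0) ** 2 + \
            ((g[..., 2] - 20) / 7.0) ** 2
        vox = np.argwhere(d <= 1.0)
        p, _ = field_axes(vox, voxel_size=1.0)
        assert abs(p[0] / p[1] - 2.0) < 0.1

    def test_planar_field_raises(self):
        vox = np.array([[i, j, 5] for i in range(5) for j in range(5)])
        with pytest.raises(ValueError):
            field_axes(vox, 1.0)

    def test_elongation_examples(self):
        assert elongation_index([4.0, 2.0, 2.0]) == pytest.approx(2.0)
        assert elongation_index([3.0, 3.0, 3.0]) == pytest.approx(1.0)
        assert elongation_index([3.0, 3.0], dims=2) == pytest.approx(1.0)

    def test_equivalent_diameter_formula(self):
        assert equivalent_diameter(np.pi / 6.0) == pytest.approx(1.0)


@pytest.fixture(scope="module")
def spherical_setup(volume_session):
    traj = volume_session[0]
    m0 = _blob_map([[48.0, 48.0, 48.0]], [9.0], [8.0])
    spikes = synthetic.generate_spikes(m0, traj, gain_hz=1.5, seed=41)
    rm = adaptive_ratemap(traj, spikes, voxel=2.5,
                          bounds=(np.zeros(3), np.full(3, 97.0)))
    fs = detect_fields(rm, traj=traj)
    return traj, spikes, rm, fs


class TestElongationShuffle:

    def test_spherical_field_not_flagged(self, spherical_setup):
        traj, spikes, rm, fs = spherical_setup
        assert len(fs) >= 1
        res = elongation_shuffle(fs[0], traj, spikes, rm, n=40, seed=5)
        assert np.isfinite(res["z"])
        assert res["z"] < 3.5      # no gross false alarm on a sphere

    def test_elongated_field_flagged(self, volume_session):
        traj = volume_session[0]
        ax = [(np.arange(s) + 0.5) * 2.5 for s in (39, 39, 39)]
        gx, gy, gz = np.meshgrid(*ax, indexing="ij")
        d = ((gx - 48) / 24.0) ** 2 + ((gy - 48) / 7.0) ** 2 + \
            ((gz - 48) / 7.0) ** 2
        rate = 8.0 * np.exp(-0.5 * d)
        m0 = RateMap(rate=rate, occupancy=np.ones_like(rate),
                     spikes=np.zeros_like(rate), voxel_size=2.5,
                     origin=np.zeros(3), visited=np.ones_like(rate, bool))
        spikes = synthetic.generate_spikes(m0, traj, gain_hz=6.0, seed=43)
        rm = adaptive_ratemap(traj, spikes, voxel=2.5,
                              bounds=(np.zeros(3), np.full(3, 97.0)))
        fs = detect_fields(rm, traj=traj)
        assert len(fs) >= 1
        f = fs[int(np.argmax([x.volume for x in fs]))]
        res = elongation_shuffle(f, traj, spikes, rm, n=40, seed=6)
        assert res["z"] > 1.96 and res["nonspherical"]

    def test_no_infield_spikes_raises(self, spherical_setup):
        traj, _, rm, fs = spherical_setup
        empty = SpikeTrain(times=np.array([0.5]))
        with pytest.raises(ValueError):
            elongation_shuffle(fs[0], traj, empty, rm, n=5)


class TestOrientation:
    def _fieldset_from_vectors(self, vecs):
        from volgrid.fields import Field, FieldSet
        fs = FieldSet()
        for v in vecs:
            E = np.eye(3)
            E[:, 0] = v / np.linalg.norm(v)
            fs.fields.append(Field(voxels=np.zeros((5, 3)),
                                   centroid=np.zeros(3), volume=1.0,
                                   convex_volume=1.0, peak_rate=2.0,
                                   visits=9, principal_axes=np.ones(3),
                                   eigenvectors=E))
        return fs

    def test_uniform_axes_match_cap_chance(self):
        rng = np.random.default_rng(9)
        v = rng.normal(size=(400, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        res = orientation_axis_test(self._fieldset_from_vectors(v), seed=1)
        assert res["chance_fraction"] == pytest.approx(1 - np.cos(np.radians(30)))
        for name in "xyz":
            frac = res[name]["count"] / res["n_fields"]
            assert abs(frac - 0.134) < 0.05
            assert not res[name]["flagged"]

    def test_all_z_axes_flagged(self):
        v = np.tile([0.0, 0.0, 1.0], (30, 1))
        res = orientation_axis_test(self._fieldset_from_vectors(v), seed=2)
        assert res["z"]["count"] == 30
        assert res["z"]["flagged"]
        assert res["x"]["count"] == 0

    def test_vmf_density_maxima(self):
        res = vmf_density(np.array([[0.0, 0.0, 1.0]]))
        imax = np.unravel_index(np.argmax(res["density"]),
                                res["density"].shape)
        assert res["grid"][imax][2] > 0.99
        pair = vmf_density(np.array([[1.0, 0, 0], [-1.0, 0, 0]]))
        d = pair["density"]
        top = np.sort(d.ravel())[::-1]
        assert top[0] == pytest.approx(top[1], rel=0.05)


@pytest.fixture(scope="module")
def shuffled(volume_session):
    traj, spikes, _, _ = volume_session
    rm = adaptive_ratemap(traj, spikes, voxel=5.0,
                          bounds=(np.zeros(3), np.full(3, 97.0)))
    return rm, field_shuffle(rm, seed=3)


class TestFieldShuffle:

    def test_value_multiset_preserved_exactly(self, shuffled):
        rm, sh = shuffled
        assert np.array_equal(np.sort(rm.rate.ravel()),
                              np.sort(sh.rate.ravel()))

    def test_unvisited_bins_keep_positions(self, shuffled):
        rm, sh = shuffled
        unv = ~rm.visited
        assert np.array_equal(rm.rate[unv], sh.rate[unv])

    def test_peak_rate_preserved(self, shuffled):
        rm, sh = shuffled
        assert sh.rate.max() == rm.rate.max()

    def test_fields_actually_move(self, shuffled):
        rm, sh = shuffled
        assert not np.array_equal(rm.rate, sh.rate)


class TestDistributions:
    def test_nn3_cv_zero_for_close_packed_points(self):
        spec = synthetic.ArrangementSpec("HCP", S=400.0, sigma=2.0, seed=4)
        pts = synthetic.make_arrangement(spec).points / 10.0
        # interior points only: every close-packed neighbour is S away
        box = spec.extent / 10.0
        inner = pts[np.all((pts > 12.0) & (pts < box - 12.0), axis=1)]
        assert len(inner) >= 3
        assert _nn3_cv(inner) < 0.05

    def test_random_points_have_larger_cv(self):
        rng = np.random.default_rng(11)
        pts = rng.uniform(0, 97, size=(25, 3))
        spec = synthetic.ArrangementSpec("HCP", S=400.0, sigma=2.0, seed=4)
        hcp = synthetic.make_arrangement(spec).points / 10.0
        assert _nn3_cv(pts) > _nn3_cv(hcp)

    def test_interfield_cv_machinery(self, volume_session):
        traj, spikes, _, _ = volume_session
        res = interfield_cv(traj, spikes, voxel=4.0, smooth_sd=1.5,
                            n_shuffles=8, max_attempts=40, seed=5,
                            bounds=(np.zeros(3), np.full(3, 97.0)))
        assert res["n_fields"] >= 2
        assert res["cv"] is not None and res["cv"] >= 0

    def test_layer_distribution_chance_mean_one_sixth(self):
        from volgrid.fields import Field, FieldSet
        rng = np.random.default_rng(13)
        fs = FieldSet()
        for z in rng.uniform(0, 97, 60):
            fs.fields.append(Field(voxels=np.zeros((1, 3)),
                                   centroid=np.array([48.0, 48.0, z]),
                                   volume=1.0, convex_volume=1.0,
                                   peak_rate=2.0, visits=9))
        res = layer_distribution_test(fs, n_mc=400, seed=3)
        assert np.allclose(res["chance_mean"], 1.0 / 6.0, atol=0.01)
        assert not res["flagged"].any()

    def test_concentrated_layer_flagged(self):
        from volgrid.fields import Field, FieldSet
        fs = FieldSet()
        for _ in range(60):
            fs.fields.append(Field(voxels=np.zeros((1, 3)),
                                   centroid=np.array([48.0, 48.0, 5.0]),
                                   volume=1.0, convex_volume=1.0,
                                   peak_rate=2.0, visits=9))
        res = layer_distribution_test(fs, n_mc=400, seed=4)
        assert res["flagged"][0]
        assert res["proportions"][0] == pytest.approx(1.0)

    def test_fields_per_m3(self):
        from volgrid.fields import Field, FieldSet
        shape = (10, 10, 10)
        dwell = RateMap(rate=np.zeros(shape), occupancy=np.full(shape, 0.5),
                        spikes=np.zeros(shape), voxel_size=10.0,
                        origin=np.zeros(3), visited=np.ones(shape, bool),
                        occupancy_unit="seconds")
        fs = FieldSet(fields=[None] * 3)
        assert fields_per_m3(fs, dwell) == pytest.approx(3.0)
        # raising the dwell threshold cannot increase the volume
        dwell.occupancy[:5] = 0.05
        assert fields_per_m3(fs, dwell) >= 3.0

    def test_field_size_cv(self):
        res = field_size_cv({"a": [1.0, 2.0, 3.0], "b": [2.0, 2.0]},
                            n=20, seed=5)
        assert res["cv"]["a"] == pytest.approx(0.5)
        assert res["cv"]["b"] == pytest.approx(0.0)
        assert res["shuffled_cvs"].shape == (20, 2)
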