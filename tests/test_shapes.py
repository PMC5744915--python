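"""Landmark I/O and generalized Procrustes superimposition."""

import numpy as np
import pytest

from opershape.shapes import (AlignedShapes, LandmarkConfiguration,
                              LandmarkDataset, MalformedRecordError,
                              average_specimens, centroid_size, gpa,
                              procrustes_distance, read_tps, write_tps)
from opershape.synthetic_data import SimulationScenario, simulate_shape_dataset


def _rot(theta):
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


class TestTpsIO:
    def test_round_trip_preserves_coordinates(self, tmp_path, rng):
        coords = [rng.normal(size=(18, 2)) for _ in range(3)]
        configs = [
            LandmarkConfiguration(specimen_id=f"s{i}", taxon=f"s{i}", coords=c)
            for i, c in enumerate(coords)
        ]
        path = tmp_path / "shapes.tps"
        write_tps(LandmarkDataset(configs), path)
        back = read_tps(path)
        assert len(back) == 3
        for orig, rt in zip(coords, back):
            np.testing.assert_allclose(rt.coords, orig, rtol=0, atol=1e-12)

    def test_malformed_record_names_the_record(self, tmp_path):
        text = "LM=18\n" + "\n".join("0.0 0.0" for _ in range(17)) + "\nID=bad\n"
        path = tmp_path / "bad.tps"
        path.write_text(text)
        with pytest.raises(MalformedRecordError, match="LM=18"):
            read_tps(path)

    def test_scale_factor_multiplies_coordinates(self, tmp_path):
        text = "LM=3\n1 2\n3 4\n5 6\nID=a\nSCALE=0.5\n"
        path = tmp_path / "scaled.tps"
        path.write_text(text)
        ds = read_tps(path)
        np.testing.assert_allclose(
            ds.configurations[0].coords, 0.5 * np.array([[1, 2], [3, 4], [5, 6]])
        )

    def test_inconsistent_landmark_counts_rejected(self, tmp_path):
        text = "LM=3\n0 0\n1 0\n0 1\nID=a\nLM=4\n0 0\n1 0\n0 1\n1 1\nID=b\n"
        path = tmp_path / "mixed.tps"
        path.write_text(text)
        with pytest.raises(ValueError, match="inconsistent"):
            read_tps(path)

    def test_generator_fixture_round_trips(self, tmp_path):
        dataset, _, _ = simulate_shape_dataset(SimulationScenario(n_taxa=4, seed=1))
        path = tmp_path / "gen.tps"
        write_tps(dataset, path)
        back = read_tps(path)
        for orig, rt in zip(dataset, back):
            np.testing.assert_allclose(rt.coords, orig.coords, atol=1e-10)


class TestCentroidSize:
    def test_unit_square_closed_form(self):
        square = LandmarkConfiguration(
            specimen_id="sq", taxon="sq",
            coords=np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float),
        )
        assert centroid_size(square) == pytest.approx(np.sqrt(2))

    def test_homogeneous_in_scale(self, rng):
        xy = rng.normal(size=(18, 2))
        assert centroid_size(3.7 * xy) == pytest.approx(3.7 * centroid_size(xy))

    def test_matches_direct_formula(self, rng):
        xy = rng.normal(size=(18, 2))
        expected = np.sqrt(
            sum(np.sum((p - xy.mean(axis=0)) ** 2) for p in xy)
        )
        assert centroid_size(xy) == pytest.approx(expected, abs=1e-12)


class TestAverageSpecimens:
    def _cfg(self, coords, taxon="T", sid="s"):
        return LandmarkConfiguration(specimen_id=sid, taxon=taxon,
                                     coords=np.asarray(coords, float))

    def test_identical_configs_idempotent(self, rng):
        xy = rng.normal(size=(5, 2))
        avg = average_specimens([self._cfg(xy, sid="a"), self._cfg(xy, sid="b")])
        d = procrustes_distance(avg.coords, xy)
        assert d < 1e-10

    def test_single_config_identity(self, rng):
        cfg = self._cfg(rng.normal(size=(5, 2)))
        assert average_specimens([cfg]) is cfg

    def test_mixed_taxa_rejected(self, rng):
        a = self._cfg(rng.normal(size=(4, 2)), taxon="A")
        b = self._cfg(rng.normal(size=(4, 2)), taxon="B")
        with pytest.raises(ValueError, match="mixed taxa"):
            average_specimens([a, b])

    def test_mean_of_prealigned_offset(self):
        base = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        eps = 0.01
        shifted = base.copy()
        shifted[2, 1] += 2 * eps
        avg = average_specimens(
            [self._cfg(base, sid="a"), self._cfg(shifted, sid="b")],
            superimpose=False,
        )
        expected = base.copy()
        expected[2, 1] += eps
        np.testing.assert_allclose(avg.coords, expected, atol=1e-12)


class TestGpa:
    def test_similarity_transforms_removed(self, rng):
        base = rng.normal(size=(18, 2))
        variants = [base,
                    3.0 * base @ _rot(np.deg2rad(37)).T + np.array([5.0, -2.0]),
                    0.4 * base @ _rot(1.2).T + np.array([-1.0, 9.0])]
        ds = LandmarkDataset([
            LandmarkConfiguration(specimen_id=f"v{i}", taxon=f"v{i}", coords=v)
            for i, v in enumerate(variants)
        ])
        aligned = gpa(ds)
        for i in range(3):
            for j in range(i + 1, 3):
                d = np.sqrt(np.sum((aligned.coords[i] - aligned.coords[j]) ** 2))
                assert d < 1e-10

    def test_reflection_contract(self, rng):
        base = rng.normal(size=(6, 2))
        mirrored = base.copy()
        mirrored[:, 0] *= -1
        ds = LandmarkDataset([
            LandmarkConfiguration(specimen_id="a", taxon="a", coords=base),
            LandmarkConfiguration(specimen_id="b", taxon="b", coords=mirrored),
        ])
        no_reflect = gpa(ds, allow_reflection=False)
        d_no = np.sqrt(np.sum((no_reflect.coords[0] - no_reflect.coords[1]) ** 2))
        with_reflect = gpa(ds, allow_reflection=True)
        d_yes = np.sqrt(np.sum((with_reflect.coords[0] - with_reflect.coords[1]) ** 2))
        assert d_no > 1e-3
        assert d_yes < 1e-10

    def test_rotation_matches_grid_search(self, rng):
        a = rng.normal(size=(3, 2))
        b = rng.normal(size=(3, 2))
        d_opt = procrustes_distance(a, b)
        from opershape.shapes import _center_and_scale

        ac, _ = _center_and_scale(a)
        bc, _ = _center_and_scale(b)
        angles = np.arange(0, 2 * np.pi, 0.001)
        best = min(
            np.sqrt(np.sum((ac - bc @ _rot(t).T) ** 2)) for t in angles
        )
        assert d_opt == pytest.approx(best, abs=1e-5)

    def test_order_and_pretransform_invariance(self, small_dataset, rng):
        aligned = gpa(small_dataset)
        # permuted, pre-rotated/scaled input
        configs = list(small_dataset)
        perm = rng.permutation(len(configs))
        jittered = []
        for i in perm:
            c = configs[i]
            coords = 2.0 * c.coords @ _rot(rng.uniform(0, 6)).T + rng.normal(size=2)
            jittered.append(
                LandmarkConfiguration(specimen_id=c.specimen_id, taxon=c.taxon,
                                      coords=coords)
            )
        aligned2 = gpa(LandmarkDataset(jittered))
        # compare all pairwise shape distances
        def pairwise(a: AlignedShapes, order):
            out = {}
            for x in range(a.n):
                for y in range(x + 1, a.n):
                    key = tuple(sorted((order[x], order[y])))
                    out[key] = np.sqrt(np.sum((a.coords[x] - a.coords[y]) ** 2))
            return out

        d1 = pairwise(aligned, [c.specimen_id for c in configs])
        d2 = pairwise(aligned2, [c.specimen_id for c in jittered])
        for key in d1:
            assert d1[key] == pytest.approx(d2[key], abs=1e-8)

    def test_residuals_sum_to_zero(self, small_dataset):
        aligned = gpa(small_dataset)
        residuals = aligned.coords - aligned.consensus
        np.testing.assert_allclose(residuals.sum(axis=0), 0, atol=1e-6)

    def test_unit_size_and_centering(self, small_dataset):
        aligned = gpa(small_dataset)
        for shape in aligned.coords:
            np.testing.assert_allclose(shape.mean(axis=0), 0, atol=1e-12)
            assert centroid_size(shape) == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_configuration_identified(self):
        good = LandmarkConfiguration(specimen_id="ok", taxon="ok",
                                     coords=np.array([[0., 0], [1, 0], [0, 1]]))
        bad = LandmarkConfiguration(specimen_id="flatliner", taxon="bad",
                                    coords=np.ones((3, 2)))
        with pytest.raises(ValueError, match="flatliner"):
            gpa(LandmarkDataset([good, bad]))

    def test_left_side_reflection_preserves_distances(self, rng):
        base = [rng.normal(size=(6, 2)) for _ in range(4)]
        right = LandmarkDataset([
            LandmarkConfiguration(specimen_id=f"r{i}", taxon=f"t{i}", coords=b,
                                  side="right")
            for i, b in enumerate(base)
        ])
        mixed_coords = [b.copy() for b in base]
        for i in (1, 3):
            mixed_coords[i][:, 0] *= -1  # photographed from the left
        mixed = LandmarkDataset([
            LandmarkConfiguration(specimen_id=f"m{i}", taxon=f"t{i}",
                                  coords=mixed_coords[i],
                                  side="left" if i in (1, 3) else "right")
            for i in range(4)
        ])
        a1, a2 = gpa(right), gpa(mixed)
        for i in range(4):
            for j in range(i + 1, 4):
                d1 = np.sqrt(np.sum((a1.coords[i] - a1.coords[j]) ** 2))
                d2 = np.sqrt(np.sum((a2.coords[i] - a2.coords[j]) ** 2))
                assert d1 == pytest.approx(d2, abs=1e-8)


class TestProcrustesDistance:
    def test_self_distance_zero(self, rng):
        xy = rng.normal(size=(7, 2))
        assert procrustes_distance(xy, xy) == pytest.approx(0, abs=1e-12)

    def test_symmetry(self, rng):
        a, b = rng.normal(size=(7, 2)), rng.normal(size=(7, 2))
        assert procrustes_distance(a, b) == pytest.approx(
            procrustes_distance(b, a), abs=1e-12
        )

    def test_mismatched_landmark_count(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            procrustes_distance(rng.normal(size=(5, 2)), rng.normal(size=(6, 2)))
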