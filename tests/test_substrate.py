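import logging

import numpy as np
import pytest

from dwiphantom.substrate import (
    BundleSpec,
    SubstrateRecipe,
    Tractogram,
    generate_numerical_brain,
    read_fraction_map,
    read_tractogram,
    toy_parcellation,
    write_fraction_map,
    write_tractogram,
)


def straight_recipe(direction=(1.0, 0.0, 0.0), **kw):
    c = (19.5, 19.5, 19.5)
    return SubstrateRecipe(
        grid_shape=(40, 40, 40),
        rng_seed=7,
        bundles=(
            BundleSpec(kind="straight", radius_mm=2.0, n_streamlines=50,
                       center_mm=c, direction=direction, length_mm=20.0),
        ),
        csf_center_mm=None,
        dgm_blobs=(),
        **kw,
    )


class TestGeneration:
    def test_fraction_invariants(self, default_substrate):
        _, vf, _ = default_substrate
        s = vf.fractions.sum(axis=-1)
        assert np.all(vf.fractions >= 0.0)
        assert np.all(vf.fractions <= 1.0)
        assert np.allclose(s[vf.brain_mask], 1.0, atol=1e-6)
        assert np.all(s[~vf.brain_mask] == 0.0)

    def test_all_tissues_present(self, default_substrate):
        _, vf, _ = default_substrate
        for t in ("WM", "CGM", "DGM", "CSF"):
            assert vf.tissue(t).sum() > 0.0, t

    def test_streamlines_in_wm(self, default_substrate):
        _, vf, tractogram = default_substrate
        pts = np.vstack([s[1:-1] for s in tractogram.streamlines[:300]])
        vox = np.floor(vf.world_to_voxel(pts) + 0.5).astype(int)
        wm = vf.tissue("WM")[vox[:, 0], vox[:, 1], vox[:, 2]]
        # interior points overwhelmingly in WM-dominant voxels (bundle
        # surfaces may graze the partial-volume shell)
        assert np.mean(wm >= 0.5) > 0.95

    def test_step_size(self, default_substrate):
        _, _, tractogram = default_substrate
        assert tractogram.mean_step_mm() == pytest.approx(
            tractogram.nominal_step_mm, rel=0.2
        )

    def test_straight_bundle_directions(self):
        vf, tractogram = generate_numerical_brain(straight_recipe())
        for s in tractogram.streamlines:
            d = np.diff(s, axis=0)
            d /= np.linalg.norm(d, axis=1, keepdims=True)
            np.testing.assert_allclose(np.abs(d @ [1.0, 0.0, 0.0]), 1.0,
                                       atol=1e-12)

    def test_determinism(self):
        recipe = SubstrateRecipe.default(rng_seed=5)
        vf1, t1 = generate_numerical_brain(recipe)
        vf2, t2 = generate_numerical_brain(recipe)
        np.testing.assert_array_equal(vf1.fractions, vf2.fractions)
        assert len(t1) == len(t2)
        for a, b in zip(t1.streamlines, t2.streamlines):
            np.testing.assert_array_equal(a, b)

    def test_zero_bundles_rejected(self):
        recipe = SubstrateRecipe(grid_shape=(20, 20, 20), bundles=())
        with pytest.raises(ValueError, match="bundle"):
            generate_numerical_brain(recipe)

    def test_geometry_outside_grid_rejected(self):
        recipe = SubstrateRecipe(
            grid_shape=(20, 20, 20),
            bundles=(
                BundleSpec(kind="straight", radius_mm=2.0, n_streamlines=5,
                           center_mm=(10.0, 10.0, 10.0), length_mm=80.0),
            ),
        )
        with pytest.raises(ValueError, match="grid"):
            generate_numerical_brain(recipe)

    def test_crossing_angle_validated(self):
        with pytest.raises(ValueError, match="angle"):
            BundleSpec(kind="crossing", radius_mm=1.0, n_streamlines=1,
                       center_mm=(0, 0, 0), angle_deg=120.0)

    def test_wm_coverage_by_segments(self, default_substrate):
        """Bundle-core WM voxels are intersected by at least one segment."""
        recipe, vf, tractogram = default_substrate
        from dwiphantom.fibermap import assign_segments

        field = assign_segments(tractogram, vf)
        # voxels within half the bundle radius of the crossing centerline
        spec = recipe.bundles[0]
        c = np.asarray(spec.center_mm)
        idx = np.argwhere(vf.tissue("WM") > 0.9)
        world = vf.voxel_to_world(idx)
        near = (
            (np.abs(world[:, 2] - c[2]) < spec.radius_mm / 2)
            & (np.abs(world[:, 1] - c[1]) < spec.radius_mm / 2)
            & (np.abs(world[:, 0] - c[0]) < spec.length_mm / 3)
        )
        covered = field.counts[tuple(idx[near].T)] > 0
        assert covered.mean() > 0.99


class TestCrossingGeometry:
    def test_two_antipodal_direction_clusters(self):
        recipe = SubstrateRecipe(
            grid_shape=(40, 40, 40),
            rng_seed=3,
            bundles=(
                BundleSpec(kind="crossing", radius_mm=2.5, n_streamlines=150,
                           center_mm=(19.5, 19.5, 19.5), angle_deg=90.0,
                           length_mm=24.0),
            ),
            csf_center_mm=None,
            dgm_blobs=(),
        )
        vf, tractogram = generate_numerical_brain(recipe)
        from dwiphantom.fibermap import assign_segments

        field = assign_segments(tractogram, vf)
        center = np.floor(vf.world_to_voxel([19.5, 19.5, 19.5])[0] + 0.5)
        dirs = field.segment_directions(tuple(int(v) for v in center))
        assert len(dirs) >= 2
        # antipodal clustering: fold into a hemisphere, cluster by the first
        # direction, and measure the angle between cluster means
        folded = dirs * np.where(dirs @ dirs[0] < 0, -1.0, 1.0)[:, None]
        cos_to_first = folded @ folded[0]
        cluster1 = folded[cos_to_first > np.cos(np.radians(45))]
        cluster2 = folded[cos_to_first <= np.cos(np.radians(45))]
        assert len(cluster1) and len(cluster2)
        m1 = cluster1.mean(axis=0)
        m2 = cluster2.mean(axis=0)
        ang = np.degrees(
            np.arccos(abs(m1 @ m2 / np.linalg.norm(m1) / np.linalg.norm(m2)))
        )
        assert ang == pytest.approx(90.0, abs=5.0)


class TestTractogramType:
    def test_short_streamline_rejected(self):
        with pytest.raises(ValueError):
            Tractogram(streamlines=[np.array([[0.0, 0.0, 0.0]])])

    def test_duplicate_points_rejected(self):
        with pytest.raises(ValueError):
            Tractogram(streamlines=[np.zeros((3, 3))])


class TestFractionMapIO:
    def test_round_trip(self, default_substrate, tmp_path):
        _, vf, _ = default_substrate
        p = tmp_path / "vf.nii.gz"
        write_fraction_map(vf, p)
        back = read_fraction_map(p)
        np.testing.assert_allclose(back.fractions, vf.fractions, atol=1e-6)
        np.testing.assert_array_equal(back.affine, vf.affine)
        np.testing.assert_array_equal(back.brain_mask, vf.brain_mask)

    def test_negative_fraction_rejected(self, tmp_path):
        import nibabel as nib

        data = np.zeros((4, 4, 4, 4), dtype=np.float32)
        data[..., 0] = 1.0
        data[1, 1, 1] = (-0.2, 0.6, 0.3, 0.3)
        nib.save(nib.Nifti1Image(data, np.eye(4)), str(tmp_path / "bad.nii.gz"))
        with pytest.raises(ValueError, match="1 voxel"):
            read_fraction_map(tmp_path / "bad.nii.gz")

    def test_three_component_file_rejected(self, tmp_path):
        import nibabel as nib

        data = np.zeros((4, 4, 4, 3), dtype=np.float32)
        nib.save(nib.Nifti1Image(data, np.eye(4)), str(tmp_path / "three.nii.gz"))
        with pytest.raises(ValueError, match="4 tissue components"):
            read_fraction_map(tmp_path / "three.nii.gz")

    def test_missing_tissue_named(self, tmp_path):
        with pytest.raises(ValueError, match="CSF"):
            read_fraction_map({"WM": "a", "CGM": "b", "DGM": "c"})


class TestTractogramIO:
    @pytest.mark.parametrize("ext", ["tck", "trk"])
    def test_round_trip(self, default_substrate, tmp_path, ext):
        _, vf, tractogram = default_substrate
        sub = Tractogram(streamlines=tractogram.streamlines[:10],
                         nominal_step_mm=tractogram.nominal_step_mm)
        p = tmp_path / f"t.{ext}"
        write_tractogram(sub, p, reference=vf)
        back = read_tractogram(p)
        assert len(back) == 10
        for a, b in zip(back.streamlines, sub.streamlines):
            np.testing.assert_allclose(a, b, atol=1e-4)

    def test_trk_requires_reference(self, default_substrate, tmp_path):
        _, _, tractogram = default_substrate
        with pytest.raises(ValueError, match="reference"):
            write_tractogram(tractogram, tmp_path / "t.trk")

    def test_empty_file_warns(self, tmp_path, caplog):
        empty = Tractogram.__new__(Tractogram)
        empty.streamlines = []
        empty.nominal_step_mm = 0.7
        p = tmp_path / "e.tck"
        write_tractogram(empty, p)
        with caplog.at_level(logging.WARNING):
            back = read_tractogram(p)
        assert len(back) == 0
        assert any("no usable streamlines" in r.message for r in caplog.records)

    def test_single_point_streamline_dropped(self, tmp_path, caplog):
        import nibabel as nib

        streams = [np.array([[0.0, 0.0, 0.0]]),
                   np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]])]
        sl = nib.streamlines.Tractogram(streams, affine_to_rasmm=np.eye(4))
        nib.streamlines.save(sl, str(tmp_path / "s.tck"))
        with caplog.at_level(logging.WARNING):
            back = read_tractogram(tmp_path / "s.tck")
        assert len(back) == 1
        assert any("dropped 1" in r.message for r in caplog.records)

    def test_unknown_extension_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="format"):
            read_tractogram(tmp_path / "x.vtk")


def test_toy_parcellation_labels(default_substrate):
    recipe, vf, _ = default_substrate
    labels = toy_parcellation(recipe)
    assert labels.shape == vf.grid_shape
    # crossing bundle has 2 centerlines -> 4 endpoints; arc -> 2
    assert labels.max() == 6
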