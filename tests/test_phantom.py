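"""Phantom generation, target-site definition, region masks and NIfTI I/O."""

import numpy as np
import pytest

from fielddose import phantom
from fielddose.phantom import TISSUE_CODES, make_sphere_phantom


def shell_volume(r_out, r_in):
    return 4.0 / 3.0 * np.pi * (r_out**3 - r_in**3)


SHELLS = (
    ("scalp", 6.0),
    ("compact_bone", 4.0),
    ("csf", 3.0),
    ("gray_matter", 4.0),
    ("white_matter", None),
)


class TestSpherePhantom:
    def test_shell_voxel_counts_match_analytic_volumes(self):
        spacing = 2.0
        vol = make_sphere_phantom(85.0, SHELLS, spacing)
        vvol = spacing**3
        bounds = [85.0, 79.0, 75.0, 72.0, 68.0, 0.0]
        names = ["scalp", "compact_bone", "csf", "gray_matter", "white_matter"]
        for name, r_out, r_in in zip(names, bounds[:-1], bounds[1:]):
            count = int((vol.labels == TISSUE_CODES[name]).sum())
            analytic = shell_volume(r_out, r_in) / vvol
            # tolerance: one voxel layer over each bounding sphere surface
            tol = 4 * np.pi * (r_out**2 + r_in**2) * spacing / vvol
            assert abs(count - analytic) < tol, name

    def test_shell_volume_error_decreases_with_resolution(self):
        shells = (("scalp", 6.0), ("compact_bone", 5.0), ("csf", 5.0), ("gray_matter", None))
        errors = []
        for spacing in (4.0, 2.0, 1.0):
            vol = make_sphere_phantom(85.0, shells, spacing)
            count = int((vol.labels == TISSUE_CODES["csf"]).sum()) * spacing**3
            errors.append(abs(count - shell_volume(74.0, 69.0)))
        assert errors[0] > errors[1] > errors[2]

    def test_zero_gyrification_is_identity(self):
        a = make_sphere_phantom(85.0, SHELLS, 2.0, gyrification=None)
        b = make_sphere_phantom(85.0, SHELLS, 2.0, gyrification=(0.0, 20.0))
        assert np.array_equal(a.labels, b.labels)

    def test_deterministic(self):
        a = make_sphere_phantom(85.0, SHELLS, 2.0, gyrification=(2.0, 25.0))
        b = make_sphere_phantom(85.0, SHELLS, 2.0, gyrification=(2.0, 25.0))
        assert np.array_equal(a.labels, b.labels)

    def test_background_forms_boundary_shell(self, small_phantom):
        lab = small_phantom.labels
        for face in (lab[0], lab[-1], lab[:, 0], lab[:, -1], lab[..., 0], lab[..., -1]):
            assert np.all(face == 0)

    def test_brain_separated_from_skull(self, small_phantom):
        lab = small_phantom.labels
        brain = np.isin(lab, (TISSUE_CODES["gray_matter"], TISSUE_CODES["white_matter"]))
        skull = np.isin(lab, (TISSUE_CODES["compact_bone"], TISSUE_CODES["cancellous_bone"]))
        for ax in range(3):
            for shift in (1, -1):
                rolled = np.roll(skull, shift, axis=ax)
                assert not np.any(brain & rolled)

    def test_negative_thickness_rejected(self):
        with pytest.raises(ValueError, match="thickness"):
            make_sphere_phantom(85.0, (("scalp", -1.0), ("gray_matter", None)), 2.0)

    def test_spacing_exceeding_thinnest_shell_rejected(self):
        with pytest.raises(ValueError, match="csf"):
            make_sphere_phantom(85.0, SHELLS, 3.5)

    def test_fine_grid_topology_matches_coarse_by_majority_vote(self):
        """Label adjacency structure is resolution independent."""
        coarse = make_sphere_phantom(40.0, (("scalp", 5.0), ("csf", 4.0), ("gray_matter", None)), 2.0)
        fine = make_sphere_phantom(40.0, (("scalp", 5.0), ("csf", 4.0), ("gray_matter", None)), 1.0)

        def adjacency(lab):
            pairs = set()
            for ax in range(3):
                a = np.moveaxis(lab, ax, 0)
                for x, y in zip(a[:-1].ravel(), a[1:].ravel()):
                    if x != y:
                        pairs.add(frozenset((int(x), int(y))))
            return pairs

        # downsample fine volume by 2x2x2 majority vote
        f = fine.labels
        n = (np.array(f.shape) // 2) * 2
        f = f[: n[0], : n[1], : n[2]]
        blocks = f.reshape(n[0] // 2, 2, n[1] // 2, 2, n[2] // 2, 2).transpose(0, 2, 4, 1, 3, 5)
        blocks = blocks.reshape(n[0] // 2, n[1] // 2, n[2] // 2, 8)
        maj = np.apply_along_axis(lambda v: np.bincount(v).argmax(), 3, blocks)
        assert adjacency(maj) == adjacency(coarse.labels)


class TestTargetSite:
    def test_normal_is_radial_on_sphere(self, small_phantom):
        site = phantom.define_target_site(small_phantom)
        p = np.asarray(site.world_mm)
        radial = p / np.linalg.norm(p)
        assert np.dot(radial, site.normal) > np.cos(np.radians(8.0))

    def test_site_depth_against_distance_transform(self, small_phantom):
        site = phantom.define_target_site(small_phantom)
        sd = phantom.signed_distance_to_pial(small_phantom)
        idx = small_phantom.containing_voxel(site.world_mm)
        depth = -sd[tuple(idx)]
        assert abs(depth - 2.0) <= max(small_phantom.spacing_mm) / 2 + 2.0

    def test_site_in_gray_matter(self, small_phantom):
        site = phantom.define_target_site(small_phantom)
        assert small_phantom.label_at(site.world_mm) == TISSUE_CODES["gray_matter"]

    def test_rotation_equivariance_quarter_turn(self, small_phantom):
        """90-degree rotations about z map the site and normal exactly."""
        a = np.array([-0.5, -0.2, 0.8])
        a /= np.linalg.norm(a)
        rot = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        s1 = phantom.define_target_site(small_phantom, anchor=a)
        s2 = phantom.define_target_site(small_phantom, anchor=rot @ a)
        assert np.allclose(rot @ np.asarray(s1.world_mm), s2.world_mm, atol=1e-6)
        assert np.allclose(rot @ np.asarray(s1.normal), s2.normal, atol=1e-6)

    def test_gyrified_normal_matches_gradient(self):
        vol = make_sphere_phantom(60.0, (("scalp", 5.0), ("csf", 4.0), ("gray_matter", 5.0), ("white_matter", None)), 2.0, (2.0, 25.0))
        site = phantom.define_target_site(vol)
        from scipy import ndimage

        sd = ndimage.gaussian_filter(phantom.signed_distance_to_pial(vol), 1.0)
        g = np.stack(np.gradient(sd, *vol.spacing_mm), axis=-1)
        idx = tuple(vol.containing_voxel(site.world_mm))
        gi = g[idx] / np.linalg.norm(g[idx])
        angle = np.degrees(np.arccos(np.clip(np.dot(gi, site.normal), -1, 1)))
        assert angle < 25.0

    def test_no_gray_matter_raises(self):
        vol = make_sphere_phantom(40.0, (("scalp", 5.0), ("muscle", None)), 2.0)
        with pytest.raises(ValueError, match="gray matter"):
            phantom.define_target_site(vol)


class TestRegionMasks:
    def test_mask_within_ball_and_gray_matter(self, small_phantom):
        site = phantom.define_target_site(small_phantom)
        (mask,) = phantom.make_region_masks(small_phantom, site)
        centers = small_phantom.voxel_center(mask.voxel_indices)
        d = np.linalg.norm(centers - np.asarray(site.world_mm), axis=1)
        assert np.all(d <= 15.0 + 1e-9)
        labs = small_phantom.labels[tuple(mask.voxel_indices.T)]
        assert np.all(labs == TISSUE_CODES["gray_matter"])

    def test_mask_count_close_to_analytic_intersection(self, small_phantom):
        site = phantom.define_target_site(small_phantom)
        (mask,) = phantom.make_region_masks(small_phantom, site)
        # Monte-Carlo estimate of |GM shell ball| via dense sampling
        rng = np.random.default_rng(0)
        pts = np.asarray(site.world_mm) + (rng.random((200000, 3)) - 0.5) * 30.0
        inside_ball = np.linalg.norm(pts - np.asarray(site.world_mm), axis=1) <= 15.0
        r = np.linalg.norm(pts, axis=1)
        inside_gm = (r <= 72.0) & (r > 68.0)
        frac = np.mean(inside_ball & inside_gm)
        analytic = frac * 30.0**3
        voxel_vol = float(np.prod(small_phantom.spacing_mm))
        assert abs(len(mask) * voxel_vol - analytic) / analytic < 0.35

    def test_empty_intersection_raises(self, small_phantom):
        site = phantom.define_target_site(small_phantom)
        far = phantom.CorticalSite(
            (0.0, 0.0, 0.0), site.normal, site.source_coord_mni
        )
        with pytest.raises(ValueError):
            phantom.make_region_masks(small_phantom, far, ball_diameter_mm=4.0)


class TestLabelVolumeIO:
    def test_round_trip(self, small_phantom, tmp_path):
        p = tmp_path / "head.nii.gz"
        phantom.write_label_volume(small_phantom, p)
        back = phantom.read_label_volume(p)
        assert np.array_equal(back.labels, small_phantom.labels)
        assert np.allclose(back.spacing_mm, small_phantom.spacing_mm)
        assert np.allclose(back.origin_mm, small_phantom.origin_mm)
        assert back.label_legend == small_phantom.label_legend

    def test_anisotropic_spacing_preserved(self, tmp_path):
        vol = make_sphere_phantom(40.0, (("scalp", 5.0), ("gray_matter", None)), (2.0, 2.5, 3.0))
        p = tmp_path / "aniso.nii"
        phantom.write_label_volume(vol, p)
        assert np.allclose(phantom.read_label_volume(p).spacing_mm, (2.0, 2.5, 3.0))

    def test_missing_legend_entry_raises(self, small_phantom, tmp_path):
        import json

        p = tmp_path / "head.nii"
        phantom.write_label_volume(small_phantom, p)
        side = tmp_path / "head.legend.json"
        legend = json.loads(side.read_text())
        legend["label_legend"].pop(str(TISSUE_CODES["csf"]))
        side.write_text(json.dumps(legend))
        with pytest.raises(ValueError, match=str(TISSUE_CODES["csf"])):
            phantom.read_label_volume(p)

    def test_non_integer_data_raises(self, tmp_path):
        import nibabel as nib

        img = nib.Nifti1Image(np.random.default_rng(0).random((4, 4, 4)), np.eye(4))
        p = tmp_path / "float.nii"
        nib.save(img, str(p))
        (tmp_path / "float.legend.json").write_text('{"label_legend": {"0": "air"}}')
        with pytest.raises(ValueError, match="integer"):
            phantom.read_label_volume(p)
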