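"""3D morphometry: contacts, colocalization, Sholl, orientation."""

import numpy as np
import pytest

from gliaquant.micromorph import (
    classify_contacts,
    colocalize,
    contact_summary,
    dominant_orientation,
    extract_objects,
    preprocess_volume,
    sholl_profile,
    signed_distance_field,
)
from gliaquant.syndata import MicrogliaSceneSpec, gen_microglia_scene
from gliaquant.types import ImageVolume

PAPER_VOXEL = (70.7, 70.7, 311.0)  # (x, y, z) nm


def brute_force_distances(synapses, microglia):
    """Oracle: pairwise voxel-center distances, same sign convention."""
    sp = np.array(microglia.spacing_zyx_um)
    mvox = np.argwhere(microglia.mask) * sp
    ovox = np.argwhere(~microglia.mask) * sp
    out = {}
    for obj in synapses.objects:
        vox = np.argwhere(synapses.label_volume == obj.label) * sp
        dmin = np.inf
        for v in vox:
            din = np.min(np.linalg.norm(mvox - v, axis=1))
            d = din if din > 0 else -np.min(np.linalg.norm(ovox - v, axis=1))
            dmin = min(dmin, d)
        out[obj.label] = dmin
    return out


def _vol(channels, voxel=PAPER_VOXEL):
    return ImageVolume(channels=channels, voxel_size_nm=voxel)


class TestPreprocess:
    def test_uniform_volume_flattens_to_zero(self):
        vol = _vol({"a": np.full((8, 32, 32), 500.0)})
        out = preprocess_volume(vol)
        assert np.abs(out.channel("a")).max() < 1.0

    def test_isolated_punctum_peak_retained(self):
        # a realistic punctum is wider than the 0.0707-μm (1 px) smoothing,
        # so its peak survives background subtraction plus smoothing
        from scipy.ndimage import gaussian_filter

        img = np.zeros((8, 64, 64))
        img[4, 32, 32] = 1.0
        img = gaussian_filter(img, (0.5, 3.0, 3.0))
        img *= 1000.0 / img.max()
        out = preprocess_volume(_vol({"a": img}))
        assert out.channel("a").max() >= 0.8 * img.max()

    def test_linear_ramp_suppressed(self):
        # field must span several background-filter widths for the large-
        # scale estimate to track the ramp: 1-μm voxels put 53.1 μm at
        # ~53 px against a 512-px extent
        ny = 512
        ramp = np.tile(np.linspace(0, 1000, ny)[None, :, None], (4, 1, 32))
        vol = ImageVolume(channels={"a": ramp},
                          voxel_size_nm=(1000.0, 1000.0, 1000.0))
        out = preprocess_volume(vol)
        core = slice(100, 412)
        amp_in = np.ptp(ramp[2, core, 16])
        slope_out = np.polyfit(np.arange(ny)[core],
                               out.channel("a")[2, core, 16], 1)[0]
        assert abs(slope_out * (412 - 100)) <= amp_in / 10


class TestExtractObjects:
    def test_empty_channel_no_objects(self):
        objs = extract_objects(_vol({"a": np.zeros((4, 16, 16))}), "a",
                               threshold=10)
        assert len(objs) == 0

    def test_sphere_volume_near_analytic(self):
        sp = (0.311, 0.0707, 0.0707)
        shape = (24, 48, 48)
        zz, yy, xx = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
        d = np.sqrt(((zz - 12) * sp[0]) ** 2 + ((yy - 24) * sp[1]) ** 2
                    + ((xx - 24) * sp[2]) ** 2)
        vol = _vol({"a": np.where(d <= 1.0, 1000.0, 0.0)})
        objs = extract_objects(vol, "a", threshold=500)
        assert len(objs) == 1
        assert objs.objects[0].volume_um3 == pytest.approx(4 / 3 * np.pi,
                                                           rel=0.15)

    def test_two_separated_spheres_two_objects(self):
        img = np.zeros((8, 32, 32))
        img[2:4, 4:8, 4:8] = 1000.0
        img[5:7, 20:24, 20:24] = 1000.0
        objs = extract_objects(_vol({"a": img}), "a", threshold=500)
        assert len(objs) == 2

    def test_volumes_additive_under_disjoint_union(self):
        img1 = np.zeros((8, 32, 32))
        img1[2:4, 4:10, 4:10] = 1000.0
        img2 = np.zeros((8, 32, 32))
        img2[5:7, 20:26, 20:26] = 1000.0
        v1 = extract_objects(_vol({"a": img1}), "a", threshold=500)
        v2 = extract_objects(_vol({"a": img2}), "a", threshold=500)
        v12 = extract_objects(_vol({"a": img1 + img2}), "a", threshold=500)
        assert v12.total_volume_um3 == pytest.approx(
            v1.total_volume_um3 + v2.total_volume_um3
        )


class TestContacts:
    @staticmethod
    def _scene(seed, distances=(0.0707, 0.2, 0.5, -0.0707, -0.3, -0.5)):
        import warnings

        spec = MicrogliaSceneSpec(
            shape=(24, 64, 64),
            puncta={"vGluT1": list(distances)},
            seed=seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # sub-pitch requests are expected
            vol, gt = gen_microglia_scene(spec)
        mg = extract_objects(vol, "Iba1", threshold=500)
        sy = extract_objects(vol, "vGluT1", threshold=500)
        return vol, gt, mg, sy

    def test_agrees_exactly_with_brute_force_oracle(self):
        for seed in (1, 2):
            _, _, mg, sy = self._scene(seed)
            table = classify_contacts(sy, mg)
            oracle = brute_force_distances(sy, mg)
            for _, row in table.iterrows():
                assert row["min_signed_distance_um"] == pytest.approx(
                    oracle[row["label"]], abs=1e-9
                )

    def test_fine_grid_contact_and_engulfed_classification(self):
        # at 25-nm isotropic voxels the requested distances are achievable,
        # so the ±0.07 μm band classifies as the ground truth dictates
        spec = MicrogliaSceneSpec(
            shape=(48, 96, 96),
            voxel_size_nm=(25.0, 25.0, 25.0),
            tube_radius_um=0.4,
            puncta={"vGluT1": [0.05, 0.25, -0.05, -0.3]},
            seed=3,
        )
        vol, gt = gen_microglia_scene(spec)
        mg = extract_objects(vol, "Iba1", threshold=500)
        sy = extract_objects(vol, "vGluT1", threshold=500)
        table = classify_contacts(sy, mg)
        by_dist = {
            round(r["min_signed_distance_um"], 2): r
            for _, r in table.iterrows()
        }
        assert by_dist[0.05]["contact"]
        assert not by_dist[0.25]["contact"]
        assert by_dist[-0.05]["contact"]
        assert by_dist[-0.3]["engulfed"]
        assert not by_dist[-0.3]["contact"]

    def test_band_monotonicity(self):
        _, _, mg, sy = self._scene(4)
        counts = [
            contact_summary(classify_contacts(sy, mg, band_um=b))["n_contacts"]
            for b in (0.0, 0.07, 0.15, 0.5, 1.0)
        ]
        assert counts == sorted(counts)

    def test_translation_invariance(self):
        _, _, mg, sy = self._scene(5)
        t1 = classify_contacts(sy, mg)
        shift = (2, 5, -3)
        mg2 = extract_objects(
            _vol({"Iba1": np.roll(
                np.where(mg.mask, 1000.0, 0.0), shift, axis=(0, 1, 2))}),
            "Iba1", threshold=500,
        )
        sy2 = extract_objects(
            _vol({"v": np.roll(
                np.where(sy.mask, 1000.0, 0.0), shift, axis=(0, 1, 2))}),
            "v", threshold=500,
        )
        t2 = classify_contacts(sy2, mg2)
        assert sorted(np.round(t1["min_signed_distance_um"], 9)) == sorted(
            np.round(t2["min_signed_distance_um"], 9)
        )

    def test_no_microglia_all_undefined(self):
        img = np.zeros((8, 16, 16))
        img[4, 8, 8] = 1000.0
        sy = extract_objects(_vol({"v": img}), "v", threshold=500)
        mg = extract_objects(_vol({"m": np.zeros((8, 16, 16))}), "m",
                             threshold=500)
        table = classify_contacts(sy, mg)
        assert table["min_signed_distance_um"].isna().all()
        assert not table["contact"].any()

    def test_no_puncta_empty_table(self):
        _, _, mg, _ = self._scene(6, distances=(0.2,))
        empty = extract_objects(_vol({"v": np.zeros((24, 64, 64))}), "v",
                                threshold=500)
        assert len(classify_contacts(empty, mg)) == 0


class TestColocalize:
    def test_disjoint_masks_no_objects(self):
        a = np.zeros((4, 16, 16))
        b = np.zeros((4, 16, 16))
        a[1, 2:5, 2:5] = 1000
        b[2, 10:13, 10:13] = 1000
        r = colocalize(_vol({"a": a, "b": b}), "a", "b",
                       threshold_a=500, threshold_b=500)
        assert r["n_objects"] == 0

    def test_identical_blobs_full_overlap(self):
        a = np.zeros((4, 16, 16))
        a[1:3, 2:7, 2:12] = 1000.0  # 2*5*10 = 100 voxels
        vol = _vol({"a": a, "b": a.copy()})
        r = colocalize(vol, "a", "b", threshold_a=500, threshold_b=500)
        assert r["n_objects"] == 1
        assert r["summed_volume_um3"] == pytest.approx(
            100 * vol.voxel_volume_um3
        )

    def test_half_overlap_counts_intersection(self):
        a = np.zeros((4, 16, 16))
        b = np.zeros((4, 16, 16))
        a[1, 2:6, 2:10] = 1000
        b[1, 2:6, 6:14] = 1000
        vol = _vol({"a": a, "b": b})
        r = colocalize(vol, "a", "b", threshold_a=500, threshold_b=500)
        inter = int(((a > 500) & (b > 500)).sum())
        assert r["summed_volume_um3"] == pytest.approx(
            inter * vol.voxel_volume_um3
        )

    def test_missing_channel_rejected(self):
        with pytest.raises(KeyError):
            colocalize(_vol({"a": np.zeros((2, 4, 4))}), "a", "missing")


class TestSholl:
    def _y_phantom(self):
        mask = np.zeros((5, 64, 64), dtype=bool)
        for x in range(5, 21):
            mask[2, 32, x] = True
        for i in range(1, 24):
            x = 20 + i
            if x < 64:
                mask[2, 32 + i, x] = True
                mask[2, 32 - i, x] = True
        return mask

    def test_straight_process_single_intersection(self):
        mask = np.zeros((3, 8, 40), dtype=bool)
        mask[1, 4, 2:32] = True
        prof = sholl_profile(mask, (1, 4, 2), (1.0, 1.0, 1.0),
                             radius_step_um=1.0, max_radius_um=40.0)
        assert (prof.intersections[prof.radii_um < 28] == 1).all()
        assert (prof.intersections[prof.radii_um > 32] == 0).all()

    def test_y_branch_steps_one_to_two(self):
        prof = sholl_profile(self._y_phantom(), (2, 32, 5), (1.0, 1.0, 1.0),
                             radius_step_um=1.0, max_radius_um=40.0)
        pre = prof.intersections[(prof.radii_um >= 3) & (prof.radii_um <= 13)]
        post = prof.intersections[(prof.radii_um >= 18) & (prof.radii_um <= 38)]
        assert (pre == 1).all()
        assert (post == 2).all()
        assert prof.auc > 0

    def test_matches_ray_oracle_on_phantom(self):
        # oracle: a radius r crosses the trunk once when r < branch radius
        # and both arms once each beyond it (thin, well-separated tubes)
        prof = sholl_profile(self._y_phantom(), (2, 32, 5), (1.0, 1.0, 1.0),
                             radius_step_um=1.0, max_radius_um=38.0)
        branch_r = 15.0
        for r, n in zip(prof.radii_um, prof.intersections):
            if abs(r - branch_r) <= 2.0:
                continue  # transition zone: shell thickness blurs the step
            assert n == (1 if r < branch_r else 2)

    def test_radius_beyond_extent_zero(self):
        mask = np.zeros((3, 8, 8), dtype=bool)
        mask[1, 4, 4] = True
        prof = sholl_profile(mask, (1, 4, 4), (1.0, 1.0, 1.0),
                             radius_step_um=1.0, max_radius_um=6.0)
        assert (prof.intersections[prof.radii_um > 2] == 0).all()

    def test_center_outside_mask_rejected(self):
        mask = np.zeros((3, 8, 8), dtype=bool)
        mask[1, 4, 4] = True
        with pytest.raises(ValueError, match="center"):
            sholl_profile(mask, (0, 0, 0), (1.0, 1.0, 1.0))


class TestOrientation:
    def test_horizontal_stripes_near_zero_degrees(self):
        yy = np.mgrid[0:200, 0:200][0]
        r = dominant_orientation(np.sin(2 * np.pi * yy / 10.0))
        assert abs(r.dominant_angle_deg) <= 2.0

    def test_diagonal_stripes_near_45_degrees(self):
        yy, xx = np.mgrid[0:200, 0:200]
        r = dominant_orientation(np.sin(2 * np.pi * (xx + yy) / 14.0))
        assert r.reported_abs_deg == pytest.approx(45.0, abs=2.0)

    def test_isotropic_noise_flagged_undefined(self):
        rng = np.random.default_rng(7)
        r = dominant_orientation(rng.normal(size=(200, 200)))
        assert r.undefined
        assert r.dominant_angle_deg is None

    def test_constant_image_flagged_undefined(self):
        r = dominant_orientation(np.ones((100, 100)))
        assert r.undefined


class TestSignedDistanceField:
    def test_sign_convention(self):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[2, 2, 2] = True
        sdf = signed_distance_field(mask, (1.0, 1.0, 1.0))
        assert sdf[2, 2, 2] == -1.0
        assert sdf[2, 2, 3] == 1.0
        assert sdf[2, 3, 3] == pytest.approx(np.sqrt(2))

    def test_empty_mask_all_infinite(self):
        sdf = signed_distance_field(np.zeros((3, 3, 3), bool), (1, 1, 1))
        assert np.isinf(sdf).all()
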