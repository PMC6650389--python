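"""Feature extraction: the 54-descriptor contract and its invariances."""

import numpy as np
import pytest

from morphoscreen.features import (
    FEATURE_BLOCKS,
    FEATURE_NAMES,
    N_FEATURES,
    extract_features,
    fourier_descriptors,
    intensity_features,
    microenvironment_features,
    shape_features,
)
from morphoscreen.segmentation import CellRecord, records_from_label_image
from morphoscreen.synth import render_frame, sample_cell, scatter_cells


def _circle_contour(radius=10.0, center=(0.0, 0.0), n=256):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    c = np.column_stack([center[0] + radius * np.sin(th), center[1] + radius * np.cos(th)])
    return np.vstack([c, c[:1]])


def _rect_mask_record(h=10, w=40, angle_deg=0.0, pad=30):
    """Axis-aligned or rotated solid rectangle as a CellRecord."""
    from scipy.ndimage import rotate

    size = max(h, w) + 2 * pad
    mask = np.zeros((size, size), bool)
    r0 = size // 2 - h // 2
    c0 = size // 2 - w // 2
    mask[r0 : r0 + h, c0 : c0 + w] = True
    if angle_deg:
        mask = rotate(mask.astype(float), angle_deg, order=1, reshape=False) > 0.5
    labels = mask.astype(int)
    return records_from_label_image(labels)[0]


class TestContract:
    def test_block_sizes_sum_to_54(self):
        assert sum(len(v) for v in FEATURE_BLOCKS.values()) == N_FEATURES == 54
        assert len(set(FEATURE_NAMES)) == 54

    def test_any_cell_gives_54_finite_values(self, gt_records, mixed_frame):
        vec = extract_features(gt_records[0], mixed_frame.image, mixed_frame.labels)
        assert vec.shape == (54,)
        assert np.isfinite(vec).all()

    def test_feature_order_is_frozen(self):
        # golden first/last entries of each block guard the serialized order
        assert FEATURE_NAMES[0] == "area"
        assert FEATURE_NAMES[21] == "bending_energy"
        assert FEATURE_NAMES[22] == "fourier_mag_2"
        assert FEATURE_NAMES[32] == "int_mean"
        assert FEATURE_NAMES[44] == "env_mean"
        assert FEATURE_NAMES[53] == "env_range"

    def test_fuzz_no_nans_over_generator_cells(self):
        rng = np.random.default_rng(11)
        names = ["normal", "small", "elongated", "round", "deformed", "lysed"] * 5
        n_checked = 0
        for _ in range(20):
            cells = scatter_cells(names, (512, 512), rng)
            frame = render_frame(cells, (512, 512), rng=rng)
            for rec in records_from_label_image(frame.labels):
                vec = extract_features(rec, frame.image, frame.labels)
                assert np.isfinite(vec).all()
                n_checked += 1
        assert n_checked > 500


class TestShape:
    def test_circle_is_round_and_circular(self):
        from skimage.draw import disk

        mask = np.zeros((40, 40), int)
        rr, cc = disk((20, 20), 10)
        mask[rr, cc] = 1
        rec = records_from_label_image(mask)[0]
        vec = dict(zip(FEATURE_NAMES, np.r_[shape_features(rec), np.zeros(32)]))
        assert 1.0 <= vec["aspect_ratio"] <= 1.1
        assert 0.9 <= vec["circularity"] <= 1.0

    def test_rectangle_dimensions_analytic(self):
        rec = _rect_mask_record(h=10, w=40)
        s = dict(zip(FEATURE_NAMES[:22], shape_features(rec)))
        assert abs(s["length"] - 40) <= 1.5
        assert abs(s["width"] - 10) <= 1.5
        assert abs(s["aspect_ratio"] - 4.0) < 0.6

    def test_rotation_invariance_of_length_width(self):
        s0 = dict(zip(FEATURE_NAMES[:22], shape_features(_rect_mask_record(10, 40, 0))))
        s37 = dict(zip(FEATURE_NAMES[:22], shape_features(_rect_mask_record(10, 40, 37))))
        assert abs(s37["length"] - s0["length"]) / s0["length"] < 0.05
        assert abs(s37["width"] - s0["width"]) / s0["width"] < 0.05

    def test_degenerate_contour_rejected(self):
        rec = CellRecord(
            label_id=1,
            mask=np.ones((1, 1), bool),
            bbox=(0, 0, 1, 1),
            contour=np.array([[0.0, 0.0], [0.0, 1.0], [0.0, 0.0]]),
            centroid=(0.0, 0.0),
        )
        with pytest.raises(ValueError, match="degenerate"):
            shape_features(rec)


class TestFourier:
    def test_circle_matches_unit_circle_anywhere(self):
        a = fourier_descriptors(_circle_contour(10, (50, 70)))
        b = fourier_descriptors(_circle_contour(1, (0, 0)))
        assert np.abs(a - b).max() < 1e-6

    def test_rotation_and_scale_invariance(self):
        rng = np.random.default_rng(0)
        cell = sample_cell("normal", rng=rng, centroid=(60.0, 60.0))
        frame = render_frame([cell], (120, 120), rng=rng)
        contour = records_from_label_image(frame.labels)[0].contour
        rot = contour @ np.array([[0.0, -1.0], [1.0, 0.0]])  # 90 degrees
        scaled = 2.0 * rot + np.array([17.0, -4.0])
        a = fourier_descriptors(contour)
        b = fourier_descriptors(scaled)
        assert np.abs(a - b).max() < 1e-6

    def test_starting_point_invariance(self):
        c = _circle_contour(5)[:-1]
        shifted = np.roll(c, 57, axis=0)
        a = fourier_descriptors(np.vstack([c, c[:1]]))
        b = fourier_descriptors(np.vstack([shifted, shifted[:1]]))
        assert np.abs(a - b).max() < 1e-6

    def test_bulged_rod_discriminated_from_rod(self):
        rng = np.random.default_rng(5)
        rod = sample_cell("normal", rng=rng, centroid=(60.0, 60.0))
        f1 = render_frame([rod], (120, 120), rng=np.random.default_rng(1))
        c_rod = records_from_label_image(f1.labels)[0].contour
        bulged = sample_cell("deformed", rng=rng, centroid=(60.0, 60.0))
        f2 = render_frame([bulged], (140, 140), rng=np.random.default_rng(1))
        c_bulge = records_from_label_image(f2.labels)[0].contour
        d_same = np.linalg.norm(
            fourier_descriptors(c_rod) - fourier_descriptors(c_rod[::-1] * 1.0 if False else c_rod)
        )
        d_diff = np.linalg.norm(fourier_descriptors(c_rod) - fourier_descriptors(c_bulge))
        assert d_diff > d_same

    def test_too_many_harmonics_rejected(self):
        with pytest.raises(ValueError, match="harmonics"):
            fourier_descriptors(_circle_contour(5), n_harmonics=500)


class TestIntensity:
    def test_constant_cell_has_zero_variance(self):
        img = np.full((20, 20), 0.3)
        mask = np.zeros((20, 20), bool)
        mask[5:15, 5:15] = True
        rec = records_from_label_image(mask.astype(int))[0]
        vals = dict(zip(FEATURE_NAMES[32:44], intensity_features(rec, img)))
        assert vals["int_std"] == 0.0
        assert vals["int_skewness"] == 0.0

    def test_intact_brighter_contrast_than_lysed(self, mixed_frame, gt_records):
        by_class = {}
        for rec in gt_records:
            cls = mixed_frame.cells[rec.label_id - 1].morph_class
            vec = intensity_features(rec, mixed_frame.image)
            by_class.setdefault(cls in ("lysed",), []).append(vec[0])
        # lysed ghosts are closer to background (higher mean intensity)
        assert np.mean(by_class[True]) > np.mean(by_class[False])

    def test_affine_rescaling_leaves_normalized_features(self, mixed_frame, gt_records):
        rec = gt_records[0]
        img = mixed_frame.image / 65535.0
        a = intensity_features(rec, img)
        b = intensity_features(rec, 0.37 * img + 0.11)
        # skewness, kurtosis, (mean-median)/sd, IQR/sd are affine-invariant
        for idx in (8, 9, 10, 11):
            assert abs(a[idx] - b[idx]) < 1e-6

    def test_empty_mask_rejected(self):
        rec = CellRecord(
            label_id=1,
            mask=np.zeros((4, 4), bool),
            bbox=(0, 0, 4, 4),
            contour=_circle_contour(1),
            centroid=(2.0, 2.0),
        )
        with pytest.raises(ValueError, match="empty mask"):
            intensity_features(rec, np.zeros((4, 4)))


class TestMicroenvironment:
    def _uniform_case(self, level=0.5):
        img = np.full((40, 40), level)
        mask = np.zeros((40, 40), bool)
        mask[15:25, 15:25] = True
        rec = records_from_label_image(mask.astype(int))[0]
        return rec, img

    def test_cell_equal_to_background_gives_zero_contrasts(self):
        rec, img = self._uniform_case()
        vec = dict(zip(FEATURE_NAMES[44:], microenvironment_features(rec, img)))
        for key in (
            "env_contrast_mean",
            "env_contrast_median",
            "env_weber_contrast",
            "env_michelson_contrast",
            "env_std_contrast",
            "env_halo_contrast",
        ):
            assert abs(vec[key]) < 1e-12

    def test_bright_halo_detected(self, mixed_frame, gt_records):
        rec = next(
            r
            for r in gt_records
            if mixed_frame.cells[r.label_id - 1].morph_class == "normal"
        )
        vec = dict(
            zip(
                FEATURE_NAMES[44:],
                microenvironment_features(rec, mixed_frame.image, label_image=mixed_frame.labels),
            )
        )
        assert vec["env_halo_contrast"] > 0

    def test_neighbor_exclusion_changes_annulus(self):
        img = np.full((60, 60), 0.5)
        labels = np.zeros((60, 60), int)
        labels[20:30, 10:25] = 1
        labels[20:30, 27:42] = 2  # neighbour 2 px away
        img[labels == 2] = 0.05  # dark neighbour contaminates a naive annulus
        rec = records_from_label_image(labels)[0]
        naive = microenvironment_features(rec, img, label_image=None)
        excl = microenvironment_features(rec, img, label_image=labels)
        assert abs(naive[0] - excl[0]) > 1e-3

    def test_identical_cells_differ_only_in_microenvironment(self):
        img = np.full((120, 120), 0.5)
        labels = np.zeros((120, 120), int)
        labels[10:20, 10:30] = 1
        labels[80:90, 60:80] = 2
        img[labels > 0] = 0.2
        img[91:120, :] = 0.9  # local background difference inside cell 2's annulus
        recs = records_from_label_image(labels)
        v1 = extract_features(recs[0], img, labels)
        v2 = extract_features(recs[1], img, labels)
        assert np.allclose(v1[:44], v2[:44], atol=1e-9)
        assert not np.allclose(v1[44:], v2[44:], atol=1e-9)
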