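"""Polarity, shape and circular-statistics behaviour."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import i0, i1

import flowvasc as fv
from flowvasc.core_io import ImageStack
from flowvasc.polarity import records_to_frame


def make_cell(shape=(40, 40), nucleus_at=(10, 10), golgi_at=(10, 20)):
    """Single-cell label images with point-like nucleus and Golgi."""
    cells = np.ones(shape, dtype=np.int32)
    nuclei = np.zeros(shape, dtype=np.int32)
    nuclei[nucleus_at] = 1
    nuclei[nucleus_at[0] + 1, nucleus_at[1]] = 1  # 2 px, avoids degeneracy
    golgi = np.zeros(shape, dtype=float)
    golgi[golgi_at] = 50.0
    return (ImageStack(cells, kind="label"), ImageStack(nuclei, kind="label"),
            ImageStack(golgi, kind="intensity"))


class TestExtractCells:
    def test_flow_aligned_polarity_angle(self):
        # nucleus at x=10, Golgi at x=20, same y: angle 0 = with +x flow
        cells, nuclei, golgi = make_cell(nucleus_at=(10, 10), golgi_at=(10, 20))
        # symmetric 2-px nucleus centred on row 10.5; Golgi on the same rows
        golgi.data[11, 20] = 50.0
        rec, = fv.extract_cells(cells, nuclei, golgi)
        assert rec.angle == pytest.approx(0.0, abs=1e-12)

    def test_upward_golgi_gives_positive_angle(self):
        cells, nuclei, golgi = make_cell(nucleus_at=(20, 10), golgi_at=(10, 10))
        golgi.data[:] = 0
        golgi.data[10, 10] = 50.0
        rec, = fv.extract_cells(cells, nuclei, golgi)
        assert rec.angle == pytest.approx(np.pi / 2, abs=1e-9)

    def test_uniform_marker_gives_unit_ratio(self):
        cells, nuclei, golgi = make_cell()
        marker = ImageStack(np.full(cells.shape, 7.0))
        rec, = fv.extract_cells(cells, nuclei, golgi, {"m": marker})
        assert rec.ratios["m"] == pytest.approx(1.0)

    def test_known_ratio_recovered(self, monolayer_clean):
        sample = monolayer_clean
        records = fv.extract_cells(sample.cells, sample.nuclei, sample.golgi,
                                   sample.markers)
        ratios = np.array([r.ratios["psmad159"] for r in records])
        np.testing.assert_allclose(ratios, 2.5)

    def test_generator_angles_recovered(self, monolayer_clean):
        sample = monolayer_clean
        records = fv.extract_cells(sample.cells, sample.nuclei, sample.golgi)
        truth = sample.truth.set_index("cell")["angle"]
        for rec in records:
            dev = np.angle(np.exp(1j * (rec.angle - truth.loc[rec.cell])))
            assert abs(dev) < 0.1  # rasterization jitter only

    def test_nucleus_spanning_two_cells_rejected(self):
        cells = np.ones((20, 20), dtype=np.int32)
        cells[:, 10:] = 2
        nuclei = np.zeros_like(cells)
        nuclei[10, 9:12] = 1
        golgi = np.zeros(cells.shape)
        golgi[5, 5] = 1.0
        with pytest.raises(ValueError, match="spans cells"):
            fv.extract_cells(ImageStack(cells, kind="label"),
                             ImageStack(nuclei, kind="label"),
                             ImageStack(golgi))

    def test_cell_without_nucleus_skipped(self, caplog):
        cells = np.ones((20, 40), dtype=np.int32)
        cells[:, 20:] = 2
        nuclei = np.zeros_like(cells)
        nuclei[10, 5], nuclei[11, 5] = 1, 1
        golgi = np.zeros(cells.shape)
        golgi[10, 10] = golgi[10, 30] = 1.0
        records = fv.extract_cells(ImageStack(cells, kind="label"),
                                   ImageStack(nuclei, kind="label"),
                                   ImageStack(golgi))
        assert [r.cell for r in records] == [1]


class TestShapeFeatures:
    @staticmethod
    def rect_labels(h, w, at=(5, 5), canvas=(40, 40), pixel_size=1.0):
        arr = np.zeros(canvas, dtype=np.int32)
        arr[at[0]:at[0] + h, at[1]:at[1] + w] = 1
        return ImageStack(arr, pixel_size=pixel_size, kind="label")

    def test_rectangle_moments(self):
        # 10 rows x 20 cols: long axis along x, side ratio = elongation
        feats = fv.shape_features(self.rect_labels(10, 20))
        row = feats.iloc[0]
        assert row["area"] == pytest.approx(200.0)
        assert row["elongation"] == pytest.approx(2.0)
        assert row["orientation"] == pytest.approx(0.0, abs=1e-9)

    def test_rotated_rectangle(self):
        feats = fv.shape_features(self.rect_labels(20, 10))
        row = feats.iloc[0]
        assert row["area"] == pytest.approx(200.0)
        assert row["elongation"] == pytest.approx(2.0)
        assert row["orientation"] == pytest.approx(np.pi / 2, abs=1e-9)

    def test_square_is_isotropic(self):
        feats = fv.shape_features(self.rect_labels(10, 10))
        assert feats.iloc[0]["elongation"] == pytest.approx(1.0)

    def test_area_scales_with_pixel_size_squared(self):
        feats = fv.shape_features(self.rect_labels(10, 20, pixel_size=0.5))
        assert feats.iloc[0]["area"] == pytest.approx(200 * 0.25)

    def test_translation_invariance(self):
        a = fv.shape_features(self.rect_labels(10, 20, at=(2, 3)))
        b = fv.shape_features(self.rect_labels(10, 20, at=(15, 12)))
        for col in ("area", "elongation", "orientation"):
            assert a.iloc[0][col] == pytest.approx(b.iloc[0][col])

    def test_border_cells_flagged(self):
        feats = fv.shape_features(self.rect_labels(10, 20, at=(0, 5)))
        assert bool(feats.iloc[0]["border"])


class TestCircularSummary:
    def test_all_angles_at_reference(self):
        s = fv.circular_summary([0.3] * 10, reference=0.3)
        assert s.pi_ == pytest.approx(1.0)
        assert s.v == pytest.approx(1.0)

    def test_perfect_symmetry_cancels(self):
        s = fv.circular_summary([0, np.pi / 2, np.pi, 3 * np.pi / 2])
        assert s.pi_ == pytest.approx(0.0, abs=1e-12)
        assert s.v == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_resultant(self):
        s = fv.circular_summary([0.0, 0.0, np.pi / 2], reference=0.0)
        assert s.pi_ == pytest.approx(np.sqrt(5) / 3)
        assert s.v == pytest.approx(2 / 3)

    def test_von_mises_bessel_ratio(self):
        rng = np.random.default_rng(42)
        angles = rng.vonmises(np.pi, 2.0, size=10_000)
        s = fv.circular_summary(angles, reference=0.0)
        expected = i1(2.0) / i0(2.0)
        assert s.pi_ == pytest.approx(expected, abs=0.02)
        assert s.v == pytest.approx(-expected, abs=0.02)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fv.circular_summary([])

    @given(st.lists(st.floats(-np.pi, np.pi), min_size=1, max_size=50),
           st.floats(-np.pi, np.pi))
    @settings(derandomize=True, max_examples=100)
    def test_v_never_exceeds_pi(self, angles, ref):
        s = fv.circular_summary(angles, reference=ref)
        assert abs(s.v) <= s.pi_ + 1e-12

    @given(st.floats(-np.pi, np.pi))
    @settings(derandomize=True, max_examples=50)
    def test_global_rotation_invariance(self, rot):
        rng = np.random.default_rng(5)
        angles = rng.uniform(-np.pi, np.pi, 40)
        ref = 0.7
        s0 = fv.circular_summary(angles, reference=ref)
        s1 = fv.circular_summary(angles + rot, reference=ref + rot)
        assert s1.pi_ == pytest.approx(s0.pi_)
        assert s1.v == pytest.approx(s0.v)

    @pytest.mark.parametrize("kappa", [0.0, 0.5, 2.0, 8.0])
    def test_generator_recovery_across_concentrations(self, kappa):
        """Full image pipeline: generate 5000 cells, segment-free extraction,
        estimated PI within 0.03 of the Bessel ratio I1(k)/I0(k)."""
        params = fv.MonolayerParams(n_cells=5000, kappa=kappa, seed=31)
        sample = fv.gen_monolayer(params)
        records = fv.extract_cells(sample.cells, sample.nuclei, sample.golgi)
        s = fv.circular_summary([r.angle for r in records])
        expected = i1(kappa) / i0(kappa)
        assert s.pi_ == pytest.approx(expected, abs=0.03)


class TestAxialStatistics:
    def test_flow_parallel_orientation_scores_plus_one(self):
        s = fv.circular_summary([0.0, np.pi], reference=0.0, axial=True)
        assert s.v == pytest.approx(1.0)
        assert s.pi_ == pytest.approx(1.0)

    def test_perpendicular_orientation_scores_minus_one(self):
        s = fv.circular_summary([np.pi / 2] * 5, reference=0.0, axial=True)
        assert s.v == pytest.approx(-1.0)

    def test_axial_mean_direction_mod_pi(self):
        s = fv.circular_summary([0.2, 0.2 + np.pi], axial=True)
        assert s.mean_direction == pytest.approx(0.2)


class TestRoseHistogram:
    def test_delta_distribution_fills_one_bin(self):
        counts, _ = fv.rose_histogram(np.zeros(25), n_bins=36)
        assert counts.max() == 25
        assert counts.sum() == 25
        assert (counts > 0).sum() == 1

    def test_uniform_grid_partitions_evenly(self):
        angles = -np.pi + (np.arange(360) + 0.5) * (2 * np.pi / 360)
        counts, _ = fv.rose_histogram(angles, n_bins=36)
        np.testing.assert_array_equal(counts, 10)

    def test_axial_mode_identifies_opposite_angles(self):
        counts, _ = fv.rose_histogram([0.3, 0.3 + np.pi], n_bins=12, axial=True)
        assert counts.max() == 2

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError, match="4 bins"):
            fv.rose_histogram([0.0], n_bins=3)


class TestImageLevelVScore:
    def test_aligned_and_perpendicular_images(self):
        df = pd.DataFrame({
            "image": ["a"] * 4 + ["b"] * 4,
            "orientation": [0.0] * 4 + [np.pi / 2] * 4,
            "elongation": [2.0] * 8,
        })
        out = fv.image_level_vscore(df, reference=0.0)
        out = out.set_index("image")
        assert out.loc["a", "V"] == pytest.approx(1.0)
        assert out.loc["b", "V"] == pytest.approx(-1.0)

    def test_matches_per_image_hand_computation(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame({
            "image": np.repeat(["im0", "im1"], 30),
            "orientation": rng.uniform(0, np.pi, 60),
            "elongation": np.full(60, 1.5),
        })
        out = fv.image_level_vscore(df, reference=0.4).set_index("image")
        for im in ("im0", "im1"):
            theta = df.loc[df["image"] == im, "orientation"].to_numpy()
            expected = np.mean(np.cos(2 * (theta - 0.4)))
            assert out.loc[im, "V"] == pytest.approx(expected)

    def test_near_isotropic_cells_excluded(self):
        df = pd.DataFrame({
            "image": ["a"] * 3,
            "orientation": [0.0, 0.0, np.pi / 2],
            "elongation": [2.0, 2.0, 1.01],
        })
        out = fv.image_level_vscore(df, reference=0.0)
        assert out.loc[0, "n"] == 2
        assert out.loc[0, "V"] == pytest.approx(1.0)
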