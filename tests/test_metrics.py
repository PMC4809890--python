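import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mantis import LabelVolume
from mantis.metrics import (
    confusion_matrix,
    dice,
    evaluate,
    sensitivity_specificity,
    surface_distances,
)
from mantis.volumes import TISSUE_CLASSES
from oracles import confusion_oracle, surface_distances_oracle


class TestDice:
    def test_identical_masks(self, rng):
        m = rng.random((6, 6, 6)) > 0.5
        assert dice(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4, 4), bool)
        b = np.zeros((4, 4, 4), bool)
        a[0, 0, 0] = True
        b[3, 3, 3] = True
        assert dice(a, b) == 0.0

    def test_half_overlap(self):
        a = np.zeros((4, 4, 4), bool)
        b = np.zeros((4, 4, 4), bool)
        a[0, 0, :2] = a[0, 1, :2] = a[1, 0, :2] = a[1, 1, :2] = True  # 8
        b[0, 0, :2] = b[0, 1, :2] = b[2, 2, :2] = b[2, 3, :2] = True  # 8, 4 shared
        assert dice(a, b) == 0.5

    def test_both_empty_defined_as_one(self):
        z = np.zeros((3, 3, 3), bool)
        assert dice(z, z) == 1.0

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            dice(np.zeros((3, 3, 3), bool), np.zeros((4, 4, 4), bool))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 27 - 1))
    def test_symmetry(self, seed):
        r = np.random.default_rng(seed)
        a = r.random((5, 5, 5)) > 0.5
        b = r.random((5, 5, 5)) > 0.5
        assert dice(a, b) == dice(b, a)


class TestSurfaceDistances:
    def test_identical_masks_zero(self, rng):
        m = np.zeros((6, 6, 6), bool)
        m[2:5, 2:5, 2:5] = True
        assert surface_distances(m, m) == (0.0, 0.0)

    def test_two_points_three_mm_apart(self):
        a = np.zeros((8, 8, 8), bool)
        b = np.zeros((8, 8, 8), bool)
        a[2, 2, 2] = True
        b[2, 2, 5] = True
        msd, hd = surface_distances(a, b, (1.0, 1.0, 1.0))
        assert msd == pytest.approx(3.0)
        assert hd == pytest.approx(3.0)

    def test_empty_mask_undefined(self):
        m = np.ones((3, 3, 3), bool)
        with pytest.raises(ValueError, match="undefined"):
            surface_distances(m, np.zeros((3, 3, 3), bool))

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(10):
            a = rng.random((16, 16, 16)) > 0.6
            b = rng.random((16, 16, 16)) > 0.6
            if not a.any() or not b.any():
                continue
            spacing = tuple(rng.uniform(0.3, 2.0, 3))
            got = surface_distances(a, b, spacing)
            want = surface_distances_oracle(a, b, spacing)
            assert got[0] == pytest.approx(want[0], abs=1e-9)
            assert got[1] == pytest.approx(want[1], abs=1e-9)

    def test_distances_scale_with_spacing(self, rng):
        a = rng.random((10, 10, 10)) > 0.6
        b = rng.random((10, 10, 10)) > 0.6
        m1, h1 = surface_distances(a, b, (1.0, 1.0, 1.0))
        m2, h2 = surface_distances(a, b, (2.0, 2.0, 2.0))
        assert m2 == pytest.approx(2 * m1)
        assert h2 == pytest.approx(2 * h1)

    def test_hausdorff_at_least_msd(self, rng):
        for _ in range(5):
            a = rng.random((8, 8, 8)) > 0.5
            b = rng.random((8, 8, 8)) > 0.5
            msd, hd = surface_distances(a, b)
            assert hd >= msd - 1e-12


class TestSensitivitySpecificity:
    def test_perfect_candidate(self, rng):
        ref = rng.random((6, 6, 6)) > 0.5
        dom = np.ones((6, 6, 6), bool)
        assert sensitivity_specificity(ref, ref, dom) == (1.0, 1.0)

    def test_labels_everything(self, rng):
        ref = rng.random((6, 6, 6)) > 0.5
        dom = np.ones((6, 6, 6), bool)
        sens, spec = sensitivity_specificity(dom, ref, dom)
        assert sens == 1.0
        assert spec == 0.0

    def test_printed_count_fixture(self):
        # TP=40, FN=10, TN=45, FP=5 -> sens 0.8, spec 0.9
        dom = np.ones((100, 1, 1), bool)
        ref = np.zeros((100, 1, 1), bool)
        cand = np.zeros((100, 1, 1), bool)
        ref[:50] = True
        cand[:40] = True      # 40 TP, 10 FN
        cand[50:55] = True    # 5 FP, 45 TN
        sens, spec = sensitivity_specificity(cand, ref, dom)
        assert sens == pytest.approx(0.8)
        assert spec == pytest.approx(0.9)

    def test_empty_reference_gives_nan_with_warning(self):
        dom = np.ones((3, 3, 3), bool)
        with pytest.warns(UserWarning, match="sensitivity undefined"):
            sens, spec = sensitivity_specificity(
                np.zeros((3, 3, 3), bool), np.zeros((3, 3, 3), bool), dom)
        assert np.isnan(sens)

    def test_counts_restricted_to_domain(self, rng):
        ref = np.zeros((6, 6, 6), bool)
        cand = np.zeros((6, 6, 6), bool)
        ref[0] = cand[0] = True
        dom = np.zeros((6, 6, 6), bool)
        dom[:2] = True
        # outside the domain, plant disagreements that must be ignored
        cand[4] = True
        sens, spec = sensitivity_specificity(cand, ref, dom)
        assert (sens, spec) == (1.0, 1.0)


class TestConfusionMatrix:
    def test_identity_candidate(self, rng):
        data = rng.integers(0, 9, (8, 8, 8)).astype(np.int32)
        vol = LabelVolume(data)
        conf = confusion_matrix(vol, vol)
        for code in range(1, 9):
            name = TISSUE_CLASSES[code]
            if (data == code).any():
                assert conf.loc[name, name] == pytest.approx(100.0)

    def test_half_half_row(self):
        cand = np.ones((4, 4, 4), np.int32)
        ref = np.ones((4, 4, 4), np.int32)
        ref[:2] = 2
        conf = confusion_matrix(LabelVolume(cand), LabelVolume(ref))
        assert conf.loc["cortical_gm", "cortical_gm"] == pytest.approx(50.0)
        assert conf.loc["cortical_gm", "white_matter"] == pytest.approx(50.0)

    def test_matches_exhaustive_tally(self, rng):
        cand = LabelVolume(rng.integers(0, 9, (10, 10, 10)).astype(np.int32))
        ref = LabelVolume(rng.integers(0, 9, (10, 10, 10)).astype(np.int32))
        conf = confusion_matrix(cand, ref)
        codes = list(range(1, 9))
        want = confusion_oracle(cand.data, ref.data, codes, [0] + codes)
        np.testing.assert_allclose(conf.to_numpy(), want, atol=1e-9)

    def test_rows_sum_to_100(self, rng):
        cand = LabelVolume(rng.integers(1, 9, (8, 8, 8)).astype(np.int32))
        ref = LabelVolume(rng.integers(0, 9, (8, 8, 8)).astype(np.int32))
        conf = confusion_matrix(cand, ref)
        sums = conf.to_numpy().sum(axis=1)
        np.testing.assert_allclose(sums, 100.0, atol=0.1)


class TestEvaluate:
    def test_identity_gives_perfect_scores(self, rng):
        data = rng.integers(0, 9, (10, 10, 10)).astype(np.int32)
        vol = LabelVolume(data)
        report = evaluate(vol, vol)
        present = [TISSUE_CLASSES[c] for c in range(1, 9)
                   if (data == c).any()]
        assert (report.per_class.loc[present, "dice"] == 1.0).all()
        assert (report.per_class.loc[present,
                                     "mean_surface_distance_mm"] == 0.0).all()

    def test_limbic_merge_folds_into_cortex(self):
        cand = np.zeros((6, 6, 6), np.int32)
        ref = np.zeros((6, 6, 6), np.int32)
        cand[0] = 7   # hippocampus predicted
        ref[0] = 1    # cortical GM in reference
        report = evaluate(LabelVolume(cand), LabelVolume(ref),
                          merge_limbic_into_cortex=True)
        assert "hippocampus" not in report.per_class.index
        assert report.per_class.loc["cortical_gm", "dice"] == 1.0

    def test_shifted_cube_matches_geometry(self):
        # 5-cube shifted by one voxel: overlap 4x5x5 -> Dice 0.8; distances
        # against the exhaustive oracle
        cand = np.zeros((12, 12, 12), np.int32)
        ref = np.zeros((12, 12, 12), np.int32)
        ref[3:8, 3:8, 3:8] = 4
        cand[4:9, 3:8, 3:8] = 4
        report = evaluate(LabelVolume(cand), LabelVolume(ref),
                          domain=np.ones((12, 12, 12), bool))
        assert report.per_class.loc["csf", "dice"] == pytest.approx(0.8)
        msd, hd = surface_distances_oracle(cand == 4, ref == 4, (1, 1, 1))
        assert report.per_class.loc["csf",
                                    "mean_surface_distance_mm"] == \
            pytest.approx(msd, abs=1e-9)
        assert report.per_class.loc["csf", "hausdorff_mm"] == \
            pytest.approx(hd, abs=1e-9)
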