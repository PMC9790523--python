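"""Wall derivation, scar threshold, fibrosis percentage, EAT volumetry, BSA."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lgedixon import (
    StructureMasks,
    bsa,
    derive_wall_mask,
    eat_volume,
    fibrosis_percentage,
    mean_si,
    quantify_fibrosis,
    scar_threshold,
)

SPACING = (1.25, 1.25, 2.5)


def _masks(la, blood=None, mv=None, exclusions=None, eat=None, spacing=SPACING):
    shape = la.shape
    zero = np.zeros(shape, bool)
    return StructureMasks(
        la_intramural=la,
        blood_pool=zero if blood is None else blood,
        mitral_valve=zero if mv is None else mv,
        exclusions=exclusions or {},
        eat=zero if eat is None else eat,
        spacing_mm=spacing,
    )


class TestWallDerivation:
    def test_subtraction_removes_overlap(self):
        la = np.zeros((10, 10, 1), bool)
        la.ravel()[:100] = True
        mv = np.zeros((10, 10, 1), bool)
        mv.ravel()[:10] = True
        wall = derive_wall_mask(_masks(la, mv=mv))
        assert wall.sum() == 90
        assert not np.any(wall & mv)

    def test_no_overlap_is_identity(self):
        la = np.zeros((6, 6, 2), bool)
        la[1:4, 1:4, 0] = True
        wall = derive_wall_mask(_masks(la))
        assert np.array_equal(wall, la)

    def test_full_exclusion_raises(self):
        la = np.ones((4, 4, 1), bool)
        with pytest.raises(ValueError, match="fully excluded"):
            derive_wall_mask(_masks(la, blood=np.ones((4, 4, 1), bool)))

    def test_phantom_wall_matches_independent_construction(self, small_gt):
        """The subtraction rule reproduces the phantom's own wall label."""
        wall = derive_wall_mask(small_gt.masks)
        assert np.array_equal(wall, small_gt.wall_mask)


class TestMeanSiAndThreshold:
    def test_constant_image(self):
        img = np.full((5, 5, 5), 7.0)
        mask = np.zeros((5, 5, 5), bool)
        mask[0, 0, 0] = True
        assert mean_si(img, mask) == 7.0

    def test_two_value_mask(self):
        img = np.zeros((2, 2, 1))
        img[0, 0, 0] = 0.0
        img[1, 1, 0] = 10.0
        mask = np.zeros((2, 2, 1), bool)
        mask[0, 0, 0] = mask[1, 1, 0] = True
        assert mean_si(img, mask) == 5.0

    def test_empty_mask_error_names_structure(self):
        with pytest.raises(ValueError, match="blood_pool"):
            mean_si(np.ones((2, 2, 2)), np.zeros((2, 2, 2), bool), "blood_pool")

    @pytest.mark.parametrize(
        "blood,mv,expected", [(100.0, 200.0, 150.0), (0.0, 0.0, 0.0), (40.0, 100.0, 70.0)]
    )
    def test_threshold_examples(self, blood, mv, expected):
        assert scar_threshold(blood, mv) == pytest.approx(expected)

    def test_inverted_contrast_warns_but_returns_formula_value(self):
        with pytest.warns(UserWarning, match="inverted contrast"):
            assert scar_threshold(10.0, 4.0) == pytest.approx(7.0)

    @given(
        b=st.floats(-1e6, 1e6, allow_nan=False),
        m=st.floats(-1e6, 1e6, allow_nan=False),
    )
    @settings(max_examples=200, deadline=None)
    def test_threshold_is_midpoint(self, b, m):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert scar_threshold(b, m) == pytest.approx((b + m) / 2.0, rel=1e-12, abs=1e-12)


class TestFibrosisPercentage:
    def test_counting_example(self):
        wall = np.zeros((2, 2, 2), bool)
        wall.ravel()[:8] = True
        img = np.zeros((2, 2, 2))
        img.ravel()[[0, 3]] = 5.0
        res = fibrosis_percentage(img, wall, threshold=1.0)
        assert res.scar_voxels == 2 and res.wall_voxels == 8
        assert res.fibrosis_pct == 25.0

    def test_all_below_threshold_is_zero(self):
        wall = np.ones((3, 3, 1), bool)
        res = fibrosis_percentage(np.zeros((3, 3, 1)), wall, threshold=0.0)
        assert res.fibrosis_pct == 0.0  # strict inequality: ties are healthy

    def test_empty_wall_raises(self):
        with pytest.raises(ValueError, match="empty"):
            fibrosis_percentage(np.ones((2, 2, 2)), np.zeros((2, 2, 2), bool), 0.5)

    def test_brute_force_oracle_on_random_scenes(self, rng):
        """Vectorized counting equals an explicit per-voxel loop, 50 scenes."""
        for _ in range(50):
            shape = tuple(rng.integers(2, 6, size=3))
            img = rng.normal(0, 1, shape)
            wall = rng.random(shape) < 0.6
            if not wall.any():
                wall.ravel()[0] = True
            thr = float(rng.normal(0, 1))
            res = fibrosis_percentage(img, wall, thr)
            count = 0
            total = 0
            for idx in np.ndindex(shape):
                if wall[idx]:
                    total += 1
                    if img[idx] > thr:
                        count += 1
            assert res.scar_voxels == count
            assert res.fibrosis_pct == pytest.approx(100.0 * count / total)

    def test_monotone_non_increasing_in_threshold(self, rng):
        img = rng.normal(0, 1, (6, 6, 3))
        wall = np.ones((6, 6, 3), bool)
        thresholds = np.sort(rng.normal(0, 1, 10))
        pcts = [fibrosis_percentage(img, wall, t).fibrosis_pct for t in thresholds]
        assert all(a >= b for a, b in zip(pcts, pcts[1:]))

    def test_axis_permutation_invariance(self, small_gt, acq):
        from lgedixon import simulate_echoes, separate_water_fat

        e1, e2 = simulate_echoes(small_gt, acq, 0.0)
        water = separate_water_fat(e1, e2, small_gt.field_map_hz, acq).water
        res = quantify_fibrosis(water, small_gt.masks)
        perm = (2, 0, 1)
        masks_p = StructureMasks(
            la_intramural=small_gt.masks.la_intramural.transpose(perm),
            blood_pool=small_gt.masks.blood_pool.transpose(perm),
            mitral_valve=small_gt.masks.mitral_valve.transpose(perm),
            exclusions={
                k: v.transpose(perm) for k, v in small_gt.masks.exclusions.items()
            },
            eat=small_gt.masks.eat.transpose(perm),
            spacing_mm=tuple(small_gt.masks.spacing_mm[i] for i in perm),
        )
        res_p = quantify_fibrosis(water.transpose(perm), masks_p)
        assert res_p.fibrosis_pct == res.fibrosis_pct
        assert eat_volume(masks_p).volume_ml == eat_volume(small_gt.masks).volume_ml


class TestEatVolume:
    def test_256_voxels_is_exactly_one_ml(self):
        eat = np.zeros((8, 8, 8), bool)
        eat.ravel()[:256] = True
        la = np.zeros((8, 8, 8), bool)
        la[0, 0, 7] = True
        res = eat_volume(_masks(la, eat=eat))
        assert res.eat_voxels == 256
        assert res.volume_ml == 1.0  # 256 x 3.90625 mm^3 = 1000 mm^3 exactly

    def test_empty_eat_mask(self):
        la = np.zeros((4, 4, 4), bool)
        la[0, 0, 0] = True
        res = eat_volume(_masks(la))
        assert res.eat_voxels == 0 and res.volume_ml == 0.0

    def test_bsa_indexing(self):
        eat = np.zeros((16, 16, 16), bool)
        eat.ravel()[: int(13.0 * 1000 / 3.90625)] = True
        la = np.zeros((16, 16, 16), bool)
        la[15, 15, 15] = True
        # height/weight chosen so Mosteller BSA = 2.0 m^2 exactly
        res = eat_volume(_masks(la, eat=eat), height_m=1.8, weight_kg=80.0)
        assert res.bsa_m2 == pytest.approx(2.0)
        assert res.volume_indexed == pytest.approx(res.volume_ml / 2.0)
        assert res.volume_indexed == pytest.approx(6.5, abs=0.01)

    def test_eat_overlapping_blood_pool_rejected(self):
        la = np.zeros((4, 4, 4), bool)
        la[0, 0, 0] = True
        blood = np.zeros((4, 4, 4), bool)
        blood[2, 2, 2] = True
        eat = blood.copy()
        with pytest.raises(ValueError, match="topologically impossible"):
            eat_volume(_masks(la, blood=blood, eat=eat))


class TestBsa:
    def test_mosteller_examples(self):
        assert bsa(1.80, 72.0) == pytest.approx(math.sqrt(3.6))
        assert bsa(0.36, 100.0) == pytest.approx(1.0)

    def test_dubois_differs_from_mosteller(self):
        m = bsa(1.80, 72.0, "mosteller")
        d = bsa(1.80, 72.0, "dubois")
        assert m != d
        assert abs(m - d) / m < 0.05  # same ballpark for a typical adult

    def test_non_positive_inputs_rejected(self):
        with pytest.raises(ValueError):
            bsa(0.0, 70.0)
        with pytest.raises(ValueError):
            bsa(1.7, -1.0)
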