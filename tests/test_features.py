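"""Feature extraction oracles, imputation/normalisation, assembly."""

import numpy as np
import pandas as pd
import pytest
from skimage.draw import disk

import tissuemil as tm
from tissuemil.containers import TissueInstance
from tissuemil.features import PERCENTILE_GRID


def _extract(slide, inst_index, nuclei=()):
    gt = slide.instances[inst_index]
    inst = TissueInstance(0, gt.class_label, gt.mask)
    crop = tm.crop_instance(slide.image, inst, 1.32, slide.mpp, 8.0)
    r0, c0, r1, c1 = inst.bbox
    nuc = [m[r0:r1, c0:c1] for m in nuclei]
    return tm.handcrafted_features(
        crop, gt.mask[r0:r1, c0:c1], nuclei_masks=nuc, mpp=slide.mpp
    )


class TestHandcrafted:
    def test_vessel_lumen_ratio_analytic_oracle(self, vessel_slide):
        rec = _extract(vessel_slide, 0)
        assert rec["lumen_total_ratio"] == pytest.approx(0.25, rel=0.02)

    def test_tubule_lumen_ratio_and_eccentricity(self):
        cfg = tm.SlideConfig(
            height=256, width=256, n_tubules=1, n_glomeruli=0, n_vessels=0,
            nuclei_per_compartment=(0, 0),
        )
        slide = tm.make_slide(cfg, seed=7)
        gt = slide.instances[0]
        rec = _extract(slide, 0)
        assert rec["lumen_total_ratio"] == pytest.approx(
            gt.shape_params["analytic_lumen_ratio"], rel=0.02
        )
        assert rec["eccentricity"] == pytest.approx(
            gt.shape_params["analytic_eccentricity"], abs=0.02
        )

    def test_filled_disk_solidity_one_no_cavity(self):
        mask = np.zeros((64, 64), dtype=bool)
        rr, cc = disk((32, 32), 20)
        mask[rr, cc] = True
        crop = np.full((64, 64, 3), 100, dtype=np.uint8)
        rec = tm.handcrafted_features(crop, mask, mpp=0.44)
        assert rec["solidity"] == pytest.approx(1.0, abs=0.02)
        assert rec["lumen_area_um2"] == 0.0

    def test_no_nuclei_gives_missing_not_zero(self):
        mask = np.zeros((32, 32), dtype=bool)
        mask[8:24, 8:24] = True
        crop = np.full((32, 32, 3), 100, dtype=np.uint8)
        rec = tm.handcrafted_features(crop, mask, nuclei_masks=[], mpp=0.44)
        nuc_cols = [n for n in rec.index if n.startswith("nuclei_")]
        assert len(nuc_cols) == 2 + 2 * len(PERCENTILE_GRID)
        assert rec[nuc_cols].isna().all()
        assert rec.drop(nuc_cols).notna().all()

    def test_zero_area_mask_raises(self):
        with pytest.raises(ValueError):
            tm.handcrafted_features(
                np.zeros((8, 8, 3), dtype=np.uint8), np.zeros((8, 8), dtype=bool)
            )

    def test_translation_invariance(self, rng):
        """Morphology and colour features do not change when the shape is
        moved within the canvas."""
        mask = np.zeros((96, 96), dtype=bool)
        rr, cc = disk((30, 30), 14)
        mask[rr, cc] = True
        texture = rng.integers(60, 200, (29, 29, 3)).astype(np.uint8)
        crop = np.full((96, 96, 3), 230, dtype=np.uint8)
        crop[16:45, 16:45] = texture
        rec1 = tm.handcrafted_features(crop, mask, mpp=0.44)
        shifted_mask = np.roll(np.roll(mask, 25, axis=0), 30, axis=1)
        shifted_crop = np.full((96, 96, 3), 230, dtype=np.uint8)
        shifted_crop[41:70, 46:75] = texture
        rec2 = tm.handcrafted_features(shifted_crop, shifted_mask, mpp=0.44)
        keep = [n for n in rec1.index if not n.startswith("nuclei_")]
        pd.testing.assert_series_equal(rec1[keep], rec2[keep])

    def test_nuclei_percentile_pooling_order_invariant_and_monotone(self):
        mask = np.zeros((64, 64), dtype=bool)
        mask[4:60, 4:60] = True
        crop = np.full((64, 64, 3), 200, dtype=np.uint8)
        rng = np.random.default_rng(3)
        nuclei = []
        shades = rng.integers(60, 160, 12)
        for k, shade in enumerate(shades):
            m = np.zeros((64, 64), dtype=bool)
            cy, cx = 8 + 4 * k, 8 + 4 * k
            m[cy : cy + 3, cx : cx + 3] = True
            crop[m] = shade
            nuclei.append(m)
        rec_fwd = tm.handcrafted_features(crop, mask, nuclei_masks=nuclei, mpp=0.44)
        rec_rev = tm.handcrafted_features(crop, mask, nuclei_masks=nuclei[::-1], mpp=0.44)
        pd.testing.assert_series_equal(rec_fwd, rec_rev)
        # adding a nucleus brighter than all others raises the 100th
        # percentile of darkness and never lowers the other percentiles
        m = np.zeros((64, 64), dtype=bool)
        m[4:7, 56:59] = True
        crop2 = crop.copy()
        crop2[m] = 250
        rec_more = tm.handcrafted_features(
            crop2, mask, nuclei_masks=nuclei + [m], mpp=0.44
        )
        assert rec_more["nuclei_darkness_p100"] > rec_fwd["nuclei_darkness_p100"]
        for p in PERCENTILE_GRID:
            assert (
                rec_more[f"nuclei_darkness_p{p}"]
                >= rec_fwd[f"nuclei_darkness_p{p}"] - 1e-12
            )

    def test_determinism(self, vessel_slide):
        a = _extract(vessel_slide, 0)
        b = _extract(vessel_slide, 0)
        pd.testing.assert_series_equal(a, b)


class TestSchema:
    def test_profiles(self):
        pas = tm.make_schema("PAS")
        sr = tm.make_schema("SR")
        assert len(pas) == len(sr) + 2 + 2 * len(PERCENTILE_GRID)
        assert not [n for n in sr.names if sr.groups[n] == "nuclei"]
        assert len(set(pas.names)) == len(pas.names)

    def test_deep_and_g_columns(self):
        s = tm.make_schema("PAS", deep_width=8, include_g=True)
        assert sum(1 for n in s.names if s.groups[n] == "deep") == 8
        assert s.names[-1] == "g"

    def test_unknown_profile_rejected(self):
        with pytest.raises(ValueError):
            tm.make_schema("HE")


class TestDeepFeatures:
    def test_identity_extractor_constant_crop(self):
        crop = np.full((20, 24, 3), [10, 20, 30], dtype=float)
        vec = tm.deep_features(crop, lambda x: x)
        np.testing.assert_allclose(vec, [10, 20, 30])

    def test_deterministic(self, rng):
        crop = rng.random((16, 16, 3))
        v1 = tm.deep_features(crop, lambda x: x**2)
        v2 = tm.deep_features(crop, lambda x: x**2)
        np.testing.assert_array_equal(v1, v2)

    def test_background_dilution_closed_form(self):
        """Same content on a larger canvas dilutes the pooled mean by the
        exact area ratio (identity extractor)."""
        small = np.zeros((10, 10, 3))
        small[:, :, 0] = 1.0
        big = np.zeros((20, 20, 3))
        big[:10, :10] = small
        v_small = tm.deep_features(small, lambda x: x)
        v_big = tm.deep_features(big, lambda x: x)
        assert v_big[0] == pytest.approx(v_small[0] * 100 / 400)

    def test_small_crop_padded_and_flagged(self):
        crop = np.ones((4, 4, 3))
        vec, info = tm.deep_features(crop, lambda x: x, min_size=8, return_info=True)
        assert info["padded"]
        np.testing.assert_allclose(vec, 1.0)


class TestImputeNormalise:
    def test_impute_with_training_mean(self):
        train = pd.DataFrame({"f": [1.0, 2.0, 3.0]})
        test = pd.DataFrame({"f": [np.nan]})
        stats = tm.fit_impute_normalise(train)
        assert stats.impute_means["f"] == pytest.approx(2.0)
        out = tm.apply_impute_normalise(stats, test)
        # imputed at the training mean, hence normalised to exactly 0
        assert out["f"].iloc[0] == pytest.approx(0.0)

    def test_training_column_normalised_to_zero_mean_unit_sd(self):
        train = pd.DataFrame({"f": [1.0, 2.0, 3.0], "h": [0.0, 1.0, 4.0]})
        stats = tm.fit_impute_normalise(train)
        out = tm.apply_impute_normalise(stats, train)
        assert abs(out["f"].mean()) < 1e-9
        assert out["f"].std(ddof=0) == pytest.approx(1.0, abs=1e-9)

    def test_test_value_uses_population_sd(self):
        train = pd.DataFrame({"f": [1.0, 2.0, 3.0]})
        stats = tm.fit_impute_normalise(train)
        out = tm.apply_impute_normalise(stats, pd.DataFrame({"f": [4.0]}))
        assert out["f"].iloc[0] == pytest.approx((4.0 - 2.0) / 0.8165, abs=1e-3)

    def test_constant_feature_passes_as_zeros(self):
        train = pd.DataFrame({"c": [5.0, 5.0, 5.0], "f": [0.0, 1.0, 2.0]})
        stats = tm.fit_impute_normalise(train)
        out = tm.apply_impute_normalise(stats, train)
        assert (out["c"] == 0.0).all()
        assert bool(stats.constant["c"])

    def test_entirely_missing_training_feature_raises(self):
        train = pd.DataFrame({"f": [np.nan, np.nan], "h": [1.0, 2.0]})
        with pytest.raises(ValueError, match="f"):
            tm.fit_impute_normalise(train)

    def test_stats_frozen_across_splits(self):
        """Applying train-fitted stats to a shifted test split must use the
        training statistics, not refit (leakage guard)."""
        train = pd.DataFrame({"f": [0.0, 1.0, 2.0]})
        test = pd.DataFrame({"f": [10.0, 11.0, 12.0]})
        stats = tm.fit_impute_normalise(train)
        out = tm.apply_impute_normalise(stats, test)
        assert out["f"].mean() > 5  # clearly not re-centred on the test split


class TestAssemble:
    def test_identity_without_deep_or_g(self):
        hc = pd.DataFrame({"a": [1.0, 2.0]}, index=["i0", "i1"])
        out = tm.assemble_featureset(hc)
        pd.testing.assert_frame_equal(out, hc)

    def test_column_counts_add_up(self):
        idx = [f"i{k}" for k in range(5)]
        hc = pd.DataFrame(np.zeros((5, 98)), index=idx,
                          columns=[f"hc_{i}" for i in range(98)])
        deep = pd.DataFrame(np.zeros((5, 1024)), index=idx,
                            columns=[f"deep_{i}" for i in range(1024)])
        g = pd.Series(np.ones(5), index=idx)
        out = tm.assemble_featureset(hc, deep, g=g, include_g=True)
        assert out.shape[1] == 98 + 1024 + 1

    def test_empty_deep_matrix_is_noop(self):
        hc = pd.DataFrame({"a": [1.0]}, index=["i0"])
        out = tm.assemble_featureset(hc, pd.DataFrame(index=["i0"]))
        pd.testing.assert_frame_equal(out, hc)

    def test_mismatched_keys_listed_in_error(self):
        hc = pd.DataFrame({"a": [1.0]}, index=["i0"])
        deep = pd.DataFrame({"d": [1.0]}, index=["iX"])
        with pytest.raises(ValueError, match="iX"):
            tm.assemble_featureset(hc, deep)
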