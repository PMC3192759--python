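"""Phantom generator: geometry, determinism, planted effects, tables."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage, stats

from admri.image import LEFT_HIPPO, RIGHT_HIPPO, PARCEL_OFFSET, Image3D
from admri.phantom import (
    _FRAC,
    EffectSpec,
    GROUPS,
    make_template,
    sample_cohort,
    sample_feature_table,
    sample_subject,
    template_hippo_volume,
)
from admri.register import warp


class TestTemplate:
    def test_parcel_count_and_legend(self, template48):
        _, lm = template48
        parcel_names = [v for v in lm.legend.values() if v.startswith("parcel_")]
        assert len(parcel_names) == 84
        assert lm.n_parcels == 84
        # anatomical labels present alongside
        assert "left-hippocampus" in lm.legend.values()
        assert "CSF" in lm.legend.values()

    def test_determinism(self):
        a_img, a_lm = make_template((32, 32, 32), n_parcels=8, seed=11)
        b_img, b_lm = make_template((32, 32, 32), n_parcels=8, seed=11)
        assert np.array_equal(a_img.data, b_img.data)
        assert np.array_equal(a_lm.labels, b_lm.labels)
        assert np.array_equal(a_lm.parcels, b_lm.parcels)

    def test_hippocampus_volume_matches_analytic_ellipsoid(self, template48):
        _, lm = template48
        ext = 48.0
        semi = np.asarray(_FRAC["hippo_semi"]) * ext
        analytic = 4.0 / 3.0 * np.pi * np.prod(semi)
        for side in (LEFT_HIPPO, RIGHT_HIPPO):
            vox = float(lm.mask(side).sum())  # 1 mm isotropic
            assert abs(vox - analytic) / analytic < 0.05

    def test_hippocampus_two_components(self, template48):
        _, lm = template48
        structure = ndimage.generate_binary_structure(3, 1)
        _, n = ndimage.label(lm.hippocampus_mask, structure=structure)
        assert n == 2

    def test_too_small_image_names_structure(self):
        with pytest.raises(ValueError, match="structure"):
            make_template((12, 12, 12), n_parcels=4, seed=0)


class TestSubject:
    def test_identity_effects_equals_warped_template(self, template32):
        tpl, lm = template32
        s = sample_subject(tpl, lm, "HC", 75.0, "F", EffectSpec.identity(), seed=5)
        warped = warp(tpl, s.truth.deformation)
        assert np.allclose(s.image.data, warped.data)
        assert s.truth.hippo_volume_mm3 == template_hippo_volume(lm)

    def test_ad_volume_factor_recovered_from_labels(self, template48):
        tpl, lm = template48
        eff = EffectSpec()
        s = sample_subject(tpl, lm, "AD", 75.0, "F", eff, seed=3)
        ratio = s.truth.hippo_volume_voxel_mm3 / template_hippo_volume(lm)
        assert 0.82 <= ratio <= 0.88

    def test_same_seed_different_group_controlled_difference(self, template32):
        tpl, lm = template32
        eff = EffectSpec.identity(
            hippo_factor={"HC": 1.0, "S-MCI": 0.9, "P-MCI": 0.85, "AD": 0.8}
        )
        hc = sample_subject(tpl, lm, "HC", 75.0, "F", eff, seed=9)
        ad = sample_subject(tpl, lm, "AD", 75.0, "F", eff, seed=9)
        # same random deformation, difference confined to the group effect
        assert np.allclose(
            hc.truth.deformation.control_displacements,
            ad.truth.deformation.control_displacements,
        )
        # group effect is local: smoothing (+-2), interpolation (+-1) and the
        # random warp (~2.4 mm) spread the hippocampal difference by <= 7 vox
        diff = np.abs(hc.image.data - ad.image.data)
        hippo_zone = ndimage.binary_dilation(lm.hippocampus_mask, iterations=7)
        assert diff.max() > 1.0
        assert diff[~hippo_zone].max() < 1e-5

    def test_unreachable_factor_raises(self, template32):
        tpl, lm = template32
        eff = EffectSpec.identity(
            hippo_factor={"HC": 1.0, "S-MCI": 1.0, "P-MCI": 1.0, "AD": 1e-4}
        )
        with pytest.raises(ValueError, match="(unreachable|below 1 voxel)"):
            sample_subject(tpl, lm, "AD", 75.0, "F", eff, seed=0)


class TestCohort:
    def test_counts_and_determinism(self, template32):
        tpl, lm = template32
        eff = EffectSpec.identity()
        c1 = sample_cohort(tpl, lm, {"HC": 4, "AD": 4}, eff, seed=2)
        c2 = sample_cohort(tpl, lm, {"HC": 4, "AD": 4}, eff, seed=2)
        assert len(c1) == 8
        assert [s.group for s in c1] == ["HC"] * 4 + ["AD"] * 4
        for a, b in zip(c1, c2):
            assert np.array_equal(a.image.data, b.image.data)
            assert a.age == b.age and a.sex == b.sex

    def test_missing_cth_flag_rounding_rule(self, template32):
        tpl, lm = template32
        eff = EffectSpec.identity(missing_cth_fraction=0.13)
        cohort = sample_cohort(tpl, lm, {"HC": 5, "AD": 5}, eff, seed=4)
        # floor(10 * 0.13 + 0.5) = 1
        assert sum(s.cth_missing for s in cohort) == 1
        assert int(np.floor(100 * 0.13 + 0.5)) == 13  # the stated rule at n=100

    def test_monotone_ground_truth_ordering(self, template32):
        tpl, lm = template32
        cohort = sample_cohort(
            tpl, lm, {g: 25 for g in GROUPS}, EffectSpec(), seed=6
        )
        means = {
            g: np.mean([s.truth.hippo_volume_mm3 for s in cohort.by_group(g)])
            for g in GROUPS
        }
        assert means["HC"] > means["S-MCI"] > means["P-MCI"] > means["AD"]


class TestFeatureTable:
    def test_null_feature_rejection_rate(self):
        """d=0: two-sample t-tests reject at ~5% of feature/seed draws."""
        rejections, total = 0, 0
        for seed in range(8):
            X, y, _ = sample_feature_table(
                {"HC": 200, "AD": 200}, 25, informative=set(), effect_size_d=0.0,
                seed=seed,
            )
            a = X[y == "HC"]
            b = X[y == "AD"]
            _, p = stats.ttest_ind(a, b, axis=0)
            rejections += (p < 0.05).sum()
            total += 25
        rate = rejections / total
        assert 0.02 < rate < 0.09

    def test_no_signal_gives_chance_level_lda(self):
        from admri.classify import lda_fit, lda_predict

        X, y, _ = sample_feature_table(
            {"HC": 300, "AD": 300}, 5, informative=set(), effect_size_d=0.0, seed=1
        )
        Xt, yt, _ = sample_feature_table(
            {"HC": 300, "AD": 300}, 5, informative=set(), effect_size_d=0.0, seed=2
        )
        model = lda_fit(X.to_numpy(), y.to_numpy())
        ccr = 100.0 * (lda_predict(model, Xt.to_numpy()) == yt.to_numpy()).mean()
        assert abs(ccr - 50.0) < 8.0

    def test_bayes_rate_single_feature(self):
        """d=2 single feature: LDA approaches Phi(d/2) ~ 84.1%."""
        from admri.classify import lda_fit, lda_predict

        X, y, _ = sample_feature_table(
            {"HC": 2000, "AD": 2000}, 1, informative={0}, effect_size_d=2.0, seed=3
        )
        model = lda_fit(X.to_numpy(), y.to_numpy())
        ccr = 100.0 * (lda_predict(model, X.to_numpy()) == y.to_numpy()).mean()
        bayes = 100.0 * stats.norm.cdf(1.0)
        assert abs(ccr - bayes) < 2.0

    def test_covariate_terms_and_missing_spec(self):
        X, y, cov = sample_feature_table(
            {"HC": 150, "AD": 150}, 4, informative=set(), effect_size_d=0.0,
            age_slope=0.05, sex_offset=0.5,
            missing_spec={"columns": [0, 1], "fraction": 0.13}, seed=5,
        )
        # planted age slope recovered by regression on a noise feature
        ok = X["f002"].notna()
        slope = np.polyfit(cov.loc[ok, "age"], X.loc[ok, "f002"], 1)[0]
        assert abs(slope - 0.05) < 0.02
        assert int(X["f000"].isna().sum()) == int(np.floor(300 * 0.13 + 0.5))
        assert X["f002"].isna().sum() == 0

    def test_negative_effect_size_rejected(self):
        with pytest.raises(ValueError, match="effect size"):
            sample_feature_table({"HC": 5, "AD": 5}, 2, {0}, effect_size_d=-1.0)
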