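"""Cortical thickness: surface pairs, t-link distances, smoothing, ROIs."""

import numpy as np
import pytest

from admri.image import CSF, GM, WM, LabelMap
from admri.cth import (
    CorticalSurfacePair,
    cth_stat_roi_features,
    extract_surface_pair,
    flag_missing_cth,
    smooth_thickness,
    tlink_thickness,
)
from admri.phantom import EffectSpec, make_template, sample_cohort


def _shell_labels(shape, inner_semi, thickness, csf=2.0):
    c = (np.asarray(shape) - 1) / 2.0
    x = np.indices(shape).astype(float)
    inner_semi = np.asarray(inner_semi, dtype=float)
    r_in = np.sqrt((((x - c.reshape(3, 1, 1, 1)) / inner_semi.reshape(3, 1, 1, 1)) ** 2).sum(0))
    out_semi = inner_semi + thickness
    r_out = np.sqrt((((x - c.reshape(3, 1, 1, 1)) / out_semi.reshape(3, 1, 1, 1)) ** 2).sum(0))
    csf_semi = out_semi + csf
    r_csf = np.sqrt((((x - c.reshape(3, 1, 1, 1)) / csf_semi.reshape(3, 1, 1, 1)) ** 2).sum(0))
    lab = np.zeros(shape, dtype=np.int16)
    lab[r_csf <= 1] = CSF
    lab[r_out <= 1] = GM
    lab[r_in <= 1] = WM
    return LabelMap(lab)


class TestSurfacePair:
    def test_concentric_spheres_shell_thickness(self):
        """Spherical shell r=20 -> 23 mm: t-link distances are 3.0 mm."""
        lm = _shell_labels((56, 56, 56), (20, 20, 20), 3.0)
        pair = extract_surface_pair(lm)
        th = tlink_thickness(pair)
        assert abs(np.nanmean(th) - 3.0) < 0.1
        assert np.mean(np.abs(th[pair.valid] - 3.0) <= 0.3) > 0.95

    def test_concentric_ellipsoids_match_analytic(self):
        """Ellipsoidal shell with semi-axis gap 3: thickness within 15%."""
        lm = _shell_labels((56, 56, 56), (20, 16, 13), 3.0)
        pair = extract_surface_pair(lm)
        th = tlink_thickness(pair)
        ok = pair.valid
        assert np.mean(np.abs(th[ok] - 3.0) / 3.0 < 0.15) > 0.9
        assert abs(np.nanmean(th) - 3.0) / 3.0 < 0.05

    def test_node_count_stable_under_subvoxel_shift(self):
        lm1 = _shell_labels((48, 48, 48), (14, 14, 14), 3.0)
        # regenerate with the center shifted by a non-integer offset
        shape = (48, 48, 48)
        c = (np.asarray(shape) - 1) / 2.0 + np.array([0.4, -0.3, 0.6])
        x = np.indices(shape).astype(float)
        lab = np.zeros(shape, dtype=np.int16)
        for semi, code in (((19.0,) * 3, CSF), ((17.0,) * 3, GM), ((14.0,) * 3, WM)):
            r = np.sqrt((((x - c.reshape(3, 1, 1, 1)) / np.asarray(semi).reshape(3, 1, 1, 1)) ** 2).sum(0))
            lab[r <= 1] = code
        pair1 = extract_surface_pair(lm1)
        pair2 = extract_surface_pair(LabelMap(lab))
        assert abs(len(pair2) - len(pair1)) / len(pair1) < 0.05

    def test_missing_ribbon_raises(self):
        lab = np.zeros((16, 16, 16), dtype=np.int16)
        lab[4:12, 4:12, 4:12] = WM
        with pytest.raises(ValueError, match="GM"):
            extract_surface_pair(LabelMap(lab))


class TestTlink:
    def test_identical_nodes_zero(self):
        pts = np.random.default_rng(0).normal(size=(10, 3))
        pair = CorticalSurfacePair(pts, pts.copy(), np.ones(10, int), np.ones(10, bool))
        assert np.allclose(tlink_thickness(pair), 0.0)

    def test_three_four_five(self):
        inner = np.zeros((5, 3))
        outer = inner + np.array([1.0, 2.0, 2.0])
        pair = CorticalSurfacePair(inner, outer, np.ones(5, int), np.ones(5, bool))
        assert np.allclose(tlink_thickness(pair), 3.0)

    def test_flagged_nodes_are_nan(self):
        inner = np.zeros((4, 3))
        outer = inner + 1.0
        valid = np.array([True, False, True, True])
        th = tlink_thickness(CorticalSurfacePair(inner, outer, np.ones(4, int), valid))
        assert np.isnan(th[1]) and np.isfinite(th[[0, 2, 3]]).all()

    def test_planted_group_thinning_recovered(self, template32):
        """0.5 mm planted AD thinning appears in mean node thickness."""
        tpl, lm = template32
        eff = EffectSpec.identity(
            thickness_offset_mm={"HC": 0.0, "S-MCI": -0.2, "P-MCI": -0.35, "AD": -0.5},
            noise_sd=2.0,
        )
        cohort = sample_cohort(tpl, lm, {"HC": 6, "AD": 6}, eff, seed=31)
        means = {"HC": [], "AD": []}
        for s in cohort:
            pair = extract_surface_pair(s.labels)
            means[s.group].append(np.nanmean(tlink_thickness(pair)))
        diff = np.mean(means["HC"]) - np.mean(means["AD"])
        assert abs(diff - 0.5) < 0.15


class TestSmoothing:
    @pytest.fixture(scope="class")
    def sphere_pair(self):
        lm = _shell_labels((48, 48, 48), (16, 16, 16), 3.0)
        return extract_surface_pair(lm)

    def test_fwhm_zero_identity(self, sphere_pair):
        v = np.random.default_rng(1).normal(3, 0.2, len(sphere_pair))
        assert np.array_equal(smooth_thickness(sphere_pair, v, 0.0), v)

    def test_constant_preserved(self, sphere_pair):
        v = np.full(len(sphere_pair), 2.7)
        assert np.allclose(smooth_thickness(sphere_pair, v, 15.0), 2.7)

    def test_mean_preserved(self, sphere_pair):
        v = np.random.default_rng(2).normal(3, 0.3, len(sphere_pair))
        sv = smooth_thickness(sphere_pair, v, 12.0)
        assert abs(np.nanmean(sv) - v.mean()) < 1e-6

    @pytest.mark.parametrize("fwhm", [6.0, 8.0, 12.0])
    def test_kernel_width_matches_fwhm(self, sphere_pair, fwhm):
        """A smoothed point source is Gaussian with the requested FWHM."""
        from admri.cth import FWHM_TO_SIGMA

        v = np.zeros(len(sphere_pair))
        src = 10
        v[src] = 1.0
        sv = smooth_thickness(sphere_pair, v, fwhm)
        d = np.linalg.norm(sphere_pair.inner - sphere_pair.inner[src], axis=1)
        sel = (sv > sv.max() * 0.01) & (d < 12)
        slope = np.polyfit(d[sel] ** 2, np.log(sv[sel]), 1)[0]
        measured = np.sqrt(-1.0 / (2 * slope)) / FWHM_TO_SIGMA
        assert abs(measured - fwhm) / fwhm < 0.25


class TestStatRoiFeatures:
    def _toy(self, rng, n_nodes=60, thinning=0.0, parcels=3):
        parcel = np.repeat(np.arange(1, parcels + 1), n_nodes // parcels)
        data, groups = {}, {}
        for i in range(10):
            sid = f"HC_{i}"
            data[sid] = 3.0 + rng.normal(0, 0.1, n_nodes)
            groups[sid] = "HC"
        for i in range(10):
            sid = f"AD_{i}"
            v = 3.0 + rng.normal(0, 0.1, n_nodes)
            v[parcel == 1] -= thinning
            data[sid] = v
            groups[sid] = "AD"
        return data, groups, parcel

    def test_alpha_one_gives_parcel_means(self, rng):
        data, groups, parcel = self._toy(rng)
        ids = list(data)
        feats, parcels = cth_stat_roi_features(
            data, groups, ("HC", "AD"), ids[:2], ids[2:], parcel, alpha=1.0
        )
        sid = ids[0]
        for j, parc in enumerate(parcels):
            assert feats[sid][j] == pytest.approx(data[sid][parcel == parc].mean())

    def test_two_node_hand_example(self):
        parcel = np.array([1, 1])
        data = {}
        groups = {}
        rng = np.random.default_rng(3)
        for i in range(6):
            data[f"HC_{i}"] = np.array([3.0, 4.0]) + rng.normal(0, 0.01, 2)
            groups[f"HC_{i}"] = "HC"
            data[f"AD_{i}"] = np.array([1.9, 2.9]) + rng.normal(0, 0.01, 2)
            groups[f"AD_{i}"] = "AD"
        data["q"] = np.array([2.0, 3.0])
        groups["q"] = "AD"
        feats, _ = cth_stat_roi_features(
            data, groups, ("HC", "AD"), ["q"],
            [i for i in data if i != "q"], parcel, alpha=0.05,
        )
        assert feats["q"][0] == pytest.approx(2.5)

    def test_planted_thinning_selects_parcel(self, rng):
        data, groups, parcel = self._toy(rng, thinning=0.3)
        ids = list(data)
        stat = [i for i in ids if int(i.split("_")[1]) >= 3]
        feat_ids = [i for i in ids if int(i.split("_")[1]) < 3]
        _, parcels = cth_stat_roi_features(
            data, groups, ("HC", "AD"), feat_ids, stat, parcel, alpha=0.05
        )
        assert 1 in parcels

    def test_overlap_raises(self, rng):
        data, groups, parcel = self._toy(rng)
        ids = list(data)
        with pytest.raises(ValueError, match="overlap"):
            cth_stat_roi_features(
                data, groups, ("HC", "AD"), ids[:4], ids[2:], parcel
            )


class TestMissingFlag:
    def test_flagged_subject_features_nan(self, template32):
        tpl, lm = template32
        cohort = sample_cohort(tpl, lm, {"HC": 2}, EffectSpec.identity(), seed=8)
        s = cohort.subjects[0]
        s.features["CTH"] = np.ones(4)
        s = flag_missing_cth(s, failed=True)
        assert s.cth_missing
        assert np.isnan(s.features["CTH"]).all()

    def test_unflagged_subject_untouched(self, template32):
        tpl, lm = template32
        cohort = sample_cohort(tpl, lm, {"HC": 2}, EffectSpec.identity(), seed=8)
        s = cohort.subjects[1]
        s.features["CTH"] = np.ones(4)
        s = flag_missing_cth(s)
        assert not s.cth_missing
        assert np.isfinite(s.features["CTH"]).all()

    def test_cohort_missing_fraction_bookkeeping(self, template32):
        tpl, lm = template32
        eff = EffectSpec.identity(missing_cth_fraction=0.25)
        cohort = sample_cohort(tpl, lm, {"HC": 4, "AD": 4}, eff, seed=9)
        n_flagged = sum(s.cth_missing for s in cohort)
        assert n_flagged == int(np.floor(8 * 0.25 + 0.5))
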