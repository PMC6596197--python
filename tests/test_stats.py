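"""Inference-layer tests: intercept effects, t tests, CIs, ANOVA, clusters."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage, stats as sps

from seqobs import stats


class TestInterceptEffect:
    def test_zero_variance_predictor_gives_mean_outcome(self):
        post = np.array([1.0, 2.0, 3.0, 4.0])
        eff = stats.intercept_effect(np.zeros(4), post)
        assert eff.b0 == pytest.approx(post.mean())
        assert eff.ci_low <= eff.b0 <= eff.ci_high

    def test_textbook_four_point_closed_form(self):
        """Intercept equals ybar - b * xbar from the normal equations."""
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([2.1, 2.9, 4.2, 4.8])
        slope = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
        expected = y.mean() - slope * x.mean()
        eff = stats.intercept_effect(x, y)
        assert eff.b0 == pytest.approx(expected, abs=1e-10)
        assert eff.slope == pytest.approx(slope, abs=1e-10)
        assert eff.df == 2

    def test_centered_predictor_equals_paired_mean(self, rng):
        """With a zero-mean predictor the intercept is exactly mean(post)."""
        pre = rng.standard_normal(12)
        pre -= pre.mean()
        post = rng.standard_normal(12)
        eff = stats.intercept_effect(pre, post)
        assert eff.b0 == pytest.approx(post.mean(), abs=1e-10)

    def test_matches_statsmodels_oracle(self, rng):
        import statsmodels.api as sm

        pre = rng.standard_normal(16)
        post = 0.5 * pre + rng.standard_normal(16)
        eff = stats.intercept_effect(pre, post)
        fit = sm.OLS(post, sm.add_constant(pre)).fit()
        assert eff.b0 == pytest.approx(fit.params[0], abs=1e-10)
        assert eff.se == pytest.approx(fit.bse[0], abs=1e-10)
        assert eff.p == pytest.approx(fit.pvalues[0], abs=1e-10)
        lo, hi = fit.conf_int()[0]
        assert eff.ci_low == pytest.approx(lo, abs=1e-8)
        assert eff.ci_high == pytest.approx(hi, abs=1e-8)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            stats.intercept_effect(np.zeros(5), np.zeros(4))


class TestOneSampleT:
    def test_symmetric_values_give_half_p(self):
        res = stats.one_sample_t(np.array([-2.0, -1.0, 1.0, 2.0]), tail="one")
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(0.5)

    def test_t259_df15_one_tailed_p_about_01(self):
        """n=16 sample built to give t = 2.59 reproduces one-tailed p ~ .01."""
        n, target_t = 16, 2.59
        base = np.arange(n) - (n - 1) / 2.0
        base = base / base.std(ddof=1)  # mean 0, sd 1
        values = base + target_t / np.sqrt(n)
        res = stats.one_sample_t(values, tail="one")
        assert res.statistic == pytest.approx(target_t, abs=1e-9)
        assert res.p == pytest.approx(sps.t.sf(target_t, 15), abs=1e-12)
        assert round(res.p, 2) == 0.01

    def test_p_matches_distribution_oracle(self, rng):
        values = rng.standard_normal(10) + 0.4
        res = stats.one_sample_t(values, tail="two")
        assert res.p == pytest.approx(2 * sps.t.sf(abs(res.statistic), 9), abs=1e-12)

    def test_bonferroni_caps_at_one(self):
        res = stats.one_sample_t(np.array([-1.0, 1.0, -1.0, 1.1]), m_corrections=50)
        assert res.p == 1.0
        assert res.correction == "bonferroni"

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            stats.one_sample_t(np.ones(5))


class TestCiMultiplier:
    def test_df15_two_tailed_is_213(self):
        assert stats.ci_multiplier(15, tails=2) == 2.13

    def test_large_df_normal_limit(self):
        assert stats.ci_multiplier(10**6, tails=2) == 1.96

    def test_df15_one_tailed_matches_quantile(self):
        # the exact t quantile, 1.7531, rounds to 1.75
        assert stats.ci_multiplier(15, tails=1) == pytest.approx(
            round(float(sps.t.ppf(0.95, 15)), 2)
        )

    def test_invalid_df_rejected(self):
        with pytest.raises(ValueError):
            stats.ci_multiplier(0)


class TestWithinSubjectCi:
    def test_pure_subject_offsets_give_zero_width(self):
        base = np.array([1.0, 2.0, 3.0])
        data = base + np.array([[0.0], [5.0], [-3.0], [1.0]])
        out = stats.within_subject_ci(data)
        assert np.allclose(out["ci_high"] - out["ci_low"], 0.0, atol=1e-10)

    def test_single_condition_reduces_to_ordinary_ci(self, rng):
        x = rng.standard_normal((8, 1))
        out = stats.within_subject_ci(x)
        se = x.std(ddof=1) / np.sqrt(8)
        half = stats.ci_multiplier(7, 2) * se
        assert out["ci_high"][0] - out["mean"][0] == pytest.approx(half, abs=1e-10)

    def test_toy_matrix_matches_hand_computation(self):
        data = np.array([[1.0, 3.0], [2.0, 6.0], [0.0, 2.0], [1.0, 5.0]])
        centered = data - data.mean(axis=1, keepdims=True) + data.mean()
        sd = centered.std(axis=0, ddof=1) * np.sqrt(2.0)  # Morey factor C/(C-1)
        half = stats.ci_multiplier(3, 2) * sd / 2.0  # sqrt(n)=2
        out = stats.within_subject_ci(data)
        assert np.allclose(out["ci_high"] - out["mean"], half, atol=1e-10)

    def test_missing_cells_rejected(self):
        bad = np.array([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValueError):
            stats.within_subject_ci(bad)


def make_rm_data(rng, n_subj=8, effects=None):
    """Long-format 2x2 within data with optional injected effects."""
    effects = effects or {}
    rows = []
    for s in range(n_subj):
        offset = rng.standard_normal() * effects.get("subject_sd", 1.0)
        for scan in ("pre", "post"):
            for training in ("trained", "untrained"):
                val = offset + rng.standard_normal() * 0.3
                val += effects.get("scan", 0.0) * (scan == "post")
                val += effects.get("training", 0.0) * (training == "trained")
                rows.append(
                    {"subject": s, "scan": scan, "training": training, "ldc": val}
                )
    return pd.DataFrame(rows)


class TestRmAnova:
    def test_pure_subject_offsets_give_tiny_f(self, rng):
        df = make_rm_data(rng, effects={"subject_sd": 10.0})
        # make within-cell noise essentially zero relative to offsets
        tab = stats.rm_anova(df, dv="ldc", within=["scan", "training"])
        assert (tab.p > 0.01).all()  # no systematic within-subject effect

    def test_injected_main_effect_detected(self, rng):
        df = make_rm_data(rng, n_subj=12, effects={"training": 3.0})
        tab = stats.rm_anova(df, dv="ldc", within=["scan", "training"]).set_index("effect")
        assert tab.loc["training", "p"] < 1e-4
        assert tab.loc["training", "eta_p2"] > 0.8
        assert tab.loc["scan", "p"] > 0.01

    def test_matches_pingouin_reference(self, rng):
        pg = pytest.importorskip("pingouin")
        df = make_rm_data(rng, n_subj=10, effects={"training": 0.5, "scan": 0.3})
        tab = stats.rm_anova(df, dv="ldc", within=["scan", "training"]).set_index("effect")
        ref = pg.rm_anova(
            data=df, dv="ldc", within=["scan", "training"], subject="subject",
            effsize="np2", detailed=True,
        ).set_index("Source")
        for ours, theirs in [
            ("scan", "scan"),
            ("training", "training"),
            ("scan:training", "scan * training"),
        ]:
            assert tab.loc[ours, "F"] == pytest.approx(ref.loc[theirs, "F"], abs=1e-6)
            assert tab.loc[ours, "p"] == pytest.approx(ref.loc[theirs, "p_unc"], abs=1e-6)
            assert tab.loc[ours, "eta_p2"] == pytest.approx(ref.loc[theirs, "np2"], abs=1e-6)

    def test_incomplete_design_rejected(self, rng):
        df = make_rm_data(rng).iloc[:-1]
        with pytest.raises(ValueError):
            stats.rm_anova(df, dv="ldc", within=["scan", "training"])


class TestClusterInference:
    def _smooth_null_maps(self, rng, n_subj=12, shape=(8, 8, 8)):
        maps = rng.standard_normal((n_subj, *shape))
        return np.stack([ndimage.gaussian_filter(m, 1.2) for m in maps])

    def test_strong_blob_detected_and_localized(self, rng):
        shape = (10, 10, 10)
        blob = np.zeros(shape)
        blob[3:7, 3:7, 3:7] = 1.0
        maps = blob + 0.3 * self._smooth_null_maps(rng, 12, shape)
        out, clusters = stats.cluster_inference(maps, n_perm=200, seed=1)
        assert len(clusters) >= 1
        peak = clusters[0].peak_index
        assert blob[peak] == 1.0

    def test_cluster_smaller_than_kmin_not_reported(self, rng):
        shape = (8, 8, 8)
        maps = 0.05 * rng.standard_normal((12, *shape))
        maps[:, 2, 2, 2] += 5.0  # single-voxel effect, size 1 < 10
        out, clusters = stats.cluster_inference(maps, n_perm=150, seed=2)
        assert clusters == []
        assert np.all(out == 0)

    def test_null_maps_rarely_significant(self, rng):
        hits = 0
        n_sims = 40
        for i in range(n_sims):
            maps = self._smooth_null_maps(rng)
            _, clusters = stats.cluster_inference(maps, n_perm=150, seed=i)
            hits += bool(clusters)
        assert hits / n_sims <= 0.15  # loose bound; calibration suite is separate

    def test_too_few_subjects_or_perms_rejected(self, rng):
        maps = rng.standard_normal((5, 6, 6, 6))
        with pytest.raises(ValueError):
            stats.cluster_inference(maps)
        with pytest.raises(ValueError):
            stats.cluster_inference(rng.standard_normal((10, 6, 6, 6)), n_perm=50)
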