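import numpy as np
import pandas as pd
import pytest
from scipy import stats

import countvar as cv
import countvar.glm_engine as ge

from test_glm_engine import design_for


class TestPearsonGOF:
    def test_exact_fit_gives_zero(self):
        d = design_for(["a", "a", "a"])
        fit = ge.fit_gene([4, 4, 4], d)
        rec = cv.pearson_gof(fit)
        assert rec.X2 == pytest.approx(0.0, abs=1e-12)
        assert rec.low_count_flag  # mean 4 < 5

    def test_poisson_arithmetic(self):
        d = design_for(["a", "a"])
        fit = ge.fit_gene([4, 0], d)  # fitted = 2, 2
        assert fit.pearson_X2 == pytest.approx(4.0)

    def test_nb_denominator_arithmetic(self):
        from countvar.glm_engine import pearson_statistic
        x2 = pearson_statistic(np.array([[10.0]]), np.array([[2.0]]), "nb", 0.5)
        assert x2[0] == pytest.approx(64 / (2 + 0.5 * 4))  # = 16


class TestQQ:
    def test_observed_equal_to_theoretical_lies_on_identity(self):
        theo = stats.chi2.ppf((np.arange(1, 101) - 0.5) / 100, 22)
        qq = cv.qq_against_chisq(theo, 22)
        np.testing.assert_allclose(qq.observed, qq.theoretical, rtol=1e-12)

    def test_flag_counts_one_and_four_percent(self):
        qq = cv.qq_against_chisq(np.arange(1000.0), 22)
        assert qq.top1pct.sum() == 10
        assert qq.next4pct.sum() == 40
        # the flagged statistics are the largest ones
        assert qq.observed[qq.top1pct].min() >= qq.observed[qq.next4pct].max()

    def test_too_few_records_error(self):
        with pytest.raises(ValueError):
            cv.qq_against_chisq(np.arange(5.0), 22)


class TestTechnicalPairs:
    def test_identical_lanes_give_zero(self):
        tab = cv.technical_pair_gof(np.arange(20), np.arange(20), 1e6, 1e6)
        assert (tab["X2"] == 0).all()

    def test_split_arithmetic(self):
        tab = cv.technical_pair_gof(np.array([4]), np.array([0]), 1e6, 1e6)
        assert tab["X2"].iloc[0] == pytest.approx(4.0)

    def test_zero_pair_totals_excluded_and_counted(self):
        tab = cv.technical_pair_gof(np.array([1, 0, 2]), np.array([3, 0, 0]), 1e6, 1e6)
        assert len(tab) == 2
        assert tab.attrs["excluded"] == 1

    def test_poisson_pairs_match_chisq_one(self):
        """Pair statistics are chi-square(1) under Poisson technical noise."""
        rng = np.random.default_rng(13)
        lam = 10 ** rng.uniform(1, 3, 10000)
        N1, N2 = 8e6, 6e6
        y1 = rng.poisson(lam)
        y2 = rng.poisson(lam * N2 / N1)
        tab = cv.technical_pair_gof(y1, y2, N1, N2)
        big = tab[tab["total"] >= 20]
        ks = stats.kstest(big["X2"], stats.chi2(1).cdf).statistic
        assert ks < 0.02


class TestMVA:
    def test_identical_scaled_lanes_give_zero_m(self):
        y = np.arange(1, 200)
        out = cv.mva(y, y, 1e6, 1e6)
        np.testing.assert_allclose(out["M"], 0.0, atol=1e-12)
        np.testing.assert_allclose(out["smooth"], 0.0, atol=1e-12)

    def test_depth_scaling_symmetry(self):
        y = np.arange(1, 100)
        out = cv.mva(y, 2 * y, 1e6, 2e6)
        np.testing.assert_allclose(out["M"], 0.0, atol=1e-12)

    def test_unbiased_poisson_pair_has_flat_smoother(self):
        # full-transcriptome complement at study lane depth
        rng = np.random.default_rng(14)
        lam = 10 ** rng.uniform(0.0, 5.0, 17000) * 0.05
        y1, y2 = rng.poisson(lam), rng.poisson(lam)
        out = cv.mva(y1, y2, 1e6, 1e6)
        order = np.argsort(out["A"].to_numpy())
        smooth = out["smooth"].to_numpy()[order]
        for dec in np.array_split(smooth, 10):
            assert abs(dec.mean()) < 0.05

    def test_too_few_positive_genes_error(self):
        with pytest.raises(ValueError, match="10"):
            cv.mva(np.array([1, 0, 3]), np.array([0, 2, 5]), 1e6, 1e6)


class TestSpearman:
    def test_perfect_and_reversed(self):
        y = np.array([3, 1, 4, 1, 5, 9, 2, 6])
        assert cv.spearman_pair(y, y) == pytest.approx(1.0)
        assert cv.spearman_pair(np.arange(8), np.arange(8)[::-1]) == pytest.approx(-1.0)

    def test_constant_vector_errors(self):
        with pytest.raises(ValueError, match="constant"):
            cv.spearman_pair(np.ones(5), np.arange(5))

    def test_simulated_deep_pair_is_highly_correlated(self, study_design):
        cfg = cv.SimConfig(n_genes=5000, dispersion=cv.DispersionSpec.point(0.1), seed=32)
        m, d, _ = cv.simulate_experiment(cfg, design=study_design)
        lanes = d.ok()
        pair = lanes[lanes["flowcell_id"] == "FC08"]["lane_id"].iloc[:2]
        i1, i2 = [list(m.sample_ids).index(s) for s in pair]
        y1, y2 = m.counts[:, i1], m.counts[:, i2]
        pos = (y1 > 0) & (y2 > 0)  # the genes shown on the log-scale plots
        assert cv.spearman_pair(y1[pos], y2[pos]) > 0.99


class TestMeanVariance:
    def test_group_points_arithmetic(self):
        Y = np.array([[5, 5, 5, 2, 4]])
        groups = np.array(["a", "a", "a", "b", "b"])
        pts = cv.group_mean_variance(Y, groups)
        a = pts[pts["group"] == "a"].iloc[0]
        b = pts[pts["group"] == "b"].iloc[0]
        assert (a["xbar"], a["s2"]) == (5.0, 0.0)
        assert (b["xbar"], b["s2"]) == (3.0, 2.0)

    def test_single_subject_group_errors(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            cv.group_mean_variance(np.ones((2, 3)), np.array(["a", "a", "b"]))

    def test_quadratic_slope_single_point(self):
        pts = pd.DataFrame({"xbar": [10.0], "s2": [110.0]})
        assert cv.fit_variance_laws(pts).phi_quadratic == pytest.approx(1.0)

    def test_exact_linear_law_recovers_k(self):
        x = np.linspace(1, 50, 20)
        pts = pd.DataFrame({"xbar": x, "s2": 2 * x})
        fit = cv.fit_variance_laws(pts)
        assert fit.k_linear == pytest.approx(2.0)

    def test_nb_cloud_straddles_the_quadratic_curve(self, nb_bundle):
        subj = nb_bundle["subj"]
        groups = nb_bundle["subjects"]["group"].to_numpy()
        const = nb_bundle["norm"].constants.reindex(list(subj.sample_ids)).to_numpy()
        pts = cv.group_mean_variance(subj, groups, const)
        big = pts[pts["xbar"] > 50]
        expected = big["xbar"] + 0.131 * big["xbar"] ** 2
        above = (big["s2"] > expected).mean()
        assert 0.25 < above < 0.75


class TestPhiVsMean:
    def test_no_trend_on_homogeneous_dispersion(self, zero_block_bundle):
        mod = zero_block_bundle["moderated"]
        zmask = zero_block_bundle["zero_mask"]
        mean_counts = zero_block_bundle["subj"].counts.mean(axis=1)
        out = cv.phi_vs_mean(mod[~zmask], mean_counts[~zmask])
        assert abs(out.attrs["trend_slope"]) < 0.01
        assert not out["flagged"].any()

    def test_zero_block_flags_sit_at_mid_high_means(self, zero_block_bundle):
        mod = zero_block_bundle["moderated"]
        zmask = zero_block_bundle["zero_mask"]
        mean_counts = zero_block_bundle["subj"].counts.mean(axis=1)
        out = cv.phi_vs_mean(mod, mean_counts, zero_block=zmask)
        flagged = out[out["flagged"]]
        rest = out[~out["flagged"]]
        assert flagged["phi"].median() > rest["phi"].median()
        assert flagged["log10_mean"].median() > rest["log10_mean"].median()


class TestOverAndUnderFitting:
    def test_pergene_phi_concentrates_the_gof_distribution(self, nb_bundle):
        """Fitting phi per gene over-adapts: X2 collapses toward its df."""
        subj, dinfo, off = nb_bundle["subj"], nb_bundle["design_info"], nb_bundle["offsets"]
        pergene = cv.estimate_phi_pergene(subj, dinfo, off)
        f_pg = ge.fit_all(subj, dinfo, off, family="nb",
                          phi=np.nan_to_num(pergene, nan=0.131))
        f_true = ge.fit_all(subj, dinfo, off, family="nb", phi=0.131)
        sel = subj.counts.mean(axis=1) >= 5
        iqr_pg = np.subtract(*np.percentile(f_pg.pearson_X2[sel], [75, 25]))
        iqr_true = np.subtract(*np.percentile(f_true.pearson_X2[sel], [75, 25]))
        assert iqr_pg < 0.8 * iqr_true

    def test_poisson_fit_to_nb_data_inflates_gof_with_the_mean(self, nb_bundle):
        subj, dinfo, off = nb_bundle["subj"], nb_bundle["design_info"], nb_bundle["offsets"]
        fits = ge.fit_all(subj, dinfo, off, family="poisson")
        mean_c = subj.counts.mean(axis=1)
        lo = fits.pearson_X2[(mean_c > 1) & (mean_c < 10)]
        hi = fits.pearson_X2[mean_c > 1000]
        assert np.median(hi) > 10 * np.median(lo)
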