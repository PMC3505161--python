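import numpy as np
import pandas as pd
import pytest
from scipy import optimize
from scipy.special import gammaln

import countvar as cv
import countvar.glm_engine as ge


def design_for(groups, **factors):
    table = pd.DataFrame({"group": groups, **factors})
    blocking = next(iter(
        {"flowcell_id": "flow_cell", "lane_pair_id": "lane_pair",
         "batch_id": "batch"}[k] for k in factors), "none")
    return ge.build_design(table, cv.ModelSpec(blocking=blocking))


class TestBuildDesign:
    def test_group_only_has_one_model_df(self):
        d = design_for(["high"] * 12 + ["low"] * 11)
        assert d.p == 1
        assert d.matrix.shape == (23, 2)

    @pytest.mark.parametrize("blocking,expected_p", [
        ("none", 1), ("lane_pair", 4), ("flow_cell", 13), ("batch", 6),
    ])
    def test_study_replica_model_df(self, study_design, blocking, expected_p):
        """Replicates the study's accounting: p = 1, 4, 13 (and 6 for batch)."""
        st = cv.subject_table(study_design)
        d = ge.build_design(st, cv.ModelSpec(blocking=blocking))
        assert d.p == expected_p

    def test_confounded_blocking_raises_naming_columns(self):
        with pytest.raises(ValueError, match="rank deficient"):
            design_for(["high", "high", "low", "low"],
                       flowcell_id=["A", "A", "B", "B"])

    def test_empty_levels_are_pruned(self):
        d = design_for(["high", "low", "high", "low"],
                       batch_id=["B1", "B1", "B2", "B2"])
        assert d.p == 2  # group + one batch contrast


class TestClosedForms:
    def test_intercept_only_poisson_fits_the_sample_mean(self):
        d = design_for(["a", "a", "a"])
        fit = ge.fit_gene([2, 4, 6], d)
        np.testing.assert_allclose(fit.fitted, 4.0, rtol=1e-8)

    @pytest.mark.parametrize("phi", [0.1, 0.5, 2.0])
    def test_intercept_only_nb_also_fits_the_sample_mean(self, phi):
        d = design_for(["a", "a", "a"])
        fit = ge.fit_gene([2, 4, 6], d, family="nb", phi_fixed=phi)
        np.testing.assert_allclose(fit.fitted, 4.0, rtol=1e-7)

    def test_group_model_fits_group_means(self):
        d = design_for(["a", "a", "b", "b"])
        fit = ge.fit_gene([2, 4, 10, 20], d)
        np.testing.assert_allclose(fit.fitted, [3, 3, 15, 15], rtol=1e-8)

    def test_fitted_respect_the_offset(self):
        d = design_for(["a", "a", "b", "b"])
        off = np.array([0.0, 0.5, -0.5, 1.0])
        fit = ge.fit_gene([5, 8, 4, 11], d, offsets=off)
        log_rate = np.log(fit.fitted) - off
        assert log_rate[0] == pytest.approx(log_rate[1], rel=1e-8)
        assert log_rate[2] == pytest.approx(log_rate[3], rel=1e-8)


class TestOracleEquivalence:
    def test_irls_matches_direct_likelihood_maximization(self):
        """IRLS coefficients agree with BFGS on the explicit log-likelihood."""
        rng = np.random.default_rng(7)
        d = design_for(["high"] * 12 + ["low"] * 11)
        X = d.matrix
        off = rng.normal(0, 0.3, 23)
        worst = 0.0
        for _ in range(10):
            lam = rng.uniform(5, 200) * np.exp(rng.normal(0, 0.5) * X[:, 1] + off)
            phi = rng.uniform(0.05, 0.3)
            y = rng.poisson(lam * rng.gamma(1 / phi, phi, 23)).astype(float)
            for fam, ph in (("poisson", 0.0), ("nb", phi)):
                fit = ge.fit_gene(y, d, off, family=fam, phi_fixed=ph)

                def negll(b):
                    mu = np.exp(np.clip(X @ b + off, -30, 30))
                    if ph == 0:
                        return -(y * np.log(mu) - mu).sum()
                    r = 1 / ph
                    return -(gammaln(y + r) - gammaln(r) + r * np.log(r / (r + mu))
                             + y * np.log(mu / (r + mu))).sum()

                res = optimize.minimize(negll, fit.coefficients, method="BFGS",
                                        options={"gtol": 1e-10})
                worst = max(worst, np.abs(res.x - fit.coefficients).max())
        assert worst < 1e-6

    def test_agrees_with_statsmodels_poisson(self, nb_bundle):
        import statsmodels.api as sm
        subj, dinfo, off = nb_bundle["subj"], nb_bundle["design_info"], nb_bundle["offsets"]
        checked = 0
        for g in range(30):
            y = subj.counts[g].astype(float)
            groups = nb_bundle["subjects"]["group"].to_numpy()
            if min(y[groups == "high"].sum(), y[groups == "low"].sum()) < 5:
                continue  # separation: coefficients unbounded, fits still agree
            fit = ge.fit_gene(y, dinfo, off)
            ref = sm.GLM(y, dinfo.matrix, family=sm.families.Poisson(), offset=off).fit()
            np.testing.assert_allclose(fit.coefficients, ref.params, atol=1e-6)
            checked += 1
        assert checked >= 10

    def test_poisson_and_nb_phi_zero_coincide(self):
        d = design_for(["a", "a", "b", "b", "b"])
        y = [3, 7, 11, 9, 14]
        f1 = ge.fit_gene(y, d, family="poisson")
        f2 = ge.fit_gene(y, d, family="nb", phi_fixed=0.0)
        np.testing.assert_allclose(f1.fitted, f2.fitted, rtol=1e-9)
        assert f1.pearson_X2 == pytest.approx(f2.pearson_X2, rel=1e-9)


class TestFitAll:
    def test_batch_returns_one_fit_per_gene(self, nb_bundle):
        subj, dinfo, off = nb_bundle["subj"], nb_bundle["design_info"], nb_bundle["offsets"]
        fits = ge.fit_all(subj, dinfo, off)
        assert len(fits) == subj.n_genes
        assert fits.converged.mean() > 0.99
        one = fits[3]
        assert one.gene_id == str(subj.gene_ids[3])
        assert one.df == 22 and one.df_resid == 21

    def test_relabelled_blocking_levels_leave_fitted_means_unchanged(self, nb_bundle):
        subj = nb_bundle["subj"]
        st = nb_bundle["subjects"].copy()
        spec = cv.ModelSpec(blocking="batch")
        d1 = ge.build_design(st, spec)
        st2 = st.assign(batch_id=st["batch_id"].map(lambda b: f"Z{b}"))
        d2 = ge.build_design(st2, spec)
        small = cv.CountMatrix(subj.gene_ids[:20], subj.sample_ids, subj.counts[:20])
        f1 = ge.fit_all(small, d1, nb_bundle["offsets"])
        f2 = ge.fit_all(small, d2, nb_bundle["offsets"])
        np.testing.assert_allclose(f1.fitted, f2.fitted, rtol=1e-7)

    def test_all_zero_gene_is_flagged_not_fatal(self):
        d = design_for(["a", "a", "b", "b"])
        Y = np.array([[0, 0, 0, 0], [1, 2, 3, 4]])
        fits = ge.fit_all(Y, d)
        assert fits.degenerate[0] and not fits.degenerate[1]
        assert np.isfinite(fits.pearson_X2).all()
        assert fits.pearson_X2[0] == 0.0

    def test_od_poisson_scale_estimated_post_fit(self):
        d = design_for(["a", "a", "a", "a"])
        fit = ge.fit_gene([0, 4, 0, 4], d, family="od_poisson")
        # Poisson X2 = 4*(2^2/2) = 8, df_resid = 3, so k = 8/3
        assert fit.dispersion_used == pytest.approx(8 / 3)
        assert fit.pearson_X2 == pytest.approx(3.0)  # X2/k = df_resid by construction

    def test_non_convergence_is_flagged_but_fit_returned(self):
        d = design_for(["a", "a", "b", "b"])
        fits = ge.fit_all(np.array([[1, 40, 2, 300]]), d, max_iter=1)
        assert not fits.converged[0]
        assert np.isfinite(fits.pearson_X2[0])


class TestBlockingEffects:
    def test_depth_regime_step_visible_without_offset_and_removed_with(self, study_design):
        cfg = cv.SimConfig(n_genes=800, dispersion=cv.DispersionSpec.point(0.05), seed=6)
        m, d, truth = cv.simulate_experiment(cfg, design=study_design)
        subj = cv.sum_lane_pairs(cv.filter_expressed(m), d)
        st = cv.subject_table(d).loc[list(subj.sample_ids)]
        dinfo = ge.build_design(st, cv.ModelSpec(blocking="flow_cell"))

        eff = ge.collect_blocking_effects(ge.fit_all(subj, dinfo), "flow_cell")
        med = eff.median()
        pre = [c for c in med.index if int(c[2:]) <= 5]
        post = [c for c in med.index if int(c[2:]) > 5]
        step = med[post].mean() - med[pre].mean()
        # oracle: the generator's own depth-regime ratio
        targets = truth.lane_targets
        fc = d.ok()["flowcell_id"].str[2:].astype(int).to_numpy()
        expected = np.log(targets[fc > 5].mean() / targets[fc <= 5].mean())
        assert step == pytest.approx(expected, abs=0.15)

        off = cv.make_offsets(cv.total_count(subj), subj.sample_ids)
        eff_off = ge.collect_blocking_effects(ge.fit_all(subj, dinfo, off), "flow_cell")
        assert eff_off.median().abs().max() < 0.1

    def test_requesting_an_absent_factor_errors(self, nb_bundle):
        fits = ge.fit_all(nb_bundle["subj"], nb_bundle["design_info"],
                          nb_bundle["offsets"])
        with pytest.raises(ValueError, match="blocking factor"):
            ge.collect_blocking_effects(fits, "flow_cell")
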