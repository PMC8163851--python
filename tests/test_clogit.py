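import numpy as np
import pandas as pd
import pytest
from scipy import stats

from firegest import ConditionalLogit, lrt, simulate_matched_sets
from firegest.clogit import (
    fit_categorical_exposure,
    fit_nonlinear_exposure,
    fit_subgroup_interaction,
)
from firegest.design import TermSpec

from conftest import make_sets


def _binary_pairs(n_case_exposed, n_control_exposed):
    """1:1 pairs discordant on a binary exposure."""
    recs = []
    sid = 0
    for _ in range(n_case_exposed):
        recs += [(sid, 1, {"x": 1.0}), (sid, 0, {"x": 0.0})]
        sid += 1
    for _ in range(n_control_exposed):
        recs += [(sid, 1, {"x": 0.0}), (sid, 0, {"x": 1.0})]
        sid += 1
    return make_sets(recs)


class TestConditionalLikelihood:
    def test_discordant_pair_closed_form(self):
        """For 1:1 binary exposure the conditional MLE is the
        discordant-pair ratio: 10 exposed-case vs 5 exposed-control
        pairs give OR = 2 exactly."""
        df = _binary_pairs(10, 5)
        res = ConditionalLogit.from_dataframe(df, [TermSpec("x")]).fit()
        assert res.converged
        assert np.isclose(np.exp(res.params["x"]), 2.0, atol=1e-8)

    def test_grid_search_oracle_two_coefficients(self, rng):
        """Newton solution matches an iteratively refined dense grid
        search of the exact conditional likelihood on small sets."""
        df = simulate_matched_sets(
            120,
            {"fire": 0.4, "z": -0.6},
            rng,
            n_pregnancies=3,
            covariate_sampler=lambda r, s: pd.DataFrame(
                {"fire": r.lognormal(0, 0.7, s), "z": r.normal(0, 1, s)}
            ),
        )
        model = ConditionalLogit.from_dataframe(df, [TermSpec("fire"), TermSpec("z")])
        res = model.fit()
        best = np.zeros(2)
        width = 1.5
        for _ in range(7):
            g0 = np.linspace(best[0] - width, best[0] + width, 21)
            g1 = np.linspace(best[1] - width, best[1] + width, 21)
            ll = np.array([[model.loglike(np.array([a, b])) for b in g1] for a in g0])
            i, j = np.unravel_index(np.argmax(ll), ll.shape)
            best = np.array([g0[i], g1[j]])
            width = 2 * (2 * width / 20)
        fitted = res.params[["fire", "z"]].to_numpy()
        assert np.max(np.abs(fitted - best)) < 1e-4

    def test_set_constant_covariate_cancels(self, rng):
        """A covariate constant within every set is flagged
        non-identifiable and leaves the other estimates unchanged —
        the design's core identification property."""
        df = simulate_matched_sets(300, {"fire": 0.3}, rng)
        df["village_income"] = df.groupby("set_id")["fire"].transform("mean") * 3.1
        with_const = ConditionalLogit.from_dataframe(
            df, [TermSpec("fire"), TermSpec("village_income")]
        )
        assert with_const.nonidentifiable == ["village_income"]
        res_with = with_const.fit()
        res_without = ConditionalLogit.from_dataframe(df, [TermSpec("fire")]).fit()
        assert np.isnan(res_with.params["village_income"])
        assert np.isclose(res_with.params["fire"], res_without.params["fire"], atol=1e-8)
        assert np.isclose(res_with.llf, res_without.llf, atol=1e-8)

    def test_control_order_invariance(self, rng):
        df = simulate_matched_sets(200, {"fire": 0.3}, rng, n_pregnancies=4)
        res1 = ConditionalLogit.from_dataframe(df, [TermSpec("fire")]).fit()
        shuffled = (
            df.sample(frac=1.0, random_state=7)
            .sort_values("set_id", kind="stable")
            .reset_index(drop=True)
        )
        res2 = ConditionalLogit.from_dataframe(shuffled, [TermSpec("fire")]).fit()
        assert np.isclose(res1.params["fire"], res2.params["fire"], atol=1e-10)
        assert np.isclose(res1.llf, res2.llf, atol=1e-10)

    def test_optimum_properties(self, rng):
        df = simulate_matched_sets(400, {"fire": 0.25}, rng)
        model = ConditionalLogit.from_dataframe(df, [TermSpec("fire")])
        res = model.fit()
        beta_hat = res.params[["fire"]].to_numpy()
        assert res.llf >= model.loglike(np.zeros(1))
        # score ~ 0 and likelihood drops in both directions around the MLE
        eps = 1e-4
        assert model.loglike(beta_hat + eps) < res.llf
        assert model.loglike(beta_hat - eps) < res.llf
        # covariance symmetric positive definite; CI brackets the estimate
        cov = res.cov_params.to_numpy()
        assert np.allclose(cov, cov.T)
        assert np.all(np.linalg.eigvalsh(cov) > 0)
        ci = res.conf_int()
        assert ci.loc["fire", "lower"] < res.params["fire"] < ci.loc["fire", "upper"]

    def test_statsmodels_cross_check(self, rng):
        """Independent implementation agrees on coefficients and SEs."""
        sm_cond = pytest.importorskip("statsmodels.discrete.conditional_models")
        df = simulate_matched_sets(
            500,
            {"fire": 0.3, "z": -0.4},
            rng,
            covariate_sampler=lambda r, s: pd.DataFrame(
                {"fire": r.lognormal(0, 0.8, s), "z": r.normal(0, 1, s)}
            ),
        )
        ours = ConditionalLogit.from_dataframe(df, [TermSpec("fire"), TermSpec("z")]).fit()
        theirs = sm_cond.ConditionalLogit(
            df["is_case"].to_numpy(),
            df[["fire", "z"]].to_numpy(),
            groups=df["set_id"].to_numpy(),
        ).fit(disp=False)
        assert np.allclose(ours.params[["fire", "z"]], theirs.params, atol=1e-5)
        assert np.allclose(ours.bse[["fire", "z"]], theirs.bse, atol=1e-5)

    def test_input_validation(self):
        df = make_sets([(0, 1, {"x": 1.0}), (0, 1, {"x": 0.0}), (1, 1, {"x": 1.0})])
        with pytest.raises(ValueError, match="exactly one case"):
            ConditionalLogit.from_dataframe(df, [TermSpec("x")])


class TestLRT:
    def test_identical_models_give_zero(self, rng):
        df = simulate_matched_sets(150, {"fire": 0.3}, rng)
        res = ConditionalLogit.from_dataframe(df, [TermSpec("fire")]).fit()
        stat, dof, p = lrt(res, res)
        assert stat == 0.0 and dof == 0 and p == 1.0

    def test_chi2_reference_value(self, rng):
        """p-value comes from the chi-square upper tail: 3.8415 on 1 df
        sits at the 5 % point."""
        assert np.isclose(stats.chi2.sf(3.8415, 1), 0.05, atol=1e-4)
        df = simulate_matched_sets(
            300,
            {"fire": 0.3, "z": 0.2},
            rng,
            covariate_sampler=lambda r, s: pd.DataFrame(
                {"fire": r.lognormal(0, 0.8, s), "z": r.normal(0, 1, s)}
            ),
        )
        small = ConditionalLogit.from_dataframe(df, [TermSpec("fire")]).fit()
        big = ConditionalLogit.from_dataframe(df, [TermSpec("fire"), TermSpec("z")]).fit()
        stat, dof, p = lrt(small, big)
        assert dof == 1
        assert np.isclose(p, stats.chi2.sf(stat, 1))

    def test_reversed_nesting_rejected(self, rng):
        df = simulate_matched_sets(
            150,
            {"fire": 0.3, "z": 0.2},
            rng,
            covariate_sampler=lambda r, s: pd.DataFrame(
                {"fire": r.lognormal(0, 0.8, s), "z": r.normal(0, 1, s)}
            ),
        )
        small = ConditionalLogit.from_dataframe(df, [TermSpec("fire")]).fit()
        big = ConditionalLogit.from_dataframe(df, [TermSpec("fire"), TermSpec("z")]).fit()
        with pytest.raises(ValueError):
            lrt(big, small)


def _group_sampler(rates):
    def sampler(r, s):
        return pd.DataFrame(
            {
                "fire": r.lognormal(0, 0.8, s),
                "grp": r.choice(list(rates), size=s),
            }
        )
    return sampler


class TestSubgroupInteraction:
    def test_recovers_group_specific_effects(self, rng):
        truth = {"young": 0.05, "old": 0.25}

        def sampler(r, s):
            fire = r.lognormal(0, 0.8, s)
            grp = r.choice(["young", "old"], size=s)
            return pd.DataFrame(
                {"fire": fire, "grp": grp, "fire_x_old": fire * (grp == "old")}
            )

        df = simulate_matched_sets(
            8000,
            {"fire": truth["young"], "fire_x_old": truth["old"] - truth["young"]},
            rng,
            covariate_sampler=sampler,
        )
        sg = fit_subgroup_interaction(
            df, [TermSpec("fire")], "fire", "grp", levels=["young", "old"]
        )
        for lev in truth:
            est = sg.table.loc[lev, "coef"]
            se = sg.table.loc[lev, "se"]
            assert abs(est - truth[lev]) < 3.5 * se
        assert sg.p_heterogeneity < 0.05
        assert sg.lrt_df == 1

    def test_single_group_rejected(self, rng):
        df = simulate_matched_sets(100, {"fire": 0.3}, rng)
        df["grp"] = "only"
        with pytest.raises(ValueError):
            fit_subgroup_interaction(df, [TermSpec("fire")], "fire", "grp")

    def test_empty_group_rejected(self, rng):
        df = simulate_matched_sets(100, {"fire": 0.3}, rng)
        df["grp"] = "a"
        with pytest.raises(ValueError, match="no events"):
            fit_subgroup_interaction(
                df, [TermSpec("fire")], "fire", "grp", levels=["a", "b"]
            )

    def test_type_one_error_calibration(self):
        """Without a true interaction the heterogeneity test rejects at
        roughly its nominal level."""
        rejections = 0
        n_rep = 40
        for rep in range(n_rep):
            r = np.random.default_rng(1000 + rep)
            df = simulate_matched_sets(
                600, {"fire": 0.2}, r, covariate_sampler=_group_sampler({"a": 0, "b": 0})
            )
            sg = fit_subgroup_interaction(df, [TermSpec("fire")], "fire", "grp")
            rejections += sg.p_heterogeneity < 0.05
        assert rejections <= 7  # binomial(40, .05): P(>7) < 1e-3


class TestNonlinearExposure:
    def test_linear_truth_within_band(self, rng):
        """Under a linear log-odds the spline curve stays within its CI
        of the straight line and is anchored at zero exposure."""
        beta = 0.3
        df = simulate_matched_sets(4000, {"fire": beta}, rng)
        curve = fit_nonlinear_exposure(df, [TermSpec("fire")], "fire", spline_df=3)
        assert curve.log_or[0] == pytest.approx(0.0, abs=1e-12)
        line = beta * curve.grid
        inside = (curve.log_or_lower <= line) & (line <= curve.log_or_upper)
        assert inside.mean() > 0.9

    def test_convex_truth_detected(self):
        """A super-linear exposure-response is flagged by the linearity
        LRT in most replicates."""
        hits = 0
        n_rep = 12
        for rep in range(n_rep):
            r = np.random.default_rng(2000 + rep)
            df = simulate_matched_sets(
                2500,
                {"fire": 0.0, "fire_sq": 0.12},
                r,
                covariate_sampler=lambda rr, s: (
                    lambda f: pd.DataFrame({"fire": f, "fire_sq": f**2})
                )(rr.lognormal(0, 0.8, s)),
            )
            curve = fit_nonlinear_exposure(df, [TermSpec("fire")], "fire", spline_df=3)
            hits += curve.p_nonlinearity < 0.05
        assert hits / n_rep > 0.5

    def test_categorical_bins_reference(self, rng):
        df = simulate_matched_sets(2000, {"fire": 0.3}, rng)
        bins = [0, 0.5, 1.5, np.inf]
        table = fit_categorical_exposure(df, [TermSpec("fire")], "fire", bins)
        assert table.loc[0, "or"] == 1.0
        assert table["or"].is_monotonic_increasing  # rising exposure, rising odds
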