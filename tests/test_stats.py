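"""Event coding, mixed Cox deviance tests, and search mixed models."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sp_stats

from camotype import stats
from camotype._coxfrailty import fit_cox_frailty
from camotype.design import build_field_schedule, build_search_schedule
from camotype.simulate import DetectionModel, simulate_field, simulate_search
from camotype.typicality import ranks_to_frame


class TestCodeEvents:
    def test_fate_rules(self):
        raw = pd.DataFrame({
            "fate": ["bird", "slug", "spider", "ant", "lost", "survived"],
            "time": [24.0, 31.0, 7.0, 48.0, 55.0, 55.0],
        })
        coded = stats.code_events(raw)
        assert coded["event"].tolist() == [1, 0, 0, 0, 0, 0]
        assert coded.loc[5, "time"] == 72.0  # survivors censored at trial end
        assert coded.loc[1, "time"] == 31.0

    def test_unknown_fate_rejected(self):
        with pytest.raises(ValueError, match="unknown fate"):
            stats.code_events(pd.DataFrame({"fate": ["fox"], "time": [7.0]}))


class TestCoxFrailtyCore:
    def test_fixed_effects_match_independent_cox_implementation(self):
        """With no random effects our Breslow fit must agree with lifelines."""
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(42)
        n = 250
        x = rng.normal(size=(n, 2))
        t = rng.exponential(1 / np.exp(0.6 * x[:, 0] - 0.4 * x[:, 1]))
        c = rng.exponential(2.0, n)
        obs = np.minimum(t, c)
        ev = (t <= c).astype(int)
        ours = fit_cox_frailty(x, obs, ev, fixed_names=("a", "b"))
        df = pd.DataFrame({"t": obs, "e": ev, "a": x[:, 0], "b": x[:, 1]})
        ll = CoxPHFitter().fit(df, "t", "e")
        np.testing.assert_allclose(ours.beta, ll.params_.values, atol=1e-5)
        np.testing.assert_allclose(ours.se_beta, ll.standard_errors_.values, atol=1e-5)
        assert ours.loglik == pytest.approx(ll.log_likelihood_, abs=1e-6)

    def test_frailty_shrinks_toward_fixed_effect_fit(self):
        """Strong penalty (theta -> 0) reproduces the no-frailty estimates."""
        rng = np.random.default_rng(7)
        n = 200
        g = rng.integers(0, 10, n)
        x = rng.normal(size=(n, 1))
        t = rng.exponential(1 / np.exp(0.5 * x[:, 0]))
        ev = np.ones(n, int)
        plain = fit_cox_frailty(x, t, ev)
        tiny = fit_cox_frailty(x, t, ev, groups={"g": g}, theta={"g": 1e-8})
        assert tiny.beta[0] == pytest.approx(plain.beta[0], abs=1e-3)
        assert np.abs(tiny.ranef["g"]).max() < 1e-3

    def test_no_events_is_a_fit_error(self):
        with pytest.raises(stats.CoxFitError, match="no events"):
            fit_cox_frailty(np.zeros((5, 1)), np.arange(1.0, 6.0), np.zeros(5, int))


def simulate_records(model: DetectionModel, selection_bundle, seed: int):
    _, ranked, selection = selection_bundle
    schedule = build_field_schedule(selection, n_blocks=10, seed=seed)
    return simulate_field(schedule, ranks_to_frame(ranked), model, seed=seed + 10_000)


class TestFieldModel:
    def test_identical_models_give_zero_statistic(self, cloud_selection):
        rec = simulate_records(DetectionModel(), cloud_selection, seed=0)
        fit = stats.fit_field_model(rec)
        res = stats.lr_deviance_test(fit, fit)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_df_counts_dropped_fixed_effects(self, cloud_selection):
        rec = simulate_records(DetectionModel(), cloud_selection, seed=1)
        full = stats.fit_field_model(rec, include_interaction=True)
        null = stats.fit_field_model(rec, terms=())
        assert stats.lr_deviance_test(full, null).df == 3

    def test_non_nested_models_rejected(self, cloud_selection):
        rec = simulate_records(DetectionModel(), cloud_selection, seed=2)
        a = stats.fit_field_model(rec, terms=("colour",))
        b = stats.fit_field_model(rec, terms=("texture",))
        with pytest.raises(ValueError, match="not nested"):
            stats.lr_deviance_test(a, b)

    def test_exchangeable_groups_give_null_coefficient(self, cloud_selection):
        """Treatment labels shuffled independently of outcomes: the fitted
        colour effect must sit within 2 SE of zero."""
        rec = simulate_records(
            DetectionModel(beta_colour=0.0, beta_texture=0.0, beta_interaction=0.0),
            cloud_selection, seed=3,
        )
        fit = stats.fit_field_model(rec, include_interaction=False)
        coef = fit.coefficients()
        colour = coef[coef["term"] == "colour"].iloc[0]
        assert abs(colour["estimate"]) < 2 * colour["se"]

    def test_interaction_recovered_and_stratified_pattern(self, cloud_selection):
        """Defaults encode a negative interaction: the deviance test must
        detect it, and texture must matter only for colour-common targets,
        in a large majority of replicate experiments."""
        hits = strat_hits = 0
        n_rep = 25
        for s in range(n_rep):
            rec = simulate_records(DetectionModel(), cloud_selection, seed=100 + s)
            full = stats.fit_field_model(rec, include_interaction=True)
            red = stats.fit_field_model(rec, include_interaction=False)
            if stats.lr_deviance_test(full, red).p_value < 0.05:
                hits += 1
            strat = stats.split_by_colour_and_test_texture(rec)
            if strat["Col+"].p_value < 0.05 and strat["Col-"].p_value >= 0.05:
                strat_hits += 1
        assert hits / n_rep > 0.8
        assert strat_hits / n_rep > 0.6

    def test_null_deviance_statistic_is_chi2_calibrated(self, cloud_selection):
        """With all effects zeroed, LR p-values are uniform (KS test) and
        the rejection rate is near nominal."""
        null = DetectionModel(beta_colour=0.0, beta_texture=0.0, beta_interaction=0.0)
        ps = []
        for s in range(60):
            rec = simulate_records(null, cloud_selection, seed=500 + s)
            full = stats.fit_field_model(rec, include_interaction=True)
            red = stats.fit_field_model(rec, include_interaction=False)
            ps.append(stats.lr_deviance_test(full, red).p_value)
        assert sp_stats.kstest(ps, "uniform").pvalue > 0.01
        assert np.mean(np.array(ps) < 0.05) < 0.15

    def test_stratum_without_events_is_a_fit_error(self, cloud_selection):
        rec = simulate_records(DetectionModel(), cloud_selection, seed=4)
        rec.loc[rec["treatment"].str.startswith("Col-"), "event"] = 0
        with pytest.raises(stats.CoxFitError, match="no events"):
            stats.split_by_colour_and_test_texture(rec)


@pytest.fixture(scope="module")
def search_trials(cloud_selection):
    _, ranked, _ = cloud_selection
    ranks = ranks_to_frame(ranked)
    dist = ranks.groupby("tree_id").head(1).head(48).reset_index(drop=True)
    dist["target"] = np.arange(48)
    schedule = build_search_schedule(48, seed=0)

    def make(model, seed):
        return simulate_search(schedule, dist, model, seed=seed)

    return make


class TestSearchModels:
    def test_rt_slopes_recovered_negative_and_significant(self, search_trials):
        """Search gets faster for atypical targets: both distance slopes
        recovered negative and significant in most replicates."""
        wins = 0
        n_rep = 8
        for s in range(n_rep):
            res = stats.fit_rt_model(search_trials(DetectionModel(), seed=s))
            tbl = res.coefficients.set_index("term")
            ok = all(tbl.loc[t, "estimate"] < 0 and tbl.loc[t, "p"] < 0.05
                     for t in ("zd_colour", "zd_texture"))
            wins += ok
        assert wins / n_rep > 0.9

    def test_rt_null_slopes_centre_on_zero(self, search_trials):
        model = DetectionModel(rt_slopes=(0.0, 0.0))
        ests = []
        for s in range(6):
            res = stats.fit_rt_model(search_trials(model, seed=50 + s))
            ests.append(res.coefficients.set_index("term")["estimate"])
        mean_est = pd.concat(ests, axis=1).mean(axis=1)
        assert np.abs(mean_est).max() < 0.01

    def test_hit_slopes_sign_recovery(self, search_trials):
        """Hit probability rises with distance (atypical = easier to find)."""
        model = DetectionModel(hit_baseline_logit=0.5, hit_slopes=(0.8, 0.8))
        res = stats.fit_hit_model(search_trials(model, seed=9))
        tbl = res.coefficients.set_index("term")
        assert tbl.loc["zd_colour", "estimate"] > 0
        assert tbl.loc["zd_texture", "estimate"] > 0
        assert tbl.loc["zd_colour", "p"] < 0.05

    def test_all_hit_data_is_a_fit_error(self, search_trials):
        trials = search_trials(DetectionModel(), seed=11)
        trials["hit"] = 1
        trials["timed_out"] = False
        with pytest.raises(ValueError, match="all-success"):
            stats.fit_hit_model(trials)

    def test_predictors_are_zscored_in_the_fit(self, search_trials):
        trials = search_trials(DetectionModel(), seed=12)
        kept = trials[(trials["hit"] == 1) & ~trials["timed_out"] & ~trials["is_practice"]]
        z = (kept["d_colour"] - kept["d_colour"].mean()) / kept["d_colour"].std(ddof=0)
        assert abs(z.mean()) < 1e-9 and abs(z.std(ddof=0) - 1) < 1e-9
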