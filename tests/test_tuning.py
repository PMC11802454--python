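"""Single-neuron tuning: binning, the sliding two-way ANOVA against an
independent sums-of-squares oracle, epoch regressions and area comparisons."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import statsmodels.api as sm
from statsmodels.formula.api import ols

from sdchoice.session import code_values
from sdchoice.stats import fisher_r_to_z
from sdchoice.synthetic import TaskConfig, NeuronSpec, generate_trials, simulate_session
from sdchoice.tuning import (
    DEFAULT_EPOCHS, bin_rates, epoch_rates, omega_p2, sliding_anova,
    sliding_anova_session, prevalence_timecourse, fit_choice_epoch_model,
    state_conditional_value_betas, compare_beta_correlations,
)


def anova_oracle(y, s, c):
    """Independent two-way ANOVA decomposition via statsmodels (type III,
    sum contrasts); returns dict factor -> (ms_effect, ms_error, df, n)."""
    df = pd.DataFrame({"y": y, "s": s, "c": c})
    model = ols("y ~ C(s, Sum) * C(c, Sum)", df).fit()
    tab = sm.stats.anova_lm(model, typ=3)
    mse = tab.loc["Residual", "sum_sq"] / tab.loc["Residual", "df"]
    out = {}
    for name, key in (("state", "C(s, Sum)"), ("cue", "C(c, Sum)"),
                      ("interaction", "C(s, Sum):C(c, Sum)")):
        ms = tab.loc[key, "sum_sq"] / tab.loc[key, "df"]
        out[name] = (ms, mse, tab.loc[key, "df"], len(y))
    return out


class TestBinRates:
    def test_one_spike_in_bin_is_10hz(self):
        rates, centers = bin_rates(np.array([1.05]), np.array([1.0]), (0.0, 0.2))
        assert rates.max() == pytest.approx(10.0)

    def test_empty_train_all_zero(self):
        rates, _ = bin_rates(np.array([]), np.arange(5.0) + 1, (-0.5, 0.5))
        assert np.all(rates == 0)

    def test_constant_poisson_rate_recovered(self):
        rng = np.random.default_rng(0)
        dur = 400.0
        spikes = np.sort(rng.uniform(0, dur, size=rng.poisson(20.0 * dur)))
        events = np.arange(1.0, dur - 3, 4.0)
        rates, _ = bin_rates(spikes, events, (0.0, 2.0))
        se = np.sqrt(20.0 / (0.1 * rates.size))
        assert abs(rates.mean() - 20.0) < 3 * se

    def test_out_of_span_window_raises(self):
        with pytest.raises(ValueError):
            bin_rates(np.array([1.0]), np.array([0.2]), (-0.5, 0.5))


class TestOmegaP2:
    def test_ms_effect_equals_ms_error_gives_zero(self):
        assert omega_p2(1, 3.0, 3.0, 40) == 0.0

    def test_zero_error_gives_one(self):
        for n in (8, 20, 100):
            assert omega_p2(1, 5.0, 0.0, n) == 1.0

    def test_oracle_equivalence_on_random_tables(self):
        """Partial omega squared from the sliding ANOVA equals the value
        computed from an independent sums-of-squares decomposition on 200
        random small tables."""
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(8, 30))
            s = rng.choice([-1, 1], n)
            c = rng.choice([-1, 1], n)
            # ensure every cell occupied twice
            s[:8] = [-1, -1, -1, -1, 1, 1, 1, 1]
            c[:8] = [-1, -1, 1, 1, -1, -1, 1, 1]
            y = rng.normal(size=n) + 0.5 * s * rng.random()
            res = sliding_anova(y[:, None], s, c)
            oracle = anova_oracle(y, s, c)
            for factor, (ms_eff, ms_err, dfe, ntot) in oracle.items():
                expect = omega_p2(dfe, ms_eff, ms_err, ntot)
                got = res.loc[res["factor"] == factor, "omega_p2"].iloc[0]
                assert got == pytest.approx(expect, rel=1e-8, abs=1e-10), factor

    def test_single_factor_algebraic_identity(self):
        """On one-factor tables the partial form reduces to
        (SS_eff - df*MS_err) / (SS_total + MS_err)."""
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = 24
            s = rng.choice([-1, 1], n)
            s[:2] = [-1, 1]
            y = rng.normal(size=n) + 0.8 * s
            x = np.column_stack([np.ones(n), s])
            beta, res_ss = np.linalg.lstsq(x, y, rcond=None)[:2]
            ss_total = np.sum((y - y.mean()) ** 2)
            ss_eff = ss_total - res_ss[0]
            ms_err = res_ss[0] / (n - 2)
            partial = omega_p2(1, ss_eff, ms_err, n)
            classic = (ss_eff - ms_err) / (ss_total + ms_err)
            assert partial == pytest.approx(classic, rel=1e-10)


class TestSlidingAnova:
    def test_f_and_p_match_oracle(self):
        rng = np.random.default_rng(3)
        n = 40
        s = rng.choice([-1, 1], n)
        c = rng.choice([-1, 1], n)
        s[:8] = [-1, -1, -1, -1, 1, 1, 1, 1]
        c[:8] = [-1, 1, -1, 1, -1, 1, -1, 1]
        y = rng.normal(size=n) + s
        res = sliding_anova(y[:, None], s, c)
        df = pd.DataFrame({"y": y, "s": s, "c": c})
        tab = sm.stats.anova_lm(ols("y ~ C(s, Sum) * C(c, Sum)", df).fit(), typ=3)
        f_state = tab.loc["C(s, Sum)", "F"]
        p_state = tab.loc["C(s, Sum)", "PR(>F)"]
        row = res[res["factor"] == "state"].iloc[0]
        assert row["F"] == pytest.approx(f_state, rel=1e-8)
        assert row["p"] == pytest.approx(p_state, rel=1e-8)

    def test_empty_cell_rejected(self):
        s = np.array([-1, -1, 1, 1] * 5)
        c = np.ones(20)
        with pytest.raises(ValueError):
            sliding_anova(np.zeros((20, 1)), s, c)

    def test_null_population_prevalence_at_alpha(self):
        """Untuned neurons: fraction significant per window is near the test
        level (pointwise 5%)."""
        rng = np.random.default_rng(4)
        n_neurons, n_trials, n_wins = 60, 80, 12
        s = np.tile([-1, 1], n_trials // 2)
        c = np.repeat([-1, 1], n_trials // 2)
        frames = []
        for nid in range(n_neurons):
            y = rng.normal(size=(n_trials, n_wins))
            r = sliding_anova(y, s, c)
            r["neuron_id"] = nid
            r["area"] = "HPC" if nid < 30 else "OFC"
            r["alignment"] = "cue_on_ms"
            frames.append(r)
        prev = prevalence_timecourse(pd.concat(frames), "state")
        # 5% +/- 3 binomial SE at n=30 per area
        assert abs(prev["frac"].mean() - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 30)
        # chi2 p-values under the identical-population null are not clustered small
        assert (prev.groupby("window")["chi2_p"].first() < 0.05).mean() < 0.25


class TestEpochModels:
    @pytest.fixture(scope="class")
    def tuned_session(self):
        cfg = TaskConfig(n_trials=800)
        specs = [
            NeuronSpec(0, "HPC", baseline_rate=8.0, value_beta=(1.0, 1.0)),
            NeuronSpec(1, "OFC", baseline_rate=8.0, value_beta=(2.0, -2.0)),  # pure interaction
            NeuronSpec(2, "HPC", baseline_rate=8.0),
            NeuronSpec(3, "OFC", baseline_rate=8.0, value_beta=(2.5, 0.0)),
        ]
        return simulate_session(cfg, specs, seed=13)

    def test_planted_value_beta_recovered(self, tuned_session):
        res = fit_choice_epoch_model(tuned_session)
        row = res[res["neuron_id"] == 0].iloc[0]
        assert row["beta_value"] == pytest.approx(1.0, abs=0.6)
        assert row["p_value"] < 0.05

    def test_pure_interaction_neuron(self, tuned_session):
        row = fit_choice_epoch_model(tuned_session).set_index("neuron_id").loc[1]
        assert row["p_state_x_value"] < 0.05
        assert row["p_value"] > 0.01  # no net value main effect

    def test_untuned_neuron_null(self, tuned_session):
        row = fit_choice_epoch_model(tuned_session).set_index("neuron_id").loc[2]
        for term in ("state", "value", "state_x_value"):
            assert abs(row[f"beta_{term}"]) < 0.6

    def test_trial_order_invariance(self, tuned_session):
        """Permuting trials (with the nuisance regressor re-indexed) leaves
        the other betas unchanged."""
        sess = tuned_session
        res1 = fit_choice_epoch_model(sess)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(sess.trials))
        import copy
        sess2 = copy.copy(sess)
        sess2.trials = sess.trials.iloc[perm].reset_index(drop=True)
        res2 = fit_choice_epoch_model(sess2)
        for term in ("state", "value", "state_x_value"):
            assert np.allclose(res1[f"beta_{term}"], res2[f"beta_{term}"], atol=1e-9)

    def test_state_conditional_betas_recover_tuning_classes(self, tuned_session):
        sv = state_conditional_value_betas(tuned_session)
        sv = sv.set_index("neuron_id")
        assert sv.loc[0, "beta_A"] == pytest.approx(1.0, abs=0.6)
        assert sv.loc[0, "beta_B"] == pytest.approx(1.0, abs=0.6)
        assert sv.loc[3, "p_A"] < 0.05 and abs(sv.loc[3, "beta_B"]) < 0.7
        assert abs(sv.loc[2, "beta_A"]) < 0.7 and abs(sv.loc[2, "beta_B"]) < 0.7


class TestBetaCorrelations:
    def test_equal_correlations_give_z_zero(self):
        z, p = fisher_r_to_z(0.5, 50, 0.5, 50)
        assert z == 0.0 and p == pytest.approx(1.0)

    def test_planted_correlation_contrast_detected(self):
        """r=0.7 vs r=0 at n=50 per area rejects in most replicates."""
        rng = np.random.default_rng(7)
        hits = 0
        n_rep = 50
        for _ in range(n_rep):
            a1 = rng.normal(size=50)
            b1 = 0.7 * a1 + np.sqrt(1 - 0.49) * rng.normal(size=50)
            a2 = rng.normal(size=50)
            b2 = rng.normal(size=50)
            df = pd.DataFrame({
                "neuron_id": np.arange(100),
                "area": ["HPC"] * 50 + ["OFC"] * 50,
                "beta_A": np.concatenate([a1, a2]),
                "beta_B": np.concatenate([b1, b2]),
                "p_A": 0.01, "p_B": 0.5,
            })
            df["value_coding"] = True
            out = compare_beta_correlations(df)
            hits += out["fisher_p"] < 0.05
        assert hits / n_rep >= 0.8

    def test_too_few_value_coding_neurons_rejected(self):
        df = pd.DataFrame({"neuron_id": [0, 1], "area": ["HPC", "OFC"],
                           "beta_A": [1.0, 2.0], "beta_B": [1.0, 2.0],
                           "p_A": [0.01, 0.01], "p_B": [0.5, 0.5],
                           "value_coding": [True, True]})
        with pytest.raises(ValueError):
            compare_beta_correlations(df)
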