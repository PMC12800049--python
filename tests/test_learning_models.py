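"""Trial-table construction and the learning-curve model stack."""
import numpy as np
import pandas as pd
import pytest

from navlearn import actors as ac
from navlearn import learning_models as lm


def lmm_dataset(rng, slope=-0.18, n_participants=29, n_blocks=6, n_trials=20,
                sd_intercept=0.05, sd_resid=0.25, intercept=0.05):
    """Outcome generated directly from the random-intercept linear model."""
    t = np.tile(np.arange(1, n_trials + 1), n_blocks)
    bi = np.repeat(np.arange(n_blocks), n_trials)
    frames = []
    for p in range(n_participants):
        u = rng.normal(0, sd_intercept)
        y = intercept + slope * np.exp(-t) + u + rng.normal(0, sd_resid, t.size)
        frames.append(pd.DataFrame({
            "participant_id": p, "block_index": bi, "condition": "left_biased",
            "trial_in_block": t, "normalized_x": y}))
    return pd.concat(frames, ignore_index=True)


def ideal_actor_choice_table(seed, n_participants=25, n_blocks=6, n_trials=20,
                             bias=0.88):
    """Binary-correctness table generated by the ideal actor per block."""
    rng = np.random.default_rng(seed)
    frames = []
    for p in range(n_participants):
        blocks = ac.sample_open_sequences(n_blocks, n_trials, bias, seed=rng)
        for b, block in enumerate(blocks):
            run = ac.ideal_actor_run(block, seed=rng)
            frames.append(pd.DataFrame({
                "participant_id": p, "block_index": b,
                "condition": "left_biased",
                "trial_in_block": np.arange(1, n_trials + 1),
                "correct": run.correct.astype(float)}))
    return pd.concat(frames, ignore_index=True)


class TestBuildTrialTable:
    def test_expdecay_definition(self, small_exp1, small_exp1_metrics):
        table = lm.build_trial_table(small_exp1["trials"], small_exp1_metrics)
        t1 = table[table.trial_in_block == 1]["expdecay"].iloc[0]
        t20 = table[table.trial_in_block == 20]["expdecay"].iloc[0]
        assert t1 == pytest.approx(np.exp(-1))
        assert t20 == pytest.approx(np.exp(-20), rel=1e-9)

    def test_block_position_only_for_biased(self, small_exp1, small_exp1_metrics):
        table = lm.build_trial_table(small_exp1["trials"], small_exp1_metrics)
        assert table.loc[table.condition == "control", "block_position"].isna().all()
        biased = table[table.condition != "control"]
        assert set(biased.groupby("participant_id")["block_position"].max()) == {6}

    def test_disjoint_join_empty(self, small_exp1, small_exp1_metrics):
        shifted = small_exp1_metrics.copy()
        shifted["participant_id"] += 1000
        table = lm.build_trial_table(small_exp1["trials"], shifted)
        assert len(table) == 0

    def test_duplicate_keys_rejected(self, small_exp1, small_exp1_metrics):
        dup = pd.concat([small_exp1_metrics, small_exp1_metrics.iloc[:3]])
        with pytest.raises(ValueError, match="duplicate"):
            lm.build_trial_table(small_exp1["trials"], dup)


class TestExpdecayMixed:
    def test_planted_slope_recovered(self):
        rng = np.random.default_rng(100)
        fit = lm.fit_expdecay_mixed(lmm_dataset(rng))
        lo, hi = fit.conf_int.loc["expdecay"]
        assert lo <= -0.18 <= hi
        assert fit.marginal_r2 <= fit.conditional_r2

    def test_null_slope_ci_covers_zero_at_nominal_rate(self):
        rng = np.random.default_rng(101)
        covered = sum(
            fit.conf_int.loc["expdecay", "lower"] <= 0 <=
            fit.conf_int.loc["expdecay", "upper"]
            for fit in (lm.fit_expdecay_mixed(lmm_dataset(rng, slope=0.0,
                                                          n_participants=12,
                                                          n_blocks=3))
                        for _ in range(30)))
        assert covered >= 25  # ~95% nominal coverage

    def test_constant_outcome_degenerate(self):
        rng = np.random.default_rng(102)
        d = lmm_dataset(rng, n_participants=4, n_blocks=1)
        d["normalized_x"] = 0.2
        with pytest.raises(ValueError, match="variance"):
            lm.fit_expdecay_mixed(d)

    def test_random_slopes_raise_conditional_r2(self):
        rng = np.random.default_rng(103)
        # heterogeneous slopes across participants
        frames = []
        t = np.tile(np.arange(1, 21), 4)
        bi = np.repeat(np.arange(4), 20)
        for p in range(20):
            s = rng.normal(-0.3, 0.4)
            y = s * np.exp(-t) + rng.normal(0, 0.05, t.size)
            frames.append(pd.DataFrame({
                "participant_id": p, "block_index": bi,
                "condition": "left_biased", "trial_in_block": t,
                "normalized_x": y}))
        d = pd.concat(frames, ignore_index=True)
        plain = lm.fit_expdecay_mixed(d)
        slopes = lm.fit_expdecay_mixed(d, random_slopes=True)
        assert slopes.conditional_r2 > plain.conditional_r2

    def test_standardized_beta_affine_invariant(self):
        rng = np.random.default_rng(104)
        d = lmm_dataset(rng, n_participants=10, n_blocks=3)
        base = lm.fit_expdecay_mixed(d)
        scaled = d.copy()
        scaled["normalized_x"] = scaled["normalized_x"] * 3.7 + 1.2
        rescaled = lm.fit_expdecay_mixed(scaled)
        assert rescaled.std_beta["expdecay"] == \
            pytest.approx(base.std_beta["expdecay"], rel=1e-3)


class TestBlockPositionModel:
    def test_null_interaction_covers_zero(self):
        rng = np.random.default_rng(110)
        fit = lm.fit_block_position_model(lmm_dataset(rng, n_participants=20))
        lo, hi = fit.conf_int.loc["expdecay:block_position"]
        assert lo <= 0 <= hi

    def test_planted_cross_block_gain_detected(self):
        rng = np.random.default_rng(111)
        detections = 0
        for _ in range(10):
            d = lmm_dataset(rng, n_participants=20)
            d["normalized_x"] += 0.05 * d["block_index"]
            fit = lm.fit_block_position_model(d)
            detections += (fit.params["block_position"] > 0
                           and fit.pvalues["block_position"] < 0.05)
        assert detections >= 8

    def test_single_block_rejected(self):
        rng = np.random.default_rng(112)
        with pytest.raises(ValueError, match="block_position"):
            lm.fit_block_position_model(lmm_dataset(rng, n_blocks=1))


class TestLogisticMixed:
    def test_positive_significant_slope_on_ideal_actor_data(self):
        table = ideal_actor_choice_table(seed=120)
        fit = lm.fit_logistic_learning(table)
        assert fit.params["trial_in_block"] > 0
        assert fit.pvalues["trial_in_block"] < 0.01

    def test_coin_flip_slope_covers_zero(self):
        rng = np.random.default_rng(121)
        t = np.tile(np.arange(1, 21), 6)
        frames = [pd.DataFrame({"participant_id": p,
                                "block_index": np.repeat(np.arange(6), 20),
                                "condition": "left_biased", "trial_in_block": t,
                                "correct": (rng.random(t.size) < 0.5).astype(float)})
                  for p in range(15)]
        fit = lm.fit_logistic_learning(pd.concat(frames, ignore_index=True))
        lo, hi = fit.conf_int.loc["trial_in_block"]
        assert lo <= 0 <= hi

    def test_all_correct_flags_separation(self):
        t = np.tile(np.arange(1, 21), 2)
        frames = [pd.DataFrame({"participant_id": p,
                                "block_index": np.repeat([0, 1], 20),
                                "condition": "left_biased", "trial_in_block": t,
                                "correct": 1.0}) for p in range(4)]
        fit = lm.fit_logistic_learning(pd.concat(frames, ignore_index=True))
        assert fit.flags  # separation / divergence flagged

    def test_matches_plain_glm_when_no_grouping_variance(self):
        """With a common intercept the GLMM slope agrees with a plain
        logistic GLM (the random-intercept variance shrinks to ~0)."""
        import statsmodels.api as sm
        rng = np.random.default_rng(122)
        t = np.tile(np.arange(1, 21), 10)
        p_true = 1 / (1 + np.exp(-(-1.0 + 0.2 * t)))
        frames = [pd.DataFrame({"participant_id": p,
                                "block_index": np.repeat(np.arange(10), 20),
                                "condition": "left_biased", "trial_in_block": t,
                                "correct": (rng.random(t.size) < p_true).astype(float)})
                  for p in range(10)]
        table = pd.concat(frames, ignore_index=True)
        fit = lm.fit_logistic_learning(table)
        X = sm.add_constant(table["trial_in_block"].to_numpy())
        glm = sm.GLM(table["correct"].to_numpy(), X,
                     family=sm.families.Binomial()).fit()
        assert fit.params["trial_in_block"] == pytest.approx(glm.params[1],
                                                             abs=0.02)


class TestExponentialCurve:
    def test_aic_prefers_logistic_on_logistic_data(self):
        """On logistic-mechanism choices the logistic model wins the AIC
        comparison in most replicates."""
        rng = np.random.default_rng(130)
        wins = 0
        for _ in range(6):
            t = np.tile(np.arange(1, 21), 6)
            p_true = 1 / (1 + np.exp(-(-0.5 + 0.25 * t)))
            frames = [pd.DataFrame({
                "participant_id": p, "block_index": np.repeat(np.arange(6), 20),
                "condition": "left_biased", "trial_in_block": t,
                "correct": (rng.random(t.size) < p_true).astype(float)})
                for p in range(15)]
            table = pd.concat(frames, ignore_index=True)
            logistic = lm.fit_logistic_learning(table)
            expo = lm.fit_exponential_learning_curve(table)
            wins += logistic.aic < expo.aic
        assert wins >= 5

    def test_flat_data_flags_unidentified_rate(self):
        rng = np.random.default_rng(131)
        t = np.tile(np.arange(1, 21), 20)
        table = pd.DataFrame({"participant_id": 0, "block_index": 0,
                              "condition": "left_biased", "trial_in_block": t,
                              "correct": (rng.random(t.size) < 0.7).astype(float)})
        fit = lm.fit_exponential_learning_curve(table)
        assert fit.flags


class TestThresholdTrial:
    def test_closed_form_inverse_logit(self):
        fit = _logistic_stub(intercept=0.0, slope=0.45)
        # logit(0.8) = log 4 ~ 1.386; 1.386 / 0.45 ~ 3.08 -> trial 4
        assert lm.predict_threshold_trial(fit, 0.8).trial == 4

    def test_already_above_threshold(self):
        fit = _logistic_stub(intercept=2.0, slope=0.1)
        assert lm.predict_threshold_trial(fit, 0.8).trial == 1

    def test_flat_never_reaches(self):
        fit = _logistic_stub(intercept=0.0, slope=0.0)
        est = lm.predict_threshold_trial(fit, 0.8)
        assert est.trial is None and not est.reached

    def test_monotone_in_slope(self):
        trials = [lm.predict_threshold_trial(_logistic_stub(-1.0, s), 0.8).trial
                  for s in (0.2, 0.4, 0.8)]
        cleaned = [t if t is not None else 99 for t in trials]
        assert cleaned == sorted(cleaned, reverse=True)


def _logistic_stub(intercept, slope):
    names = ["Intercept", "trial_in_block"]
    params = pd.Series([intercept, slope], index=names)
    ones = pd.Series([1.0, 1.0], index=names)
    return lm.ModelFit(formula="stub", params=params, se=ones, zvalues=params,
                       pvalues=ones, conf_int=pd.DataFrame(
                           {"lower": params - 1, "upper": params + 1}),
                       std_beta=ones, aic=0.0)


class TestGazeModels:
    def test_planted_block_decline_recovered(self):
        rng = np.random.default_rng(140)
        frames = []
        t = np.tile(np.arange(1, 21), 9)
        bi = np.repeat(np.arange(9), 20)
        cond = np.where(bi % 3 == 0, "control", "left_biased")
        for p in range(15):
            u = rng.normal(0, 0.3)
            sr = 3.0 - 0.05 * bi + u + rng.normal(0, 0.4, t.size)
            fd = 0.4 - 0.011 * t + rng.normal(0, 0.08, t.size)
            frames.append(pd.DataFrame({
                "participant_id": p, "block_index": bi, "condition": cond,
                "trial_in_block": t, "saccade_rate": sr,
                "fixation_dispersion": fd}))
        table = pd.concat(frames, ignore_index=True)
        fits = lm.fit_gaze_models(table)
        sr_fit = fits["saccade_rate"]
        assert sr_fit.params["block_number"] < 0
        assert sr_fit.pvalues["block_number"] < 0.05
        fd_fit = fits["fixation_dispersion"]
        assert fd_fit.params["trial_in_block"] < 0
        # condition-free generation: condition effect CI covers zero
        lo, hi = sr_fit.conf_int.loc["biased"]
        assert lo <= 0 <= hi

    def test_single_trial_blocks_rejected(self):
        table = pd.DataFrame({"participant_id": [0, 0, 1, 1],
                              "block_index": [0, 1, 0, 1],
                              "condition": "left_biased",
                              "trial_in_block": 1,
                              "saccade_rate": [1.0, 2.0, 1.5, 2.5],
                              "fixation_dispersion": [0.1, 0.2, 0.15, 0.25]})
        with pytest.raises(ValueError, match="single-trial"):
            lm.fit_gaze_models(table)


class TestSupportingTests:
    def test_one_sample_t_constant_at_null(self):
        out = lm.one_sample_t(np.full(10, 0.5), 0.5)
        assert out["t"] == 0.0 or out.get("flag") == "zero variance"

    def test_welch_identical_samples(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        out = lm.welch_t(x, x.copy())
        assert out["t"] == pytest.approx(0.0)
        assert out["cohens_d"] == pytest.approx(0.0)

    def test_kruskal_matches_rank_formula_oracle(self):
        rng = np.random.default_rng(150)
        groups = [rng.normal(loc, 1.0, 25) for loc in (0.0, 0.6, 1.2)]
        out = lm.kruskal_wallis(*groups)
        # rank-formula oracle (no ties with continuous data)
        pooled = np.concatenate(groups)
        ranks = pd.Series(pooled).rank().to_numpy()
        n = pooled.size
        start = 0
        h = 0.0
        for g in groups:
            r = ranks[start:start + g.size]
            h += r.sum() ** 2 / g.size
            start += g.size
        h = 12 / (n * (n + 1)) * h - 3 * (n + 1)
        assert out["H"] == pytest.approx(h, abs=1e-9)

    def test_bootstrap_ci_brackets_mean(self):
        rng = np.random.default_rng(151)
        x = rng.normal(0.51, 0.1, 400)
        out = lm.bootstrap_mean_ci(x, seed=5)
        lo, hi = out["ci"]
        assert lo < x.mean() < hi
        assert hi - lo < 0.05
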