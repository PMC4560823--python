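"""Behavioural summaries, transfer-test prediction and repeated-measures ANOVA."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from contextrl import (
    ABSOLUTE,
    COMPLETE,
    PARTIAL,
    PUNISHMENT,
    RELATIVE,
    REWARD,
    AgentParams,
    PipelineConfig,
    build_postlearning_schedule,
    cohort_learning_rates,
    postlearning_loglik,
    postlearning_option_rates,
    predict_postlearning,
    rm_anova,
    run_paper_pipeline,
    sample_postlearning_choices,
    session_contexts,
    simulate_agent,
    simulate_cohort,
    summarize_learning,
)


class TestSummarizeLearning:
    def test_always_correct_agent_scores_one(self):
        sim = simulate_agent(ABSOLUTE, AgentParams(beta=1000, alpha1=1.0, alpha2=1.0),
                             np.random.default_rng(0))
        df = sim.frame
        good = np.where(df["context_valence"] == REWARD, "G75", "L25")
        df = df[df["chosen_label"] == good]  # degenerate: keep only correct rows
        assert (summarize_learning(df).to_numpy() == 1.0).all()

    def test_zero_learning_agent_near_chance(self):
        sims = simulate_cohort(ABSOLUTE, AgentParams(beta=10, alpha1=0.0, alpha2=0.0),
                               50, np.random.default_rng(1), record_trace=False)
        df = pd.concat([s.frame.assign(subject=i) for i, s in enumerate(sims)])
        rates = summarize_learning(df).to_numpy()
        assert abs(rates.mean() - 0.5) < 0.02

    def test_complete_feedback_beats_partial_under_relative(self, relative_params):
        sims = simulate_cohort(RELATIVE, relative_params, 60, np.random.default_rng(2))
        rates = cohort_learning_rates(sims).mean()
        assert rates[(REWARD, COMPLETE)] > rates[(REWARD, PARTIAL)]
        assert rates[(PUNISHMENT, COMPLETE)] > rates[(PUNISHMENT, PARTIAL)]

    def test_empty_cell_rejected(self, small_dataset):
        df = small_dataset[small_dataset["context_valence"] == REWARD]
        with pytest.raises(Exception):
            summarize_learning(df)[(PUNISHMENT, PARTIAL)]


class TestPredictPostlearning:
    def test_equal_values_give_half_everywhere(self):
        q = {(l, f): 0.1 for l, f in itertools.product(
            ["G75", "G25", "L25", "L75"], [PARTIAL, COMPLETE])}
        pairs = predict_postlearning(q, beta=25.0)
        assert (pairs["p_choose"] == 0.5).all()

    def test_option_rate_mean_is_exactly_half(self, relative_params):
        """Each trial awards one choice between two options, so rates average 0.5."""
        sim = simulate_agent(RELATIVE, relative_params, np.random.default_rng(3))
        pairs = predict_postlearning(sim.final_q[4], relative_params.beta)
        rates = pairs.groupby("option")["p_choose"].mean()
        assert rates.mean() == pytest.approx(0.5, abs=1e-12)

    def test_sampled_rate_mean_is_exactly_half(self, relative_params, rng):
        sim = simulate_agent(RELATIVE, relative_params, np.random.default_rng(4))
        options = [o for c in session_contexts(4) for o in c.options]
        sched = build_postlearning_schedule(options, rng)
        choices = sample_postlearning_choices(sched, sim.final_q[4],
                                              relative_params.beta, rng)
        rates = postlearning_option_rates(choices)
        assert len(rates) == 8
        assert rates.mean() == pytest.approx(0.5, abs=1e-12)

    def test_loglik_invariant_to_trial_order(self, relative_params, rng):
        """Values are frozen in the transfer test: order cannot matter."""
        sim = simulate_agent(RELATIVE, relative_params, np.random.default_rng(5))
        options = [o for c in session_contexts(4) for o in c.options]
        sched = build_postlearning_schedule(options, rng)
        choices = sample_postlearning_choices(sched, sim.final_q[4],
                                              relative_params.beta, rng)
        ll = postlearning_loglik(choices, sim.final_q[4], relative_params.beta)
        shuffled = [choices[i] for i in rng.permutation(len(choices))]
        # identical term set; only float summation order differs
        assert postlearning_loglik(shuffled, sim.final_q[4], relative_params.beta) == \
            pytest.approx(ll, rel=1e-12)

    def test_zero_beta_loglik(self, relative_params, rng):
        sim = simulate_agent(RELATIVE, relative_params, np.random.default_rng(6))
        options = [o for c in session_contexts(4) for o in c.options]
        sched = build_postlearning_schedule(options, rng)
        choices = sample_postlearning_choices(sched, sim.final_q[4], 0.0, rng)
        ll = postlearning_loglik(choices, sim.final_q[4], 0.0)
        assert ll == pytest.approx(112 * math.log(0.5))

    def test_mean_loglik_approaches_negative_entropy(self, rng):
        """Choices sampled from the scoring distribution: E[log p] = -H(p)."""
        q = {("G75", PARTIAL): 0.3, ("G25", PARTIAL): 0.1,
             ("L25", PARTIAL): -0.1, ("L75", PARTIAL): -0.3}
        beta = 6.0
        opts = list(q)
        pairs = list(itertools.combinations(opts, 2))

        def h(p):
            return -(p * math.log(p) + (1 - p) * math.log(1 - p))

        from contextrl import softmax_prob
        expected = -sum(h(softmax_prob(q[a], q[b], beta)) for a, b in pairs)
        sims = []
        for _ in range(400):
            choices = []
            for a, b in pairs:
                p = softmax_prob(q[a], q[b], beta)
                choices.append((a, b) if rng.random() < p else (b, a))
            sims.append(postlearning_loglik(choices, q, beta))
        assert np.mean(sims) == pytest.approx(expected, abs=0.15)

    def test_unknown_option_rejected(self):
        with pytest.raises(ValueError):
            postlearning_loglik([(("X", PARTIAL), ("G75", PARTIAL))],
                                {("G75", PARTIAL): 0.1}, 1.0)

    def test_value_inversion_direction(self, relative_params, absolute_params):
        """RELATIVE prefers L25-complete over G25-complete; ABSOLUTE the reverse."""
        from contextrl import cohort_postlearning_rates
        rel = simulate_cohort(RELATIVE, relative_params, 80, np.random.default_rng(7),
                              record_trace=False)
        ab = simulate_cohort(ABSOLUTE, absolute_params, 80, np.random.default_rng(8),
                             record_trace=False)
        r = cohort_postlearning_rates(rel).mean()
        a = cohort_postlearning_rates(ab).mean()
        assert r[("L25", COMPLETE)] > r[("G25", COMPLETE)]
        assert a[("G25", COMPLETE)] > a[("L25", COMPLETE)]


def _brute_force_rm_anova(cell: pd.DataFrame, factors: list[str]) -> dict:
    """Independent sum-of-squares partition via inclusion-exclusion marginal means.

    For each effect E the per-(subject x E-level) effect estimate is the
    alternating sum of marginal means over subsets of E; SS_E uses the
    across-subject mean estimates and the error term is the effect-by-
    subject interaction. Exact for balanced all-two-level within designs.
    """
    y = cell.to_numpy()
    n, _ = y.shape
    cols = [c if isinstance(c, tuple) else (c,) for c in cell.columns]
    levels = {f: sorted({key[i] for key in cols}) for i, f in enumerate(factors)}
    out = {}
    for r in range(1, len(factors) + 1):
        for effect in itertools.combinations(factors, r):
            level_combos = list(itertools.product(*[levels[f] for f in effect]))
            est = np.zeros((n, len(level_combos)))
            for j, combo in enumerate(level_combos):
                assign = dict(zip(effect, combo))
                for T_size in range(len(effect) + 1):
                    for T in itertools.combinations(effect, T_size):
                        mask = [all(key[factors.index(f)] == assign[f] for f in T)
                                for key in cols]
                        marg = y[:, np.array(mask)].mean(axis=1)
                        est[:, j] += (-1) ** (len(effect) - len(T)) * marg
            mult = 2 ** (len(factors) - len(effect))
            ss_e = n * mult * np.sum(est.mean(axis=0) ** 2)
            ss_err = mult * np.sum((est - est.mean(axis=0)) ** 2)
            df_e = np.prod([len(levels[f]) - 1 for f in effect])
            df_err = df_e * (n - 1)
            out[" x ".join(effect)] = (ss_e / df_e) / (ss_err / df_err)
    return out


class TestRmAnova:
    def _toy(self, n=6, seed=0, effects=None):
        rng = np.random.default_rng(seed)
        rows = []
        effects = effects or {}
        for s in range(n):
            base = rng.normal()
            for v, f in itertools.product(["a", "b"], ["x", "y"]):
                val = base + rng.normal() * 0.3
                val += effects.get("valence", 0.0) * (1 if v == "a" else -1)
                val += effects.get("feedback", 0.0) * (1 if f == "x" else -1)
                rows.append({"subject": s, "valence": v, "feedback": f, "rate": val})
        return pd.DataFrame(rows)

    def test_identical_cells_give_zero_f(self):
        rows = [{"subject": s, "valence": v, "feedback": f, "rate": 1.0 + s}
                for s in range(5) for v in ("a", "b") for f in ("x", "y")]
        res = rm_anova(pd.DataFrame(rows), "rate", "subject", ["valence", "feedback"])
        assert (res["F"] == 0.0).all()

    def test_pure_main_effect_detected(self):
        df = self._toy(n=12, seed=3, effects={"valence": 1.0})
        res = rm_anova(df, "rate", "subject", ["valence", "feedback"]).set_index("effect")
        assert res.loc["valence", "p"] < 1e-6
        assert res.loc["feedback", "p"] > 0.01
        assert res.loc["valence x feedback", "p"] > 0.01

    @pytest.mark.parametrize("n_factors", [2, 3])
    def test_agrees_with_brute_force_partition(self, n_factors, rng):
        """F statistics match the independent SS partition to 1e-8."""
        factors = ["valence", "feedback", "correctness"][:n_factors]
        rows = []
        for s in range(7):
            for combo in itertools.product(*[("a", "b")] * n_factors):
                rows.append({"subject": s, "rate": float(rng.normal()),
                             **dict(zip(factors, combo))})
        df = pd.DataFrame(rows)
        mine = rm_anova(df, "rate", "subject", factors).set_index("effect")["F"]
        cell = df.groupby(["subject"] + factors)["rate"].mean().unstack(factors)
        oracle = _brute_force_rm_anova(cell, factors)
        for effect, f_oracle in oracle.items():
            assert mine[effect] == pytest.approx(f_oracle, abs=1e-8)

    def test_agrees_with_pingouin_two_way(self):
        """Library cross-check on a two-way within design."""
        pingouin = pytest.importorskip("pingouin")
        df = self._toy(n=10, seed=9, effects={"valence": 0.4, "feedback": 0.2})
        mine = rm_anova(df, "rate", "subject", ["valence", "feedback"]).set_index("effect")
        ref = pingouin.rm_anova(data=df, dv="rate", within=["valence", "feedback"],
                                subject="subject", detailed=True)
        ref_f = {"valence": ref.loc[0, "F"], "feedback": ref.loc[1, "F"],
                 "valence x feedback": ref.loc[2, "F"]}
        for effect, f in ref_f.items():
            assert mine.loc[effect, "F"] == pytest.approx(f, rel=1e-6)

    def test_unbalanced_rejected(self):
        df = self._toy(n=4)
        df = df.drop(df.index[0])
        with pytest.raises(ValueError, match="unbalanced"):
            rm_anova(df, "rate", "subject", ["valence", "feedback"])


class TestPipeline:
    def test_smoke_and_determinism(self, tmp_path):
        """Small end-to-end run completes and is byte-identical under one seed."""
        config = PipelineConfig(n_subjects=4, n_starts=2, n_sim_subjects=10,
                                make_figures=True)
        run_paper_pipeline(config, seed=5, outdir=tmp_path / "a")
        run_paper_pipeline(config, seed=5, outdir=tmp_path / "b")
        for name in ["learning_rates.csv", "model_comparison.csv",
                     "sim_postlearning_relative.csv", "anova_learning.csv"]:
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()
        assert (tmp_path / "a" / "fig_learning.png").exists()
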