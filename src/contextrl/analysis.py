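"""Behavioural analyses and simulation-based signatures.

Covers the study's statistical surface: per-context correct-choice rates in
the learning test, option-wise choice rates in the post-learning transfer
test, repeated-measures ANOVA over the two-level within-subject factors,
out-of-sample post-learning prediction from final option values (frozen, no
updating), and the end-to-end pipeline that ties simulation, fitting, model
comparison and reporting together.

The headline signatures this module can reproduce:

* matched reward/punishment learning under the RELATIVE model vs a
  reward > punishment asymmetry in partial feedback under ABSOLUTE;
* value inversion in the transfer test — the RELATIVE model prefers the
  correct punishment option L25 (EV -12.5c) over the incorrect reward
  option G25 (EV +12.5c) in complete-feedback contexts, ABSOLUTE the
  reverse;
* better context-value resolution (V_reward - V_punishment) with complete
  than with partial feedback.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .agents import (
    ABSOLUTE,
    MODELS,
    RELATIVE,
    AgentParams,
    SimulatedSubject,
    simulate_agent,
    softmax_prob,
)
from .task_env import (
    COMPLETE,
    DEFAULT_TASK,
    PARTIAL,
    PUNISHMENT,
    REWARD,
    TaskConfig,
)

__all__ = [
    "summarize_learning",
    "predict_postlearning",
    "sample_postlearning_choices",
    "postlearning_option_rates",
    "postlearning_loglik",
    "rm_anova",
    "simulate_cohort",
    "cohort_learning_rates",
    "cohort_postlearning_rates",
    "cohort_final_values_cents",
    "cohort_context_value_resolution",
    "run_paper_pipeline",
    "PipelineConfig",
]

CELL_ORDER = [(REWARD, PARTIAL), (PUNISHMENT, PARTIAL), (REWARD, COMPLETE), (PUNISHMENT, COMPLETE)]
OPTION_ORDER = [("G75", PARTIAL), ("G25", PARTIAL), ("L25", PARTIAL), ("L75", PARTIAL),
                ("G75", COMPLETE), ("G25", COMPLETE), ("L25", COMPLETE), ("L75", COMPLETE)]


# ---------------------------------------------------------------------------
# Learning test
# ---------------------------------------------------------------------------

def summarize_learning(df: pd.DataFrame, value: str = "choice") -> pd.DataFrame:
    """Correct-choice rate per subject and design cell.

    ``value="choice"`` scores the indicator of choosing the most
    advantageous option (G75 in reward, L25 in punishment contexts);
    ``value="prob"`` averages a model's trial-wise probability of the
    correct choice (column ``p_correct`` from a replay or simulation
    trace). Wide output: one row per subject, one column per
    (valence, feedback) cell.
    """
    df = df.copy()
    if "subject" not in df.columns:
        df["subject"] = 0
    if value == "choice":
        good = np.where(df["context_valence"] == REWARD, "G75", "L25")
        df["_score"] = (df["chosen_label"] == good).astype(float)
    elif value == "prob":
        if "p_correct" not in df.columns:
            raise ValueError("value='prob' requires a p_correct column")
        df["_score"] = df["p_correct"]
    else:
        raise ValueError("value must be 'choice' or 'prob'")
    counts = df.groupby(["subject", "context_valence", "context_feedback"])["_score"].count()
    if (counts == 0).any():
        raise ValueError("design cell with zero trials")
    wide = (df.groupby(["subject", "context_valence", "context_feedback"])["_score"]
              .mean().unstack(["context_valence", "context_feedback"]))
    return wide[[c for c in CELL_ORDER if c in wide.columns]]


# ---------------------------------------------------------------------------
# Post-learning transfer test
# ---------------------------------------------------------------------------

def _as_option_key(key) -> tuple:
    # OptionSpec -> (label, feedback); tuples pass through
    label = getattr(key, "label", None)
    if label is not None:
        return (label, key.feedback)
    return tuple(key)


def predict_postlearning(q_by_option: dict, beta: float) -> pd.DataFrame:
    """Pairwise softmax choice probabilities from frozen final option values.

    ``q_by_option`` maps the 8 final-session options — keyed by
    ``(label, feedback)`` or by :class:`~contextrl.task_env.OptionSpec` —
    to their end-of-learning values. No feedback is delivered and no
    updating occurs, so predictions are invariant to trial order. Returns
    one row per ordered pair with the probability of choosing the first
    option.
    """
    q = {_as_option_key(k): float(v) for k, v in q_by_option.items()}
    rows = []
    for a, b in itertools.permutations(q, 2):
        rows.append({"option": a, "other": b,
                     "p_choose": softmax_prob(q[a], q[b], beta)})
    return pd.DataFrame(rows)


def _option_rates_from_pairs(pairs: pd.DataFrame) -> pd.Series:
    """Option-wise choice rate: mean probability across the 7 opponents."""
    rates = pairs.groupby("option")["p_choose"].mean()
    order = [k for k in OPTION_ORDER if k in rates.index]
    return rates.reindex(order)


def sample_postlearning_choices(schedule, q_by_option: dict, beta: float,
                                rng: np.random.Generator) -> list:
    """Sample transfer-test choices for a schedule from frozen values.

    Returns ``[(chosen_key, unchosen_key), ...]`` aligned with the
    schedule's trials.
    """
    q = {_as_option_key(k): float(v) for k, v in q_by_option.items()}
    out = []
    for trial in schedule:
        a, b = _as_option_key(trial.left_option), _as_option_key(trial.right_option)
        p_left = softmax_prob(q[a], q[b], beta)
        if rng.random() < p_left:
            out.append((a, b))
        else:
            out.append((b, a))
    return out


def postlearning_option_rates(choices) -> pd.Series:
    """Observed option-wise choice rate over all comparisons.

    ``choices`` is an iterable of ``(chosen_key, unchosen_key)``; each
    option's rate is the fraction of its trials in which it was chosen
    (28 trials per option under the full 112-trial schedule). The mean
    rate across options is exactly 0.5: every trial awards one choice
    shared between two options.
    """
    won: dict = {}
    seen: dict = {}
    for chosen, unchosen in choices:
        chosen, unchosen = _as_option_key(chosen), _as_option_key(unchosen)
        won[chosen] = won.get(chosen, 0) + 1
        seen[chosen] = seen.get(chosen, 0) + 1
        won.setdefault(unchosen, 0)
        seen[unchosen] = seen.get(unchosen, 0) + 1
    rates = pd.Series({k: won[k] / seen[k] for k in seen})
    order = [k for k in OPTION_ORDER if k in rates.index]
    return rates.reindex(order)


def postlearning_loglik(choices, q_by_option: dict, beta: float) -> float:
    """Cumulative log-likelihood of observed transfer choices.

    Scores each observed choice with the softmax over the pair's frozen
    final values; comparable across models on the same choice set.
    """
    q = {_as_option_key(k): float(v) for k, v in q_by_option.items()}
    ll = 0.0
    for chosen, unchosen in choices:
        chosen, unchosen = _as_option_key(chosen), _as_option_key(unchosen)
        if chosen not in q or unchosen not in q:
            raise ValueError(f"choice references unknown option {chosen} / {unchosen}")
        p = softmax_prob(q[chosen], q[unchosen], beta)
        ll += np.log(max(p, 1e-12))
    return float(ll)


# ---------------------------------------------------------------------------
# Repeated-measures ANOVA (all factors two-level, fully within subject)
# ---------------------------------------------------------------------------

def rm_anova(data: pd.DataFrame, dv: str, subject: str, factors: list[str]) -> pd.DataFrame:
    """Repeated-measures ANOVA for 2 or 3 two-level within-subject factors.

    Implements the standard within-subject partition in which every effect
    is tested against its own effect-by-subject interaction. With two-level
    factors this reduces to a one-sample t-test on per-subject +/-1
    contrast scores (F = t^2, df = (1, n-1)); the equivalence to the full
    sum-of-squares partition is exact. Unbalanced designs (missing
    subject x cell combinations) are rejected.
    """
    if not 2 <= len(factors) <= 3:
        raise ValueError("rm_anova supports 2 or 3 within factors")
    cell = data.groupby([subject] + factors, observed=True)[dv].mean().unstack(factors)
    if cell.isna().any().any():
        raise ValueError("unbalanced design: missing subject x cell combinations")
    levels = {f: sorted(data[f].unique()) for f in factors}
    for f, lv in levels.items():
        if len(lv) != 2:
            raise ValueError(f"factor {f!r} must have exactly 2 levels, got {lv}")
    n = len(cell)
    rows = []
    for r in range(1, len(factors) + 1):
        for effect in itertools.combinations(factors, r):
            signs = np.ones(cell.shape[1])
            for j, col in enumerate(cell.columns):
                key = col if isinstance(col, tuple) else (col,)
                for f in effect:
                    lvl = key[factors.index(f)]
                    signs[j] *= 1.0 if lvl == levels[f][0] else -1.0
            scores = cell.to_numpy() @ signs / cell.shape[1]
            mean, var = scores.mean(), scores.var(ddof=1)
            if var < 1e-300:
                F = 0.0 if mean * mean < 1e-300 else np.inf
            else:
                F = n * mean * mean / var
            p = float(stats.f.sf(F, 1, n - 1)) if np.isfinite(F) else 0.0
            rows.append({"effect": " x ".join(effect), "F": float(F),
                         "df1": 1, "df2": n - 1, "p": p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cohort simulation summaries
# ---------------------------------------------------------------------------

def simulate_cohort(model: str, params, n_subjects: int, rng: np.random.Generator,
                    config: TaskConfig = DEFAULT_TASK,
                    record_trace: bool = True) -> list[SimulatedSubject]:
    """Simulate ``n_subjects`` synthetic subjects generatively.

    ``params`` is either one :class:`AgentParams` shared by all subjects
    (group-mean mode) or a callable ``params(rng) -> AgentParams`` drawing
    individual parameters.
    """
    subjects = []
    for _ in range(n_subjects):
        p = params(rng) if callable(params) else params
        subjects.append(simulate_agent(model, p, rng, config=config,
                                       record_trace=record_trace))
    return subjects


def cohort_learning_rates(subjects: list[SimulatedSubject]) -> pd.DataFrame:
    """Per-subject mean p(correct) in each design cell (wide, one row each)."""
    rows = [s.p_correct_by_context() for s in subjects]
    out = pd.DataFrame(rows).reset_index(drop=True)
    out.columns = [tuple(c) for c in out.columns]
    return out[[c for c in CELL_ORDER if c in out.columns]]


def _final_session(config: TaskConfig) -> int:
    return config.n_sessions


def cohort_postlearning_rates(subjects: list[SimulatedSubject],
                              config: TaskConfig = DEFAULT_TASK) -> pd.DataFrame:
    """Per-subject predicted transfer-test choice rate for each option.

    Uses each subject's own inverse temperature on the frozen final values
    of the last learning session (the only options probed in the transfer
    test).
    """
    rows = []
    for s in subjects:
        q = s.final_q[_final_session(config)]
        pairs = predict_postlearning(q, s.params.beta)
        rows.append(_option_rates_from_pairs(pairs))
    return pd.DataFrame(rows).reset_index(drop=True)


def cohort_final_values_cents(subjects: list[SimulatedSubject],
                              config: TaskConfig = DEFAULT_TASK) -> pd.DataFrame:
    """Per-subject final option values of the last session, in cents."""
    rows = []
    for s in subjects:
        q = {_as_option_key(k): 100.0 * v
             for k, v in s.final_q[_final_session(config)].items()}
        rows.append(pd.Series(q))
    out = pd.DataFrame(rows).reset_index(drop=True)
    return out[[c for c in OPTION_ORDER if c in out.columns]]


def cohort_context_value_resolution(subjects: list[SimulatedSubject],
                                    config: TaskConfig = DEFAULT_TASK) -> pd.DataFrame:
    """Final V(reward) - V(punishment) per feedback condition, in cents.

    The RELATIVE model resolves context values better when counterfactual
    feedback is available, so the difference should be larger in complete
    than in partial contexts.
    """
    rows = []
    for s in subjects:
        v = s.final_v[_final_session(config)]
        rows.append({
            "dV_partial": 100.0 * (v[(REWARD, PARTIAL)] - v[(PUNISHMENT, PARTIAL)]),
            "dV_complete": 100.0 * (v[(REWARD, COMPLETE)] - v[(PUNISHMENT, COMPLETE)]),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Configuration for the full simulate-fit-compare-report pipeline."""

    n_subjects: int = 16
    generating_model: str = RELATIVE
    individual_params: bool = True  # sample per-subject parameters
    n_starts: int = 8
    n_sim_subjects: int = 200       # group-mean generative summaries
    make_figures: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


#: between-subject spreads implied by the reported group s.e.m. (n = 28)
GROUP_PARAM_SD = {
    ABSOLUTE: dict(beta=5.92, alpha1=0.02, alpha2=0.02, alpha3=0.0),
    RELATIVE: dict(beta=5.95, alpha1=0.02, alpha2=0.02, alpha3=0.07),
}
_SQRT_N = np.sqrt(28.0)


def sample_group_params(model: str, rng: np.random.Generator) -> AgentParams:
    """Draw one subject's parameters around the group means.

    Truncated normal draws centred on the likelihood-maximization group
    means with standard deviations sem * sqrt(28) (the cohort size behind
    the reported s.e.m.), clipped to the parameter bounds.
    """
    mean = AgentParams.group_means(model, "ll")
    sd = GROUP_PARAM_SD[model]
    beta = float(np.clip(rng.normal(mean.beta, sd["beta"] * _SQRT_N), 0.5, 100.0))
    a = {}
    for name in ("alpha1", "alpha2", "alpha3"):
        a[name] = float(np.clip(rng.normal(getattr(mean, name), sd[name] * _SQRT_N),
                                0.01, 0.99))
    if model == ABSOLUTE:
        a["alpha3"] = 0.0
    return AgentParams(beta=beta, **a)


def run_paper_pipeline(config: PipelineConfig, seed: int, outdir) -> dict:
    """End-to-end replication pipeline; writes tables (and figures) to outdir.

    Simulates a cohort from the generating model, fits both models by ML
    and MAP, produces the model-comparison table with random-effects BMS,
    the learning and transfer-test summaries with their ANOVAs, and the
    generative group-mean signatures. Deterministic given the seed; every
    table is written as CSV with the seed recorded in a manifest.
    """
    import json
    from pathlib import Path

    from .fitting import fit_cohort, fits_to_frame
    from .model_selection import bms_random_effects, fixed_effects_compare

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng([seed, 0xC0117])
    if config.individual_params:
        gen_params = lambda r: sample_group_params(config.generating_model, r)
    else:
        gen_params = AgentParams.group_means(config.generating_model, "ll")
    cohort = simulate_cohort(config.generating_model, gen_params,
                             config.n_subjects, rng)
    frames = {i: s.frame for i, s in enumerate(cohort)}

    # --- behavioural summaries of the simulated "observed" data
    observed = pd.concat([f.assign(subject=i) for i, f in frames.items()])
    learning = summarize_learning(observed, value="choice")
    learning.to_csv(outdir / "learning_rates.csv")
    long = learning.stack([0, 1], future_stack=True).rename("rate").reset_index()
    long.columns = ["subject", "valence", "feedback", "rate"]
    anova_learning = rm_anova(long, "rate", "subject", ["feedback", "valence"])
    anova_learning.to_csv(outdir / "anova_learning.csv", index=False)

    # --- fit both models, both objectives
    fits = {}
    for model in MODELS:
        for objective in ("ll", "lpp"):
            fits[(model, objective)] = fit_cohort(
                model, frames, objective=objective,
                n_starts=config.n_starts, seed=seed, bic_n=384)
            fits_to_frame(fits[(model, objective)]).to_csv(
                outdir / f"fits_{model}_{objective}.csv", index=False)

    # --- model-comparison table (deviance-scale criteria + BMS)
    comparison_rows = []
    evidence = np.column_stack([
        [fits[(m, "lpp")][s].lpp for s in sorted(frames)] for m in MODELS])
    bms = bms_random_effects(evidence, rng=rng, n_mc_samples=200_000)
    for j, model in enumerate(MODELS):
        per = [fits[(model, "ll")][s] for s in sorted(frames)]
        per_map = [fits[(model, "lpp")][s] for s in sorted(frames)]
        comparison_rows.append({
            "model": model, "df": per[0].df,
            "minus2_llmax": np.mean([f.deviance for f in per]),
            "aic_table": np.mean([f.aic_table for f in per]),
            "bic": np.mean([f.bic for f in per]),
            "minus2_lpp": np.mean([-2 * f.lpp for f in per_map]),
            "pp": bms.pp[j], "xp": bms.xp[j],
        })
    pd.DataFrame(comparison_rows).to_csv(outdir / "model_comparison.csv", index=False)
    fe = fixed_effects_compare(fits[(MODELS[0], "ll")], fits[(MODELS[1], "ll")])
    fe.to_csv(outdir / "fixed_effects.csv", index=False)

    # --- generative signatures at the group-mean parameters
    signatures = {}
    for model in MODELS:
        params = AgentParams.group_means(model, "ll")
        sim = simulate_cohort(model, params, config.n_sim_subjects, rng)
        lr = cohort_learning_rates(sim)
        pr = cohort_postlearning_rates(sim)
        fv = cohort_final_values_cents(sim)
        signatures[model] = {"learning": lr, "postlearning": pr, "final_values": fv}
        lr.to_csv(outdir / f"sim_learning_{model}.csv", index=False)
        pr.to_csv(outdir / f"sim_postlearning_{model}.csv", index=False)
        fv.to_csv(outdir / f"sim_final_values_{model}.csv", index=False)

    if config.make_figures:
        _write_figures(learning, signatures, outdir)

    manifest = {"seed": seed, "n_subjects": config.n_subjects,
                "generating_model": config.generating_model,
                "n_starts": config.n_starts,
                "n_sim_subjects": config.n_sim_subjects}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {"learning": learning, "anova_learning": anova_learning,
            "fits": fits, "bms": bms, "fixed_effects": fe,
            "signatures": signatures}


def _write_figures(learning: pd.DataFrame, signatures: dict, outdir) -> None:
    """Bar summaries of learning and transfer-test rates (one PNG each)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    means = learning.mean()
    sems = learning.sem()
    labels = [f"{v}\n{f}" for v, f in means.index]
    ax.bar(range(len(means)), means.to_numpy(), yerr=sems.to_numpy(),
           color=["tab:green", "tab:red", "tab:green", "tab:red"], alpha=0.7)
    for j, model in enumerate(signatures):
        sim = signatures[model]["learning"].mean()
        ax.plot(np.arange(len(sim)) + (j - 0.5) * 0.15, sim.to_numpy(),
                "o", mfc="k" if model == RELATIVE else "w", mec="k",
                label=model.upper())
    ax.set_xticks(range(len(means)), labels)
    ax.axhline(0.5, ls=":", c="gray")
    ax.set_ylabel("correct choice rate")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(outdir / "fig_learning.png", dpi=150)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(7, 4))
    for j, model in enumerate(signatures):
        pr = signatures[model]["postlearning"].mean()
        ax.plot(range(len(pr)), pr.to_numpy(), "o-",
                mfc="k" if model == RELATIVE else "w", mec="k", c="gray",
                label=model.upper())
        ax.set_xticks(range(len(pr)), [f"{l}\n{f}" for l, f in pr.index])
    ax.axhline(0.5, ls=":", c="gray")
    ax.set_ylabel("transfer-test choice rate")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(outdir / "fig_postlearning.png", dpi=150)
    plt.close(fig)
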