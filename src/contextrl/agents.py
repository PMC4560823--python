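"""ABSOLUTE and RELATIVE reinforcement-learning agents.

Two delta-rule learners compete to explain choices in the contextual bandit:

* **ABSOLUTE** — counterfactual Q-learning. The chosen option's value is
  updated with the Rescorla-Wagner rule ``Q(s,c) += alpha1 * dC`` where
  ``dC = R_C - Q(s,c)``; in complete-feedback contexts the unchosen option
  is updated analogously with the counterfactual learning rate
  (``dU = R_U - Q(s,u)``, ``Q(s,u) += alpha2 * dU``). Option values live on
  the absolute outcome scale.

* **RELATIVE** — context-value-centred learning. The agent additionally
  tracks a context value V(s), learned in a random-policy manner from the
  context-level outcome ``R_V = (R_C + R_U) / 2`` (in partial feedback the
  current Q(s,u) stands proxy for the unseen R_U):
  ``dV = R_V - V(s)``, ``V(s) += alpha3 * dV``. V(s) is the reference point
  that centres option prediction errors: ``dC = (R_C - V(s)) - Q(s,c)`` and
  ``dU = (R_U - V(s)) - Q(s,u)``. Option values therefore become relative to
  their choice context, which lets successful punishment avoidance (the
  neutral 0 EUR outcome) acquire a positive value.

Setting ``alpha3 = 0`` (with V0 = 0) reduces RELATIVE exactly to ABSOLUTE.

All prediction errors on a trial are computed from pre-update (time-t)
values, then all increments are applied. Decision-making is a softmax over
the pair's current Q values with inverse temperature beta. Q and V start at
0 and reset with each session's novel options.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .task_env import (
    COMPLETE,
    DEFAULT_TASK,
    PUNISHMENT,
    REWARD,
    ContextSpec,
    LearningTrial,
    OptionSpec,
    TaskConfig,
    build_session_schedule,
    draw_outcomes,
    trials_to_frame,
)

__all__ = [
    "ABSOLUTE",
    "RELATIVE",
    "MODELS",
    "AgentParams",
    "AgentState",
    "TrialUpdate",
    "softmax_prob",
    "compute_rv",
    "absolute_update",
    "relative_update",
    "simulate_agent",
    "one_step_probs",
    "replay_final_values",
    "SimulatedSubject",
    "GROUP_PARAMS_LL",
    "GROUP_PARAMS_MAP",
]

ABSOLUTE = "absolute"
RELATIVE = "relative"
MODELS = (ABSOLUTE, RELATIVE)

#: group-mean parameters from likelihood maximization (learning-test fits)
GROUP_PARAMS_LL = {
    ABSOLUTE: dict(beta=17.4, alpha1=0.28, alpha2=0.18, alpha3=0.0),
    RELATIVE: dict(beta=21.52, alpha1=0.19, alpha2=0.15, alpha3=0.33),
}
#: group-mean parameters from posterior-probability (MAP) maximization
GROUP_PARAMS_MAP = {
    ABSOLUTE: dict(beta=11.4, alpha1=0.29, alpha2=0.20, alpha3=0.0),
    RELATIVE: dict(beta=13.66, alpha1=0.20, alpha2=0.16, alpha3=0.34),
}


@dataclass(frozen=True)
class AgentParams:
    """Free parameters: inverse temperature and the three learning rates.

    ``alpha3`` (contextual learning rate) is fixed at 0 for the ABSOLUTE
    model, giving it 3 free parameters to RELATIVE's 4.
    """

    beta: float
    alpha1: float
    alpha2: float
    alpha3: float = 0.0

    def __post_init__(self):
        if not (math.isfinite(self.beta) and self.beta >= 0):
            raise ValueError(f"beta must be finite and >= 0, got {self.beta}")
        for name in ("alpha1", "alpha2", "alpha3"):
            a = getattr(self, name)
            if not (0.0 <= a <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {a}")

    @classmethod
    def group_means(cls, model: str, objective: str = "ll") -> "AgentParams":
        table = GROUP_PARAMS_LL if objective == "ll" else GROUP_PARAMS_MAP
        return cls(**table[model])

    def n_free(self, model: str) -> int:
        return 4 if model == RELATIVE else 3

    def as_vector(self, model: str) -> np.ndarray:
        v = [self.beta, self.alpha1, self.alpha2]
        if model == RELATIVE:
            v.append(self.alpha3)
        return np.asarray(v)

    @classmethod
    def from_vector(cls, theta, model: str) -> "AgentParams":
        theta = list(theta)
        if model == RELATIVE:
            return cls(beta=theta[0], alpha1=theta[1], alpha2=theta[2], alpha3=theta[3])
        return cls(beta=theta[0], alpha1=theta[1], alpha2=theta[2], alpha3=0.0)


@dataclass
class AgentState:
    """Per-context option values Q(s, .) and context values V(s), in euros."""

    Q: dict = field(default_factory=dict)  # option_id -> value
    V: dict = field(default_factory=dict)  # context_id -> value

    def q(self, option: OptionSpec) -> float:
        return self.Q.get(option.option_id, 0.0)

    def v(self, context: ContextSpec) -> float:
        return self.V.get(context.context_id, 0.0)


@dataclass(frozen=True)
class TrialUpdate:
    """Prediction errors of one trial (pre-update values on the RHS)."""

    delta_c: float
    delta_u: float | None = None   # complete feedback only
    delta_v: float | None = None   # RELATIVE only
    r_v: float | None = None       # RELATIVE only


def softmax_prob(q_chosen: float, q_other: float, beta: float) -> float:
    """Probability of picking the first option under a two-option softmax.

    Computed through the logistic of ``beta * (q_chosen - q_other)`` so it
    stays numerically stable at large inverse temperatures.
    """
    if beta < 0 or not math.isfinite(beta):
        raise ValueError(f"beta must be finite and >= 0, got {beta}")
    if not (math.isfinite(q_chosen) and math.isfinite(q_other)):
        raise ValueError("non-finite option values")
    x = beta * (q_chosen - q_other)
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def _check_feedback(trial: LearningTrial) -> bool:
    complete = trial.context.feedback == COMPLETE
    if complete and trial.outcome_unchosen is None:
        raise ValueError("complete-feedback trial without counterfactual outcome")
    if not complete and trial.outcome_unchosen is not None:
        raise ValueError("partial-feedback trial with counterfactual outcome")
    return complete


def absolute_update(state: AgentState, trial: LearningTrial, params: AgentParams) -> TrialUpdate:
    """Apply the ABSOLUTE (counterfactual Q-learning) update in place."""
    complete = _check_feedback(trial)
    c, u = trial.chosen, trial.unchosen
    q_c = state.q(c)
    delta_c = trial.outcome_chosen - q_c
    delta_u = None
    if complete:
        q_u = state.q(u)
        delta_u = trial.outcome_unchosen - q_u
        state.Q[u.option_id] = q_u + params.alpha2 * delta_u
    state.Q[c.option_id] = q_c + params.alpha1 * delta_c
    return TrialUpdate(delta_c=delta_c, delta_u=delta_u)


def compute_rv(r_c: float, r_u_or_qu: float) -> float:
    """Context-level outcome: the mean of factual and counterfactual terms.

    In complete-feedback contexts the second argument is the observed R_U;
    in partial feedback it is the current Q(s,u), used as a proxy for the
    unseen counterfactual outcome.
    """
    return 0.5 * (r_c + r_u_or_qu)


def relative_update(state: AgentState, trial: LearningTrial, params: AgentParams) -> TrialUpdate:
    """Apply the RELATIVE (context-value-centred) update in place.

    All right-hand sides use pre-update values: in partial feedback the
    unchosen Q feeds R_V read-only before any increment is applied.
    """
    complete = _check_feedback(trial)
    c, u = trial.chosen, trial.unchosen
    ctx = trial.context
    q_c, q_u, v = state.q(c), state.q(u), state.v(ctx)
    delta_c = (trial.outcome_chosen - v) - q_c
    if complete:
        delta_u = (trial.outcome_unchosen - v) - q_u
        r_v = compute_rv(trial.outcome_chosen, trial.outcome_unchosen)
    else:
        delta_u = None
        r_v = compute_rv(trial.outcome_chosen, q_u)
    delta_v = r_v - v
    state.Q[c.option_id] = q_c + params.alpha1 * delta_c
    if complete:
        state.Q[u.option_id] = q_u + params.alpha2 * delta_u
    state.V[ctx.context_id] = v + params.alpha3 * delta_v
    return TrialUpdate(delta_c=delta_c, delta_u=delta_u, delta_v=delta_v, r_v=r_v)


def _update(model: str, state: AgentState, trial: LearningTrial, params: AgentParams) -> TrialUpdate:
    if model == ABSOLUTE:
        return absolute_update(state, trial, params)
    if model == RELATIVE:
        return relative_update(state, trial, params)
    raise ValueError(f"unknown model {model!r}")


@dataclass
class SimulatedSubject:
    """Output of one generative simulation run."""

    model: str
    params: AgentParams
    trials: list                              # completed LearningTrial objects
    trace: pd.DataFrame | None                # tidy latent-variable table
    final_q: dict                             # session -> {OptionSpec: Q}
    final_v: dict                             # session -> {(valence, feedback): V}

    @property
    def frame(self) -> pd.DataFrame:
        return trials_to_frame(self.trials)

    def p_correct_by_context(self) -> pd.Series:
        """Mean model probability of the correct choice per design cell."""
        if self.trace is None:
            raise ValueError("simulation was run without trace recording")
        return self.trace.groupby(["context_valence", "context_feedback"])["p_correct"].mean()


def simulate_agent(
    model: str,
    params: AgentParams,
    rng: np.random.Generator,
    config: TaskConfig = DEFAULT_TASK,
    schedules: list | None = None,
    record_trace: bool = True,
) -> SimulatedSubject:
    """Generative simulation of one synthetic subject on the full task.

    At every trial the choice is sampled from the softmax over the pair's
    current Q values, outcomes are drawn from the task contingencies, and
    the model's rule updates the state. Values reset with each session's
    novel options. The trace records, per trial, the softmax probability of
    the sampled choice and of the correct option plus all latent variables.
    """
    if schedules is None:
        schedules = [build_session_schedule(s, rng, config)
                     for s in range(1, config.n_sessions + 1)]
    trials: list[LearningTrial] = []
    rows: list[dict] | None = [] if record_trace else None
    final_q: dict[int, dict] = {}
    final_v: dict[int, dict] = {}
    for schedule in schedules:
        state = AgentState()
        session = schedule[0].session
        for skel in schedule:
            ctx = skel.context
            left, right = skel.left_option, skel.right_option
            p_left = softmax_prob(state.q(left), state.q(right), params.beta)
            choose_left = rng.random() < p_left
            chosen, unchosen = (left, right) if choose_left else (right, left)
            p_chosen = p_left if choose_left else 1.0 - p_left
            p_correct = softmax_prob(state.q(ctx.good_option), state.q(ctx.bad_option),
                                     params.beta)
            r_c, r_u = draw_outcomes(skel, chosen, rng)
            trial = LearningTrial(session=skel.session, trial_index=skel.trial_index,
                                  context=ctx, left_option=left, right_option=right,
                                  chosen=chosen, unchosen=unchosen,
                                  outcome_chosen=r_c, outcome_unchosen=r_u)
            q_c_pre, q_u_pre, v_pre = state.q(chosen), state.q(unchosen), state.v(ctx)
            upd = _update(model, state, trial, params)
            trials.append(trial)
            if rows is not None:
                rows.append({
                    "session": trial.session, "trial": trial.trial_index,
                    "context_valence": ctx.valence, "context_feedback": ctx.feedback,
                    "chosen_label": chosen.label, "correct": chosen.option_id == ctx.good_option.option_id,
                    "p_chosen": p_chosen, "p_correct": p_correct,
                    "Q_chosen": q_c_pre, "Q_unchosen": q_u_pre, "V": v_pre,
                    "delta_C": upd.delta_c,
                    "delta_U": 0.0 if upd.delta_u is None else upd.delta_u,
                    "delta_V": np.nan if upd.delta_v is None else upd.delta_v,
                    "R_C": r_c, "R_U": np.nan if r_u is None else r_u,
                })
        contexts = {t.context.context_id: t.context for t in schedule}
        final_q[session] = {opt: state.q(opt)
                            for ctx in contexts.values() for opt in ctx.options}
        final_v[session] = {(ctx.valence, ctx.feedback): state.v(ctx)
                            for ctx in contexts.values()}
    trace = pd.DataFrame(rows) if rows is not None else None
    return SimulatedSubject(model=model, params=params, trials=trials,
                            trace=trace, final_q=final_q, final_v=final_v)


# ---------------------------------------------------------------------------
# Observed-data replay (one-step-ahead probabilities)
# ---------------------------------------------------------------------------

def _good_label(valence: str) -> str:
    return "G75" if valence == REWARD else "L25"


def encode_frame(df: pd.DataFrame):
    """Compile a single-subject trial table into flat replay arrays.

    Options and contexts are indexed session-locally (identity never crosses
    sessions), so zero-initialised flat value arrays implement the
    per-session reset for free. Returns plain Python lists: the replay loop
    is scalar and list indexing is the fast path.
    """
    if df["subject"].nunique() > 1:
        raise ValueError("encode_frame expects a single subject")
    df = df.sort_values(["session", "trial"])
    tr = df["trial"].to_numpy()
    ses = df["session"].to_numpy()
    for s in np.unique(ses):
        t = tr[ses == s]
        if not np.array_equal(np.sort(t), np.arange(1, len(t) + 1)):
            raise ValueError(f"session {s}: trial indices must be 1..n without gaps")
    ctx_key = list(zip(df["session"], df["context_valence"], df["context_feedback"]))
    ctx_ids = {k: i for i, k in enumerate(dict.fromkeys(ctx_key))}
    opt_ids: dict = {}

    def oid(session, valence, feedback, label):
        k = (session, valence, feedback, label)
        return opt_ids.setdefault(k, len(opt_ids))

    ctx = [ctx_ids[k] for k in ctx_key]
    rows = df.itertuples(index=False)
    chosen, unchosen, good, r_c, r_u, complete, correct = [], [], [], [], [], [], []
    for row in rows:
        g = _good_label(row.context_valence)
        chosen.append(oid(row.session, row.context_valence, row.context_feedback, row.chosen_label))
        unchosen.append(oid(row.session, row.context_valence, row.context_feedback, row.unchosen_label))
        good.append(oid(row.session, row.context_valence, row.context_feedback, g))
        r_c.append(float(row.outcome_chosen))
        is_complete = row.context_feedback == COMPLETE
        complete.append(is_complete)
        r_u.append(float(row.outcome_unchosen) if is_complete else 0.0)
        correct.append(row.chosen_label == g)
    return dict(ctx=ctx, chosen=chosen, unchosen=unchosen, good=good,
                r_c=r_c, r_u=r_u, complete=complete, correct=correct,
                n_ctx=len(ctx_ids), n_opt=len(opt_ids),
                ctx_keys=list(ctx_ids), opt_keys=list(opt_ids))


def replay_probs(coded: dict, beta: float, a1: float, a2: float, a3: float,
                 relative: bool, return_state: bool = False):
    """Replay an observed choice sequence; return per-trial probabilities.

    Emits, before each update, the softmax probability of the observed
    choice and of the correct option. Deterministic given the data and
    parameters.
    """
    Q = [0.0] * coded["n_opt"]
    V = [0.0] * coded["n_ctx"]
    p_choice: list[float] = []
    p_correct: list[float] = []
    exp = math.exp
    for s, c, u, g, rc, ru, comp in zip(coded["ctx"], coded["chosen"], coded["unchosen"],
                                        coded["good"], coded["r_c"], coded["r_u"],
                                        coded["complete"]):
        qc, qu = Q[c], Q[u]
        x = beta * (qc - qu)
        if x >= 0:
            p = 1.0 / (1.0 + exp(-x))
        else:
            e = exp(x)
            p = e / (1.0 + e)
        p_choice.append(p)
        qg = Q[g]
        qb = qu if g == c else qc  # the bad option is the other one in the pair
        y = beta * (qg - qb)
        if y >= 0:
            p_correct.append(1.0 / (1.0 + exp(-y)))
        else:
            e = exp(y)
            p_correct.append(e / (1.0 + e))
        if relative:
            v = V[s]
            dc = (rc - v) - qc
            if comp:
                du = (ru - v) - qu
                rv = 0.5 * (rc + ru)
                Q[u] = qu + a2 * du
            else:
                rv = 0.5 * (rc + qu)
            Q[c] = qc + a1 * dc
            V[s] = v + a3 * (rv - v)
        else:
            if comp:
                Q[u] = qu + a2 * (ru - qu)
            Q[c] = qc + a1 * (rc - qc)
    if return_state:
        return p_choice, p_correct, Q, V
    return p_choice, p_correct


def one_step_probs(model: str, params: AgentParams, df: pd.DataFrame) -> pd.DataFrame:
    """Per-trial one-step-ahead probabilities on observed data.

    Replays the subject's own history of choices and outcomes under the
    model with the given parameters, emitting for every trial the softmax
    probability of the observed choice and of the correct option, computed
    from the values held before that trial's update.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    coded = encode_frame(df)
    p_choice, p_correct = replay_probs(coded, params.beta, params.alpha1,
                                       params.alpha2, params.alpha3,
                                       relative=(model == RELATIVE))
    out = df.sort_values(["session", "trial"]).reset_index(drop=True).copy()
    out["p_choice"] = p_choice
    out["p_correct"] = p_correct
    out["chose_correct"] = coded["correct"]
    return out


def replay_final_values(model: str, params: AgentParams, df: pd.DataFrame):
    """End-of-run latent values from replaying an observed dataset.

    Returns ``(final_q, final_v)`` where ``final_q`` maps
    ``(session, valence, feedback, label)`` to the option's final Q and
    ``final_v`` maps ``(session, valence, feedback)`` to the context's
    final V. Used for out-of-sample post-learning prediction, which relies
    on the values held at the end of the last learning session.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    coded = encode_frame(df)
    _, _, Q, V = replay_probs(coded, params.beta, params.alpha1, params.alpha2,
                              params.alpha3, relative=(model == RELATIVE),
                              return_state=True)
    final_q = {key: Q[i] for i, key in enumerate(coded["opt_keys"])}
    final_v = {key: V[i] for i, key in enumerate(coded["ctx_keys"])}
    return final_q, final_v
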