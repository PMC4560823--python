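"""Probabilistic instrumental-learning task: structure, schedules and outcomes.

The task is a 2x2 within-subject contextual bandit. Each learning session
presents four fixed pairs of options ("contexts"), one per cell of the
(valence: reward/punishment) x (feedback: partial/complete) design. Within a
context the two options deliver a non-zero outcome (+0.5 EUR in reward
contexts, -0.5 EUR in punishment contexts, 0 EUR otherwise) with reciprocal
probabilities 0.75/0.25, drawn independently per option on every trial. Each
pair appears 24 times per session (96 trials/session, 4 sessions), and every
session introduces eight novel options. After learning, a transfer
("post-learning") test presents all 28 unordered pairs of the final session's
8 options, 4 times each (112 trials), with no feedback.

Outcomes are stored in euros (+/-0.5, 0); :func:`expected_value_cents`
converts to the cent scale used for reporting.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "REWARD",
    "PUNISHMENT",
    "PARTIAL",
    "COMPLETE",
    "TaskConfig",
    "DEFAULT_TASK",
    "OptionSpec",
    "ContextSpec",
    "LearningTrial",
    "PostLearningTrial",
    "expected_value_cents",
    "session_contexts",
    "build_session_schedule",
    "draw_outcomes",
    "build_postlearning_schedule",
    "trials_to_frame",
    "frame_to_trials",
    "write_trials",
    "read_trials",
]

REWARD = "reward"
PUNISHMENT = "punishment"
PARTIAL = "partial"
COMPLETE = "complete"

VALENCES = (REWARD, PUNISHMENT)
FEEDBACKS = (PARTIAL, COMPLETE)

#: canonical context order within a session (one per design cell)
CONTEXT_CELLS = tuple(itertools.product(VALENCES, FEEDBACKS))


@dataclass(frozen=True)
class TaskConfig:
    """Tunable task-structure constants.

    Defaults reproduce the study design; they are configurable so that
    degenerate variants (e.g. deterministic outcomes) can be built for
    testing and sensitivity analyses.
    """

    n_sessions: int = 4
    trials_per_context: int = 24
    p_high: float = 0.75
    p_low: float = 0.25
    magnitude: float = 0.5  # euros
    post_repeats: int = 4
    max_context_run: int = 4  # pseudorandomization run-length cap

    @property
    def trials_per_session(self) -> int:
        return self.trials_per_context * len(CONTEXT_CELLS)

    @classmethod
    def from_yaml(cls, path) -> "TaskConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


DEFAULT_TASK = TaskConfig()


@dataclass(frozen=True)
class OptionSpec:
    """One bandit option: a symbol with a fixed outcome lottery.

    ``label`` follows the field's G/L naming: G75/G25 win +0.5 EUR with
    probability 0.75/0.25; L75/L25 lose 0.5 EUR with probability 0.75/0.25.
    Option identity is session-scoped: every session introduces 8 novel
    options and ``option_id`` is unique across the whole experiment.
    """

    option_id: int
    label: str  # G75 | G25 | L75 | L25
    feedback: str
    p_nonzero: float
    magnitude: float

    def __post_init__(self):
        if not 0.0 <= self.p_nonzero <= 1.0:
            raise ValueError(f"p_nonzero out of [0,1]: {self.p_nonzero}")


def expected_value_cents(option: OptionSpec) -> float:
    """Expected outcome of one pull, in cents: 100 * p(non-zero) * magnitude."""
    return 100.0 * option.p_nonzero * option.magnitude


@dataclass(frozen=True)
class ContextSpec:
    """A fixed pair of options always shown together (the choice state s)."""

    context_id: int
    valence: str
    feedback: str
    good_option: OptionSpec
    bad_option: OptionSpec

    def __post_init__(self):
        if self.valence not in VALENCES:
            raise ValueError(f"unknown valence {self.valence!r}")
        if self.feedback not in FEEDBACKS:
            raise ValueError(f"unknown feedback {self.feedback!r}")

    @property
    def options(self) -> tuple[OptionSpec, OptionSpec]:
        return (self.good_option, self.bad_option)

    @property
    def outcome_set(self) -> tuple[float, float]:
        return (self.good_option.magnitude, 0.0)


@dataclass
class LearningTrial:
    """One learning-test trial; outcome fields are None on skeletons."""

    session: int
    trial_index: int
    context: ContextSpec
    left_option: OptionSpec
    right_option: OptionSpec
    chosen: OptionSpec | None = None
    unchosen: OptionSpec | None = None
    outcome_chosen: float | None = None     # R_C, euros
    outcome_unchosen: float | None = None   # R_U, euros; None in partial feedback

    @property
    def side_of_chosen(self) -> str | None:
        if self.chosen is None:
            return None
        return "left" if self.chosen.option_id == self.left_option.option_id else "right"


@dataclass
class PostLearningTrial:
    """One transfer-test trial (no feedback, values probed out of context)."""

    trial_index: int
    left_option: OptionSpec
    right_option: OptionSpec
    chosen: OptionSpec | None = None


def session_contexts(session_index: int, config: TaskConfig = DEFAULT_TASK) -> list[ContextSpec]:
    """The four contexts of one session, with session-scoped option ids.

    Option ids are ``(session_index - 1) * 8 + k`` so that options are never
    reused across sessions and learned values never carry over.
    """
    if not 1 <= session_index <= config.n_sessions:
        raise ValueError(f"session index {session_index} out of 1..{config.n_sessions}")
    contexts = []
    base = (session_index - 1) * 8
    for c, (valence, feedback) in enumerate(CONTEXT_CELLS):
        sign = 1.0 if valence == REWARD else -1.0
        letter = "G" if valence == REWARD else "L"
        mag = sign * config.magnitude
        if valence == REWARD:
            good = OptionSpec(base + 2 * c, f"{letter}75", feedback, config.p_high, mag)
            bad = OptionSpec(base + 2 * c + 1, f"{letter}25", feedback, config.p_low, mag)
        else:
            # least-punishing option is correct: L25 loses only 25% of the time
            good = OptionSpec(base + 2 * c, f"{letter}25", feedback, config.p_low, mag)
            bad = OptionSpec(base + 2 * c + 1, f"{letter}75", feedback, config.p_high, mag)
        contexts.append(ContextSpec(4 * (session_index - 1) + c, valence, feedback, good, bad))
    return contexts


def _interleave_contexts(n_ctx: int, reps: int, max_run: int, rng: np.random.Generator) -> np.ndarray:
    """Shuffle a balanced context sequence, rejecting runs longer than max_run."""
    seq = np.repeat(np.arange(n_ctx), reps)
    for _ in range(10_000):
        rng.shuffle(seq)
        run, longest = 1, 1
        for a, b in zip(seq[:-1], seq[1:]):
            run = run + 1 if a == b else 1
            longest = max(longest, run)
        if longest <= max_run:
            return seq.copy()
    raise RuntimeError("could not satisfy run-length constraint")  # pragma: no cover


def build_session_schedule(
    session_index: int,
    rng: np.random.Generator,
    config: TaskConfig = DEFAULT_TASK,
) -> list[LearningTrial]:
    """Generate one session's 96 trial skeletons (no choices, no outcomes).

    Contexts are interleaved pseudorandomly (no context more than
    ``config.max_context_run`` times in a row) and within each context the
    good option appears on the left on exactly half of its presentations.
    """
    contexts = session_contexts(session_index, config)
    order = _interleave_contexts(len(contexts), config.trials_per_context,
                                 config.max_context_run, rng)
    # per context: balanced left/right assignment of the good option
    sides: dict[int, list[bool]] = {}
    for c in range(len(contexts)):
        half = config.trials_per_context // 2
        good_left = np.array([True] * half + [False] * (config.trials_per_context - half))
        rng.shuffle(good_left)
        sides[c] = list(good_left)
    counters = [0] * len(contexts)
    trials = []
    for t, c in enumerate(order, start=1):
        ctx = contexts[c]
        good_left = sides[c][counters[c]]
        counters[c] += 1
        left, right = (ctx.good_option, ctx.bad_option) if good_left else (ctx.bad_option, ctx.good_option)
        trials.append(LearningTrial(session=session_index, trial_index=t,
                                    context=ctx, left_option=left, right_option=right))
    return trials


def draw_outcomes(
    trial: LearningTrial,
    chosen: OptionSpec,
    rng: np.random.Generator,
) -> tuple[float, float | None]:
    """Draw (R_C, R_U) for a trial given the chosen option.

    Both options' outcomes are Bernoulli(p_nonzero) * magnitude, drawn
    independently; the unchosen outcome is revealed (returned) only in
    complete-feedback contexts, else None.
    """
    pair_ids = {trial.left_option.option_id, trial.right_option.option_id}
    if chosen.option_id not in pair_ids:
        raise ValueError(f"option {chosen.option_id} not in this trial's pair {pair_ids}")
    unchosen = trial.right_option if chosen.option_id == trial.left_option.option_id else trial.left_option
    r_c = chosen.magnitude if rng.random() < chosen.p_nonzero else 0.0
    if trial.context.feedback == COMPLETE:
        r_u = unchosen.magnitude if rng.random() < unchosen.p_nonzero else 0.0
    else:
        r_u = None
    return r_c, r_u


def build_postlearning_schedule(
    options: Sequence[OptionSpec],
    rng: np.random.Generator,
    repeats: int = DEFAULT_TASK.post_repeats,
) -> list[PostLearningTrial]:
    """All pairwise combinations of the final session's options.

    Every unordered pair of the 8 options appears ``repeats`` times (112
    trials at the default 4), with left/right placement balanced within pair.
    """
    ids = [o.option_id for o in options]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate options in post-learning set")
    pairs = list(itertools.combinations(options, 2))
    slots: list[tuple[OptionSpec, OptionSpec]] = []
    for a, b in pairs:
        arrangement = [(a, b), (b, a)] * (repeats // 2) + [(a, b)] * (repeats % 2)
        slots.extend(arrangement)
    idx = rng.permutation(len(slots))
    return [PostLearningTrial(trial_index=t + 1, left_option=slots[i][0], right_option=slots[i][1])
            for t, i in enumerate(idx)]


# ---------------------------------------------------------------------------
# Tabular interchange: one row per trial, delimited text
# ---------------------------------------------------------------------------

TRIAL_COLUMNS = [
    "subject", "session", "trial", "context_valence", "context_feedback",
    "chosen_label", "unchosen_label", "outcome_chosen", "outcome_unchosen", "side",
]


def trials_to_frame(trials: Iterable[LearningTrial], subject: int | str = 0) -> pd.DataFrame:
    """Flatten completed learning trials to the documented column schema.

    The missing counterfactual outcome (partial feedback) is an empty field
    (NaN). Raises on trials without a recorded choice.
    """
    rows = []
    for tr in trials:
        if tr.chosen is None or tr.outcome_chosen is None:
            raise ValueError(f"trial {tr.session}:{tr.trial_index} has no recorded choice/outcome")
        rows.append({
            "subject": subject,
            "session": tr.session,
            "trial": tr.trial_index,
            "context_valence": tr.context.valence,
            "context_feedback": tr.context.feedback,
            "chosen_label": tr.chosen.label,
            "unchosen_label": tr.unchosen.label,
            "outcome_chosen": tr.outcome_chosen,
            "outcome_unchosen": np.nan if tr.outcome_unchosen is None else tr.outcome_unchosen,
            "side": tr.side_of_chosen,
        })
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def frame_to_trials(df: pd.DataFrame, config: TaskConfig = DEFAULT_TASK) -> dict:
    """Validate and regroup a trial table by subject.

    Checks the schema, rejects rows with missing choices, and enforces the
    feedback/counterfactual consistency rule (R_U present iff complete).
    Returns ``{subject: sorted DataFrame}``.
    """
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    if df["chosen_label"].isna().any() or df["outcome_chosen"].isna().any():
        raise ValueError("trial table contains missing choices/outcomes")
    complete = df["context_feedback"] == COMPLETE
    if df.loc[complete, "outcome_unchosen"].isna().any():
        raise ValueError("complete-feedback trial without counterfactual outcome")
    if df.loc[~complete, "outcome_unchosen"].notna().any():
        raise ValueError("partial-feedback trial with counterfactual outcome")
    out = {}
    for subject, grp in df.groupby("subject"):
        out[subject] = grp.sort_values(["session", "trial"]).reset_index(drop=True)
    return out


def write_trials(df: pd.DataFrame, path, sep: str = ",") -> None:
    df.to_csv(path, sep=sep, index=False)


def read_trials(path, sep: str = ",") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep)
    frame_to_trials(df)  # validation only
    return df
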