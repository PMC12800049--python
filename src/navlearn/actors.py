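"""Computational benchmark policies for the two-path choice task.

Three families of actors are run on sequences of open pathways:

* the **Bayesian ideal actor** — holds a Beta posterior over the
  probability that the left pathway is open, updated from a uniform
  prior by the observed open side each trial, and chooses the side with
  the higher posterior mean (seeded fair coin on ties);
* the **win-stay/lose-shift (WSLS) actor** — repeats its previous choice
  after a correct outcome and switches after an error, which is
  equivalent to always choosing the previously-open side;
* **fixed policies** (always-left / always-right / always-majority-side)
  used as analytic checks on the generators.

The posterior resets at each block boundary: the block-wise regularity
must be re-inferred every block.  The actor observes the realized open
side on every trial regardless of its own choice.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class PosteriorState:
    """Beta posterior over P(left pathway open); uniform prior is (1, 1)."""
    alpha: float = 1.0  # pseudo-count of "left open" + 1
    beta: float = 1.0   # pseudo-count of "right open" + 1

    def __post_init__(self) -> None:
        if self.alpha < 1 or self.beta < 1:
            raise ValueError("alpha and beta must be >= 1")

    @property
    def mean_left(self) -> float:
        return self.alpha / (self.alpha + self.beta)


def beta_bernoulli_update(state: PosteriorState, observed_open: str) -> PosteriorState:
    """Conjugate update after observing which side was open."""
    if observed_open == "left":
        return PosteriorState(state.alpha + 1, state.beta)
    if observed_open == "right":
        return PosteriorState(state.alpha, state.beta + 1)
    raise ValueError(f"observed_open must be 'left' or 'right', got {observed_open!r}")


@dataclass
class ActorRun:
    """Choices and correctness of one policy on one block's open sequence."""
    policy: str
    choices: np.ndarray
    correct: np.ndarray

    def __post_init__(self) -> None:
        if len(self.choices) != len(self.correct):
            raise ValueError("choices and correct must have equal length")

    @property
    def accuracy(self) -> float:
        return float(np.mean(self.correct))


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _coin(rng: np.random.Generator) -> str:
    return "left" if rng.random() < 0.5 else "right"


def ideal_actor_run(open_sequence, seed=0) -> ActorRun:
    """Bayesian ideal actor on one block (posterior starts uniform).

    Each trial it chooses the side with the higher posterior mean of
    being open (ties, including trial 1, broken by a seeded fair coin),
    then updates with the observed open side.
    """
    open_sequence = list(open_sequence)
    if not open_sequence:
        raise ValueError("open_sequence must be nonempty")
    rng = _as_rng(seed)
    state = PosteriorState()
    choices, correct = [], []
    for open_side in open_sequence:
        if state.mean_left > 0.5:
            c = "left"
        elif state.mean_left < 0.5:
            c = "right"
        else:
            c = _coin(rng)
        choices.append(c)
        correct.append(c == open_side)
        state = beta_bernoulli_update(state, open_side)
    return ActorRun("ideal", np.array(choices), np.array(correct, dtype=bool))


def wsls_run(open_sequence, seed=0) -> ActorRun:
    """Win-stay/lose-shift actor on one block (first choice: fair coin).

    Staying after a win and shifting after a loss both land on the side
    that was open on the previous trial.
    """
    open_sequence = list(open_sequence)
    if not open_sequence:
        raise ValueError("open_sequence must be nonempty")
    rng = _as_rng(seed)
    c = _coin(rng)
    choices, correct = [], []
    for open_side in open_sequence:
        choices.append(c)
        win = c == open_side
        correct.append(win)
        c = c if win else ("left" if c == "right" else "right")
    return ActorRun("wsls", np.array(choices), np.array(correct, dtype=bool))


def fixed_policy_run(open_sequence, policy: str, condition: str | None = None) -> ActorRun:
    """Deterministic fixed policy: always_left, always_right, or
    always_majority_side (requires a biased block's condition; the
    majority *open* side is the complement of the biased guard side)."""
    open_sequence = list(open_sequence)
    if not open_sequence:
        raise ValueError("open_sequence must be nonempty")
    if policy == "always_left":
        side = "left"
    elif policy == "always_right":
        side = "right"
    elif policy == "always_majority_side":
        if condition == "left_biased":
            side = "right"  # left usually blocked -> right usually open
        elif condition == "right_biased":
            side = "left"
        else:
            raise ValueError("always_majority_side undefined for control blocks")
    else:
        raise ValueError(f"unknown policy {policy!r}")
    choices = np.array([side] * len(open_sequence))
    correct = np.array([side == o for o in open_sequence], dtype=bool)
    return ActorRun(policy, choices, correct)


def run_policy_on_blocks(open_blocks, policy: str, seed=0,
                         condition: str | None = None) -> list[ActorRun]:
    """Run a policy independently on each block (posterior/choice reset)."""
    rng = _as_rng(seed)
    runs = []
    for block in open_blocks:
        if policy == "ideal":
            runs.append(ideal_actor_run(block, rng))
        elif policy == "wsls":
            runs.append(wsls_run(block, rng))
        else:
            runs.append(fixed_policy_run(block, policy, condition))
    return runs


def sample_open_sequences(n_blocks: int, n_trials: int = 20,
                          p_open_majority: float = 0.88, seed=0,
                          majority_side: str = "right") -> list[np.ndarray]:
    """i.i.d. open-side sequences for simulated blocks.

    With ``p_open_majority = 0.5`` this yields control blocks.
    """
    rng = _as_rng(seed)
    other = "left" if majority_side == "right" else "right"
    return [np.where(rng.random(n_trials) < p_open_majority, majority_side, other)
            for _ in range(n_blocks)]


@dataclass
class AccuracyCurve:
    """Per-trial-index mean correctness (and SEM) across blocks."""
    mean: np.ndarray
    sem: np.ndarray
    n_blocks: int

    def __post_init__(self) -> None:
        if np.any((self.mean < 0) | (self.mean > 1)):
            raise ValueError("curve values must lie in [0, 1]")


def accuracy_curve(runs) -> AccuracyCurve:
    """Average correctness at each within-block trial index.

    ``runs`` is a list of :class:`ActorRun` (or boolean arrays) sharing
    one block length.
    """
    if not len(runs):
        raise ValueError("no runs given")
    mat = np.array([r.correct if isinstance(r, ActorRun) else np.asarray(r, dtype=bool)
                    for r in runs], dtype=float)
    mean = mat.mean(axis=0)
    sem = mat.std(axis=0, ddof=1) / np.sqrt(mat.shape[0]) if mat.shape[0] > 1 \
        else np.zeros(mat.shape[1])
    return AccuracyCurve(mean, sem, mat.shape[0])


def compare_curves(a: AccuracyCurve | np.ndarray, b: AccuracyCurve | np.ndarray) -> dict:
    """Pointwise agreement between two accuracy curves.

    Returns Pearson r, RMSE of pointwise differences, and Spearman rho
    with its p-value.  Zero-variance inputs leave the correlations NaN
    with ``degenerate=True``.
    """
    av = a.mean if isinstance(a, AccuracyCurve) else np.asarray(a, dtype=float)
    bv = b.mean if isinstance(b, AccuracyCurve) else np.asarray(b, dtype=float)
    if av.shape != bv.shape or av.size < 3:
        raise ValueError("curves must share a length >= 3")
    out = {"rmse": float(np.sqrt(np.mean((av - bv) ** 2)))}
    if np.std(av) == 0 or np.std(bv) == 0:
        out.update(pearson_r=np.nan, spearman_rho=np.nan, spearman_p=np.nan,
                   degenerate=True)
        return out
    pr = stats.pearsonr(av, bv)
    sr = stats.spearmanr(av, bv)
    out.update(pearson_r=float(pr.statistic), spearman_rho=float(sr.statistic),
               spearman_p=float(sr.pvalue), degenerate=False)
    return out


def wsls_stationary_accuracy(p: float) -> float:
    """Long-run WSLS accuracy on i.i.d. sequences with majority rate p.

    WSLS always chooses the previously open side, so a trial is correct
    iff consecutive open sides repeat: p^2 + (1 - p)^2.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    return p * p + (1.0 - p) * (1.0 - p)


def late_trial_accuracy(runs, last_n: int = 5) -> float:
    """Mean correctness over the last ``last_n`` trials, pooled over blocks."""
    mat = np.array([r.correct if isinstance(r, ActorRun) else np.asarray(r, dtype=bool)
                    for r in runs], dtype=float)
    return float(mat[:, -last_n:].mean())
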