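"""Shared helpers for the test suite."""
import numpy as np
import pandas as pd

from navlearn.config import DEFAULT_PROFILES, BlockSpec, EnvironmentConfig
from navlearn import synthetic_world as sw
from navlearn import trajectory_metrics as tm


def mixed_roster():
    """All four movement strategies, small n, for clustering checks."""
    P = DEFAULT_PROFILES
    return ([P["waiter"]] * 4 + [P["moderate_learner"]] * 2
            + [P["super_learner"]] + [P["random_walker"]])


def biased_blocks(n_trials: int = 20):
    return [BlockSpec("left_biased", 0, n_trials),
            BlockSpec("right_biased", 1, n_trials)]


def simulate_strategy_cohort(profiles, seed, n_trials=20, with_gaze=False):
    """Simulate biased blocks only for a roster of profiles.

    Returns (trials, tracker) concatenated over participants.
    """
    env = EnvironmentConfig.for_experiment(1)
    trials_parts, tracker_parts = [], []
    for p, profile in enumerate(profiles):
        rng = sw.participant_rng(seed, p)
        trials, tracker, _ = sw.simulate_participant(
            p, profile, biased_blocks(n_trials), env, rng, with_gaze=with_gaze)
        trials_parts.append(trials)
        tracker_parts.append(tracker)
    return (pd.concat(trials_parts, ignore_index=True),
            pd.concat(tracker_parts, ignore_index=True))


def strategy_metrics_table(profiles, seed, n_trials=20):
    """Trial table (with movement metrics) for a strategy cohort."""
    from navlearn import learning_models as lm
    trials, tracker = simulate_strategy_cohort(profiles, seed, n_trials)
    met = tm.compute_trial_metrics(tracker, trials)
    return lm.build_trial_table(trials, met)


def idt_oracle(t, pts, threshold, min_duration):
    """Brute-force I-DT reference: recompute window spread from scratch.

    Independent of the package's incremental implementation; returns
    fixation (start, end) inclusive index pairs.
    """
    events = []
    n = len(t)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and np.ptp(pts[i:j + 2], axis=0).max() <= threshold:
            j += 1
        if t[j] - t[i] >= min_duration:
            events.append((i, j))
            i = j + 1
        else:
            i += 1
    return events


def random_gaze_stream(rng, n_max=200, hz=120.0):
    """A random stream mixing dwell clusters and jumps, for oracle checks."""
    n = int(rng.integers(5, n_max + 1))
    t = np.arange(n) / hz
    pts = np.zeros((n, 3))
    pos = rng.normal(0, 0.5, 3)
    for k in range(n):
        if rng.random() < 0.08:
            pos = pos + rng.normal(0, 0.5, 3)  # saccadic jump
        pts[k] = pos + rng.normal(0, rng.choice([0.002, 0.02]), 3)
    return t, pts
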