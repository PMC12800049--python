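"""Synthetic two-path navigation experiments.

Generates complete experiments — per-participant block designs, guard
sequences, waist-tracker trajectories, binary early-commitment choices,
and gaze streams — with the statistical structure the downstream
analyses assume, so every stage of the pipeline is testable without any
recorded data.

Coordinates: x lateral (positive = right), y vertical, z forward from
the start door (0 at the start).  Units are meters and seconds.  The
waist tracker samples at ~90 Hz and gaze at ~120 Hz.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import (
    CONDITIONS,
    DEFAULT_BIAS,
    DEFAULT_N_TRIALS,
    AgentProfile,
    BlockSpec,
    EnvironmentConfig,
    default_roster,
)
from .trajectory_metrics import minimum_jerk_profile

TRACKER_HZ = 90.0
GAZE_HZ = 120.0

#: Lateral target (m) of the early commitment in experiment 2 — agents
#: steer to this offset by the pathway-separation point.
COMMIT_OFFSET = 0.55


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def participant_rng(master_seed: int, participant_index: int) -> np.random.Generator:
    """Independent, reproducible stream per participant."""
    return np.random.default_rng(
        np.random.SeedSequence((int(master_seed), int(participant_index)))
    )


# ---------------------------------------------------------------------------
# design and guard sequences
# ---------------------------------------------------------------------------

def make_design(experiment_id: int, n_participants: int, seed=0,
                n_trials: int = DEFAULT_N_TRIALS,
                bias: float = DEFAULT_BIAS) -> list[list[BlockSpec]]:
    """Per-participant randomized block sequences.

    Experiment 1 has nine blocks (3 left-biased, 3 right-biased, 3
    control); experiment 2 drops one control block (3/3/2).  Block order
    is an independent uniform permutation per participant, deterministic
    given ``seed``.
    """
    if experiment_id == 1:
        counts = {"left_biased": 3, "right_biased": 3, "control": 3}
    elif experiment_id == 2:
        counts = {"left_biased": 3, "right_biased": 3, "control": 2}
    else:
        raise ValueError(f"experiment_id must be 1 or 2, got {experiment_id!r}")
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    base = [cond for cond in CONDITIONS for _ in range(counts[cond])]
    designs = []
    for p in range(n_participants):
        rng = participant_rng(seed, p)
        order = [base[i] for i in rng.permutation(len(base))]
        designs.append([
            BlockSpec(condition=c, block_index=i, n_trials=n_trials, bias=bias)
            for i, c in enumerate(order)
        ])
    return designs


def sample_guard_sides(block: BlockSpec, seed=0) -> np.ndarray:
    """i.i.d. guard (blocked) sides for one block: P(left) = p_block_left."""
    rng = _as_rng(seed)
    u = rng.random(block.n_trials)
    return np.where(u < block.p_block_left, "left", "right")


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

def _smooth_noise(rng: np.random.Generator, n: int, sd: float,
                  dt: float, tau: float = 1.5) -> np.ndarray:
    """Temporally smooth lateral noise with marginal SD ``sd``.

    White noise convolved with a Gaussian kernel of width ``tau`` seconds
    and rescaled to unit marginal variance: postural sway and tracker
    noise are slow relative to the 90 Hz sampling, so consecutive samples
    are strongly correlated and the jitter adds almost nothing to the
    path's arc length.
    """
    if sd == 0 or n == 0:
        return np.zeros(n)
    sigma = max(tau / dt, 1.0)
    half = int(np.ceil(3 * sigma))
    kern = np.exp(-0.5 * (np.arange(-half, half + 1) / sigma) ** 2)
    kern /= np.sqrt(np.sum(kern ** 2))
    w = rng.standard_normal(n + 2 * half)
    return sd * np.convolve(w, kern, mode="valid")[:n]


def simulate_trajectory(profile: AgentProfile, guard_side: str, trigger_z: float,
                        env: EnvironmentConfig, belief: float, seed=0,
                        choice_side: str | None = None, x_bias: float = 0.0,
                        speed_factor: float = 1.0) -> pd.DataFrame:
    """One trial's waist trajectory as a DataFrame with columns t, x, y, z.

    Before the trigger the lateral profile is a minimum-jerk shift of
    amplitude ``anticipation_gain * (2 * belief - 1)`` (``belief`` =
    probability that the *right* side is open; positive = rightward)
    plus Gaussian noise; random walkers shift with a random sign.  In
    experiment 2, ``choice_side`` overrides the graded shift with a
    committed minimum-jerk move to ±COMMIT_OFFSET by the pathway
    separation point.  After the trigger the path steers to the open
    doorknob at (±doorknob_lateral_offset, room_length); forward speed
    is ``base_speed`` with a small per-trial jitter, and lateral noise
    tapers to zero at the door so the path ends on the knob.
    ``x_bias`` is a participant-level idiosyncratic lateral offset and
    ``speed_factor`` a participant-level speed multiplier.
    """
    if not 0.0 <= belief <= 1.0:
        raise ValueError("belief must lie in [0, 1]")
    if guard_side not in ("left", "right"):
        raise ValueError("guard_side must be 'left' or 'right'")
    rng = _as_rng(seed)
    dt = 1.0 / TRACKER_HZ
    speed = profile.base_speed * speed_factor * float(1.0 + 0.05 * rng.standard_normal())
    speed = max(speed, 0.1)
    knob_z = env.knob_z
    n = int(np.ceil(knob_z / (speed * dt))) + 1
    t = np.arange(n) * dt
    z = np.minimum(np.arange(n) * speed * dt, knob_z)
    z[-1] = knob_z

    open_x = env.doorknob_lateral_offset if guard_side == "left" else -env.doorknob_lateral_offset

    if choice_side is not None:
        # experiment 2: committed pre-trigger move to the chosen pathway
        sign = 1.0 if choice_side == "right" else -1.0
        sep = env.path_separation_z
        x_pre = sign * COMMIT_OFFSET * minimum_jerk_profile(z / sep)
    else:
        amplitude = profile.anticipation_gain * (2.0 * belief - 1.0)
        if profile.strategy == "random_walker":
            amplitude = profile.anticipation_gain * rng.choice([-1.0, 1.0])
        x_pre = amplitude * minimum_jerk_profile(z / trigger_z)

    pre = z < trigger_z
    # lateral position at the moment the guard appears
    if pre.any():
        x_trig = x_pre[pre][-1]
    else:
        x_trig = x_pre[0]
    denom = max(knob_z - trigger_z, 1e-9)
    s_post = minimum_jerk_profile((z - trigger_z) / denom)
    x = np.where(pre, x_pre, x_trig + (open_x - x_trig) * s_post)

    taper = np.where(pre, 1.0, 1.0 - s_post)
    x = x + (_smooth_noise(rng, n, profile.lateral_noise_sd, dt) + x_bias) * taper
    y = 0.95 + 0.02 * np.sin(2 * np.pi * 1.8 * t)
    return pd.DataFrame({"t": t, "x": x, "y": y, "z": z})


# ---------------------------------------------------------------------------
# gaze
# ---------------------------------------------------------------------------

def simulate_gaze(duration: float, planted_fixations: list[tuple[tuple, float]],
                  noise_sd: float = 0.005, seed=0,
                  saccade_duration: float = 1.0 / 30.0):
    """120 Hz gaze stream from planted fixations, with ground truth.

    ``planted_fixations`` is a list of ``(center, duration)`` pairs; the
    stream dwells at each center (plus isotropic Gaussian noise of
    ``noise_sd``) for its duration and sweeps linearly between
    consecutive centers (a saccade of ``saccade_duration``).  If the
    schedule is shorter than ``duration`` the last fixation is extended;
    the stream is truncated at ``duration``.

    Returns ``(gaze, labels)`` where ``gaze`` is a DataFrame with
    columns t, gx, gy, gz and ``labels`` an int array per sample:
    the fixation index, or -1 for saccade samples.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if duration < 0:
        raise ValueError("duration must be >= 0")
    for center, dur in planted_fixations:
        if dur < 0:
            raise ValueError("fixation durations must be >= 0")
        if not np.all(np.isfinite(center)):
            raise ValueError("fixation centers must be finite")
    rng = _as_rng(seed)
    dt = 1.0 / GAZE_HZ

    # build the noise-free schedule: (start_t, end_t, label, p0, p1)
    segments = []
    t_cursor = 0.0
    for k, (center, dur) in enumerate(planted_fixations):
        c = np.asarray(center, dtype=float)
        if k > 0:
            prev = np.asarray(planted_fixations[k - 1][0], dtype=float)
            segments.append((t_cursor, t_cursor + saccade_duration, -1, prev, c))
            t_cursor += saccade_duration
        segments.append((t_cursor, t_cursor + dur, k, c, c))
        t_cursor += dur
    if not segments:
        segments.append((0.0, duration, -1, np.zeros(3), np.zeros(3)))
        t_cursor = duration
    if t_cursor < duration:
        s0, _, lab, p0, p1 = segments[-1]
        segments[-1] = (s0, duration, lab, p0, p1)
        t_cursor = duration

    n = max(int(np.floor(min(t_cursor, duration) / dt)) + 1, 1)
    t = np.arange(n) * dt
    pts = np.zeros((n, 3))
    labels = np.full(n, -1, dtype=int)
    for (s0, s1, lab, p0, p1) in segments:
        m = (t >= s0) & (t < s1 + 1e-12)
        if not m.any():
            continue
        if s1 > s0 and lab == -1:
            frac = (t[m] - s0) / (s1 - s0)
        else:
            frac = np.zeros(m.sum())
        pts[m] = p0 + frac[:, None] * (p1 - p0)
        labels[m] = lab
    if noise_sd > 0:
        fix_mask = labels >= 0
        pts[fix_mask] += rng.normal(0.0, noise_sd, (int(fix_mask.sum()), 3))
    gaze = pd.DataFrame({"t": t, "gx": pts[:, 0], "gy": pts[:, 1], "gz": pts[:, 2]})
    return gaze, labels


@dataclass(frozen=True)
class GazeStyle:
    """Parameters of naturalistic scanning used for full-experiment gaze.

    Scanning becomes calmer with familiarity: mean fixation duration
    grows across blocks (fewer saccades per second) and the spatial
    spread of fixation targets shrinks within blocks and across blocks,
    mirroring the direction of the empirical gaze effects.
    """
    base_fixation_duration: float = 0.25
    fixation_duration_block_gain: float = 0.05
    base_target_spread: float = 0.30
    spread_trial_decay: float = 0.012
    spread_block_decay: float = 0.03
    noise_sd: float = 0.005


def _trial_gaze(rng: np.random.Generator, duration: float, block_index: int,
                trial_in_block: int, style: GazeStyle):
    """Planted-fixation gaze for one trial of a full experiment."""
    mean_dur = style.base_fixation_duration * (1.0 + style.fixation_duration_block_gain * block_index)
    spread = style.base_target_spread * max(
        1.0 - style.spread_trial_decay * (trial_in_block - 1)
        - style.spread_block_decay * block_index, 0.2)
    center0 = np.array([0.0, 1.4, 3.5])  # gaze toward the far doors
    fixations = []
    total = 0.0
    while total < duration:
        c = center0 + rng.normal(0.0, spread, 3)
        d = float(rng.gamma(4.0, mean_dur / 4.0))
        d = max(d, 0.05)
        fixations.append((tuple(c), d))
        total += d + 1.0 / 30.0
    return simulate_gaze(duration, fixations, noise_sd=style.noise_sd, seed=rng)


# ---------------------------------------------------------------------------
# full experiments
# ---------------------------------------------------------------------------

def _belief_right_open(profile: AgentProfile, n_right_open: int, n_obs: int) -> float:
    """Agent's belief that the right pathway will be open.

    A learning-rate-weighted Beta-Bernoulli posterior mean from a
    uniform prior: counts are scaled by ``learning_rate`` so slow
    learners discount the evidence (0 = never leaves 0.5).
    """
    lr = profile.learning_rate
    return (1.0 + lr * n_right_open) / (2.0 + lr * n_obs)


def _choose_side(profile: AgentProfile, n_right_open: int, n_obs: int,
                 rng: np.random.Generator) -> str:
    """Early-commitment choice (experiment 2).

    Learner agents choose by posterior (Thompson) sampling: draw p from
    their learning-rate-weighted Beta posterior over P(right open) and
    pick the side the draw favours.  Early in a block the posterior is
    wide and choices hover near chance; as evidence accumulates they
    converge on the majority side — a gradual, human-like learning
    curve.  A ``choice_noise`` lapse replaces the choice with a fair
    coin; the 'ideal' strategy uses the posterior-mean argmax instead.
    """
    if profile.choice_noise >= 1.0 or rng.random() < profile.choice_noise:
        return "left" if rng.random() < 0.5 else "right"
    lr = profile.learning_rate
    a = 1.0 + lr * n_right_open          # right-open pseudo-counts
    b = 1.0 + lr * (n_obs - n_right_open)
    if profile.strategy == "ideal":
        mean = a / (a + b)
        if mean != 0.5:
            return "right" if mean > 0.5 else "left"
        return "left" if rng.random() < 0.5 else "right"
    return "right" if rng.beta(a, b) > 0.5 else "left"


def simulate_participant(participant_id: int, profile: AgentProfile,
                         blocks: list[BlockSpec], env: EnvironmentConfig,
                         rng: np.random.Generator, with_gaze: bool = True,
                         gaze_style: GazeStyle | None = None):
    """Simulate every trial of one participant.

    Returns ``(trials, tracker, gaze)`` DataFrames (``gaze`` is None when
    ``with_gaze`` is False).
    """
    style = gaze_style or GazeStyle()
    trial_rows, tracker_parts, gaze_parts = [], [], []
    exp2 = env.experiment_id == 2
    # participant-level idiosyncrasies: baseline lateral offset and pace
    x_bias = float(rng.normal(0.0, 0.05))
    speed_factor = float(np.clip(1.0 + 0.08 * rng.standard_normal(), 0.6, 1.4))
    for block in blocks:
        guard_sides = sample_guard_sides(block, rng)
        n_right_open = 0  # open side = complement of guard side
        for i, guard in enumerate(guard_sides):
            trial_no = i + 1
            trigger_z = float(rng.uniform(*env.trigger_range))
            belief = _belief_right_open(profile, n_right_open, i)
            choice = _choose_side(profile, n_right_open, i, rng) if exp2 else None
            traj = simulate_trajectory(profile, guard, trigger_z, env, belief,
                                       seed=rng, choice_side=choice,
                                       x_bias=x_bias, speed_factor=speed_factor)
            correct = (choice != guard) if exp2 else None
            trial_rows.append({
                "participant_id": participant_id,
                "experiment_id": env.experiment_id,
                "block_index": block.block_index,
                "condition": block.condition,
                "trial_in_block": trial_no,
                "guard_side": guard,
                "trigger_z": trigger_z,
                "choice_side": choice if exp2 else "none",
                "correct": correct,
            })
            traj.insert(0, "trial_in_block", trial_no)
            traj.insert(0, "block_index", block.block_index)
            traj.insert(0, "participant_id", participant_id)
            tracker_parts.append(traj)
            if with_gaze:
                # gaze is analysed pre-guard; cover that window plus a margin
                onset_t = float(traj.loc[traj["z"] >= trigger_z, "t"].iloc[0])
                g, _ = _trial_gaze(rng, onset_t + 0.5, block.block_index,
                                   trial_no, style)
                g.insert(0, "trial_in_block", trial_no)
                g.insert(0, "block_index", block.block_index)
                g.insert(0, "participant_id", participant_id)
                gaze_parts.append(g)
            if guard == "left":
                n_right_open += 1  # left blocked -> right open observed
        # posterior resets implicitly: counters are per block
    trials = pd.DataFrame(trial_rows)
    tracker = pd.concat(tracker_parts, ignore_index=True)
    gaze = pd.concat(gaze_parts, ignore_index=True) if gaze_parts else None
    return trials, tracker, gaze


def generate_experiment(experiment_id: int, n_participants: int | None = None,
                        seed: int = 0, roster: list[AgentProfile] | None = None,
                        env: EnvironmentConfig | None = None,
                        n_trials: int = DEFAULT_N_TRIALS,
                        bias: float = DEFAULT_BIAS,
                        with_gaze: bool = True,
                        gaze_style: GazeStyle | None = None) -> dict:
    """Generate a complete synthetic experiment.

    Returns a dict with keys ``trials``, ``tracker``, ``gaze`` (DataFrames;
    ``gaze`` is None without gaze) and ``roster`` (profile per participant).
    The default roster matches each experiment's empirical composition
    (see :func:`navlearn.config.default_roster`).
    """
    env = env or EnvironmentConfig.for_experiment(experiment_id)
    roster = roster or default_roster(experiment_id, n_participants)
    if n_participants is None:
        n_participants = len(roster)
    if len(roster) < n_participants:
        reps = -(-n_participants // len(roster))
        roster = (roster * reps)[:n_participants]
    designs = make_design(experiment_id, n_participants, seed,
                          n_trials=n_trials, bias=bias)
    all_trials, all_tracker, all_gaze = [], [], []
    for p in range(n_participants):
        rng = participant_rng(seed, p)
        trials, tracker, gaze = simulate_participant(
            p, roster[p], designs[p], env, rng, with_gaze=with_gaze,
            gaze_style=gaze_style)
        all_trials.append(trials)
        all_tracker.append(tracker)
        if gaze is not None:
            all_gaze.append(gaze)
    return {
        "trials": pd.concat(all_trials, ignore_index=True),
        "tracker": pd.concat(all_tracker, ignore_index=True),
        "gaze": pd.concat(all_gaze, ignore_index=True) if all_gaze else None,
        "roster": {p: roster[p].strategy for p in range(n_participants)},
    }


def write_csvs(data: dict, out_dir) -> list[str]:
    """Write trials/tracker/gaze tables as UTF-8 CSVs with fixed formatting.

    Fixed float formatting keeps identical seeds byte-identical on disk.
    Returns the list of files written.
    """
    from pathlib import Path
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name in ("trials", "tracker", "gaze"):
        df = data.get(name)
        if df is None:
            continue
        path = out / f"{name}.csv"
        df.to_csv(path, index=False, float_format="%.6f")
        written.append(str(path))
    return written
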