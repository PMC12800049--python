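"""Configuration objects for the two-path navigation experiments.

The task: a participant walks from a start door toward one of two exit
doors in a small room.  A guard appears mid-walk and blocks one pathway;
within a block the blocked side is drawn i.i.d. with a fixed probability
(50/50 in control blocks, 88/12 in biased blocks).  These dataclasses
hold the geometry, block structure, and the behavioural profiles of the
simulated agents.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

CONDITIONS = ("control", "left_biased", "right_biased")
SIDES = ("left", "right")

#: Guard-side probability on the biased side in biased blocks.
DEFAULT_BIAS = 0.88
#: Trials per block.
DEFAULT_N_TRIALS = 20


@dataclass(frozen=True)
class EnvironmentConfig:
    """Geometry of the virtual room, in meters.

    The coordinate convention is x lateral (positive = right), y vertical,
    z forward from the start door (z = 0 at the start).  ``trigger_range``
    is the interval from which the per-trial guard-trigger distance is
    drawn uniformly.
    """

    room_length: float = 4.9
    room_width: float = 3.6
    doorknob_lateral_offset: float = 1.5
    obstacle_z: float = 2.7
    obstacle_width: float = 0.85
    path_separation_z: float = 1.2
    trigger_range: tuple[float, float] = (0.8, 1.2)
    experiment_id: int = 1

    def __post_init__(self) -> None:
        if self.experiment_id not in (1, 2):
            raise ValueError(f"experiment_id must be 1 or 2, got {self.experiment_id!r}")
        lo, hi = self.trigger_range
        if not lo < hi:
            raise ValueError(f"trigger_range must be increasing, got {self.trigger_range}")
        for name in ("room_length", "room_width", "doorknob_lateral_offset",
                     "obstacle_z", "obstacle_width", "path_separation_z"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.doorknob_lateral_offset > self.room_width / 2:
            raise ValueError("doorknob_lateral_offset exceeds half the room width")

    @classmethod
    def for_experiment(cls, experiment_id: int) -> "EnvironmentConfig":
        """Default geometry for experiment 1 or 2.

        Experiment 2 separates the two pathways already 1.2 m from the
        start and triggers the guard later (1.2-1.6 m), forcing an early
        commitment to one side.
        """
        if experiment_id == 1:
            return cls(experiment_id=1, trigger_range=(0.8, 1.2))
        if experiment_id == 2:
            return cls(experiment_id=2, trigger_range=(1.2, 1.6))
        raise ValueError(f"experiment_id must be 1 or 2, got {experiment_id!r}")

    @property
    def knob_z(self) -> float:
        """Forward position of the exit doorknobs."""
        return self.room_length


@dataclass(frozen=True)
class BlockSpec:
    """One block of trials with a fixed guard-side probability."""

    condition: str
    block_index: int = 0
    n_trials: int = DEFAULT_N_TRIALS
    bias: float = DEFAULT_BIAS

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}, got {self.condition!r}")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if not 0.5 < self.bias <= 1.0:
            raise ValueError("bias must lie in (0.5, 1]")

    @property
    def p_block_left(self) -> float:
        """Probability that the guard blocks the *left* pathway."""
        if self.condition == "control":
            return 0.5
        if self.condition == "left_biased":
            return self.bias
        return 1.0 - self.bias

    @property
    def is_biased(self) -> bool:
        return self.condition != "control"


@dataclass(frozen=True)
class AgentProfile:
    """Behavioural profile of a simulated participant.

    ``anticipation_gain`` is the asymptotic lateral pre-shift (m) toward
    the believed open side; ``learning_rate`` scales how strongly the
    agent's belief tracks the evidence (1 = full Bayesian counting, 0 =
    no learning); ``choice_noise`` is a lapse rate used for the binary
    early-commitment choice of experiment 2.
    """

    strategy: str
    learning_rate: float = 1.0
    anticipation_gain: float = 0.0
    lateral_noise_sd: float = 0.03
    base_speed: float = 0.5
    choice_noise: float = 0.0
    seed: int = 0

    _STRATEGIES = ("waiter", "moderate_learner", "super_learner",
                   "random_walker", "ideal", "wsls")

    def __post_init__(self) -> None:
        if self.strategy not in self._STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.anticipation_gain < 0:
            raise ValueError("anticipation_gain must be >= 0")
        if self.lateral_noise_sd < 0:
            raise ValueError("lateral_noise_sd must be >= 0")
        if self.base_speed <= 0:
            raise ValueError("base_speed must be > 0")
        if not 0.0 <= self.choice_noise <= 1.0:
            raise ValueError("choice_noise must lie in [0, 1]")


# Canonical agent profiles matching the four empirical movement-strategy
# clusters (slow, near-midline "waiters"; small- and large-gain learners;
# side-to-side "random walkers"), plus the two benchmark choosers used in
# the early-commitment experiment.
DEFAULT_PROFILES: dict[str, AgentProfile] = {
    "waiter": AgentProfile("waiter", learning_rate=1.0, anticipation_gain=0.0,
                           lateral_noise_sd=0.02, base_speed=0.45),
    "moderate_learner": AgentProfile("moderate_learner", learning_rate=0.5,
                                     anticipation_gain=0.18, lateral_noise_sd=0.04,
                                     base_speed=0.55),
    "super_learner": AgentProfile("super_learner", learning_rate=1.0,
                                  anticipation_gain=0.6, lateral_noise_sd=0.04,
                                  base_speed=0.55),
    "random_walker": AgentProfile("random_walker", learning_rate=0.0,
                                  anticipation_gain=0.35, lateral_noise_sd=0.06,
                                  base_speed=0.55, choice_noise=1.0),
    "ideal": AgentProfile("ideal", learning_rate=1.0, anticipation_gain=0.5,
                          lateral_noise_sd=0.04, base_speed=0.62, choice_noise=0.12),
    "wsls": AgentProfile("wsls", learning_rate=1.0, anticipation_gain=0.5,
                         lateral_noise_sd=0.04, base_speed=0.62),
}


def default_roster(experiment_id: int, n_participants: int | None = None) -> list[AgentProfile]:
    """Agent roster emulating the composition of each experiment's sample.

    Experiment 1 (n = 29): 18 waiters, 6 moderate learners, 4 random
    walkers, 1 super learner — the empirical cluster sizes.  Experiment 2
    (n = 25): 23 learners choosing by posterior (Thompson) sampling with
    a small lapse rate — which yields the gradual, logistic-shaped group
    learning curve humans show — plus 2 random choosers (the two
    at-or-below-chance participants).  If ``n_participants`` is given,
    the roster is subsampled evenly so strategy proportions are kept.
    """
    if experiment_id == 1:
        roster = ([DEFAULT_PROFILES["waiter"]] * 18
                  + [DEFAULT_PROFILES["moderate_learner"]] * 6
                  + [DEFAULT_PROFILES["random_walker"]] * 4
                  + [DEFAULT_PROFILES["super_learner"]])
    elif experiment_id == 2:
        roster = ([AgentProfile("super_learner", learning_rate=1.0,
                                anticipation_gain=0.5, lateral_noise_sd=0.04,
                                base_speed=0.57, choice_noise=0.06)] * 23
                  + [AgentProfile("random_walker", learning_rate=0.0,
                                  anticipation_gain=0.35, lateral_noise_sd=0.06,
                                  base_speed=0.57, choice_noise=1.0)] * 2)
    else:
        raise ValueError(f"experiment_id must be 1 or 2, got {experiment_id!r}")
    if n_participants is not None:
        if n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        # evenly spaced indices into the full roster keep the strategy
        # proportions approximately intact at any sample size
        m = len(roster)
        roster = [roster[(i * m) // n_participants % m] for i in range(n_participants)]
    return roster


@dataclass
class RunConfig:
    """Top-level configuration for an end-to-end pipeline run."""

    master_seed: int = 0
    experiment_id: int = 1
    n_participants: int | None = None
    n_trials: int = DEFAULT_N_TRIALS
    bias: float = DEFAULT_BIAS
    commitment_threshold: float = 0.25
    idt_dispersion: float = 0.05
    idt_min_duration: float = 0.100
    cluster_weight: float = 2.0
    cluster_k: int = 4
    with_gaze: bool = True
    out_dir: str = "navlearn_out"

    def __post_init__(self) -> None:
        if self.experiment_id not in (1, 2):
            raise ValueError("experiment_id must be 1 or 2")
        if self.n_participants is not None and self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")

    def environment(self) -> EnvironmentConfig:
        return EnvironmentConfig.for_experiment(self.experiment_id)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        """Stable short hash identifying the configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
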