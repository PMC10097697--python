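"""Task and simulation configuration types.

The Pavlovian trace-conditioning session is organised in three 80-trial
blocks (appetitive, aversive, bivalent).  Within a block each of three
conditioned stimuli (CSs) predicts its outcome with probability 1.0, 0.5 or
0.0, and two kinds of uncued ("free") trials deliver an outcome with no
preceding CS.  All times are integer milliseconds from trial start; analysis
windows are half-open ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Tuple

CONTEXTS = ("appetitive", "aversive", "bivalent")
CS_PROBABILITIES = (1.0, 0.5, 0.0)

#: uncued trial types available per context, in schedule order
UNCUED_TYPES = {
    "appetitive": ("free_reward", "free_tone"),
    "aversive": ("free_airpuff", "free_tone"),
    "bivalent": ("free_reward", "free_airpuff"),
}

UNCUED_OUTCOME = {
    "free_reward": "reward",
    "free_tone": "tone",
    "free_airpuff": "airpuff",
}


class ConfigurationError(ValueError):
    """Raised when a task, behaviour or archetype configuration is invalid."""


@dataclass(frozen=True)
class TaskConfig:
    """Timing and composition of a conditioning session.

    Defaults give the standard trial sequence: a 1.2-s timing cue (TC), a
    1-s CS, a 1-s stimulus-free trace period, and a 100-ms outcome, with
    3-5 s inter-trial intervals and 80-trial blocks (20 trials per CS plus
    10 per uncued type).  ``pre_tc_ms`` and ``post_outcome_ms`` pad the
    per-trial recording epoch so that the pre-TC baseline and post-outcome
    test windows are always defined.
    """

    tc_duration: int = 1200
    cs_duration: int = 1000
    trace_duration: int = 1000
    outcome_duration: int = 100
    iti_range: Tuple[int, int] = (3000, 5000)
    trials_per_cs: int = 20
    trials_per_uncued_type: int = 10
    block_order_rule: str = "app_avers_random_then_bivalent"
    rng_seed: int = 0
    pre_tc_ms: int = 1000
    post_outcome_ms: int = 500

    def __post_init__(self) -> None:
        for name in ("tc_duration", "cs_duration", "trace_duration",
                     "outcome_duration", "pre_tc_ms", "post_outcome_ms"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.trials_per_cs <= 0 or self.trials_per_uncued_type <= 0:
            raise ConfigurationError("trial counts must be positive")
        lo, hi = self.iti_range
        if lo > hi or lo <= 0:
            raise ConfigurationError("iti_range must satisfy 0 < low <= high")
        if self.block_order_rule != "app_avers_random_then_bivalent":
            raise ConfigurationError(
                f"unknown block_order_rule {self.block_order_rule!r}")

    @property
    def block_size(self) -> int:
        return 3 * self.trials_per_cs + 2 * self.trials_per_uncued_type

    # absolute event times (ms from trial start) for a cued trial
    @property
    def tc_onset(self) -> int:
        return self.pre_tc_ms

    @property
    def cs_onset(self) -> int:
        return self.tc_onset + self.tc_duration

    @property
    def trace_onset(self) -> int:
        return self.cs_onset + self.cs_duration

    @property
    def outcome_time(self) -> int:
        return self.trace_onset + self.trace_duration

    @property
    def trial_end(self) -> int:
        return self.outcome_time + self.outcome_duration + self.post_outcome_ms

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TaskConfig":
        d = dict(d)
        if "iti_range" in d:
            d["iti_range"] = tuple(d["iti_range"])
        return cls(**d)


def airpuff_probability(context: str, cs_probability: float) -> float:
    """Probability that a cued trial of this context delivers an airpuff.

    In aversive blocks the stated CS probability IS the airpuff probability;
    in bivalent blocks the stated probability is the reward frequency and an
    airpuff is delivered whenever the reward is not, so airpuff probability
    is its complement.  Appetitive blocks never deliver airpuffs.
    """
    if context == "aversive":
        return cs_probability
    if context == "bivalent":
        return 1.0 - cs_probability
    return 0.0


def reward_probability(context: str, cs_probability: float) -> float:
    """Probability that a cued trial of this context delivers a reward."""
    if context in ("appetitive", "bivalent"):
        return cs_probability
    return 0.0
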