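"""Task paradigms for the ambiguous-tone judgement-bias task.

Three study variants are encoded:

* ``acquisition`` -- 20 training trials, low/high tones only.
* ``study1_main`` -- 120 trials, 40 each of low (500 Hz), mid (750 Hz) and
  high (1000 Hz) tones, neutral condition.
* ``study2`` -- 4 blocks x 60 trials under alternating safe / threat-of-shock
  conditions (20 of each tone per block), with shock markers in threat blocks.

Timings are modelled at millisecond integer resolution: a 1000 ms tone, a
750 ms inter-stimulus interval, and feedback lasting 750 ms after a correct
response or 3250 ms after an incorrect/slow one.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TONE_HZ",
    "BlockSpec",
    "TaskDesign",
    "TrialSchedule",
    "make_design",
    "generate_schedule",
    "duration_bounds",
    "reward_map",
]

TONE_HZ = {"low": 500, "mid": 750, "high": 1000}

#: positions of possible shocks counted in post-threat trials (i.e. within
#: the concatenation of threat-block trials only)
SHOCK_POST_THREAT_TRIALS = (45, 96)


def reward_map(variant: int) -> dict:
    """Tone-frequency -> reward mapping for a counterbalance variant.

    Variant 0 pairs the high-frequency tone with the large reward (pound 4),
    variant 1 reverses the pairing.  The mid tone itself carries no fixed
    reward; its outcome follows the scheduled 50/50 sequence.
    """
    if variant not in (0, 1):
        raise ValueError("reward_map variant must be 0 or 1")
    if variant == 0:
        return {"high": "£4", "low": "£1"}
    return {"high": "£1", "low": "£4"}


@dataclass(frozen=True)
class BlockSpec:
    """One block of the threat/safe design."""

    condition: str  # "safe" | "threat"
    background: str  # "blue" | "red"
    shock_trial_indices: tuple = ()  # within-block trial positions

    def __post_init__(self):
        if self.condition not in ("safe", "threat"):
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.shock_trial_indices and self.condition != "threat":
            raise ValueError("shocks can only occur in threat blocks")


@dataclass(frozen=True)
class TaskDesign:
    name: str
    n_trials_per_tone: int
    tone_set: tuple  # subset of ("low", "mid", "high")
    tone_duration_ms: int = 1000
    isi_ms: int = 750
    feedback_correct_ms: int = 750
    feedback_timeout_ms: int = 3250
    reward_map_variant: int = 0
    blocks: tuple = ()  # BlockSpec, study 2 only

    @property
    def n_blocks(self) -> int:
        return max(1, len(self.blocks))

    @property
    def n_trials(self) -> int:
        return self.n_trials_per_tone * len(self.tone_set) * self.n_blocks

    @property
    def reward_map(self) -> dict:
        return reward_map(self.reward_map_variant)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["n_trials"] = self.n_trials
        d["tone_hz"] = {t: TONE_HZ[t] for t in self.tone_set}
        return d

    def to_yaml(self, path=None):
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


@dataclass
class TrialSchedule:
    """Ordered trial list: (trial_index, tone, condition, scheduled outcome).

    The scheduled mid-tone outcome is a balanced 50/50 high/low assignment
    (uniform random permutation within each block); unambiguous tones carry
    an empty scheduled outcome.
    """

    frame: pd.DataFrame

    def __len__(self) -> int:
        return len(self.frame)

    def to_csv(self, path=None):
        cols = ["trial_index", "tone", "tone_hz", "block", "condition", "scheduled_outcome"]
        return self.frame[cols].to_csv(path, index=False)


def _study2_blocks(order: int = 0, shock_variant: str = "both") -> tuple:
    """Block layout for the threat/safe design.

    ``order`` 0 = threat first, 1 = safe first (counterbalanced by subject
    parity upstream).  ``shock_variant`` selects whether the shock falls in
    the first threat block (post-threat trial 45), the second (96) or both.
    """
    if shock_variant not in ("first", "second", "both"):
        raise ValueError(f"unknown shock variant {shock_variant!r}")
    conds = ("threat", "safe", "threat", "safe") if order == 0 else ("safe", "threat", "safe", "threat")
    shocks_post_threat = {
        "first": (SHOCK_POST_THREAT_TRIALS[0],),
        "second": (SHOCK_POST_THREAT_TRIALS[1],),
        "both": SHOCK_POST_THREAT_TRIALS,
    }[shock_variant]
    blocks = []
    threat_offset = 0  # trials seen so far in threat blocks
    for cond in conds:
        if cond == "threat":
            within = tuple(p - threat_offset for p in shocks_post_threat
                           if threat_offset <= p < threat_offset + 60)
            blocks.append(BlockSpec("threat", "red", within))
            threat_offset += 60
        else:
            blocks.append(BlockSpec("safe", "blue"))
    return tuple(blocks)


def make_design(study: str, reward_map_variant: int = 0, order: int = 0,
                shock_variant: str = "both") -> TaskDesign:
    """Build a fully populated task design for a named study."""
    if study == "acquisition":
        return TaskDesign("acquisition", 10, ("low", "high"),
                          reward_map_variant=reward_map_variant)
    if study == "study1_main":
        return TaskDesign("study1_main", 40, ("low", "mid", "high"),
                          reward_map_variant=reward_map_variant)
    if study == "study2":
        return TaskDesign("study2", 20, ("low", "mid", "high"),
                          reward_map_variant=reward_map_variant,
                          blocks=_study2_blocks(order, shock_variant))
    raise ValueError(f"unknown study label {study!r}")


def generate_schedule(design: TaskDesign, seed: int) -> TrialSchedule:
    """Seeded trial schedule: uniform tone permutation per block, balanced
    50/50 mid-tone outcome assignment per block."""
    rng = np.random.default_rng(seed)
    per_block = design.n_trials_per_tone
    rows = []
    trial_index = 0
    blocks = design.blocks if design.blocks else (None,)
    for b, block in enumerate(blocks):
        tones = np.repeat(np.array(design.tone_set), per_block)
        tones = tones[rng.permutation(len(tones))]
        n_mid = int(np.sum(tones == "mid"))
        outcomes = np.array(["high", "low"] * (n_mid // 2) + (["high"] if n_mid % 2 else []))
        outcomes = outcomes[rng.permutation(n_mid)]
        shock_set = set(block.shock_trial_indices) if block is not None else set()
        mid_seen = 0
        for i, tone in enumerate(tones):
            sched = ""
            if tone == "mid":
                sched = outcomes[mid_seen]
                mid_seen += 1
            rows.append({
                "trial_index": trial_index,
                "tone": tone,
                "tone_hz": TONE_HZ[tone],
                "block": b,
                "condition": block.condition if block is not None else "neutral",
                "scheduled_outcome": sched,
                "shock_after": i in shock_set,
            })
            trial_index += 1
    return TrialSchedule(pd.DataFrame(rows))


def duration_bounds(design: TaskDesign) -> tuple:
    """(min, max) task duration in seconds.

    Every trial costs tone + ISI plus the feedback period; the bounds assume
    all-correct (750 ms feedback) v. all-timeout (3250 ms feedback).
    """
    per_trial_min = design.tone_duration_ms + design.isi_ms + design.feedback_correct_ms
    per_trial_max = design.tone_duration_ms + design.isi_ms + design.feedback_timeout_ms
    n = design.n_trials
    return n * per_trial_min / 1000.0, n * per_trial_max / 1000.0
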