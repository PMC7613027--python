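"""Trial generation for the two-stage "heist" task.

The task is a two-stage planning problem. On each trial the agent sees one
of two doors (dark/light) in one of four contexts (cued by a coloured gem).
Choosing the dark door leads to a high-stakes "heist" state with probability
``p`` and to a "neutral" state with probability ``1 - p``; the light door has
the complementary transition probabilities.  ``p`` alternates between two
levels (0.2/0.8 by default) with a per-trial hazard rate (0.1 by default).
A per-trial valence cue signals whether the heist state pays +1 (gain) or
-1 (loss); the neutral state always pays 0.

Blocks come in two conditions: in *dependent* blocks the two contexts share a
single transition schedule (yoked), in *independent* blocks each context has
its own schedule.  Forced trials require selecting the presented door; free
trials allow either door.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

DEPENDENT_CONTEXTS = (1, 2)
INDEPENDENT_CONTEXTS = (3, 4)

#: context id -> condition name
CONTEXT_CONDITION = {1: "dependent", 2: "dependent", 3: "independent", 4: "independent"}

#: canonical column order of a TrialTable
TRIAL_COLUMNS = [
    "subject",
    "session",
    "block",
    "condition",
    "context",
    "trial_index",
    "trial_type",
    "valence",
    "door_presented",
    "choice",
    "state",
    "outcome",
    "p_true",
]


@dataclass(frozen=True)
class TaskConfig:
    """Design parameters of one subject's task.

    The fMRI design has 5 sessions of 2 blocks (one per condition) of 32
    trials, 24 forced + 8 free, 320 trials total.  The pilot design has 4
    sessions of 2 blocks of 60 trials, all free choice, 480 trials total.
    """

    n_sessions: int = 5
    blocks_per_session: int = 2
    trials_per_block: int = 32
    forced_per_block: int = 24
    free_per_block: int = 8
    p_levels: tuple = (0.2, 0.8)
    hazard: float = 0.1
    design: str = "fmri"

    def __post_init__(self):
        if self.forced_per_block + self.free_per_block != self.trials_per_block:
            raise ValueError(
                "forced_per_block + free_per_block must equal trials_per_block "
                f"({self.forced_per_block} + {self.free_per_block} != {self.trials_per_block})"
            )
        if self.trials_per_block % 2:
            raise ValueError("trials_per_block must be even (two interleaved contexts)")
        if not 0.0 <= self.hazard <= 1.0:
            raise ValueError(f"hazard must be a probability, got {self.hazard}")
        if len(self.p_levels) != 2 or self.p_levels[0] == self.p_levels[1]:
            raise ValueError("p_levels must be two distinct probabilities")
        for lev in self.p_levels:
            if not 0.0 <= lev <= 1.0:
                raise ValueError(f"p_levels must be probabilities, got {self.p_levels}")
        if self.blocks_per_session != 2:
            raise ValueError("each session holds one dependent and one independent block")
        if self.design not in ("fmri", "pilot"):
            raise ValueError(f"unknown design {self.design!r}")

    @property
    def n_trials(self) -> int:
        return self.n_sessions * self.blocks_per_session * self.trials_per_block

    @classmethod
    def fmri(cls, **kw) -> "TaskConfig":
        return cls(**kw)

    @classmethod
    def pilot(cls, **kw) -> "TaskConfig":
        defaults = dict(
            n_sessions=4,
            blocks_per_session=2,
            trials_per_block=60,
            forced_per_block=0,
            free_per_block=60,
            design="pilot",
        )
        defaults.update(kw)
        return cls(**defaults)


def generate_transition_schedule(
    n_trials: int,
    hazard: float,
    levels: tuple = (0.2, 0.8),
    yoked: bool = True,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Per-trial transition probability for each of a block's two contexts.

    Each schedule starts at a level drawn uniformly from ``levels`` and
    switches to the other level with probability ``hazard`` on every
    subsequent trial.  ``yoked=True`` returns one draw copied into both rows
    (dependent blocks); ``yoked=False`` returns two independent draws.

    Returns an array of shape ``(2, n_trials)``.
    """
    if rng is None:
        rng = np.random.default_rng()
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if not 0.0 <= hazard <= 1.0:
        raise ValueError(f"hazard must be a probability, got {hazard}")
    levels = tuple(levels)
    if len(levels) != 2 or levels[0] == levels[1]:
        raise ValueError("levels must be two distinct probabilities")

    def one_draw() -> np.ndarray:
        start = rng.integers(2)
        flips = rng.random(n_trials - 1) < hazard
        idx = (start + np.concatenate([[0], np.cumsum(flips)])) % 2
        return np.asarray(levels)[idx]

    if yoked:
        sched = one_draw()
        return np.vstack([sched, sched])
    return np.vstack([one_draw(), one_draw()])


def generate_trial_table(
    config: TaskConfig,
    rng: Optional[np.random.Generator] = None,
    subject: int = 0,
) -> pd.DataFrame:
    """Generate one subject's design (choice/state/outcome left empty).

    Each session holds one dependent and one independent block in a
    counterbalanced (coin-flip) order.  Within a block the two contexts are
    randomly interleaved with equal counts, valence and presented door are
    uniform per trial, and forced/free labels are randomly placed with the
    configured counts.  ``p_true`` is the probability that the dark door
    leads to the heist state on that trial, taken from the block's schedule
    for the trial's context.
    """
    if rng is None:
        rng = np.random.default_rng()
    rows = []
    trial_index = 0
    for session in range(config.n_sessions):
        conditions = ["dependent", "independent"]
        if rng.random() < 0.5:
            conditions.reverse()
        for block, condition in enumerate(conditions):
            contexts = DEPENDENT_CONTEXTS if condition == "dependent" else INDEPENDENT_CONTEXTS
            n = config.trials_per_block
            sched = generate_transition_schedule(
                n, config.hazard, config.p_levels, yoked=(condition == "dependent"), rng=rng
            )
            ctx_seq = np.repeat(contexts, n // 2)
            rng.shuffle(ctx_seq)
            types = np.array(
                ["forced"] * config.forced_per_block + ["free"] * config.free_per_block
            )
            rng.shuffle(types)
            valence = np.where(rng.random(n) < 0.5, "gain", "loss")
            door = np.where(rng.random(n) < 0.5, "dark", "light")
            for t in range(n):
                ctx = int(ctx_seq[t])
                rows.append(
                    dict(
                        subject=subject,
                        session=session,
                        block=block,
                        condition=condition,
                        context=ctx,
                        trial_index=trial_index,
                        trial_type=types[t],
                        valence=valence[t],
                        door_presented=door[t],
                        choice=pd.NA,
                        state=pd.NA,
                        outcome=np.nan,
                        p_true=sched[contexts.index(ctx), t],
                    )
                )
                trial_index += 1
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def sample_step(choice: str, p_true: float, valence: str, rng: np.random.Generator):
    """Sample the transitioned-to state and outcome for one choice.

    The dark door reaches the heist state with probability ``p_true``, the
    light door with ``1 - p_true``.  Outcome is +1 in the heist state on gain
    trials, -1 on loss trials, and 0 in the neutral state.  A missed choice
    samples nothing and returns ``(None, nan)``.
    """
    if choice == "missed":
        return None, float("nan")
    if choice not in ("dark", "light"):
        raise ValueError(f"choice must be 'dark', 'light' or 'missed', got {choice!r}")
    if valence not in ("gain", "loss"):
        raise ValueError(f"valence must be 'gain' or 'loss', got {valence!r}")
    p_heist = p_true if choice == "dark" else 1.0 - p_true
    state = "heist" if rng.random() < p_heist else "neutral"
    if state == "heist":
        outcome = 1 if valence == "gain" else -1
    else:
        outcome = 0
    return state, outcome
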