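"""Probabilistic reversal-learning task simulator.

Three symbols (A, B, C) are offered in pairs in a fixed cycle (AB, BC, CA).
At any moment one symbol carries the high reward probability (default 0.7)
and the other two the low probability (default 0.3).  Once the agent picks
the high symbol in ``criterion_hits`` of the last ``criterion_window``
trials, a buffer period with a fixed per-trial reversal hazard begins; when
it ends the high reward probability is reassigned uniformly to one of the
other two symbols.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TaskConfig",
    "TrialRecord",
    "SessionData",
    "TrialContext",
    "next_pair",
    "check_learning_criterion",
    "draw_buffer_length",
    "reassign_high_symbol",
    "run_session",
    "oracle_agent",
    "anti_oracle_agent",
    "random_agent",
]


@dataclass(frozen=True)
class TaskConfig:
    """Task parameters.  Defaults reproduce the two-block, 170-trial session
    with 70/30 contingencies, 5-of-6 learning criterion and a buffer whose
    length follows a per-trial reversal hazard of 0.3 truncated to [1, 8]."""

    n_blocks: int = 2
    trials_per_block: int = 170
    p_high: float = 0.7
    p_low: float = 0.3
    criterion_hits: int = 5
    criterion_window: int = 6
    buffer_hazard: float = 0.3
    buffer_min: int = 1
    buffer_max: int = 8
    pair_cycle: tuple[str, ...] = ("AB", "BC", "CA")
    seed: int | None = None
    # event timing (seconds): fixation and outcome delays are uniform(lo, hi)
    delay_range: tuple[float, float] = (1.0, 4.0)
    stim_duration: float = 1.25
    outcome_duration: float = 0.65

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_low < self.p_high <= 1.0):
            raise ValueError("require 0 <= p_low < p_high <= 1")
        if self.criterion_hits > self.criterion_window:
            raise ValueError("criterion_hits must not exceed criterion_window")
        if not (1 <= self.buffer_min <= self.buffer_max):
            raise ValueError("require 1 <= buffer_min <= buffer_max")
        if not self.pair_cycle:
            raise ValueError("pair_cycle must not be empty")

    @property
    def symbols(self) -> tuple[str, ...]:
        seen: list[str] = []
        for pair in self.pair_cycle:
            for s in pair:
                if s not in seen:
                    seen.append(s)
        return tuple(seen)

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block


@dataclass(frozen=True)
class TrialRecord:
    trial_index: int            # 0-based within the session
    block: int                  # 0-based block (run) index
    pair: str                   # e.g. "AB"; first-listed symbol comes first
    choice: str
    outcome: int                # 1 reward, 0 no reward
    high_symbol: str            # symbol carrying p_high when the trial ran
    phase: str                  # "learning" or "buffer"
    reversal_flag: bool         # first trial under a freshly reassigned contingency
    onset_s: float              # stimulus (decision-phase) onset, block-relative
    outcome_onset_s: float      # feedback onset, block-relative


@dataclass
class SessionData:
    """One simulated session: an ordered list of trials plus its config."""

    trials: list[TrialRecord]
    config: TaskConfig

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(t) for t in self.trials])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, config: TaskConfig | None = None) -> "SessionData":
        df = pd.read_csv(path, sep="\t")
        trials = [
            TrialRecord(
                trial_index=int(r.trial_index),
                block=int(r.block),
                pair=str(r.pair),
                choice=str(r.choice),
                outcome=int(r.outcome),
                high_symbol=str(r.high_symbol),
                phase=str(r.phase),
                reversal_flag=bool(r.reversal_flag),
                onset_s=float(r.onset_s),
                outcome_onset_s=float(r.outcome_onset_s),
            )
            for r in df.itertuples()
        ]
        return cls(trials=trials, config=config or TaskConfig())

    def block_trials(self, block: int) -> list[TrialRecord]:
        return [t for t in self.trials if t.block == block]

    @property
    def choices(self) -> list[str]:
        return [t.choice for t in self.trials]

    @property
    def outcomes(self) -> np.ndarray:
        return np.array([t.outcome for t in self.trials], dtype=int)

    @property
    def reward_rate(self) -> float:
        return float(self.outcomes.mean())


@dataclass(frozen=True)
class TrialContext:
    """What an agent may condition on when choosing.  ``high_symbol`` is
    ground truth, exposed for oracle/probe agents; learning agents must
    ignore it."""

    trial_index: int
    pair: str
    high_symbol: str
    history: Sequence[TrialRecord]


Agent = Callable[[TrialContext, np.random.Generator], str]


def next_pair(trial_index: int, cycle: Sequence[str]) -> str:
    """Pair offered on a trial: the cycle repeats in fixed order."""
    if len(cycle) == 0:
        raise ValueError("pair cycle is empty")
    if trial_index < 0:
        raise ValueError("trial_index must be >= 0")
    return cycle[trial_index % len(cycle)]


def check_learning_criterion(
    recent_correct: Sequence[bool], hits: int = 5, window: int = 6
) -> bool:
    """True once at least ``hits`` of the last ``window`` choices were the
    high symbol; always False while fewer than ``window`` choices have
    accrued since the last reversal."""
    if len(recent_correct) < window:
        return False
    return sum(bool(c) for c in recent_correct[-window:]) >= hits


def draw_buffer_length(
    hazard: float, min_len: int, max_len: int, rng: np.random.Generator
) -> int:
    """Number of post-criterion buffer trials before the reversal.

    Truncated-geometric hazard process: each buffer trial from ``min_len``
    on ends the buffer with probability ``hazard``; the length is capped at
    ``max_len`` (remaining mass on the cap).
    """
    if not (0.0 < hazard <= 1.0):
        raise ValueError("hazard must lie in (0, 1]; 0 would never terminate")
    k = min_len
    while k < max_len:
        if rng.random() < hazard:
            return k
        k += 1
    return max_len


def buffer_length_pmf(hazard: float, min_len: int, max_len: int) -> np.ndarray:
    """Closed-form pmf over lengths min_len..max_len (incl.)."""
    ks = np.arange(min_len, max_len + 1)
    pmf = hazard * (1 - hazard) ** (ks - min_len)
    pmf[-1] = (1 - hazard) ** (max_len - min_len)
    return pmf


def reassign_high_symbol(
    current: str, symbols: Sequence[str], rng: np.random.Generator
) -> str:
    """Reassign the high reward probability uniformly to a different symbol."""
    others = [s for s in symbols if s != current]
    return others[rng.integers(len(others))]


def run_session(
    config: TaskConfig,
    agent: Agent,
    rng: np.random.Generator | None = None,
) -> SessionData:
    """Simulate a full session for the given choice policy.

    Reversals only ever occur after the learning criterion is reached and
    the buffer is exhausted; the criterion window resets at each reversal.
    The same three symbols are reused across blocks within a run.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    symbols = config.symbols
    high = symbols[rng.integers(len(symbols))]

    trials: list[TrialRecord] = []
    correct_since_reversal: list[bool] = []
    buffer_remaining = 0  # 0 -> learning phase
    pending_reversal = False

    idx = 0
    for block in range(config.n_blocks):
        clock = 0.0  # block-relative time (one scanner run per block)
        for _ in range(config.trials_per_block):
            if pending_reversal:
                high = reassign_high_symbol(high, symbols, rng)
                correct_since_reversal = []
                pending_reversal = False
                reversal_flag = True
            else:
                reversal_flag = False

            pair = next_pair(idx, config.pair_cycle)
            ctx = TrialContext(
                trial_index=idx, pair=pair, high_symbol=high, history=trials
            )
            choice = agent(ctx, rng)
            if choice not in pair:
                raise ValueError(
                    f"agent chose {choice!r}, not in offered pair {pair!r}"
                )
            p = config.p_high if choice == high else config.p_low
            outcome = int(rng.random() < p)

            lo, hi_d = config.delay_range
            onset = clock + rng.uniform(lo, hi_d)
            outcome_onset = onset + config.stim_duration + rng.uniform(lo, hi_d)
            clock = outcome_onset + config.outcome_duration

            phase = "buffer" if buffer_remaining > 0 else "learning"
            trials.append(
                TrialRecord(
                    trial_index=idx,
                    block=block,
                    pair=pair,
                    choice=choice,
                    outcome=outcome,
                    high_symbol=high,
                    phase=phase,
                    reversal_flag=reversal_flag,
                    onset_s=onset,
                    outcome_onset_s=outcome_onset,
                )
            )

            # the criterion counts only trials on which the high symbol is
            # actually offered: on the low/low pair picking it is impossible,
            # and counting those trials would make 5-of-6 unreachable even
            # for a perfect agent under the 3-pair cycle
            if high in pair:
                correct_since_reversal.append(choice == high)
            if buffer_remaining > 0:
                buffer_remaining -= 1
                if buffer_remaining == 0:
                    pending_reversal = True
            elif check_learning_criterion(
                correct_since_reversal, config.criterion_hits, config.criterion_window
            ):
                buffer_remaining = draw_buffer_length(
                    config.buffer_hazard, config.buffer_min, config.buffer_max, rng
                )
            idx += 1

    return SessionData(trials=trials, config=config)


# ---------------------------------------------------------------- agents


def oracle_agent(ctx: TrialContext, rng: np.random.Generator) -> str:
    """Always picks the current high symbol when offered, else random."""
    if ctx.high_symbol in ctx.pair:
        return ctx.high_symbol
    return ctx.pair[rng.integers(len(ctx.pair))]


def anti_oracle_agent(ctx: TrialContext, rng: np.random.Generator) -> str:
    """Always avoids the current high symbol: picks a low symbol."""
    lows = [s for s in ctx.pair if s != ctx.high_symbol]
    return lows[rng.integers(len(lows))]


def random_agent(ctx: TrialContext, rng: np.random.Generator) -> str:
    return ctx.pair[rng.integers(len(ctx.pair))]
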