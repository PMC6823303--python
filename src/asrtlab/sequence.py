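"""ASRT trial-stream construction.

The alternating serial reaction time (ASRT) task presents arrows in four
spatial directions (1=left, 2=up, 3=down, 4=right).  Stimuli follow an
eight-element sequence P-r-P-r-P-r-P-r in which predetermined *pattern*
elements alternate with uniformly *random* ones.  Each 85-trial block opens
with five random warm-up trials followed by ten repetitions of the
eight-element cycle.

Because the stream is presented continuously, sequences that are cyclic
rotations of one another are behaviourally identical, leaving six unique
permutations of the four directions out of 24.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd

DIRECTIONS = (1, 2, 3, 4)

#: trial classes
WARMUP = "warmup"
PATTERN = "pattern"
RANDOM = "random"

TRIALS_PER_BLOCK = 85
WARMUP_TRIALS = 5
CYCLE_REPEATS = 10

#: trial timing constants (ms) — carried as metadata for event bookkeeping
STIMULUS_DURATION_MS = 200.0
RESPONSE_WINDOW_MS = 700.0   # 200 ms stimulus + up to 500 ms blank
RSI_MS = 700.0               # response-to-stimulus interval


@dataclass(frozen=True)
class SequenceSpec:
    """An ASRT pattern sequence: an ordered permutation of the 4 directions.

    The successor relation is cyclic — the element after the fourth is the
    first, so ``(2, 1, 3, 4)`` encodes the repeating pattern 2-r-1-r-3-r-4-r.
    """

    elements: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        if sorted(self.elements) != list(DIRECTIONS):
            raise ValueError(
                f"sequence elements must be a permutation of {DIRECTIONS}, "
                f"got {self.elements}"
            )

    @property
    def successor(self) -> dict[int, int]:
        """Cyclic successor map: element -> the pattern element that follows it."""
        e = self.elements
        return {e[i]: e[(i + 1) % 4] for i in range(4)}

    def canonical(self) -> "SequenceSpec":
        """Rotation-invariant representative starting with direction 1."""
        i = self.elements.index(1)
        return SequenceSpec(self.elements[i:] + self.elements[:i])


@dataclass
class TrialStream:
    """An ordered set of ASRT trials for one session.

    ``trials`` has one row per trial with columns ``block`` (1-based),
    ``pos`` (1..85 within block), ``trial_class`` (warmup/pattern/random)
    and ``direction`` (1..4).
    """

    trials: pd.DataFrame
    sequence: SequenceSpec
    n_blocks: int
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.trials)


def enumerate_unique_sequences() -> list[SequenceSpec]:
    """All rotationally unique ASRT sequences, canonicalised and sorted.

    There are 24 permutations of the four directions, but continuous
    presentation makes cyclic rotations equivalent, leaving 6 classes.
    Each representative starts with direction 1.
    """
    reps = {SequenceSpec(p).canonical().elements for p in permutations(DIRECTIONS)}
    return [SequenceSpec(e) for e in sorted(reps)]


def select_sequence(seed: int) -> SequenceSpec:
    """Pseudorandomly assign one of the six unique sequences (uniform draw)."""
    if seed < 0:
        raise ValueError("seed must be a non-negative integer")
    rng = np.random.default_rng(seed)
    pool = enumerate_unique_sequences()
    return pool[int(rng.integers(len(pool)))]


def generate_session(
    sequence: SequenceSpec,
    n_blocks: int = 30,
    rng_seed: int | None = None,
    phase_continuous: bool = False,
) -> TrialStream:
    """Build a full session of ``n_blocks`` 85-trial blocks.

    Each block is 5 i.i.d.-uniform warm-up trials followed by 10 repetitions
    of the eight-element cycle; pattern slots follow ``sequence`` cyclically,
    random slots are i.i.d. uniform over the four directions.

    By default the pattern phase restarts at the sequence's first element in
    every block (standard ASRT practice; the rotation equivalence classes make
    the starting element immaterial).  ``phase_continuous=True`` instead
    carries the phase across block boundaries.
    """
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    rng = np.random.default_rng(rng_seed)
    seq = sequence.elements

    blocks = np.repeat(np.arange(1, n_blocks + 1), TRIALS_PER_BLOCK)
    pos = np.tile(np.arange(1, TRIALS_PER_BLOCK + 1), n_blocks)
    is_warmup = pos <= WARMUP_TRIALS
    is_pattern = (~is_warmup) & (pos % 2 == 0)  # positions 6, 8, ..., 84

    direction = rng.integers(1, 5, size=n_blocks * TRIALS_PER_BLOCK)
    n_pattern = CYCLE_REPEATS * 4  # 40 per block
    if phase_continuous:
        idx = np.arange(n_blocks * n_pattern) % 4
    else:
        idx = np.tile(np.arange(n_pattern) % 4, n_blocks)
    direction[is_pattern] = np.asarray(seq)[idx]

    trial_class = np.where(is_warmup, WARMUP, np.where(is_pattern, PATTERN, RANDOM))
    trials = pd.DataFrame(
        {"block": blocks, "pos": pos, "trial_class": trial_class,
         "direction": direction}
    )
    return TrialStream(
        trials=trials,
        sequence=sequence,
        n_blocks=n_blocks,
        seed=rng_seed,
        meta={
            "stimulus_duration_ms": STIMULUS_DURATION_MS,
            "response_window_ms": RESPONSE_WINDOW_MS,
            "rsi_ms": RSI_MS,
            "phase_continuous": phase_continuous,
        },
    )


def epoch_bin_of_block(block, n_blocks: int, n_bins: int = 6):
    """Map 1-based block numbers to 1-based epoch bins of consecutive blocks.

    With the standard 30-block session and 6 bins, bin k covers blocks
    5k-4 .. 5k.  ``n_blocks`` must divide evenly into ``n_bins``.
    """
    if n_blocks % n_bins != 0:
        raise ValueError(
            f"n_blocks={n_blocks} is not divisible into {n_bins} equal epoch bins"
        )
    per = n_blocks // n_bins
    return (np.asarray(block) - 1) // per + 1


def stream_to_csv(stream: TrialStream, path, subject: int = 1) -> None:
    """Write a trial log: subject,block,pos,trial_class,direction,seed."""
    df = stream.trials.copy()
    df.insert(0, "subject", subject)
    df["seed"] = stream.seed if stream.seed is not None else ""
    df.to_csv(path, index=False)


def stream_from_csv(path, sequence: SequenceSpec) -> TrialStream:
    """Read a trial log written by :func:`stream_to_csv`."""
    df = pd.read_csv(path)
    required = {"block", "pos", "trial_class", "direction"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trial log missing columns: {sorted(missing)}")
    n_blocks = int(df["block"].max())
    seed = None
    if "seed" in df.columns and pd.notna(df["seed"].iloc[0]) and df["seed"].iloc[0] != "":
        seed = int(df["seed"].iloc[0])
    trials = df[["block", "pos", "trial_class", "direction"]].reset_index(drop=True)
    return TrialStream(trials=trials, sequence=sequence, n_blocks=n_blocks, seed=seed)
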