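"""Triplet probability structure of the ASRT task.

Every trial is the final element of exactly one *triplet* — the moving
window of three consecutive trials ending at it.  A triplet (d1, d2, d3) is
*high-probability* when d3 is the cyclic successor of d1 in the pattern
sequence; such triplets arise from both P-r-P and r-P-r structures and are
five times more frequent (per unique triplet) than low-probability ones.
Of the 64 ordered triplets, 16 are high-probability and 48 low-probability.

Trial categories used throughout the analyses:

* ``pattern_high`` — pattern-final trials (always high-probability),
* ``random_high`` — random-final trials completing a high-probability triplet,
* ``random_low``  — random-final trials completing a low-probability triplet,

occurring with steady-state probabilities 50%, 12.5% and 37.5%.  Trills
(d1 = d3, e.g. 1-2-1) and repetitions (d1 = d2 = d3) are low-probability
triplets with preexisting response tendencies and are removed from the RT
and ERP analyses.
"""

from __future__ import annotations

from itertools import product

import numpy as np
import pandas as pd

from .sequence import PATTERN, RANDOM, WARMUP, WARMUP_TRIALS, DIRECTIONS, SequenceSpec, TrialStream

UNCLASSIFIED = "unclassified"
PATTERN_HIGH = "pattern_high"
RANDOM_HIGH = "random_high"
RANDOM_LOW = "random_low"
RANDOM_COMBINED = "random_combined"

#: categories retained for RT / ERP analysis
ANALYSIS_CATEGORIES = (PATTERN_HIGH, RANDOM_HIGH, RANDOM_LOW)


def classify_stream(stream: TrialStream) -> pd.DataFrame:
    """Label every trial with its moving-window triplet category.

    The window never spans block boundaries: within each block, trial t is
    labeled from the directions at (t-2, t-1, t); the first two trials of a
    block are ``unclassified``.  Pattern-class trials are always
    ``pattern_high``; other trials are ``random_high`` when the final
    direction is the sequence's cyclic successor of the first, otherwise
    ``random_low``.  Warm-up-final triplets (positions 3-5) are labeled but
    flagged ``is_warmup_final`` so downstream filters can drop them.

    Returns a DataFrame aligned with ``stream.trials`` with columns
    ``t1, t2, t3, category, is_trill, is_repetition, is_warmup_final,
    analyzable``.
    """
    df = stream.trials
    d = df["direction"].to_numpy()
    pos = df["pos"].to_numpy()
    tclass = df["trial_class"].to_numpy()

    t1 = np.roll(d, 2)
    t2 = np.roll(d, 1)
    t1[pos <= 2] = 0  # no context: window would cross the block boundary
    t2[pos <= 1] = 0

    succ = stream.sequence.successor
    succ_arr = np.zeros(5, dtype=int)
    for k, v in succ.items():
        succ_arr[k] = v
    is_high = (t1 > 0) & (d == succ_arr[t1])

    category = np.full(len(df), UNCLASSIFIED, dtype=object)
    classified = pos > 2
    is_pat = tclass == PATTERN
    category[classified & is_pat] = PATTERN_HIGH
    category[classified & ~is_pat & is_high] = RANDOM_HIGH
    category[classified & ~is_pat & ~is_high] = RANDOM_LOW

    # trill/repetition structure is an exclusion criterion for random trials;
    # pattern-final triplets are never flagged (category stays pattern_high)
    trill_struct = classified & (t1 == d)
    is_trill = trill_struct & ~is_pat
    is_repetition = is_trill & (t2 == d)

    is_warmup_final = classified & (pos <= WARMUP_TRIALS)
    analyzable = (
        classified & ~is_warmup_final & ~is_trill & ~is_repetition
    )

    return pd.DataFrame(
        {
            "t1": t1,
            "t2": t2,
            "t3": d,
            "category": category,
            "is_trill": is_trill,
            "is_repetition": is_repetition,
            "is_warmup_final": is_warmup_final,
            "analyzable": analyzable,
        },
        index=df.index,
    )


def enumerate_triplets(sequence: SequenceSpec) -> pd.DataFrame:
    """Analytic table of all 64 ordered triplets with steady-state probabilities.

    A triplet is ``high`` iff its final direction is the cyclic successor of
    its first.  Per-trial steady-state probabilities follow from the 50/50
    pattern/random mixture: the first trial of a window is pattern or random
    with equal probability, the middle and final slots alternate accordingly,
    and random directions are uniform.

    A window ending on a pattern trial has P-r-P structure: the first element
    is a pattern direction (uniform 1/4 in steady state), the middle is
    uniform random, and the final element is the forced successor — weight
    1/2 * 1/16 on the matching high triplet.  A window ending on a random
    trial has r-P-r structure and puts weight 1/2 * 1/64 on every triplet.
    Hence each high triplet has per-trial probability 5/128 and each low
    triplet 1/128 — the printed five-fold per-unique-triplet ratio.
    """
    succ = sequence.successor
    rows = []
    for d1, d2, d3 in product(DIRECTIONS, repeat=3):
        high = succ[d1] == d3
        # steady state: a trial is pattern or random with prob 1/2;
        # P(first = d1) = 1/4 either way.  If first is pattern, the middle is
        # random (uniform 1/4) and the last is the forced successor; if first
        # is random, the middle is the pattern element (which is succ of the
        # *previous* pattern — uniform 1/4 over middles in steady state) and
        # the last is random uniform.
        p_pattern_route = 0.5 * 0.25 * 0.25 * (1.0 if high else 0.0)
        p_random_route = 0.5 * 0.25 * 0.25 * 0.25
        prob = p_pattern_route + p_random_route
        rows.append(
            {
                "d1": d1,
                "d2": d2,
                "d3": d3,
                "frequency_class": "high" if high else "low",
                "probability": prob,
            }
        )
    table = pd.DataFrame(rows)
    assert abs(table["probability"].sum() - 1.0) < 1e-12
    return table


def transitional_probability(
    sequence: SequenceSpec, d_first: int, d_third: int
) -> float:
    """Second-order transitional probability P(trial t+2 = d_third | trial t = d_first).

    Under the steady-state 50/50 pattern/random mixture the trial two ahead
    is either the forced pattern successor (probability 1/2) or uniform over
    the four directions (probability 1/2):

        p = 0.5 * 1[d_third = successor(d_first)] + 0.5 * 0.25

    yielding 62.5% for the successor continuation and 12.5% for each of the
    other three.
    """
    if d_first not in DIRECTIONS or d_third not in DIRECTIONS:
        raise ValueError("direction codes must be in 1..4")
    hit = 1.0 if sequence.successor[d_first] == d_third else 0.0
    return 0.5 * hit + 0.5 * 0.25


def filter_analysis_triplets(labels: pd.DataFrame) -> pd.DataFrame:
    """Rows of ``labels`` that enter the RT/ERP analyses.

    Drops unclassified trials, warm-up-final triplets, trills and
    repetitions; surviving categories are exactly pattern_high, random_high
    and random_low.
    """
    keep = labels["analyzable"]
    out = labels.loc[keep]
    assert set(out["category"].unique()) <= set(ANALYSIS_CATEGORIES)
    return out


def labels_to_csv(stream: TrialStream, labels: pd.DataFrame, path,
                  subject: int = 1) -> None:
    """Write the labeled trial log (trial columns + triplet columns)."""
    df = pd.concat([stream.trials, labels], axis=1)
    df.insert(0, "subject", subject)
    df.to_csv(path, index=False)
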