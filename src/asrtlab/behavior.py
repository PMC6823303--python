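"""Behavioral measures: median RTs, accuracy, and process-dissociation scores.

For each subject, epoch bin (five consecutive blocks) and triplet category
the median RT is computed over correct responses with RT > 0 ms, after the
triplet filter (trills, repetitions, warm-up-final and unclassified trials
removed).  The ``random_combined`` category pools random high- and
low-probability *trials* before taking the median — it is not a median of
medians.  Accuracy is the percentage of correct responses per cell, with
missing responses counted as incorrect.

The generation (inclusion/exclusion) task is scored as the percentage of
high-probability triplets among all moving-window triplets produced within
each run; trills and repetitions are counted here — the 25% chance level
(16 of 64 triplets) presumes their inclusion — and windows never cross run
boundaries.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .sequence import SequenceSpec
from .triplets import (
    ANALYSIS_CATEGORIES,
    RANDOM_COMBINED,
    RANDOM_HIGH,
    RANDOM_LOW,
    filter_analysis_triplets,
)

logger = logging.getLogger("asrtlab")

MEASURE_CATEGORIES = (*ANALYSIS_CATEGORIES, RANDOM_COMBINED)


def _cell_frame(record, include_warmup_triplets: bool = False) -> pd.DataFrame:
    """Analyzable trials joined with their responses and epoch bins."""
    labels = record.labels
    if include_warmup_triplets:
        keep = labels["analyzable"] | (
            labels["is_warmup_final"] & ~labels["is_trill"]
        )
        labels = labels.loc[keep]
    else:
        labels = filter_analysis_triplets(labels)
    df = labels[["category"]].join(record.responses)
    return df


def _complete(table: pd.DataFrame, epochs) -> pd.DataFrame:
    """Reindex to the full epoch x category grid; absent cells become NaN."""
    grid = pd.MultiIndex.from_product(
        [epochs, MEASURE_CATEGORIES], names=["epoch", "category"]
    )
    out = table.set_index(["epoch", "category"]).reindex(grid).reset_index()
    out["n"] = out["n"].fillna(0).astype(int)
    return out


def compute_rt_table(record, include_warmup_triplets: bool = False) -> pd.DataFrame:
    """Median RT (ms) per epoch bin x category for one subject.

    Only correct responses with RT > 0 ms contribute.  Returns a tidy frame
    with columns ``epoch, category, value, n``; empty cells carry NaN and
    are logged (such subjects are later excluded from the ANOVA).
    """
    df = _cell_frame(record, include_warmup_triplets)
    df = df[df["correct"] & (df["rt"] > 0)]
    combined = df[df["category"].isin((RANDOM_HIGH, RANDOM_LOW))].copy()
    combined["category"] = RANDOM_COMBINED
    df = pd.concat([df, combined])

    table = (
        df.groupby(["epoch_bin", "category"], sort=True)["rt"]
        .agg(value="median", n="size")
        .reset_index()
        .rename(columns={"epoch_bin": "epoch"})
    )
    epochs = sorted(record.responses["epoch_bin"].unique())
    out = _complete(table, epochs)
    n_missing = int(out["value"].isna().sum())
    if n_missing:
        logger.warning("subject %s: %d empty RT cells — excluded from ANOVA",
                       record.subject_id, n_missing)
    return out


def compute_accuracy_table(record, include_warmup_triplets: bool = False) -> pd.DataFrame:
    """Percentage of correct responses per epoch bin x category.

    The correctness filter is *not* applied; missing responses count as
    incorrect (the task treats a lapsed response window as a failure).
    """
    df = _cell_frame(record, include_warmup_triplets)
    combined = df[df["category"].isin((RANDOM_HIGH, RANDOM_LOW))].copy()
    combined["category"] = RANDOM_COMBINED
    df = pd.concat([df, combined])

    table = (
        df.groupby(["epoch_bin", "category"], sort=True)["correct"]
        .agg(value=lambda c: 100.0 * c.mean(), n="size")
        .reset_index()
        .rename(columns={"epoch_bin": "epoch"})
    )
    epochs = sorted(record.responses["epoch_bin"].unique())
    return _complete(table, epochs)


def cohort_measure_table(cohort, measure: str = "rt", **kw) -> pd.DataFrame:
    """Stack per-subject tables; adds a ``subject`` column.

    ``measure`` is ``"rt"`` or ``"accuracy"``.
    """
    fn = {"rt": compute_rt_table, "accuracy": compute_accuracy_table}[measure]
    frames = []
    for rec in cohort:
        t = fn(rec, **kw)
        t.insert(0, "subject", rec.subject_id)
        frames.append(t)
    return pd.concat(frames, ignore_index=True)


def score_runs(runs, sequence: SequenceSpec) -> float:
    """Percentage of high-probability triplets in a set of key-press runs.

    Moving-window triplets are formed within each run only; all triplets
    (including trills and repetitions) count.  Runs shorter than 3 presses
    are skipped with a warning.
    """
    succ = sequence.successor
    high = total = 0
    for run in runs:
        run = np.asarray(run)
        if len(run) < 3:
            warnings.warn("generation run shorter than 3 presses skipped",
                          stacklevel=2)
            continue
        first, last = run[:-2], run[2:]
        succ_arr = np.zeros(5, dtype=int)
        for k, v in succ.items():
            succ_arr[k] = v
        high += int((last == succ_arr[first]).sum())
        total += len(last)
    if total == 0:
        raise ValueError("no scoreable triplets in any run")
    return 100.0 * high / total


def score_generation(record) -> pd.DataFrame:
    """Process-dissociation scores for one subject: pct_high per condition."""
    rows = [
        {"subject": record.subject_id, "condition": cond,
         "pct_high": score_runs(runs, record.sequence)}
        for cond, runs in record.generation.items()
    ]
    return pd.DataFrame(rows)


def cohort_generation_scores(cohort) -> pd.DataFrame:
    return pd.concat([score_generation(r) for r in cohort], ignore_index=True)
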