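"""ERP measurement pipeline: segmentation, baseline, artifact rejection,
pooled averaging and P3 amplitude quantification.

Single-trial EEG arrives as stimulus-anchored arrays (channels x samples)
covering -700..+1300 ms so that both stimulus-locked (-200..600 ms) and
response-locked (-700..700 ms) epochs can be cut from the same trace.
Only analyzable triplets (pattern / random high / random low after trill
and repetition removal) with a correct response and RT > 0 ms are
segmented.

The P3 is quantified over a centroparietal pool (CP1, CPz, CP2, P1, Pz,
P2) as window mean amplitudes: the peak window brackets the ~330 ms grand
average maximum (280-380 ms stimulus-locked, -50..50 ms response-locked)
and the late window covers the descending flank (380-600 ms / 50-250 ms).
Baselines are -200..0 ms prestimulus and 500..700 ms post-response (the
final 200 ms of the response-to-stimulus interval).  Segments where any
channel exceeds +/-100 uV at any sample are rejected.

All windows are half-open [start, end) in ms, converted to sample indices
by flooring — a boundary sample such as 380 ms belongs to the late window
only.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .triplets import ANALYSIS_CATEGORIES, RANDOM_COMBINED, RANDOM_HIGH, RANDOM_LOW

logger = logging.getLogger("asrtlab")

STIMULUS = "stimulus"
RESPONSE = "response"

#: centroparietal electrode pool over which the P3 is quantified
CP_POOL = ("CP1", "CPz", "CP2", "P1", "Pz", "P2")

REJECTION_THRESHOLD_UV = 100.0

#: measurement components
P3_PEAK = "p3_peak"
LATE_P3 = "late_p3"


@dataclass(frozen=True)
class ComponentWindows:
    """Analysis windows in ms, keyed by locking; all half-open [lo, hi)."""

    span: dict = field(default_factory=lambda: {
        STIMULUS: (-200.0, 600.0),
        RESPONSE: (-700.0, 700.0),
    })
    p3_peak: dict = field(default_factory=lambda: {
        STIMULUS: (280.0, 380.0),
        RESPONSE: (-50.0, 50.0),
    })
    late_p3: dict = field(default_factory=lambda: {
        STIMULUS: (380.0, 600.0),
        RESPONSE: (50.0, 250.0),
    })
    baseline: dict = field(default_factory=lambda: {
        STIMULUS: (-200.0, 0.0),
        RESPONSE: (500.0, 700.0),
    })

    def component(self, which: str) -> dict:
        if which == P3_PEAK:
            return self.p3_peak
        if which == LATE_P3:
            return self.late_p3
        raise ValueError(f"unknown component {which!r}")


DEFAULT_WINDOWS = ComponentWindows()


def sample_index(t_ms: float, t0_ms: float, fs: float) -> int:
    """Index of the sample at time ``t_ms`` on a grid starting at ``t0_ms``."""
    return math.floor((t_ms - t0_ms) * fs / 1000.0)


def window_slice(window: tuple, t0_ms: float, fs: float, n_samples: int) -> slice:
    """Half-open sample slice for a [lo, hi) ms window on the given grid."""
    lo, hi = window
    i = sample_index(lo, t0_ms, fs)
    j = sample_index(hi, t0_ms, fs)
    if i < 0 or j > n_samples or i >= j:
        raise ValueError(
            f"window {window} ms falls outside the sampled span "
            f"(t0={t0_ms} ms, {n_samples} samples at {fs} Hz)"
        )
    return slice(i, j)


@dataclass
class EpochSet:
    """Cut segments for one subject and one locking.

    ``data`` is (n_segments, n_channels, n_samples) in uV; ``info`` carries
    one row per segment (trial row index, category, epoch_bin, rt).
    """

    data: np.ndarray
    times: np.ndarray          # ms relative to the locking event
    fs: float
    channels: tuple
    locking: str
    info: pd.DataFrame
    n_dropped: int = 0         # qualifying trials whose span exceeded the data

    def __len__(self) -> int:
        return len(self.info)


def segment_trials(
    record,
    locking: str,
    windows: ComponentWindows = DEFAULT_WINDOWS,
) -> EpochSet:
    """Cut per-trial segments for one locking from a subject's EEG arrays.

    One segment per analyzable, correctly responded trial with RT > 0 ms.
    Response-locked segments are cut at stimulus time + RT; trials whose
    requested span exceeds the stored array are dropped and counted.
    """
    if locking not in (STIMULUS, RESPONSE):
        raise ValueError(f"locking must be {STIMULUS!r} or {RESPONSE!r}")
    if record.eeg is None:
        raise ValueError("subject record carries no EEG data")
    meta = record.eeg_meta
    t0, fs = meta["t0_ms"], meta["fs"]
    n_total = record.eeg.shape[2]

    lo, hi = windows.span[locking]
    n_samp = sample_index(hi, 0.0, fs) - sample_index(lo, 0.0, fs)

    resp = record.responses
    qual = record.labels["analyzable"] & resp["correct"] & (resp["rt"] > 0)
    rows = np.flatnonzero(qual.to_numpy())

    starts = np.empty(len(rows), dtype=int)
    if locking == STIMULUS:
        starts[:] = sample_index(lo, t0, fs)
    else:
        rts = resp["rt"].to_numpy()[rows]
        # response-locked t=0 sits at stimulus time + RT
        starts = np.floor((rts + lo - t0) * fs / 1000.0).astype(int)

    ok = (starts >= 0) & (starts + n_samp <= n_total)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("%s-locked segmentation dropped %d trials outside the "
                    "stored span", locking, n_dropped)
    rows, starts = rows[ok], starts[ok]

    data = np.empty((len(rows), record.eeg.shape[1], n_samp), dtype=np.float32)
    for k, (r, s) in enumerate(zip(rows, starts)):
        data[k] = record.eeg[r, :, s:s + n_samp]

    times = lo + np.arange(n_samp) * 1000.0 / fs
    info = pd.DataFrame({
        "trial_row": rows,
        "category": record.labels["category"].to_numpy()[rows],
        "epoch_bin": resp["epoch_bin"].to_numpy()[rows],
        "rt": resp["rt"].to_numpy()[rows],
    })
    return EpochSet(data=data, times=times, fs=fs,
                    channels=tuple(meta["channels"]), locking=locking,
                    info=info, n_dropped=n_dropped)


def baseline_correct(
    epochs: EpochSet, windows: ComponentWindows = DEFAULT_WINDOWS
) -> EpochSet:
    """Subtract each channel's mean over the locking-appropriate baseline window."""
    sl = window_slice(windows.baseline[epochs.locking], epochs.times[0],
                      epochs.fs, epochs.data.shape[2])
    base = epochs.data[:, :, sl].mean(axis=2, keepdims=True)
    return EpochSet(data=epochs.data - base, times=epochs.times, fs=epochs.fs,
                    channels=epochs.channels, locking=epochs.locking,
                    info=epochs.info, n_dropped=epochs.n_dropped)


def reject_artifacts(
    epochs: EpochSet, threshold: float = REJECTION_THRESHOLD_UV
) -> tuple[EpochSet, pd.DataFrame]:
    """Drop segments where activity exceeds ±threshold uV at any electrode.

    Exceeding is strict (> threshold); a sample at exactly the threshold is
    retained.  Returns the retained set and per-category rejection stats.
    """
    bad = (np.abs(epochs.data) > threshold).any(axis=(1, 2))
    stats = (
        epochs.info.assign(rejected=bad)
        .groupby("category", sort=True)["rejected"]
        .agg(n_total="size", n_rejected="sum")
        .reset_index()
    )
    stats["pct_rejected"] = 100.0 * stats["n_rejected"] / stats["n_total"]
    kept = EpochSet(data=epochs.data[~bad], times=epochs.times, fs=epochs.fs,
                    channels=epochs.channels, locking=epochs.locking,
                    info=epochs.info.loc[~bad].reset_index(drop=True),
                    n_dropped=epochs.n_dropped)
    return kept, stats


def average_and_pool(
    epochs: EpochSet, channel_pool=CP_POOL
) -> dict:
    """Average segments within category x epoch-bin cells, then pool channels.

    ``random_combined`` pools random high- and low-probability segments.
    Returns {(category, epoch_bin): (waveform, n_segments)}; cells with zero
    segments are flagged by ``(None, 0)``.
    """
    missing = set(channel_pool) - set(epochs.channels)
    if missing:
        raise ValueError(f"channel pool members absent from data: {sorted(missing)}")
    pool_idx = [epochs.channels.index(c) for c in channel_pool]

    cats = epochs.info["category"].to_numpy()
    bins = epochs.info["epoch_bin"].to_numpy()
    out = {}
    all_bins = sorted(set(bins)) or [1]
    for cat in (*ANALYSIS_CATEGORIES, RANDOM_COMBINED):
        if cat == RANDOM_COMBINED:
            in_cat = (cats == RANDOM_HIGH) | (cats == RANDOM_LOW)
        else:
            in_cat = cats == cat
        for b in all_bins:
            sel = in_cat & (bins == b)
            n = int(sel.sum())
            if n == 0:
                out[(cat, b)] = (None, 0)
                continue
            wave = epochs.data[sel].mean(axis=0)[pool_idx].mean(axis=0)
            out[(cat, b)] = (wave, n)
    return out


def measure_component(
    waveform: np.ndarray,
    times: np.ndarray,
    fs: float,
    windows: ComponentWindows,
    which: str,
    locking: str,
) -> float:
    """Mean amplitude of a pooled waveform over a component window."""
    sl = window_slice(windows.component(which)[locking], times[0], fs,
                      len(waveform))
    return float(np.mean(waveform[sl]))


def erp_measure_table(
    record,
    windows: ComponentWindows = DEFAULT_WINDOWS,
    threshold: float = REJECTION_THRESHOLD_UV,
    channel_pool=CP_POOL,
) -> pd.DataFrame:
    """Full single-subject ERP pipeline, both lockings.

    segment -> baseline -> artifact rejection -> pooled category x epoch-bin
    averages -> P3 peak and late P3 window means.  Returns a tidy table with
    columns locking, category, epoch, component, amplitude, n_segments
    (amplitude NaN for empty cells).
    """
    rows = []
    for locking in (STIMULUS, RESPONSE):
        epochs = segment_trials(record, locking, windows)
        epochs = baseline_correct(epochs, windows)
        epochs, _ = reject_artifacts(epochs, threshold)
        cells = average_and_pool(epochs, channel_pool)
        for (cat, b), (wave, n) in cells.items():
            for which in (P3_PEAK, LATE_P3):
                amp = (np.nan if wave is None else
                       measure_component(wave, epochs.times, epochs.fs,
                                         windows, which, locking))
                rows.append({"locking": locking, "category": cat, "epoch": b,
                             "component": which, "amplitude": amp,
                             "n_segments": n})
    return pd.DataFrame(rows)
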