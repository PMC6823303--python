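"""Synthetic ASRT participants: responses, RTs, EEG segments, generation runs.

The generator emulates the statistical structure the downstream pipelines
assume: 32 subjects x 30 blocks x 85 trials; right-skewed RTs with
triplet-category and practice (epoch-bin) effects around ~360 ms; ~93%
accuracy; multichannel stimulus-anchored EEG traces carrying a
centroparietal P3-like positivity peaking near 330 ms whose peak-window and
late-window amplitudes vary by category and epoch bin; occasional >100 uV
artifacts; and inclusion/exclusion key-press runs with a tunable bias
toward high-probability continuations.

Default effect sizes are calibrated to the group means the measurement
pipelines should recover: category RT means 363/360/370 ms (pattern /
random-high / random-low around a 360 ms baseline), accuracies from the
93% band, P3 peak amplitudes 3.74/3.61/3.67 uV, and late-P3 epoch profiles
declining after the second bin.

Amplitude calibration is exact by construction: the peak Gaussian and the
slow late wave are jointly scaled, per category and epoch bin, so that the
baseline-corrected stimulus-locked window means of the noiseless template
equal the configured ``p3_amp`` and ``late_p3_amp`` on the discrete sample
grid.  Response-locked traces are the same stimulus-anchored arrays cut at
stimulus time + RT, guaranteeing stimulus/response consistency.

Every random draw flows from one seeded generator per subject; subject
seeds are spawned deterministically from the cohort master seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .erp import CP_POOL, DEFAULT_WINDOWS, ComponentWindows, STIMULUS, sample_index
from .sequence import (
    RESPONSE_WINDOW_MS,
    SequenceSpec,
    TrialStream,
    epoch_bin_of_block,
    generate_session,
    select_sequence,
)
from .triplets import (
    ANALYSIS_CATEGORIES,
    PATTERN_HIGH,
    RANDOM_HIGH,
    RANDOM_LOW,
    classify_stream,
)

logger = logging.getLogger("asrtlab")

#: stimulus-anchored storage span (ms); wide enough to cut both lockings
EEG_SPAN_MS = (-700.0, 1300.0)

_LOGN_SHAPE = 0.5  # shape of the right-skewed RT noise distribution


@dataclass
class BehaviorParams:
    """Trial-level response model.

    RT(trial) = baseline_rt + category_effect + epoch_effect + skewed noise,
    truncated at the task's 700 ms response window (a late response counts
    as missing, mirroring the task's "!" feedback).  Responses are correct
    with the per-category probability and missing with ``miss_rate``.
    """

    baseline_rt: float = 360.0
    category_effects: dict = field(default_factory=lambda: {
        PATTERN_HIGH: 3.0, RANDOM_HIGH: 0.0, RANDOM_LOW: 10.0,
    })
    epoch_effects: tuple = (4.0, 4.0, -3.0, 1.0, -5.0, 0.0)
    rt_noise_sd: float = 35.0
    accuracy: dict = field(default_factory=lambda: {
        PATTERN_HIGH: 0.932, RANDOM_HIGH: 0.939, RANDOM_LOW: 0.919,
    })
    miss_rate: float = 0.01

    def __post_init__(self):
        if self.baseline_rt <= 0:
            raise ValueError("baseline_rt must be positive")
        for k, v in self.accuracy.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"accuracy[{k}] outside [0, 1]")
        if not 0.0 <= self.miss_rate <= 1.0:
            raise ValueError("miss_rate outside [0, 1]")


@dataclass
class ErpParams:
    """Single-trial EEG model.

    Each trial's trace is a P3-like Gaussian bump (peak ``p3_latency``,
    width ``p3_width``) plus a slow late wave, carried at unit gain by the
    centroparietal pool and attenuated elsewhere, plus white noise.  With
    probability ``artifact_rate`` one channel receives a brief excursion of
    ±``artifact_amp`` uV (kept > 100 uV so injected artifacts are
    rejectable) at a random latency within 0-600 ms post-stimulus, inside
    both locking spans.
    """

    sampling_rate: float = 250.0
    channel_names: tuple = (*CP_POOL, "Fz", "Oz")
    p3_latency: float = 330.0
    p3_width: float = 40.0
    p3_amp: dict = field(default_factory=lambda: {
        PATTERN_HIGH: 3.74, RANDOM_HIGH: 3.61, RANDOM_LOW: 3.67,
    })
    late_p3_amp: dict = field(default_factory=lambda: {
        PATTERN_HIGH:  (1.35, 1.44, 0.86, 1.17, 0.89, 1.14),
        RANDOM_HIGH:   (1.41, 1.30, 0.61, 0.86, 0.90, 0.80),
        RANDOM_LOW:    (1.32, 1.40, 0.91, 1.22, 1.00, 1.23),
    })
    late_latency: float = 470.0
    late_width: float = 120.0
    noise_sd: float = 10.0
    artifact_rate: float = 0.005
    artifact_amp: float = 150.0
    offpool_gain: float = 0.3

    def __post_init__(self):
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.artifact_amp <= 100.0:
            raise ValueError("artifact_amp must exceed the 100 uV rejection "
                             "threshold so injected artifacts are rejectable")
        missing = set(CP_POOL) - set(self.channel_names)
        if missing:
            raise ValueError(f"channel_names must include the CP pool; "
                             f"missing {sorted(missing)}")


@dataclass
class GenerationParams:
    """Inclusion/exclusion generation task: 4 runs of 24 key presses each.

    At every press after the second, the high-probability continuation of
    the press two back is chosen with probability ``bias``; otherwise one of
    the other three directions is chosen uniformly.  A bias of 0.25 makes
    presses fully uniform (chance performance, 25% high-probability
    triplets)."""

    bias_inclusion: float = 0.315
    bias_exclusion: float = 0.281
    runs: int = 4
    presses_per_run: int = 24

    def __post_init__(self):
        for b in (self.bias_inclusion, self.bias_exclusion):
            if not 0.0 <= b <= 1.0:
                raise ValueError("bias outside [0, 1]")


@dataclass
class BetweenSubjectSD:
    """Between-subject standard deviations for the cohort generator."""

    baseline_rt: float = 20.0
    category_effect: float = 2.0
    p3_offset: float = 1.0        # common shift of all P3 amplitudes
    p3_effect: float = 0.05       # per-category jitter of peak amplitudes
    late_offset: float = 0.3
    late_effect: float = 0.1


@dataclass
class CohortParams:
    n_subjects: int = 32
    n_blocks: int = 30
    n_bins: int = 6
    behavior: BehaviorParams = field(default_factory=BehaviorParams)
    erp: ErpParams = field(default_factory=ErpParams)
    generation: GenerationParams = field(default_factory=GenerationParams)
    between: BetweenSubjectSD = field(default_factory=BetweenSubjectSD)


@dataclass
class SubjectRecord:
    """One synthetic participant: trials, labels, responses, EEG, key presses."""

    subject_id: int
    sequence: SequenceSpec
    stream: TrialStream
    labels: pd.DataFrame
    responses: pd.DataFrame
    eeg: np.ndarray | None = None
    eeg_meta: dict | None = None
    generation: dict | None = None
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# behavior

def _centered_skew_noise(rng, n, sd):
    """Right-skewed (shifted lognormal) noise with mean 0 and the given SD."""
    if sd == 0:
        return np.zeros(n)
    s = _LOGN_SHAPE
    x = rng.lognormal(mean=0.0, sigma=s, size=n)
    mu = np.exp(s * s / 2.0)
    sd0 = np.sqrt((np.exp(s * s) - 1.0) * np.exp(s * s))
    return (x - mu) / sd0 * sd


def simulate_behavior(
    stream: TrialStream,
    labels: pd.DataFrame,
    params: BehaviorParams,
    rng_seed,
    n_bins: int = 6,
) -> pd.DataFrame:
    """Per-trial responses: key, correct flag, RT (NaN when missing), epoch bin."""
    if len(labels) != len(stream.trials):
        raise ValueError("labels are not aligned with the trial stream")
    rng = np.random.default_rng(rng_seed)
    n = len(stream.trials)
    cats = labels["category"].to_numpy()
    bins = epoch_bin_of_block(stream.trials["block"].to_numpy(),
                              stream.n_blocks, n_bins)

    default_acc = float(np.mean(list(params.accuracy.values())))
    acc = np.array([params.accuracy.get(c, default_acc) for c in cats])
    cat_eff = np.array([params.category_effects.get(c, 0.0) for c in cats])
    epoch_eff = np.asarray(params.epoch_effects)[bins - 1]

    rt = params.baseline_rt + cat_eff + epoch_eff \
        + _centered_skew_noise(rng, n, params.rt_noise_sd)
    rt = np.maximum(rt, 1.0)

    missing = rng.random(n) < params.miss_rate
    missing |= rt > RESPONSE_WINDOW_MS  # response window elapsed
    correct = (rng.random(n) < acc) & ~missing

    direction = stream.trials["direction"].to_numpy()
    key = direction.copy()
    wrong = ~correct & ~missing
    # incorrect responses press one of the other three keys uniformly
    offs = rng.integers(1, 4, size=int(wrong.sum()))
    key[wrong] = (direction[wrong] - 1 + offs) % 4 + 1
    key = key.astype(float)
    key[missing] = np.nan
    rt = rt.astype(float)
    rt[missing] = np.nan

    return pd.DataFrame({
        "key": key, "correct": correct, "rt": rt, "epoch_bin": bins,
    }, index=stream.trials.index)


# ---------------------------------------------------------------------------
# EEG

def _template_basis(params: ErpParams):
    """Global time grid and the two unit component shapes (peak, late)."""
    fs = params.sampling_rate
    t0, t1 = EEG_SPAN_MS
    n = sample_index(t1, t0, fs)
    t = t0 + np.arange(n) * 1000.0 / fs
    g = np.exp(-0.5 * ((t - params.p3_latency) / params.p3_width) ** 2)
    s = np.exp(-0.5 * ((t - params.late_latency) / params.late_width) ** 2)
    return t, g, s


def _window_indices(window, t0, fs, seg_lo):
    """Global sample indices of a stimulus-locked analysis window, replicating
    the segmentation pipeline's index arithmetic."""
    seg_start = sample_index(seg_lo, t0, fs)
    lo = seg_start + sample_index(window[0], seg_lo, fs)
    hi = seg_start + sample_index(window[1], seg_lo, fs)
    return slice(lo, hi)


def calibrate_template(
    params: ErpParams, windows: ComponentWindows = DEFAULT_WINDOWS
) -> dict:
    """Per (category, epoch_bin) coefficients (a, b) of the two basis shapes.

    Solves the 2x2 system so that the noiseless template's baseline-corrected
    stimulus-locked peak- and late-window means equal the configured
    amplitudes exactly on the discrete grid.
    """
    fs = params.sampling_rate
    t0 = EEG_SPAN_MS[0]
    _, g, s = _template_basis(params)
    seg_lo = windows.span[STIMULUS][0]
    pk = _window_indices(windows.p3_peak[STIMULUS], t0, fs, seg_lo)
    lt = _window_indices(windows.late_p3[STIMULUS], t0, fs, seg_lo)
    bs = _window_indices(windows.baseline[STIMULUS], t0, fs, seg_lo)

    def corrected_means(x):
        b = x[bs].mean()
        return x[pk].mean() - b, x[lt].mean() - b

    m = np.array([corrected_means(g), corrected_means(s)]).T  # rows: pk, lt
    coeffs = {}
    n_bins = len(next(iter(params.late_p3_amp.values())))
    for cat in params.p3_amp:
        for b in range(1, n_bins + 1):
            target = np.array([params.p3_amp[cat],
                               params.late_p3_amp[cat][b - 1]])
            coeffs[(cat, b)] = np.linalg.solve(m, target)
    return coeffs


def simulate_eeg(
    stream: TrialStream,
    labels: pd.DataFrame,
    responses: pd.DataFrame,
    params: ErpParams,
    rng_seed,
    windows: ComponentWindows = DEFAULT_WINDOWS,
) -> tuple[np.ndarray, dict]:
    """Stimulus-anchored per-trial EEG arrays (trials x channels x samples).

    Trials outside the three analysis categories (warm-up context, etc.)
    carry the grand-mean template of their epoch bin; they never reach the
    measurement stage but keep the arrays trial-aligned.
    """
    rng = np.random.default_rng(rng_seed)
    fs = params.sampling_rate
    t, g, s = _template_basis(params)
    n_samp = len(t)
    channels = tuple(params.channel_names)
    n_ch = len(channels)
    gains = np.array([1.0 if c in CP_POOL else params.offpool_gain
                      for c in channels])

    coeffs = calibrate_template(params, windows)
    n_bins = len(next(iter(params.late_p3_amp.values())))
    mean_by_bin = {
        b: np.mean([coeffs[(c, b)] for c in params.p3_amp], axis=0)
        for b in range(1, n_bins + 1)
    }

    cats = labels["category"].to_numpy()
    bins = responses["epoch_bin"].to_numpy()
    n_trials = len(stream.trials)

    basis = np.stack([g, s])  # (2, n_samp)
    data = np.empty((n_trials, n_ch, n_samp), dtype=np.float32)
    ab = np.array([coeffs.get((c, b), mean_by_bin[b])
                   for c, b in zip(cats, bins)])     # (n_trials, 2)
    signal = ab @ basis                              # (n_trials, n_samp)
    data[:] = (signal[:, None, :] * gains[None, :, None]).astype(np.float32)
    if params.noise_sd > 0:
        for i in range(n_trials):  # chunked to bound peak memory
            data[i] += rng.normal(0.0, params.noise_sd,
                                  size=(n_ch, n_samp)).astype(np.float32)

    if params.artifact_rate > 0:
        hit = np.flatnonzero(rng.random(n_trials) < params.artifact_rate)
        lo = sample_index(0.0, EEG_SPAN_MS[0], fs)
        hi = sample_index(600.0, EEG_SPAN_MS[0], fs) - 3
        for i in hit:
            ch = int(rng.integers(n_ch))
            at = int(rng.integers(lo, hi))
            sign = 1.0 if rng.random() < 0.5 else -1.0
            data[i, ch, at:at + 3] = sign * params.artifact_amp

    meta = {"t0_ms": EEG_SPAN_MS[0], "fs": fs, "channels": channels}
    return data, meta


# ---------------------------------------------------------------------------
# generation (inclusion/exclusion) task

def _simulate_runs(sequence: SequenceSpec, bias, runs, presses, rng):
    succ = sequence.successor
    out = []
    for _ in range(runs):
        p = np.empty(presses, dtype=int)
        p[:2] = rng.integers(1, 5, size=2)
        for i in range(2, presses):
            high = succ[p[i - 2]]
            if rng.random() < bias:
                p[i] = high
            else:
                others = [d for d in (1, 2, 3, 4) if d != high]
                p[i] = others[int(rng.integers(3))]
        out.append(p)
    return out


def simulate_generation_task(
    sequence: SequenceSpec, params: GenerationParams, rng_seed
) -> dict:
    """Key-press runs for the inclusion and exclusion conditions."""
    rng = np.random.default_rng(rng_seed)
    return {
        "inclusion": _simulate_runs(sequence, params.bias_inclusion,
                                    params.runs, params.presses_per_run, rng),
        "exclusion": _simulate_runs(sequence, params.bias_exclusion,
                                    params.runs, params.presses_per_run, rng),
    }


# ---------------------------------------------------------------------------
# cohort

def _draw_subject_params(params: CohortParams, rng):
    """Per-subject parameter draws around the population means."""
    b, sd = params.behavior, params.between
    beh = replace(
        b,
        baseline_rt=max(1.0, rng.normal(b.baseline_rt, sd.baseline_rt)),
        category_effects={
            c: v + rng.normal(0.0, sd.category_effect)
            for c, v in b.category_effects.items()
        },
    )
    e = params.erp
    p3_off = rng.normal(0.0, sd.p3_offset)
    late_off = rng.normal(0.0, sd.late_offset)
    erp = replace(
        e,
        p3_amp={c: v + p3_off + rng.normal(0.0, sd.p3_effect)
                for c, v in e.p3_amp.items()},
        late_p3_amp={
            c: tuple(v + late_off + rng.normal(0.0, sd.late_effect)
                     for v in vs)
            for c, vs in e.late_p3_amp.items()
        },
    )
    return beh, erp


def simulate_subject(
    subject_id: int,
    params: CohortParams,
    seed_seq: np.random.SeedSequence,
    with_eeg: bool = True,
    sequence: SequenceSpec | None = None,
) -> SubjectRecord:
    """One synthetic participant, fully determined by ``seed_seq``."""
    s_param, s_seq, s_beh, s_eeg, s_gen = seed_seq.spawn(5)
    rng = np.random.default_rng(s_param)
    if sequence is None:
        sequence = select_sequence(int(np.random.default_rng(s_seq)
                                       .integers(2 ** 31)))
    beh_p, erp_p = _draw_subject_params(params, rng)

    stream = generate_session(sequence, params.n_blocks, s_seq)
    labels = classify_stream(stream)
    responses = simulate_behavior(stream, labels, beh_p, s_beh, params.n_bins)
    eeg = eeg_meta = None
    if with_eeg:
        eeg, eeg_meta = simulate_eeg(stream, labels, responses, erp_p, s_eeg)
    generation = simulate_generation_task(sequence, params.generation, s_gen)
    return SubjectRecord(
        subject_id=subject_id, sequence=sequence, stream=stream,
        labels=labels, responses=responses, eeg=eeg, eeg_meta=eeg_meta,
        generation=generation,
        meta={"seed_spawn_key": tuple(seed_seq.spawn_key),
              "behavior_params": beh_p, "erp_params": erp_p},
    )


def iter_cohort(params: CohortParams, rng_seed: int, with_eeg: bool = True):
    """Yield subjects one at a time (EEG arrays are large; stream them)."""
    if params.n_subjects < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    master = np.random.SeedSequence(rng_seed)
    children = master.spawn(params.n_subjects)
    for i, child in enumerate(children, start=1):
        yield simulate_subject(i, params, child, with_eeg=with_eeg)


def simulate_cohort(
    params: CohortParams, rng_seed: int, with_eeg: bool = False
) -> list[SubjectRecord]:
    """Materialise a full cohort (EEG off by default; see :func:`iter_cohort`)."""
    return list(iter_cohort(params, rng_seed, with_eeg=with_eeg))
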