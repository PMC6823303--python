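# Methods

## Task model

A session is `n_blocks` blocks of 85 trials: 5 warm-up trials drawn
i.i.d. uniform over the four directions, then 10 repetitions of the
eight-element P–r–P–r cycle. Pattern slots follow the subject's sequence
(one of the 6 rotation-unique permutations of {1,2,3,4}) cyclically; random
slots are i.i.d. uniform. By default the pattern phase restarts at the
sequence's first element in every block — the standard convention, and
immaterial up to rotation because sequence identity is defined modulo
rotation; `phase_continuous=True` carries the phase across blocks instead.

### Triplet classification

Trial *t* is labeled from directions at (t−2, t−1, t), with the window never
crossing a block boundary (the warm-up exists to re-establish context, so a
fresh block restarts the window; the first two trials are `unclassified`).
Pattern-class trials are labeled `pattern_high` unconditionally — they are
the predetermined elements of the regularity, and their triplet is
high-probability by construction whenever its first element is also a
pattern element. Random-final (and warm-up-final) triplets are
`random_high` iff the final direction is the cyclic successor of the first,
else `random_low`. Trill (d₁ = d₃) and repetition (d₁ = d₂ = d₃) flags are
set on non-pattern-final triplets only; the analysis filter removes trills,
repetitions, warm-up-final and unclassified trials, leaving exactly
{pattern_high, random_high, random_low}. Warm-up-final triplets (positions
3–5) are excluded by default because their context is all-random rather
than alternating; `include_warmup_triplets=True` keeps the non-trill ones.

The steady-state probability table assigns 5/128 to each high and 1/128 to
each low triplet (16 × 5/128 + 48 × 1/128 = 1), the source of the printed
five-fold frequency ratio and of the 50/12.5/37.5% category split. Two
finite-block effects are worth knowing when validating against simulation:
windows that touch the warm-up trials sample an all-random context, and the
sequence's last pattern element serves as a window-first only 9 (not 10)
times per block because its tenth window would cross the block boundary.
The test suite's frequency oracle uses the exact per-block expectation; the
acceptance script's transitional-probability cross-check aggregates over
the four successor pairs on alternating-context windows (position ≥ 8),
where the 62.5%/12.5% values are exact.

## Synthetic subjects

The generator emulates only the statistical structure the pipelines
consume; it is not a biophysical EEG model (no dipole geometry, no 1/f
spectrum, no ocular/cardiac artifact morphology — the real pipeline's
upstream preprocessing, filtering/ICA/re-referencing, is out of scope and
segments are generated at that stage of cleanliness). Passing tests
therefore demonstrate correctness of the measurement chain and the
statistics under known ground truth, not robustness to real-world EEG
nuisance structure.

### Behavior

RT = baseline + category effect + epoch-bin effect + centered right-skewed
noise (shifted lognormal, shape 0.5, scaled to `rt_noise_sd`; RT
distributions are right-skewed and the downstream statistic is the median,
so the exact family is non-critical). Defaults: baseline 360 ms; category
effects +3/0/+10 ms (pattern / random-high / random-low), reproducing the
363/360/370 ms group means the pipeline should recover; epoch effects
(4, 4, −3, 1, −5, 0) ms emulating a practice curve with its epoch-3/5 dips;
noise SD 35 ms; accuracies 0.932/0.939/0.919 (the ~93% band); miss rate
0.01. Responses later than the 700 ms response window (200 ms stimulus +
500 ms blank) count as missing — the task has no explicit RT ceiling, so
the window is adopted as one. Misses carry no key and no RT and are counted
as incorrect by the accuracy table (the task treats a lapsed window as a
failure).

### EEG

Each trial's trace is stimulus-anchored over −700…+1300 ms so both
stimulus-locked (−200…600 ms) and response-locked (−700…700 ms) epochs are
cut from the same array; response-locked t = 0 sits at stimulus time + RT,
which guarantees stimulus/response consistency by construction. The signal
is a P3-like Gaussian bump (peak 330 ms, SD 40 ms) plus a separate slow
late wave (Gaussian, center 470 ms, SD 120 ms) so the peak and late windows
can be manipulated independently, carried at unit gain by the CP pool and
attenuated (×0.3) elsewhere, plus white noise (SD 10 μV). The two component
amplitudes are solved per (category, epoch-bin) from a 2×2 linear system so
that the noiseless template's baseline-corrected stimulus-locked window
means equal the configured `p3_amp` (3.74/3.61/3.67 μV) and `late_p3_amp`
(per-bin profiles declining after bin 2, with the random-high decline
steepest) exactly on the discrete sample grid — noiseless recovery is then
exact rather than approximate. Sampling rate defaults to 250 Hz,
configurable. With probability `artifact_rate` (default 0.005) one channel
receives a 3-sample ±150 μV excursion at a random latency in 0–600 ms
post-stimulus — inside both locking spans, so an artifactual trial is
rejected under either locking.

### Generation task

Four runs of 24 presses per condition. After the first two uniform presses,
each press is the high-probability continuation of the press two back with
probability `bias`, else uniform over the other three directions; bias 0.25
therefore reproduces fully uniform pressing and the 25% chance level.
Default biases 0.315 (inclusion) and 0.281 (exclusion) mirror the reported
above-chance production (≈ +6.5% and +3.1%).

### Cohorts

Per-subject parameters are drawn around the population means
(between-subject SDs: baseline RT 20 ms, category effects 2 ms, a common P3
amplitude offset 1.0 μV with 0.05 μV per-category jitter, late-wave offset
0.3 μV with 0.1 μV jitter); per-subject seeds are spawned deterministically
from the master seed (`numpy` `SeedSequence`), and each subject's sequence
is assigned pseudorandomly from the six classes. Defaults: 32 subjects,
30 blocks, 6 epoch bins.

## Measurement pipelines

Median RT per subject × epoch bin × category uses correct responses with
RT > 0 only; `random_combined` pools random-high and random-low *trials*
before the median (not a median of medians). Accuracy is % correct with
misses as errors, no RT filter. Epoch bins are consecutive five-block
groups for 30 blocks; other block counts must divide evenly into the bin
count and are rejected up front otherwise.

ERP segments are cut per analyzable, correct, RT > 0 trial; baselines are
−200…0 ms (stimulus-locked) and 500…700 ms post-response (the last 200 ms
of the response-to-stimulus interval); segments with any sample strictly
exceeding ±100 μV at any electrode are rejected (a sample at exactly
100 μV survives); cell averages are taken over segments then over the CP
pool; window means use half-open [start, end) windows floored to sample
indices, so a boundary sample (e.g. 380 ms) belongs to the late window
only. Response-locked trials whose span exceeds the stored array (RT >
600 ms at the default grid) are dropped and counted; retained + rejected +
dropped equals the qualifying-trial count per cell. Cells with zero
segments propagate as missing, and subjects with a missing analysis cell
are excluded from the ANOVA with a logged reason; a configurable
`max_rejection_fraction` (default 0.35) mirrors the conventional
per-category rejection ceiling.

## Statistics

The fully within-subject ANOVA (1–3 factors) uses orthonormal Helmert
contrasts in the full cell space: for contrast matrix C and cell matrix Y
(subjects × cells), Z = YC′ gives SS_effect = n‖Z̄‖², SS_error =
Σ‖Z − Z̄‖², F = (SS_effect/df₁)/(SS_error/df₂) with df₂ = df₁(n−1), and
η²ₚ = SS_effect/(SS_effect + SS_error). Greenhouse–Geisser ε is the Box
estimator on C S C′ (S the sample covariance of cell scores), clipped to
[1/df₁, 1]; the corrected p uses (ε·df₁, ε·df₂) and is reported only when
df₁ > 1 and ε < 1, following the "when necessary" convention; original df
values are reported alongside corrected p. Since F < 1 can make the
corrected tail smaller than the uncorrected one, p_gg is floored at p so
the correction is never anti-conservative. LSD follow-ups are uncorrected
paired t tests per level pair (scores averaged within subject × level over
other factors). A constant sample equal to the null value yields t = 0,
p = 1; constant with a nonzero difference raises (undefined t). Missing
cells raise with the offending subject and cell named; incomplete designs
are never silently dropped.

## Problem sizes used in the test suite

Parameter-recovery runs keep the study conditions (32 subjects, 30 blocks,
100 replicate cohorts for RT ordering/magnitude and for power at the 10 ms
Type effect; one 32-subject EEG cohort for the 0.09 μV peak-difference
recovery). The type-I calibration uses 500 replicates of reduced null
cohorts (8 subjects, 6 blocks — one block per bin) since the null F
distribution does not depend on session length; frequency checks use a
2,000-block stream (~1.7 × 10⁵ trials). The RT-magnitude check compares the
pipeline against a direct Monte-Carlo oracle of the cell-median estimator,
because the sample median of skewed noise has a small-sample expectation
that depends on cell size (and its parity) and the random-high and
random-low categories have systematically different cell sizes.

## Known limitations

* Synthetic EEG is template-plus-white-noise; no spatial covariance,
  autocorrelated background, or realistic artifact morphology.
* Only balanced, complete within-subject designs; no between-subject
  factors or mixed models.
* The generator's effect sizes are group-structure calibrations, not fits
  to any dataset; real-data group statistics are not reproduced here
  because the underlying single-trial data are not public.
* Peak latency is not measured (amplitude windows only), and scalp
  topographies are out of scope.
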