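# asrt-lab

Simulation and analysis pipeline for the **alternating serial reaction time
(ASRT) task**, the four-choice RT paradigm used to study implicit statistical
learning of second-order nonadjacent transitional probabilities, together
with the EEG/ERP measurement chain (P3 peak and late P3) and the
within-subject factorial statistics that accompany it.

It is written for cognitive-neuroscience researchers who want a tested,
scriptable reference implementation of the ASRT probability structure and its
standard analysis — for planning studies, validating analysis code against
known ground truth, or running parameter-recovery and power simulations.

## The task and its probability structure

Stimuli follow an eight-element sequence in which predetermined **pattern**
(P) elements alternate with uniformly **random** (r) ones, e.g.
2–r–1–r–3–r–4–r (1 = left, 2 = up, 3 = down, 4 = right). Of the 24
permutations of the four directions only **6** are unique under cyclic
rotation. Each 85-trial block is 5 random warm-up trials plus 10 repetitions
of the cycle; a session is 30 blocks (2,550 trials).

Every trial is the last element of a moving-window **triplet**
(d₁, d₂, d₃). A triplet is *high-probability* iff d₃ is the sequence's
cyclic successor of d₁; of the 64 triplets, 16 are high-probability and each
occurs five times more often than a low-probability one. The second-order
transitional probability is

P(Xₜ₊₂ = d₃ | Xₜ = d₁) = ½·𝟙[d₃ = succ(d₁)] + ½·¼,

i.e. **62.5%** for the successor continuation and **12.5%** for each other
direction. Trials split into pattern (50%), random high-probability (12.5%)
and random low-probability (37.5%) categories; trills (d₁ = d₃) and
repetitions (d₁ = d₂ = d₃) are removed from RT/ERP analyses.

The analysis pipeline computes per-subject median RTs (correct responses,
RT > 0) and ERP mean amplitudes — the P3 peak (280–380 ms stimulus-locked /
−50–50 ms response-locked) and the late P3 (380–600 ms / 50–250 ms) over a
centroparietal pool (CP1, CPz, CP2, P1, Pz, P2), after ±100 μV artifact
rejection — per triplet type and epoch bin (five consecutive blocks), and
feeds them into fully within-subject ANOVAs (up to Locking × Type × Epoch)
with Greenhouse–Geisser correction, partial η², and LSD follow-ups. A
process-dissociation (inclusion/exclusion) generation task is scored as the
percentage of high-probability triplets produced (chance 25%).

Because no public single-trial data exist for this paradigm, the package
ships a seeded synthetic-subject generator (RTs, multichannel EEG segments
with a parameterised P3, key-press runs) whose defaults emulate the group
structure the pipelines are meant to recover.

## Worked example

```python
import asrtlab as al
from asrtlab.behavior import cohort_measure_table

seq = al.SequenceSpec((2, 1, 3, 4))
print([s.elements for s in al.enumerate_unique_sequences()])
print(al.transitional_probability(seq, 3, 4),
      al.transitional_probability(seq, 3, 1))

cohort = al.simulate_cohort(al.CohortParams(n_subjects=32), rng_seed=1)
rt = cohort_measure_table(cohort, "rt")
print(rt.groupby("category")["value"].mean().round(1))

types = ["pattern_high", "random_high", "random_low"]
print(al.rm_anova(rt[rt.category.isin(types)],
                  {"category": types, "epoch": [1, 2, 3, 4, 5, 6]}).round(4))
```

prints

```
[(1, 2, 3, 4), (1, 2, 4, 3), (1, 3, 2, 4), (1, 3, 4, 2), (1, 4, 2, 3), (1, 4, 3, 2)]
0.625 0.125
category
pattern_high       347.0
random_combined    352.1
random_high        344.7
random_low         355.6
          effect        F  df1  df2  epsilon      p   p_gg  eta_p2
        category 143.4159    2   62   1.0000 0.0000 0.0000  0.8223
           epoch  83.5999    5  155   0.8246 0.0000 0.0000  0.7295
category * epoch   0.6775   10  310   0.6388 0.7453 0.7453  0.0214
```

The six rotation-unique sequences and the 62.5%/12.5% transitional
probabilities are structural constants of the task. The cohort's median RTs
show the canonical ordering — fastest on random high-probability triplets,
slowest on random low-probability ones (the ~10 ms spread is the generator's
injected triplet-type effect) — and the Type × Epoch ANOVA detects the Type
main effect with a Greenhouse–Geisser-corrected Epoch effect (ε < 1)
reflecting the injected practice curve.

A command-line interface mirrors the library:

```bash
asrt-lab simulate stream --sequence-seed 7 --blocks 30 --out trials.csv
asrt-lab classify --in trials.csv --sequence "2,1,3,4" --out labeled.csv
asrt-lab simulate cohort --config cfg.json --out cohort/
asrt-lab analyze-behavior --in cohort/ --out tables/
asrt-lab analyze-erp --in cohort/ --out tables/
asrt-lab report --seed 1 --out report/
```

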