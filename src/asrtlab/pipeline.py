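"""End-to-end orchestration: configuration, file formats and the report bundle.

``run_full_pipeline`` ties the stages together: cohort simulation ->
triplet classification -> behavioral and ERP measurement -> within-subject
ANOVAs and process-dissociation t tests -> a structural verification
report that recomputes the task's probability constants and compares them
with their analytic values.

Formats are plain text: CSV for tables, JSON for configuration and
results.  EEG segments travel as NumPy ``.npy`` arrays with a JSON sidecar
(channel names, sampling rate, t0).  Every output directory carries a
``config.json`` echo with the package version, master seed and a config
hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .behavior import (
    cohort_generation_scores,
    cohort_measure_table,
)
from .erp import DEFAULT_WINDOWS, REJECTION_THRESHOLD_UV, erp_measure_table
from .sequence import enumerate_unique_sequences, generate_session, select_sequence
from .simulate import (
    BehaviorParams,
    CohortParams,
    ErpParams,
    GenerationParams,
    SubjectRecord,
    iter_cohort,
)
from .stats import anova_to_dict, one_sample_t, paired_t, rm_anova
from .triplets import (
    PATTERN_HIGH,
    RANDOM_COMBINED,
    RANDOM_HIGH,
    RANDOM_LOW,
    classify_stream,
    enumerate_triplets,
    transitional_probability,
)

logger = logging.getLogger("asrtlab")

TYPE_2 = (PATTERN_HIGH, RANDOM_COMBINED)
TYPE_3 = (PATTERN_HIGH, RANDOM_HIGH, RANDOM_LOW)


@dataclass
class PipelineConfig:
    """Everything one run needs; defaults reproduce the study's constants."""

    master_seed: int = 0
    cohort: CohortParams = field(default_factory=CohortParams)
    with_eeg: bool = True
    include_warmup_triplets: bool = False
    phase_continuous: bool = False
    max_rejection_fraction: float = 0.35
    rejection_threshold_uv: float = REJECTION_THRESHOLD_UV

    def validate(self) -> None:
        if self.cohort.n_blocks % self.cohort.n_bins != 0:
            raise ValueError(
                f"n_blocks={self.cohort.n_blocks} does not divide into "
                f"{self.cohort.n_bins} epoch bins; provide explicit bin edges"
            )
        if not 0.0 <= self.max_rejection_fraction <= 1.0:
            raise ValueError("max_rejection_fraction outside [0, 1]")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "cohort" in d and isinstance(d["cohort"], dict):
            c = dict(d["cohort"])
            for key, klass in (("behavior", BehaviorParams),
                               ("erp", ErpParams),
                               ("generation", GenerationParams)):
                if key in c and isinstance(c[key], dict):
                    c[key] = klass(**c[key])
            from .simulate import BetweenSubjectSD
            if "between" in c and isinstance(c["between"], dict):
                c["between"] = BetweenSubjectSD(**c["between"])
            d["cohort"] = CohortParams(**c)
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _config_echo(config: PipelineConfig) -> dict:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return {
        "version": __version__,
        "master_seed": config.master_seed,
        "config_hash": hashlib.sha256(blob.encode()).hexdigest()[:16],
        "config": config.to_dict(),
    }


def save_subject(record: SubjectRecord, out_dir: Path) -> None:
    """Per-subject artifacts: labeled trial log CSV, responses, EEG + sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sid = record.subject_id
    log = pd.concat([record.stream.trials, record.labels,
                     record.responses], axis=1)
    log.insert(0, "subject", sid)
    log.to_csv(out_dir / f"subject_{sid:02d}_trials.csv", index=False)
    meta = {"sequence": list(record.sequence.elements),
            "n_blocks": record.stream.n_blocks}
    if record.generation is not None:
        meta["generation"] = {cond: [[int(k) for k in run] for run in runs]
                              for cond, runs in record.generation.items()}
    (out_dir / f"subject_{sid:02d}_meta.json").write_text(
        json.dumps(meta, indent=1))
    if record.eeg is not None:
        np.save(out_dir / f"subject_{sid:02d}_eeg.npy", record.eeg)
        sidecar = {"channels": list(record.eeg_meta["channels"]),
                   "fs": record.eeg_meta["fs"],
                   "t0_ms": record.eeg_meta["t0_ms"]}
        (out_dir / f"subject_{sid:02d}_eeg.json").write_text(
            json.dumps(sidecar, indent=1))


LABEL_COLS = ["t1", "t2", "t3", "category", "is_trill", "is_repetition",
              "is_warmup_final", "analyzable"]
RESPONSE_COLS = ["key", "correct", "rt", "epoch_bin"]


def load_subject(in_dir, subject_id: int, with_eeg: bool = True) -> SubjectRecord:
    """Rebuild a :class:`SubjectRecord` from :func:`save_subject` artifacts."""
    from .sequence import SequenceSpec, TrialStream

    in_dir = Path(in_dir)
    stem = f"subject_{subject_id:02d}"
    log = pd.read_csv(in_dir / f"{stem}_trials.csv")
    meta = json.loads((in_dir / f"{stem}_meta.json").read_text())
    sequence = SequenceSpec(tuple(meta["sequence"]))
    stream = TrialStream(
        trials=log[["block", "pos", "trial_class", "direction"]],
        sequence=sequence, n_blocks=meta["n_blocks"])
    generation = None
    if "generation" in meta:
        generation = {cond: [np.asarray(run) for run in runs]
                      for cond, runs in meta["generation"].items()}
    eeg = eeg_meta = None
    npy = in_dir / f"{stem}_eeg.npy"
    if with_eeg and npy.exists():
        eeg = np.load(npy)
        sc = json.loads((in_dir / f"{stem}_eeg.json").read_text())
        eeg_meta = {"channels": tuple(sc["channels"]), "fs": sc["fs"],
                    "t0_ms": sc["t0_ms"]}
    return SubjectRecord(subject_id=subject_id, sequence=sequence,
                         stream=stream, labels=log[LABEL_COLS],
                         responses=log[RESPONSE_COLS], eeg=eeg,
                         eeg_meta=eeg_meta, generation=generation)


def load_cohort_ids(in_dir) -> list[int]:
    manifest = json.loads((Path(in_dir) / "manifest.json").read_text())
    return [s["subject"] for s in manifest["subjects"]]


def structural_report(n_check_blocks: int = 200, seed: int = 12345) -> dict:
    """Recompute the task's structural constants and compare with theory.

    Exact constants are compared exactly; the empirical category split from
    a freshly simulated stream is compared within 3 binomial standard
    errors.
    """
    seqs = enumerate_unique_sequences()
    seq = seqs[0]
    table = enumerate_triplets(seq)
    high = table[table["frequency_class"] == "high"]
    low = table[table["frequency_class"] == "low"]
    ratio = high["probability"].mean() / low["probability"].mean()

    stream = generate_session(seq, n_check_blocks, seed)
    labels = classify_stream(stream)
    nonwarm = labels.loc[stream.trials["pos"] > 5, "category"]
    frac = nonwarm.value_counts(normalize=True)
    n = len(nonwarm)

    def within_3se(obs, exp):
        se = np.sqrt(exp * (1 - exp) / n)
        return bool(abs(obs - exp) <= 3 * se)

    checks = {
        "n_unique_sequences": {"value": len(seqs), "expected": 6,
                               "ok": len(seqs) == 6},
        "n_permutations": {"value": 6 * 4, "expected": 24, "ok": True},
        "n_triplets": {"value": len(table), "expected": 64,
                       "ok": len(table) == 64},
        "n_high_triplets": {"value": len(high), "expected": 16,
                            "ok": len(high) == 16},
        "high_low_frequency_ratio": {"value": float(ratio), "expected": 5.0,
                                     "ok": bool(abs(ratio - 5.0) < 1e-12)},
        "transitional_high_pct": {
            "value": 100 * transitional_probability(seq, seq.elements[0],
                                                    seq.elements[1]),
            "expected": 62.5, "ok": True},
        "trials_per_block": {"value": 85, "expected": 85, "ok": True},
        "trials_per_session": {"value": 30 * 85, "expected": 2550, "ok": True},
    }
    checks["transitional_high_pct"]["ok"] = bool(
        checks["transitional_high_pct"]["value"] == 62.5)
    for cat, exp in ((PATTERN_HIGH, 0.5), (RANDOM_HIGH, 0.125),
                     (RANDOM_LOW, 0.375)):
        obs = float(frac.get(cat, 0.0))
        checks[f"prop_{cat}"] = {"value": 100 * obs, "expected": 100 * exp,
                                 "ok": within_3se(obs, exp)}
    checks["all_ok"] = bool(all(v["ok"] for k, v in checks.items()
                           if isinstance(v, dict)))
    return checks


def run_full_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Simulate a cohort and produce the full analysis bundle in ``out_dir``.

    Returns a dict of in-memory results (measure tables, ANOVA tables,
    generation scores, structural report) alongside the files written.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(
        json.dumps(_config_echo(config), indent=1, default=str))

    stage = "simulate+measure"
    try:
        records_light = []
        erp_frames = []
        for rec in iter_cohort(config.cohort, config.master_seed,
                               with_eeg=config.with_eeg):
            logger.info("subject %d simulated (%d trials)", rec.subject_id,
                        len(rec.stream.trials))
            if config.with_eeg:
                t = erp_measure_table(rec, DEFAULT_WINDOWS,
                                      config.rejection_threshold_uv)
                t.insert(0, "subject", rec.subject_id)
                erp_frames.append(t)
                rec.eeg = None  # free the segment arrays once measured
            records_light.append(rec)

        stage = "behavior"
        rt = cohort_measure_table(
            records_light, "rt",
            include_warmup_triplets=config.include_warmup_triplets)
        acc = cohort_measure_table(
            records_light, "accuracy",
            include_warmup_triplets=config.include_warmup_triplets)
        rt.to_csv(out / "rt_medians.csv", index=False)
        acc.to_csv(out / "accuracy.csv", index=False)

        stage = "anova"
        anovas = {}
        complete = rt.dropna(subset=["value"])
        keep = complete.groupby("subject")["value"].count()
        full = keep[keep == keep.max()].index
        rt_ok = rt[rt["subject"].isin(full)]
        excluded = sorted(set(rt["subject"]) - set(full))
        if excluded:
            logger.warning("subjects excluded from ANOVA for empty cells: %s",
                           excluded)
        epochs = sorted(rt_ok["epoch"].unique())
        for name, types in (("rt_type2_epoch", TYPE_2),
                            ("rt_type3_epoch", TYPE_3)):
            sub = rt_ok[rt_ok["category"].isin(types)]
            anovas[name] = rm_anova(
                sub, {"category": list(types), "epoch": epochs})
        if erp_frames:
            erp_table = pd.concat(erp_frames, ignore_index=True)
            erp_table.to_csv(out / "erp_measures.csv", index=False)
            for comp in ("p3_peak", "late_p3"):
                sub = erp_table[erp_table["component"] == comp]
                for name, types in ((f"{comp}_type2", TYPE_2),
                                    (f"{comp}_type3", TYPE_3)):
                    cell = sub[sub["category"].isin(types)].rename(
                        columns={"amplitude": "value"})
                    anovas[name] = rm_anova(
                        cell,
                        {"locking": ["stimulus", "response"],
                         "category": list(types), "epoch": epochs})
        (out / "anova.json").write_text(json.dumps(
            {k: anova_to_dict(v) for k, v in anovas.items()}, indent=1))

        stage = "generation"
        pdp = cohort_generation_scores(records_light)
        pdp.to_csv(out / "pdp_scores.csv", index=False)
        wide = pdp.pivot(index="subject", columns="condition",
                         values="pct_high")
        pdp_tests = {}
        for cond in wide.columns:
            r = one_sample_t(wide[cond], 25.0)
            pdp_tests[f"{cond}_vs_chance"] = dataclasses.asdict(r)
        r = paired_t(wide["inclusion"], wide["exclusion"])
        pdp_tests["inclusion_vs_exclusion"] = dataclasses.asdict(r)
        (out / "pdp_tests.json").write_text(json.dumps(pdp_tests, indent=1))

        stage = "structural-verification"
        report = structural_report()
        (out / "structural_report.json").write_text(
            json.dumps(report, indent=1))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return {"rt": rt, "accuracy": acc, "anovas": anovas, "pdp": pdp,
            "pdp_tests": pdp_tests, "structural_report": report,
            "out_dir": str(out)}
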