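"""Subject- and cohort-level orchestration of the two decoding arms.

One subject is decoded by running the CSP+LDA arm and the CNN arm on the
identical stratified 80/20 split, plus one extra CSP+LDA run on a separate
calibration split whose held-out accuracy stands in for the subject's
real-time ("online") BCI accuracy — the ranking variable of the low/high
performer median split.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Tuple

import pandas as pd

from . import evaluate
from .cspline import MLConfig, run_ml_pipeline
from .net import CNNSpec, DLConfig, TrainConfig, run_dl_pipeline
from .records import CohortComparison, SubjectRecord
from .simulate import EpochSet, SimConfig, simulate_cohort

#: Desk-scale acquisition used by the analysis drivers and acceptance runs:
#: the full montage and trial plan, but 64 S/s and 1.5 s epochs so the numpy
#: CNN trains in seconds per subject.  The 0.5-30 Hz band fits under the
#: 32 Hz Nyquist.
DESK_SCALE = SimConfig(fs=64.0, epoch_s=1.5)

#: Training length used at desk scale; full-batch Adam converges on the
#: synthetic task well before the 500-epoch study default.
DESK_TRAIN_EPOCHS = 60


def desk_dl_config(split_seed: int = 0, train_seed: int = 0,
                   max_epochs: int = DESK_TRAIN_EPOCHS) -> DLConfig:
    return DLConfig(
        spec=CNNSpec(),
        train=TrainConfig(max_epochs=max_epochs, seed=train_seed),
        split_seed=split_seed,
    )


@dataclass(frozen=True)
class SubjectRunConfig:
    ml: MLConfig = MLConfig()
    dl: DLConfig = DLConfig()
    calibration_seed_offset: int = 7919  # decorrelates the online-proxy split


def decode_subject(epochs: EpochSet, record: SubjectRecord,
                   config: SubjectRunConfig) -> SubjectRecord:
    """Run both arms on one subject's epochs and complete the record."""
    record.eval_ml = run_ml_pipeline(epochs, config.ml)
    record.eval_dl = run_dl_pipeline(epochs, config.dl)
    record.delta_accu = evaluate.delta_accuracy(record.eval_dl, record.eval_ml)
    calib = replace(config.ml,
                    split_seed=config.ml.split_seed + config.calibration_seed_offset)
    record.online_accuracy = run_ml_pipeline(epochs, calib).test_accuracy
    return record


def run_cohort(n_subjects: int = 20, fraction_inefficient: float = 0.5,
               sim_config: SimConfig = DESK_SCALE, seed: int = 0,
               max_epochs: int = DESK_TRAIN_EPOCHS,
               ) -> Tuple[List[SubjectRecord], CohortComparison]:
    """Simulate and decode a cohort, then run the group comparison.

    Per-subject split and training seeds derive deterministically from the
    cohort seed; within a subject, both arms share the split seed (identical
    train/test partition).
    """
    subjects = simulate_cohort(n_subjects, fraction_inefficient,
                               config=sim_config, seed=seed)
    records: List[SubjectRecord] = []
    for i, (epochs, record) in enumerate(subjects):
        split_seed = int((seed * 1_000_003 + i) % (2 ** 31))
        cfg = SubjectRunConfig(
            ml=MLConfig(split_seed=split_seed),
            dl=desk_dl_config(split_seed=split_seed, train_seed=split_seed,
                              max_epochs=max_epochs),
        )
        records.append(decode_subject(epochs, record, cfg))
    comparison = evaluate.compare_cohort(records)
    return records, comparison


def records_frame(records: List[SubjectRecord]) -> pd.DataFrame:
    """Flatten subject records into the per-subject results table."""
    rows = []
    for r in records:
        rows.append({
            "subject_id": r.subject_id,
            "archetype": r.archetype,
            "seed": r.seed,
            "erd_depth": r.erd_depth,
            "waveform_contrast": r.waveform_contrast,
            "snr": r.snr,
            "online_accuracy": r.online_accuracy,
            "group": r.group,
            "csp_lda_train_accuracy": r.eval_ml.train_accuracy if r.eval_ml else None,
            "csp_lda_test_accuracy": r.eval_ml.test_accuracy if r.eval_ml else None,
            "cnn_train_accuracy": r.eval_dl.train_accuracy if r.eval_dl else None,
            "cnn_test_accuracy": r.eval_dl.test_accuracy if r.eval_dl else None,
            "csp_lda_f_left": r.eval_ml.f_score_left if r.eval_ml else None,
            "csp_lda_f_right": r.eval_ml.f_score_right if r.eval_ml else None,
            "cnn_f_left": r.eval_dl.f_score_left if r.eval_dl else None,
            "cnn_f_right": r.eval_dl.f_score_right if r.eval_dl else None,
            "delta_accu": r.delta_accu,
        })
    return pd.DataFrame(rows)


def model_summary_frames(records: List[SubjectRecord]
                         ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Cohort mean/SD tables: train/test accuracy and per-class F-score,
    one row per decoder."""
    frame = records_frame(records)
    acc_rows, f_rows = [], []
    for tag, prefix in (("CNN", "cnn"), ("CSP+LDA", "csp_lda")):
        acc_rows.append({
            "model": tag,
            "train_accuracy_mean": frame[f"{prefix}_train_accuracy"].mean(),
            "train_accuracy_sd": frame[f"{prefix}_train_accuracy"].std(ddof=1),
            "test_accuracy_mean": frame[f"{prefix}_test_accuracy"].mean(),
            "test_accuracy_sd": frame[f"{prefix}_test_accuracy"].std(ddof=1),
            "n": len(frame),
        })
        for cls in ("left", "right"):
            f_rows.append({
                "model": tag, "class": cls,
                "f_score_mean": frame[f"{prefix}_f_{cls}"].mean(),
                "f_score_sd": frame[f"{prefix}_f_{cls}"].std(ddof=1),
                "n": len(frame),
            })
    return pd.DataFrame(acc_rows), pd.DataFrame(f_rows)


def comparison_frames(comparison: CohortComparison
                      ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Group-contrast and histogram tables of a cohort comparison."""
    groups = pd.DataFrame([
        {"group": "low", "n": comparison.n_low,
         "mean_delta_accu": comparison.mean_delta_low,
         "sd_delta_accu": comparison.sd_delta_low,
         "shapiro_W": comparison.shapiro_low[0],
         "shapiro_p": comparison.shapiro_low[1]},
        {"group": "high", "n": comparison.n_high,
         "mean_delta_accu": comparison.mean_delta_high,
         "sd_delta_accu": comparison.sd_delta_high,
         "shapiro_W": comparison.shapiro_high[0],
         "shapiro_p": comparison.shapiro_high[1]},
    ])
    hist = pd.DataFrame(
        [{"bin": k, "count": v} for k, v in comparison.histogram.items()])
    return groups, hist
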