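"""Per-subject and cohort-level result records shared across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional


@dataclass
class EvalResult:
    """Outcome of one decoder on one subject's 80/20 split.

    All quantities are percentages in [0, 100], matching the reporting
    convention of BCI studies.
    """

    model_tag: str  # "CNN" or "CSP+LDA"
    train_accuracy: float
    test_accuracy: float
    f_score_left: float
    f_score_right: float
    split_seed: int

    def __post_init__(self) -> None:
        for name in ("train_accuracy", "test_accuracy", "f_score_left", "f_score_right"):
            v = getattr(self, name)
            if not (0.0 <= v <= 100.0):
                raise ValueError(f"{name}={v} outside [0, 100]")


@dataclass
class SubjectRecord:
    """One simulated subject: generative provenance plus decoding outcomes.

    ``online_accuracy`` is the stand-in for a real-time BCI accuracy: the
    CSP+LDA accuracy on a held-out calibration split, used only to rank
    subjects for the low/high performer median split.  ``delta_accu`` is the
    CNN-minus-CSP+LDA test-accuracy difference in percentage points.
    """

    subject_id: str
    archetype: Optional[str] = None  # "efficient" | "inefficient" | None
    seed: Optional[int] = None
    erd_depth: Optional[float] = None
    waveform_contrast: Optional[float] = None
    snr: Optional[float] = None
    online_accuracy: Optional[float] = None
    group: Optional[str] = None  # "low" | "high", assigned by median_split
    eval_ml: Optional[EvalResult] = None
    eval_dl: Optional[EvalResult] = None
    delta_accu: Optional[float] = None


@dataclass
class CohortComparison:
    """Cohort-level summary: the group contrast of per-subject improvements.

    Holds per-group ΔAccu moments, Shapiro–Wilk normality checks, the
    independent t-test between groups, the pooled paired t-test of CNN vs
    CSP+LDA test accuracies, and the improvement histogram.
    """

    n_low: int
    n_high: int
    mean_delta_low: float
    sd_delta_low: float
    mean_delta_high: float
    sd_delta_high: float
    shapiro_low: tuple  # (W, p)
    shapiro_high: tuple
    independent_t: tuple  # (t, df, p)
    independent_ci95: tuple  # CI of mean difference (low - high)
    paired_t: tuple  # (t, df, p) CNN vs CSP+LDA test accuracy, all subjects
    paired_ci95: tuple
    histogram: dict = field(default_factory=dict)  # bin label -> count

    @property
    def n_total(self) -> int:
        return self.n_low + self.n_high
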