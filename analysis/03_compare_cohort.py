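"""The cohort comparison: low vs high performers.

Reads results/subjects.csv, median-splits subjects on their online-proxy
accuracy, and contrasts the per-subject CNN-minus-CSP+LDA improvement
(dAccu) between groups: Shapiro-Wilk normality per group, an independent
t-test between groups, a paired t-test of the two decoders over the pooled
cohort, and the improvement histogram.  Writes results/groups.csv,
results/statistics.csv and results/improvement_bins.csv.

Run:  python analysis/03_compare_cohort.py
"""

from pathlib import Path

import pandas as pd

from mibci import evaluate, pipeline
from mibci.records import EvalResult, SubjectRecord

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    df = pd.read_csv(ROOT / "results" / "subjects.csv")
    records = []
    for _, row in df.iterrows():
        records.append(SubjectRecord(
            subject_id=row["subject_id"], archetype=row["archetype"],
            online_accuracy=row["online_accuracy"],
            eval_ml=EvalResult("CSP+LDA", row["csp_lda_train_accuracy"],
                               row["csp_lda_test_accuracy"],
                               row["csp_lda_f_left"], row["csp_lda_f_right"], 0),
            eval_dl=EvalResult("CNN", row["cnn_train_accuracy"],
                               row["cnn_test_accuracy"],
                               row["cnn_f_left"], row["cnn_f_right"], 0)))
    comp = evaluate.compare_cohort(records)

    acc_table, f_table = pipeline.model_summary_frames(records)
    acc_table.to_csv(ROOT / "results" / "model_accuracies.csv", index=False)
    f_table.to_csv(ROOT / "results" / "model_f_scores.csv", index=False)

    groups, hist = pipeline.comparison_frames(comp)
    groups.to_csv(ROOT / "results" / "groups.csv", index=False)
    hist.to_csv(ROOT / "results" / "improvement_bins.csv", index=False)
    t_i, df_i, p_i = comp.independent_t
    t_p, df_p, p_p = comp.paired_t
    stats = pd.DataFrame([
        {"test": "paired_cnn_vs_csplda", "t": t_p, "df": df_p, "p": p_p,
         "ci_low": comp.paired_ci95[0], "ci_high": comp.paired_ci95[1]},
        {"test": "independent_low_vs_high", "t": t_i, "df": df_i, "p": p_i,
         "ci_low": comp.independent_ci95[0], "ci_high": comp.independent_ci95[1]},
    ])
    stats.to_csv(ROOT / "results" / "statistics.csv", index=False)

    print(f"low performers  (n={comp.n_low}):  mean dAccu "
          f"{comp.mean_delta_low:6.2f}pp (SD {comp.sd_delta_low:.2f})")
    print(f"high performers (n={comp.n_high}): mean dAccu "
          f"{comp.mean_delta_high:6.2f}pp (SD {comp.sd_delta_high:.2f})")
    print(f"independent t-test (low vs high): t({df_i}) = {t_i:.2f}, p = {p_i:.4g}")
    print(f"paired t-test (CNN vs CSP+LDA, all subjects): "
          f"t({df_p}) = {t_p:.2f}, p = {p_p:.4g}")
    print(f"improvement histogram: "
          + ", ".join(f"{k}: {v}" for k, v in comp.histogram.items() if v))
    better = comp.mean_delta_low > comp.mean_delta_high
    print("\nThe accuracy gain from the CNN is larger for low performers"
          if better else "\nNo larger gain for low performers in this cohort")


if __name__ == "__main__":
    main()
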