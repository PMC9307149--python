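"""Decode every simulated subject with both arms.

For each container from 01_simulate_cohort.py, runs the CSP+LDA arm and
the CNN arm on a shared stratified 80/20 split, plus a separate CSP+LDA
calibration split whose held-out accuracy serves as the online-accuracy
proxy.  Writes the per-subject table to results/subjects.csv.

Run:  python analysis/02_decode_subjects.py [--seed 0]
"""

import argparse
import time
from pathlib import Path

import pandas as pd

from mibci import interface, pipeline
from mibci.cspline import MLConfig
from mibci.records import SubjectRecord

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0,
                    help="base seed for splits and CNN training")
    args = ap.parse_args()

    manifest = pd.read_csv(ROOT / "results" / "manifest.csv")
    records = []
    for i, row in manifest.iterrows():
        epochs, _ = interface.read_epochs(ROOT / row["path"])
        record = SubjectRecord(subject_id=row["subject_id"],
                               archetype=row["archetype"],
                               seed=int(row["seed"]),
                               erd_depth=row["erd_depth"],
                               waveform_contrast=row["waveform_contrast"],
                               snr=row["snr"])
        split_seed = int((args.seed * 1_000_003 + i) % (2 ** 31))
        cfg = pipeline.SubjectRunConfig(
            ml=MLConfig(split_seed=split_seed),
            dl=pipeline.desk_dl_config(split_seed=split_seed,
                                       train_seed=split_seed))
        t0 = time.time()
        records.append(pipeline.decode_subject(epochs, record, cfg))
        r = records[-1]
        print(f"{r.subject_id} ({r.archetype:11s}): CSP+LDA "
              f"{r.eval_ml.test_accuracy:5.1f}%  CNN {r.eval_dl.test_accuracy:5.1f}%  "
              f"dAccu {r.delta_accu:+6.2f}pp  ({time.time() - t0:.0f}s)")

    frame = pipeline.records_frame(records)
    out = ROOT / "results" / "subjects.csv"
    frame.to_csv(out, index=False)
    improved = (frame.delta_accu > 0).mean() * 100
    print(f"\nCNN improved on CSP+LDA for {improved:.0f}% of subjects; "
          f"mean dAccu {frame.delta_accu.mean():+.2f}pp")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
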