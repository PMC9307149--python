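"""Simulate the synthetic study cohort.

Generates 20 subjects (10 efficient, 10 inefficient) at desk scale
(16 channels, 120 trials, 1.5 s epochs at 64 S/s), writes one HDF5 epoch
container per subject under scratch/cohort/ and the cohort manifest to
results/manifest.csv.

Run:  python analysis/01_simulate_cohort.py [--seed 0]
"""

import argparse
from pathlib import Path

import pandas as pd

from mibci import interface, pipeline
from mibci.simulate import simulate_cohort

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n-subjects", type=int, default=20)
    args = ap.parse_args()

    outdir = ROOT / "scratch" / "cohort"
    outdir.mkdir(parents=True, exist_ok=True)
    resdir = ROOT / "results"
    resdir.mkdir(exist_ok=True)

    rows = []
    for epochs, record in simulate_cohort(args.n_subjects, 0.5,
                                          config=pipeline.DESK_SCALE,
                                          seed=args.seed):
        path = outdir / f"{record.subject_id}.h5"
        interface.write_epochs(epochs, path, subject_id=record.subject_id)
        rows.append({"subject_id": record.subject_id,
                     "archetype": record.archetype,
                     "seed": record.seed,
                     "erd_depth": record.erd_depth,
                     "waveform_contrast": record.waveform_contrast,
                     "snr": record.snr,
                     "path": str(path.relative_to(ROOT))})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(resdir / "manifest.csv", index=False)
    n_eff = (manifest.archetype == "efficient").sum()
    print(f"simulated {len(manifest)} subjects ({n_eff} efficient, "
          f"{len(manifest) - n_eff} inefficient) at "
          f"{pipeline.DESK_SCALE.fs:g} S/s x {pipeline.DESK_SCALE.epoch_s:g} s")
    print(f"containers under {outdir}, manifest at {resdir / 'manifest.csv'}")


if __name__ == "__main__":
    main()
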