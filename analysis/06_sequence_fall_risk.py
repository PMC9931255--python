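"""Stride-sequence (LSTM) fall-risk classification with median aggregation.

Rebuilds walking bouts from the detected bout table, cuts them into
k-stride 6-channel inputs, and evaluates a recurrent classifier under the
modified LOSO scheme (one test subject, one cyclically rotated validation
subject).  By default a reduced single-layer LSTM runs a small k grid; pass
--arch LSTM2/LSTM3 (and larger --epochs) for the reference architectures.
Writes results/pipeline/sequence_report.csv.
"""

import argparse
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from msgait import activity, io, sequence, strides
from msgait.config import PipelineConfig
from msgait.types import WalkingBout

ap = argparse.ArgumentParser(description=__doc__)
ap.add_argument("--seed", type=int, default=1)
ap.add_argument("--data", type=Path, default=Path("results/dataset"))
ap.add_argument("--out", type=Path, default=Path("results/pipeline"))
ap.add_argument("--ks", type=int, nargs="+", default=[1, 4])
ap.add_argument("--arch", default="reduced", choices=["reduced", "LSTM2", "LSTM3"])
ap.add_argument("--epochs", type=int, default=None)
ap.add_argument("--max-subjects", type=int, default=12)
args = ap.parse_args()

cfg = PipelineConfig(seed=args.seed)
bout_table = pd.read_csv(args.out / "bouts.csv")
cohort = io.read_cohort_table(args.data)

bouts = []
for sid, grp in bout_table.groupby("subject_id"):
    if bout_table["subject_id"].unique().tolist().index(sid) >= args.max_subjects:
        continue
    chest, thigh, _ = io.load_subject(args.data, sid)
    subj_bouts = [WalkingBout(bout_id=int(r.bout_id), subject_id=sid, start_s=r.start_s,
                              end_s=r.end_s, fs=chest.fs) for r in grp.itertuples()]
    activity.attach_views(subj_bouts, chest, thigh)
    for b in subj_bouts:
        strides.detect_bout_events(b)
    bouts.extend(b for b in subj_bouts if len(b.strides) >= 2)

if args.arch == "reduced":
    archs = [sequence.reduced_architecture(hidden=16, epochs=args.epochs or 5)]
else:
    archs = [sequence.ARCHITECTURES[args.arch]]

grid = sequence.run_sequence_grid(bouts, cohort, ks=args.ks, archs=archs,
                                  seed=args.seed, epochs=args.epochs)
grid.to_csv(args.out / "sequence_report.csv", index=False)
print(grid.to_string(index=False))
best = grid.loc[grid["auc_subject_median"].idxmax()]
print(f"\nbest subject-median AUC {best['auc_subject_median']:.3f} "
      f"at k={int(best['k_strides'])}, abc={best['abc']}")
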