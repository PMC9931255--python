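"""Feature-based fall-risk classification under leave-one-subject-out CV.

For each feature set (short / medium / long / all-home / lab) and each
classifier family, every fold z-scores and PCA-reduces (95% variance) the
training rows, fits the model, and scores the held-out subject's bouts.
Writes results/pipeline/classifier_report.json and prints the AUC grid.
"""

import argparse
import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from msgait import pipeline
from msgait.config import PipelineConfig

ap = argparse.ArgumentParser(description=__doc__)
ap.add_argument("--seed", type=int, default=1)
ap.add_argument("--data", type=Path, default=Path("results/dataset"))
ap.add_argument("--out", type=Path, default=Path("results/pipeline"))
ap.add_argument("--families", nargs="+", default=["LR", "SVM", "tree", "KNN", "ensemble"])
ap.add_argument("--n-search", type=int, default=0,
                help="random hyperparameter draws per fold (0 = library defaults)")
args = ap.parse_args()

cfg = PipelineConfig(seed=args.seed)
report = pipeline._classify(cfg, args.data, args.out, families=tuple(args.families),
                            n_search=args.n_search)
print(f"{'feature set':10s} {'model':9s} {'AUC(bout)':>9s} {'AUC(subj)':>9s}")
for row in report:
    print(f"{row['feature_set']:10s} {row['model']:9s} "
          f"{row['auc_per_input']:9.3f} {row['auc_subject_median']:9.3f}")
best = max(report, key=lambda r: r["auc_per_input"])
print(f"\nbest per-bout: {best['model']} on {best['feature_set']} "
      f"(AUC {best['auc_per_input']:.3f})")
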