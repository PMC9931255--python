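"""Bout-duration and fall-group comparisons (the study's Tables 3-5 layout).

Imputes missing survey entries (k-NN, k=3), then runs three Wilcoxon
rank-sum suites at alpha = 0.05 with no multiplicity correction:
duration vs duration on pooled bout-level parameters, lab vs home, and
faller vs non-faller on per-subject summary statistics.  Writes the three
comparison CSVs under results/pipeline/ and prints the significant
faller/non-faller contrasts.
"""

import argparse
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from msgait import pipeline
from msgait.config import PipelineConfig

ap = argparse.ArgumentParser(description=__doc__)
ap.add_argument("--seed", type=int, default=1)
ap.add_argument("--data", type=Path, default=Path("results/dataset"))
ap.add_argument("--out", type=Path, default=Path("results/pipeline"))
args = ap.parse_args()

cfg = PipelineConfig(seed=args.seed)
pipeline.run_pipeline(cfg, args.data, args.out, stages=("analyze",))

for name in ("duration", "context", "fall_groups"):
    df = pd.read_csv(args.out / f"comparisons_{name}.csv")
    print(f"{name}: {len(df)} comparisons, {int(df['significant'].sum())} significant")

fg = pd.read_csv(args.out / "comparisons_fall_groups.csv")
sig = fg[fg["significant"]]
if sig.empty:
    print("no significant faller vs non-faller summaries at this scale")
else:
    print("\nsignificant faller vs non-faller summaries (median_1 = fallers):")
    print(sig[["comparison", "feature", "median_1", "median_2", "p_value"]]
          .to_string(index=False))
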