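"""Simulate the study cohort: 38 subjects (21 fallers, 17 non-fallers), each
with a free-living dual-sensor recording and a one-minute lab hallway walk.

The wear time per subject is scaled down from the 48-hour protocol (default
15 minutes) — the bout-length mixture, not the total hours, drives every
downstream analysis.  Writes the dataset (sensor CSVs, annotation JSONs,
cohort table, manifest) under results/dataset/.
"""

import argparse
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from msgait import pipeline
from msgait.config import PipelineConfig

ap = argparse.ArgumentParser(description=__doc__)
ap.add_argument("--seed", type=int, default=1)
ap.add_argument("--n-subjects", type=int, default=38)
ap.add_argument("--duration-min", type=float, default=15.0)
ap.add_argument("--out", type=Path, default=Path("results/dataset"))
args = ap.parse_args()

cfg = PipelineConfig(seed=args.seed)
manifest = pipeline.simulate(cfg, args.out, n_subjects=args.n_subjects,
                             faller_fraction=21 / 38,
                             duration_min=args.duration_min, seed=args.seed)
n = len(manifest["subjects"])
print(f"wrote {n} subjects ({round(args.n_subjects * 21 / 38)} fallers) to {args.out}")
print("each subject: chest + thigh free-living CSV, lab walk CSVs, annotations JSON")
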