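"""PLS association of dynamic features with cognition and pathology.

One PLS1 model per response (MMSE, ADAS Q4, tau SUVR, amyloid SUVR) over
the amyloid-positive subjects, with log + z preprocessing, cross-validated
latent-variable selection, and VIP > 1 predictor significance.  Writes
pls_vip.csv under results/.
"""

import argparse
from pathlib import Path

import pandas as pd

from tmfc.measures import MEASURES
from tmfc.pls import run_pls_suite
from tmfc.stats import screen_outliers

parser = argparse.ArgumentParser()
parser.add_argument("--features", type=Path,
                    default=Path("results/features_wide.csv"))
parser.add_argument("--out", type=Path, default=Path("results"))
parser.add_argument("--seed", type=int, default=1)
args = parser.parse_args()

table = pd.read_csv(args.features)
feature_cols = [c for c in table.columns if c.split("_")[0] in MEASURES]
clean = screen_outliers(table, feature_cols)
reports = run_pls_suite(clean, feature_cols, seed=args.seed)

frames = []
for response, report in reports.items():
    frame = report.to_frame().reset_index(names="predictor")
    frame.insert(0, "response", response)
    frames.append(frame)
    flagged = report.significant[report.significant].index.tolist()
    print(f"{response}: R^2 = {report.r_squared:.2f}; "
          f"VIP > 1: {', '.join(flagged) if flagged else 'none'}")
pd.concat(frames).to_csv(args.out / "pls_vip.csv", index=False)
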