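"""Disease-stage classification from dynamic features vs risk factors.

For each amyloid-positive group against the amyloid-negative controls,
fits three stepwise-AIC logistic models — F (21 dynamic features),
R (age, sex, APOE e4), F+R (union) — and evaluates each with the
Mann–Whitney AUC, a 1000-replicate stratified bootstrap, and the
sensitivity+specificity-maximizing cutpoint; model AUC distributions are
compared with Kruskal–Wallis tests.  Writes classification.csv under
results/.
"""

import argparse
from pathlib import Path

import pandas as pd

from tmfc.classify import run_classification_suite
from tmfc.measures import MEASURES
from tmfc.stats import screen_outliers

parser = argparse.ArgumentParser()
parser.add_argument("--features", type=Path,
                    default=Path("results/features_wide.csv"))
parser.add_argument("--out", type=Path, default=Path("results"))
parser.add_argument("--n-boot", type=int, default=1000)
parser.add_argument("--seed", type=int, default=1)
args = parser.parse_args()

table = pd.read_csv(args.features)
feature_cols = [c for c in table.columns if c.split("_")[0] in MEASURES]
clean = screen_outliers(table, feature_cols)
suite = run_classification_suite(clean, feature_cols, n_boot=args.n_boot,
                                 seed=args.seed)

rows = []
for comparison, models in suite.items():
    for name in ("F", "R", "F+R"):
        auc = models[name]["auc"]
        rows.append({"comparison": comparison, "model": name,
                     "auc": round(auc.auc, 3),
                     "sensitivity": round(auc.sensitivity, 3),
                     "specificity": round(auc.specificity, 3),
                     "selected": ";".join(models[name]["model"].selected),
                     "kruskal_p": models["kruskal"]["p"]})
summary = pd.DataFrame(rows)
summary.to_csv(args.out / "classification.csv", index=False)
print(summary[["comparison", "model", "auc", "sensitivity", "specificity"]]
      .to_string(index=False))
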