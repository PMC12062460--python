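"""Fit the normative models on the healthy training sample.

Splits the healthy controls 80/20 (stratified by site and sex), then fits
one distributional regression per location x band on the training ids:
fractional-polynomial age powers chosen by BIC, family chosen by BIC among
NO/BCCG/BCT/BCPE/JSU, sex and site indicators kept only when they lower
BIC. Writes fits.csv, diagnostics.csv, centiles.csv and the split ids.
"""

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from eegnorm.gamlss import centile_curves
from eegnorm.pipeline import PipelineConfig, fit_normative_models, \
    split_train_test

logging.basicConfig(level=logging.INFO)
OUT = Path(__file__).resolve().parents[1] / "results" / "run"
cfg = PipelineConfig(seed=1)

cohort = pd.read_csv(OUT / "cohort.csv")
features = pd.read_csv(OUT / "features.csv")
train_ids, test_ids = split_train_test(cohort, cfg.train_fraction,
                                       seed=cfg.seed + 4)
hc = cohort["group"].str.startswith("HC")
cohort.loc[hc & cohort["subject_id"].isin(set(train_ids)), "group"] = "HC_train"
cohort.loc[hc & cohort["subject_id"].isin(set(test_ids)), "group"] = "HC_test"
cohort.to_csv(OUT / "cohort.csv", index=False)
pd.DataFrame({"subject_id": train_ids}).to_csv(OUT / "train_ids.csv", index=False)
pd.DataFrame({"subject_id": test_ids}).to_csv(OUT / "test_ids.csv", index=False)
print(f"split: {len(train_ids)} HC train / {len(test_ids)} HC test")

fits, diagnostics = fit_normative_models(features, cohort, train_ids, cfg)
rows = []
for (loc, band), f in fits.items():
    rec = f.to_record()
    rec.update({"location_id": loc, "band": band})
    rows.append(rec)
pd.DataFrame(rows).to_csv(OUT / "fits.csv", index=False)
diagnostics.to_csv(OUT / "diagnostics.csv", index=False)

grid = np.linspace(40, 92, 27)
cent = []
for (loc, band), f in fits.items():
    if f.converged:
        c = centile_curves(f, grid, age_range=(40, 92))
        for i, age in enumerate(grid):
            cent.append({"location_id": loc, "band": band, "age": age,
                         "p5": c["p5"][i], "p50": c["p50"][i],
                         "p95": c["p95"][i]})
pd.DataFrame(cent).to_csv(OUT / "centiles.csv", index=False)

conv = diagnostics["converged"].mean()
fam_counts = pd.Series([f.family for f in fits.values()]).value_counts()
print(f"fitted {len(fits)} models, {100 * conv:.0f}% converged")
print("selected families:", dict(fam_counts))
if "filliben" in diagnostics:
    print(f"median Filliben Q-Q correlation: "
          f"{diagnostics['filliben'].median():.4f} "
          f"(values near 1 mean well-calibrated residuals)")
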