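"""Score held-out and patient subjects against the normative models.

Every subject outside the training sample gets a z-score per location and
band (quantile residual under the fitted distribution); |z| > 2 defines an
extreme deviation, tracked separately for the positive and negative tails.
Writes the deviation tensor, per-subject counts, the percentage of each
group with at least one extreme deviation, and the group overlap maps.
"""

import logging
from pathlib import Path

import pandas as pd

from eegnorm.deviations import deviation_summary, overlap_map
from eegnorm.pipeline import PipelineConfig, fits_from_records, \
    score_deviations

logging.basicConfig(level=logging.INFO)
OUT = Path(__file__).resolve().parents[1] / "results" / "run"
cfg = PipelineConfig(seed=1)

cohort = pd.read_csv(OUT / "cohort.csv")
features = pd.read_csv(OUT / "features.csv")
train_ids = pd.read_csv(OUT / "train_ids.csv")["subject_id"].tolist()

fits = fits_from_records(pd.read_csv(OUT / "fits.csv"))
score_ids = [s for s in cohort["subject_id"] if s not in set(train_ids)]
tensor = score_deviations(features, cohort, fits, score_ids, cfg)
tensor.table.to_csv(OUT / "deviations.csv", index=False)

counts, group_pct = deviation_summary(tensor, cohort)
counts.to_csv(OUT / "summary_counts.csv", index=False)
group_pct.to_csv(OUT / "group_pct.csv", index=False)

rows = []
for band in cfg.bands:
    for sign in ("positive", "negative"):
        for grp in ("HC_test", "PD", "AD"):
            om = overlap_map(tensor, cohort, grp, sign, band)
            for loc, pct in zip(om.locations, om.percentage):
                rows.append({"group": grp, "band": band, "sign": sign,
                             "location_id": loc, "overlap_pct": pct,
                             "denominator": om.denominator,
                             "defined": om.defined})
overlaps = pd.DataFrame(rows)
overlaps.to_csv(OUT / "overlap_maps.csv", index=False)

print("subjects with >=1 extreme deviation (%):")
print(group_pct.round(1).to_string(index=False))
mx = (overlaps[overlaps["defined"]]
      .groupby(["group", "sign"])["overlap_pct"].max())
print("\nmaximum overlap-map value per group (heterogeneity readout; "
      "low = deviations rarely shared):")
print(mx.round(1).to_string())
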