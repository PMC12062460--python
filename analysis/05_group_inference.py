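"""Group-based permutation inference on the overlap maps.

For each patient group, band and deviation sign, case/control labels are
shuffled over the subject-level extreme-deviation masks; each iteration
recomputes both overlap maps and their difference, giving per-location
two-sided p-values (add-one convention) with BH-FDR control. Deviation
counts are also compared between each patient group and the held-out
controls (Mann-Whitney), and significant connection-style locations can be
attributed to resting-state networks via a region->network lookup.
"""

import logging
from pathlib import Path

import pandas as pd

from eegnorm.deviations import DeviationTensor
from eegnorm.inference import compare_counts, permutation_overlap_test
from eegnorm.pipeline import PipelineConfig

logging.basicConfig(level=logging.INFO)
OUT = Path(__file__).resolve().parents[1] / "results" / "run"
cfg = PipelineConfig(seed=1)

cohort = pd.read_csv(OUT / "cohort.csv")
table = pd.read_csv(OUT / "deviations.csv")
tensor = DeviationTensor(table[["subject_id", "location_id", "band", "z"]],
                         threshold=cfg.extreme_threshold)
counts = pd.read_csv(OUT / "summary_counts.csv")
hc_ids = cohort.loc[cohort["group"] == "HC_test", "subject_id"].tolist()

perm_rows, mw_rows = [], []
for band in cfg.bands:
    for sign in ("positive", "negative"):
        for grp in ("PD", "AD"):
            gids = cohort.loc[cohort["group"] == grp, "subject_id"].tolist()
            Mg, locs = tensor.mask_matrix(gids, sign, band)
            Mh, _ = tensor.mask_matrix(hc_ids, sign, band, locations=locs)
            res = permutation_overlap_test(Mg, Mh, locs,
                                           n_perm=cfg.n_perm,
                                           seed=cfg.seed + 5,
                                           alpha=cfg.alpha)
            df = res.to_frame()
            df.insert(0, "sign", sign)
            df.insert(0, "band", band)
            df.insert(0, "group", grp)
            perm_rows.append(df)
            col = "n_pos" if sign == "positive" else "n_neg"
            cg = counts[(counts["group"] == grp) & (counts["band"] == band)]
            ch = counts[(counts["group"] == "HC_test")
                        & (counts["band"] == band)]
            U, p = compare_counts(cg[col].to_numpy(), ch[col].to_numpy())
            mw_rows.append({"group": grp, "band": band, "sign": sign,
                            "U": U, "p": p})

perm = pd.concat(perm_rows, ignore_index=True)
perm.to_csv(OUT / "permutation.csv", index=False)
mw = pd.DataFrame(mw_rows)
mw.to_csv(OUT / "mannwhitney_counts.csv", index=False)

print(f"permutation test ({cfg.n_perm} iterations, alpha={cfg.alpha}):")
print(perm.groupby(["group", "band", "sign"])["significant"].sum()
      .rename("n_significant_locations").to_string())
print("\npatients vs held-out HC, extreme-deviation counts (Mann-Whitney):")
print(mw.round(4).to_string(index=False))
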