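"""Per-subject deviation (z) scores against trained normative models,
extreme-deviation masks, counts, and group overlap maps.

A subject's z-score at one location/band is the normalized quantile
residual z = Phi^-1(F(y; mu_hat, sigma_hat, ...)) under the model fitted on
the healthy training sample; for a continuous response no randomization is
involved. An extreme deviation is |z| > 2, tracked separately for positive
(z > 2) and negative (z < -2) tails. The overlap map of a group reports,
per location, the percentage of subjects carrying an extreme deviation
there among the group's subjects with at least one such deviation anywhere
(a full-group denominator is available as an option).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gamlss import NormativeModelFit, quantile_residuals

__all__ = ["zscore", "true_zscores", "DeviationTensor", "deviation_summary",
           "overlap_map", "OverlapMap", "EXTREME_THRESHOLD"]

EXTREME_THRESHOLD = 2.0
Z_CLIP = 8.0


def zscore(y, fit: NormativeModelFit, designs) -> np.ndarray:
    """Deviation score(s) for feature values under a fitted model.

    ``designs`` maps parameter name -> design row(s) built at the subject's
    covariates. Scores are clipped to ±8, where double-precision CDFs
    saturate anyway.
    """
    if not fit.converged:
        raise ValueError("z-scores require a converged normative model")
    return quantile_residuals(fit, y, designs, clip=Z_CLIP)


def true_zscores(features: pd.DataFrame, cohort: pd.DataFrame,
                 truth) -> pd.DataFrame:
    """z-scores under the *generating* model (oracle, no fitting).

    z = Phi^-1(F_truth(y)) at each subject's covariates — the scores a
    perfectly estimated normative model would produce. Used for
    calibration studies and null simulations.
    """
    from scipy import stats as _st
    from .families import get_family
    fam = get_family(truth.family)
    cov = cohort.set_index("subject_id")
    frames = []
    for sid, g in features.groupby("subject_id", sort=True):
        row = cov.loc[sid]
        params = truth.params_at(row["age"], row["sex"], row["site"])
        u = np.clip(fam.cdf(g["value"].to_numpy(float),
                            [np.asarray(p, float) for p in params]),
                    _st.norm.cdf(-Z_CLIP), _st.norm.cdf(Z_CLIP))
        frames.append(pd.DataFrame({
            "subject_id": sid, "location_id": g["location_id"].to_numpy(),
            "band": g["band"].to_numpy(),
            "z": np.clip(_st.norm.ppf(u), -Z_CLIP, Z_CLIP)}))
    return pd.concat(frames, ignore_index=True)


@dataclass
class DeviationTensor:
    """Long-format z-score table with threshold masks.

    ``table`` columns: subject_id, location_id, band, z. The positive /
    negative extreme masks are derived columns kept consistent with the
    threshold by construction.
    """

    table: pd.DataFrame
    threshold: float = EXTREME_THRESHOLD

    def __post_init__(self):
        self.table = self.table.copy()
        t = self.table
        t["extreme_pos"] = t["z"] > self.threshold
        t["extreme_neg"] = t["z"] < -self.threshold

    def mask_matrix(self, subjects, sign: str, band: str | None = None,
                    locations=None):
        """Boolean subjects x locations matrix of extreme deviations."""
        col = {"positive": "extreme_pos", "negative": "extreme_neg"}[sign]
        t = self.table
        if band is not None:
            t = t[t["band"] == band]
        pivot = t.pivot_table(index="subject_id", columns="location_id",
                              values=col, aggfunc="any", fill_value=False)
        if locations is None:
            locations = sorted(pivot.columns)
        pivot = pivot.reindex(index=list(subjects), columns=list(locations),
                              fill_value=False)
        return pivot.to_numpy(dtype=bool), list(locations)


def deviation_summary(tensor: DeviationTensor, cohort: pd.DataFrame):
    """Per-subject extreme counts and per-group any-deviation percentages.

    Returns ``(counts, group_pct)``: counts has one row per subject x band
    with positive/negative extreme counts; group_pct gives, per group x
    band x sign, the percentage of subjects with at least one extreme
    deviation.
    """
    t = tensor.table
    counts = (t.groupby(["subject_id", "band"])[["extreme_pos", "extreme_neg"]]
              .sum().astype(int).reset_index()
              .rename(columns={"extreme_pos": "n_pos", "extreme_neg": "n_neg"}))
    counts = counts.merge(cohort[["subject_id", "group"]], on="subject_id",
                          how="left")
    rows = []
    for (group, band), g in counts.groupby(["group", "band"]):
        n = len(g)
        for sign, col in (("positive", "n_pos"), ("negative", "n_neg")):
            rows.append({"group": group, "band": band, "sign": sign,
                         "n_subjects": n,
                         "pct_with_extreme": 100.0 * (g[col] > 0).sum() / n})
    return counts, pd.DataFrame(rows)


@dataclass
class OverlapMap:
    group: str
    sign: str
    band: str | None
    locations: list[str]
    percentage: np.ndarray  # per-location, [0, 100]
    denominator: int        # subjects entering the percentage
    defined: bool = True


def overlap_map(tensor: DeviationTensor, cohort: pd.DataFrame, group: str,
                sign: str, band: str | None = None,
                denominator: str = "deviant") -> OverlapMap:
    """Group overlap map for one sign (and optionally one band).

    ``denominator='deviant'`` divides by the subjects with >= 1 extreme
    deviation of that sign (the operative definition); ``'all'`` divides by
    the full group size. With a zero denominator the map is flagged
    undefined and filled with zeros.
    """
    subjects = cohort.loc[cohort["group"] == group, "subject_id"]
    if subjects.empty:
        raise ValueError(f"group {group!r} is empty")
    M, locations = tensor.mask_matrix(subjects, sign, band)
    deviant = M.any(axis=1)
    denom = int(deviant.sum()) if denominator == "deviant" else int(len(subjects))
    if denominator == "deviant":
        M = M[deviant]
    if denom == 0:
        return OverlapMap(group, sign, band, locations,
                          np.zeros(len(locations)), 0, defined=False)
    pct = 100.0 * M.sum(axis=0) / denom
    return OverlapMap(group, sign, band, locations, pct, denom)
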