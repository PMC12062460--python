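"""Patient-specific deviation markers and their clinical correlates.

The extreme deviations index (EDI) of a subject, for one band and sign, is
the mean of the raw feature (connectivity) values over that subject's
extremely deviated locations; z-EDI averages the z-scores instead. A
subject with no extreme deviation of the requested sign has an undefined
marker and is excluded (not imputed) from correlations. Markers are rank-
correlated (Spearman) with clinical scores: UPDRS (motor severity,
higher = worse) and MMSE (cognition, lower = worse).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .deviations import DeviationTensor

__all__ = ["edi", "z_edi", "spearman", "association_scan"]


def edi(values, mask) -> float:
    """Mean feature value over masked (extremely deviated) locations.

    Returns NaN (undefined) for an empty mask.
    """
    values = np.asarray(values, float)
    mask = np.asarray(mask, bool)
    if values.shape != mask.shape:
        raise ValueError("values and mask must align")
    if not mask.any():
        return float("nan")
    return float(values[mask].mean())


def z_edi(z_values, mask) -> float:
    """Mean z-score over masked locations; NaN for an empty mask."""
    return edi(z_values, mask)


class DegenerateCorrelationError(ValueError):
    pass


def _exact_spearman_p(rho_obs: float, y_ranks: np.ndarray,
                      x_ranks: np.ndarray) -> float:
    """Two-sided p by exhaustive permutation of one rank vector (n <= 7)."""
    n = len(x_ranks)
    xc = x_ranks - x_ranks.mean()
    denom_x = np.sqrt((xc ** 2).sum())
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        yp = y_ranks[list(perm)]
        yc = yp - yp.mean()
        denom_y = np.sqrt((yc ** 2).sum())
        r = float((xc * yc).sum() / (denom_x * denom_y))
        if abs(r) >= abs(rho_obs) - 1e-12:
            count += 1
        total += 1
    return count / total


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average-rank ties.

    p-values by exhaustive enumeration for n <= 7, otherwise the
    t-distribution approximation. Zero rank variance in either variable is
    an error (the correlation is undefined).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise DegenerateCorrelationError("zero rank variance")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = x.size
    if n <= 7:
        p = _exact_spearman_p(rho, ry, rx)
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return rho, float(p)


@dataclass
class AssociationCell:
    group: str
    band: str
    sign: str
    marker: str
    score: str
    n: int
    rho: float
    p: float
    skipped: str = ""


def association_scan(tensor: DeviationTensor, features: pd.DataFrame,
                     cohort: pd.DataFrame, groups=("PD", "AD"),
                     scores=("updrs", "mmse"), min_n: int = 3,
                     bh_correct: bool = False) -> pd.DataFrame:
    """EDI and z-EDI vs clinical scores, per group x band x sign x marker.

    For each cell, per-subject markers are computed over that subject's
    extreme mask; subjects with undefined markers or missing scores are
    dropped pairwise. Cells with fewer than ``min_n`` usable subjects are
    reported as skipped. Uncorrected p-values by default; ``bh_correct``
    adds a BH-adjusted column across the scanned cells.
    """
    fv = features.set_index(["subject_id", "band", "location_id"])["value"].sort_index()
    zt = tensor.table.set_index(["subject_id", "band", "location_id"]).sort_index()
    bands = sorted(tensor.table["band"].unique())
    out: list[AssociationCell] = []
    for group in groups:
        sub = cohort[cohort["group"] == group]
        for band in bands:
            for sign, col in (("positive", "extreme_pos"),
                              ("negative", "extreme_neg")):
                markers: dict[str, dict[str, float]] = {"EDI": {}, "zEDI": {}}
                for sid in sub["subject_id"]:
                    try:
                        zrows = zt.loc[(sid, band)]
                    except KeyError:
                        continue
                    mask = zrows[col].to_numpy()
                    if not mask.any():
                        continue
                    locs = zrows.index.to_numpy()
                    vals = fv.loc[(sid, band)].reindex(locs).to_numpy()
                    markers["EDI"][sid] = float(vals[mask].mean())
                    markers["zEDI"][sid] = float(zrows["z"].to_numpy()[mask].mean())
                for marker, mdict in markers.items():
                    for score in scores:
                        sc = sub.set_index("subject_id")[score]
                        pairs = [(m, sc[sid]) for sid, m in mdict.items()
                                 if sid in sc.index and np.isfinite(sc[sid])]
                        if len(pairs) < min_n:
                            out.append(AssociationCell(group, band, sign,
                                                       marker, score,
                                                       len(pairs), np.nan,
                                                       np.nan,
                                                       "insufficient n"))
                            continue
                        mv, sv = map(np.asarray, zip(*pairs))
                        try:
                            rho, p = spearman(mv, sv)
                        except DegenerateCorrelationError:
                            out.append(AssociationCell(group, band, sign,
                                                       marker, score,
                                                       len(pairs), np.nan,
                                                       np.nan,
                                                       "degenerate ranks"))
                            continue
                        out.append(AssociationCell(group, band, sign, marker,
                                                   score, len(pairs), rho, p))
    df = pd.DataFrame([c.__dict__ for c in out])
    if bh_correct and not df.empty:
        from .inference import fdr_bh
        ok = df["p"].notna()
        adj = np.full(len(df), np.nan)
        if ok.any():
            adj[ok.to_numpy()] = fdr_bh(df.loc[ok, "p"].to_numpy(),
                                        alpha=0.05)
        df["bh_significant"] = adj
    return df
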