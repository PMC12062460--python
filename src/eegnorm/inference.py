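"""Group-level inference on deviation maps: label-permutation tests on
overlap maps with FDR control, rank tests on deviation counts, and
resting-state-network attribution of significant connections.

The permutation test shuffles case/control labels over the pooled
subject-level extreme-deviation masks; each iteration recomputes both
groups' overlap maps and their difference, building a per-location null.

Two-sided p-values use the add-one convention so p is never 0. The overlap
difference is a discrete statistic (percentages over small integer
denominators), so ties |null| == |observed| carry real mass; the default
``tie_policy='midp'`` gives ties half weight,
p = (1 + #{|null| > |obs|} + 0.5 #{|null| = |obs|}) / (1 + n_perm),
which keeps the null rejection rate near nominal and returns p ~ 0.5 at
degenerate locations where every permuted difference is zero.
``tie_policy='conservative'`` counts ties fully (never anti-conservative).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["PermutationResult", "permutation_overlap_test", "fdr_bh",
           "compare_counts", "network_attribution",
           "load_region_networks"]


def load_region_networks(path=None) -> dict[str, str]:
    """Region -> resting-state-network lookup (replaceable configuration).

    The default file maps the 68 cortical atlas regions onto seven
    canonical resting-state networks by approximate majority overlap; any
    two-column delimited file (region_id, network) can be supplied
    instead.
    """
    from pathlib import Path
    if path is None:
        path = Path(__file__).parent / "data" / "dk68_networks.csv"
    df = pd.read_csv(path)
    return dict(zip(df["region_id"], df["network"]))


def _overlap_pct(M: np.ndarray) -> tuple[np.ndarray, bool]:
    """Overlap percentages from a subjects x locations mask.

    Denominator: subjects with >= 1 extreme deviation. Returns the map and
    a flag for the degenerate (no deviant subject) case, where the map is
    all zeros.
    """
    deviant = M.any(axis=1)
    d = int(deviant.sum())
    if d == 0:
        return np.zeros(M.shape[1]), True
    return 100.0 * M[deviant].sum(axis=0) / d, False


@dataclass
class PermutationResult:
    locations: list[str]
    observed_diff: np.ndarray   # clinical - control, percentage points
    pvalues: np.ndarray
    significant: np.ndarray     # BH mask at alpha
    n_permutations: int
    seed: int
    alpha: float
    degenerate_iterations: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "location_id": self.locations,
            "observed_diff": self.observed_diff,
            "p": self.pvalues,
            "significant": self.significant,
        })


def permutation_overlap_test(masks_clinical: np.ndarray,
                             masks_control: np.ndarray,
                             locations=None, n_perm: int = 5000,
                             seed: int = 0, alpha: float = 0.05,
                             tie_policy: str = "midp"
                             ) -> PermutationResult:
    """Label-permutation test of clinical vs control overlap maps.

    Inputs are boolean subjects x locations extreme-deviation masks of one
    sign. Each iteration permutes the pooled group labels, recomputes both
    overlap maps and their difference; an iteration in which a permuted
    group has no deviant subject contributes a zero map for that group and
    is counted in ``degenerate_iterations``. See the module docstring for
    the tie conventions.
    """
    if tie_policy not in ("midp", "conservative"):
        raise ValueError(f"unknown tie policy {tie_policy!r}")
    A = np.asarray(masks_clinical, bool)
    B = np.asarray(masks_control, bool)
    if A.shape[0] == 0 or B.shape[0] == 0:
        raise ValueError("both groups must be non-empty")
    if A.shape[1] != B.shape[1]:
        raise ValueError("mask location sets differ")
    n_a = A.shape[0]
    pool = np.vstack([A, B])
    obs_a, _ = _overlap_pct(A)
    obs_b, _ = _overlap_pct(B)
    observed = obs_a - obs_b

    rng = np.random.default_rng(seed)
    greater = np.zeros(A.shape[1], dtype=np.int64)
    equal = np.zeros(A.shape[1], dtype=np.int64)
    degenerate = 0
    tol = 1e-9
    for _ in range(n_perm):
        idx = rng.permutation(pool.shape[0])
        pa, da = _overlap_pct(pool[idx[:n_a]])
        pb, db = _overlap_pct(pool[idx[n_a:]])
        if da or db:
            degenerate += 1
        d = np.abs(pa - pb)
        o = np.abs(observed)
        greater += d > o + tol
        equal += np.abs(d - o) <= tol
    tie_w = 0.5 if tie_policy == "midp" else 1.0
    p = (1.0 + greater + tie_w * equal) / (1.0 + n_perm)
    sig = fdr_bh(p, alpha)
    if locations is None:
        locations = [f"loc{i:03d}" for i in range(A.shape[1])]
    return PermutationResult(list(locations), observed, p, sig, n_perm,
                             seed, alpha, degenerate)


def fdr_bh(pvalues, alpha: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up mask at level ``alpha``."""
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    reject, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject


def compare_counts(counts_a, counts_b) -> tuple[float, float]:
    """Mann-Whitney U comparison of per-subject deviation counts.

    Exact p for small tie-free samples (n <= 8 per group), otherwise the
    tie-corrected normal approximation with continuity correction.
    Returns (U statistic of the first sample, two-sided p).
    """
    a = np.asarray(counts_a, float)
    b = np.asarray(counts_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (a.size <= 8 and b.size <= 8 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def network_attribution(significant_connections,
                        region_to_network: dict[str, str]) -> pd.Series:
    """Percentage of significant connections attributed to each network.

    Each connection "regionA|regionB" contributes both endpoints' network
    labels (two attributions per connection); percentages sum to 100.
    """
    tally: dict[str, int] = {}
    total = 0
    for conn in significant_connections:
        a, b = conn.split("|")
        for region in (a, b):
            if region not in region_to_network:
                raise KeyError(f"region {region!r} has no network mapping")
            net = region_to_network[region]
            tally[net] = tally.get(net, 0) + 1
            total += 1
    if total == 0:
        return pd.Series(dtype=float, name="percent")
    out = pd.Series({k: 100.0 * v / total for k, v in sorted(tally.items())},
                    name="percent")
    return out
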