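"""End-to-end orchestration: simulate -> features -> normative fits ->
deviation maps -> group inference -> clinical association, plus the
train/test split and leave-one-site-out (LOSO) robustness check.

Every stage reads and writes delimited-text artifacts so stages can also
run independently (see :mod:`eegnorm.cli`). A run manifest records the
full configuration, seed and library versions; re-running from the
manifest reproduces every numeric output byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clinical import association_scan
from .cohort import (CohortConfig, GroundTruthModel, generate_clinical_scores,
                     generate_cohort, generate_features, generate_leadfield,
                     generate_raw_eeg, SignalSpec)
from .deviations import DeviationTensor, deviation_summary, overlap_map, zscore
from .gamlss import (NormativeModelFit, build_fp_design, centile_curves,
                     fit_gamlss, fp_basis, model_diagnostics,
                     select_covariates, select_distribution, select_fp_powers,
                     FitError)
from .inference import compare_counts, permutation_overlap_test

log = logging.getLogger("eegnorm")

__all__ = ["PipelineConfig", "split_train_test", "fit_normative_models",
           "score_deviations", "run_pipeline", "run_from_manifest",
           "loso_robustness", "fits_from_records"]

DEFAULT_FAMILIES = ("NO", "BCCG", "BCT", "BCPE", "JSU")


@dataclass
class PipelineConfig:
    """Everything a full run depends on, JSON-serializable.

    The default scale is deliberately reduced (desk-scale synthetic study);
    ``paper_scale()`` documents the full-size settings of the study design
    this pipeline targets (19 channels / 2278 connections, 5000
    permutations, 933 subjects over 14 sites).
    """

    seed: int = 0
    n_hc_train: int = 160
    n_hc_test: int = 40
    n_pd: int = 50
    n_ad: int = 50
    n_sites: int = 4
    n_locations: int = 24
    bands: tuple[str, ...] = ("theta", "alpha")
    feature_mode: str = "tabular"
    family_candidates: tuple[str, ...] = DEFAULT_FAMILIES
    covariate_candidates: tuple[str, ...] = ("sex", "site")
    fp_max_degree: int = 1
    n_restarts: int = 1
    extreme_threshold: float = 2.0
    alpha: float = 0.05
    n_perm: int = 1000
    train_fraction: float = 0.8
    truth_family: str = "NO"
    deviation_effect: float = 3.0
    deviation_k: int = 5
    overlap_concentration: float = 0.2
    sex_effect: float = 0.02
    site_effect_sd: float = 0.01
    score_link_strength: float = 1.0
    score_noise: float = 0.5

    @classmethod
    def paper_scale(cls) -> "PipelineConfig":
        return cls(n_hc_train=400, n_hc_test=99, n_pd=237, n_ad=197,
                   n_sites=14, n_locations=2278, bands=("delta", "theta",
                   "alpha", "beta", "gamma"), n_perm=5000, fp_max_degree=2,
                   n_restarts=3)

    def validate(self):
        if self.feature_mode not in ("tabular", "raw-spectral",
                                     "raw-connectivity"):
            raise ValueError(f"unknown feature mode {self.feature_mode!r}")
        known = {"delta", "theta", "alpha", "beta", "gamma"}
        bad = set(self.bands) - known
        if bad:
            raise ValueError(f"unknown band name(s): {sorted(bad)}")
        if self.extreme_threshold <= 0 or self.n_perm < 1:
            raise ValueError("thresholds must be positive")
        if not 0 < self.train_fraction <= 1:
            raise ValueError("train_fraction must be in (0, 1]")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kw = dict(d)
        for k in ("bands", "family_candidates", "covariate_candidates"):
            if k in kw:
                kw[k] = tuple(kw[k])
        return cls(**kw)

    def truth(self, seed: int) -> GroundTruthModel:
        rng = np.random.default_rng(seed + 77)
        sites = tuple(rng.normal(scale=self.site_effect_sd,
                                 size=self.n_sites))
        return GroundTruthModel(
            family=self.truth_family, sex_effect=self.sex_effect,
            site_effects=sites, deviation_effect=self.deviation_effect,
            deviation_k=self.deviation_k,
            overlap_concentration=self.overlap_concentration,
            score_link_strength=self.score_link_strength,
            score_noise=self.score_noise)

    def cohort_config(self) -> CohortConfig:
        return CohortConfig(n_hc_train=self.n_hc_train,
                            n_hc_test=self.n_hc_test, n_pd=self.n_pd,
                            n_ad=self.n_ad, n_sites=self.n_sites)


# ---------------------------------------------------------------------------
# train/test split


def split_train_test(cohort: pd.DataFrame, fraction: float = 0.8,
                     seed: int = 0) -> tuple[list[str], list[str]]:
    """Split healthy controls into train/test ids, stratified by site+sex.

    Only subjects in HC groups are split (patients are always scored
    against train-fitted models). The global train size is
    floor(fraction * n_hc) with largest-remainder allocation across
    site x sex strata; strata with < 2 subjects are pooled (with a
    warning) before stratification.
    """
    hc = cohort[cohort["group"].str.startswith("HC")]
    if hc.empty:
        raise ValueError("no healthy-control subjects to split")
    rng = np.random.default_rng(seed)
    n_target = int(np.floor(fraction * len(hc)))

    strata: dict[tuple, list[str]] = {}
    for row in hc.itertuples(index=False):
        strata.setdefault((row.site, row.sex), []).append(row.subject_id)
    pooled = [sid for key, ids in strata.items() if len(ids) < 2
              for sid in ids]
    strata = {k: v for k, v in strata.items() if len(v) >= 2}
    if pooled:
        log.warning("pooling %d subjects from small strata", len(pooled))
        strata[("pooled", "pooled")] = pooled

    train: list[str] = []
    quotas = []
    for key in sorted(strata, key=str):
        ids = sorted(strata[key])
        exact = fraction * len(ids)
        quotas.append([key, ids, int(np.floor(exact)), exact % 1.0])
    short = n_target - sum(q[2] for q in quotas)
    for q in sorted(quotas, key=lambda q: -q[3])[:max(short, 0)]:
        q[2] += 1
    for key, ids, k, _ in quotas:
        perm = rng.permutation(len(ids))
        train.extend(ids[i] for i in perm[:k])
    train_set = set(train)
    test = [sid for sid in hc["subject_id"] if sid not in train_set]
    return sorted(train), sorted(test)


# ---------------------------------------------------------------------------
# model fitting over the feature table


def _covariate_arrays(df: pd.DataFrame, n_sites: int,
                      which: tuple[str, ...]) -> dict[str, np.ndarray]:
    out = {}
    if "sex" in which:
        out["sex"] = (df["sex"] == "M").to_numpy(float)
    if "site" in which and n_sites > 1:
        site = np.zeros((len(df), n_sites - 1))
        s = df["site"].to_numpy()
        for k in range(2, n_sites + 1):
            site[:, k - 2] = s == k
        out["site"] = site
    return out


def design_from_names(names: list[str], ages, cov: dict[str, np.ndarray]):
    """Rebuild a design matrix from stored column names for new subjects."""
    ages = np.asarray(ages, float)
    fp_names = [nm for nm in names if nm.startswith("age^") or nm == "log(age)"]
    powers = [0.0 if nm == "log(age)" else float(nm.split("^")[1])
              for nm in fp_names]
    B = fp_basis(ages, powers) if powers else np.empty((len(ages), 0))
    cols, j = [], 0
    for nm in names:
        if nm == "intercept":
            cols.append(np.ones_like(ages))
        elif nm in fp_names:
            cols.append(B[:, j])
            j += 1
        elif nm == "sex":
            cols.append(np.asarray(cov["sex"], float))
        elif nm == "site":  # two sites: a single indicator column
            cols.append(np.asarray(cov["site"], float)[:, 0])
        elif nm.startswith("site["):
            k = int(nm[5:-1])
            cols.append(np.asarray(cov["site"], float)[:, k])
        else:
            raise KeyError(f"cannot rebuild design column {nm!r}")
    return np.column_stack(cols)


def fit_one_feature(y, sub: pd.DataFrame, config: PipelineConfig,
                    seed: int = 0) -> NormativeModelFit:
    """FP-power, family and covariate selection plus the final fit.

    Powers are chosen with fast normal-family fits; the family is then
    selected by BIC at those powers; sex/site indicators are added
    sequentially if they lower BIC for the selected family.
    """
    ages = sub["age"].to_numpy(float)
    optional = _covariate_arrays(sub, config.n_sites,
                                 config.covariate_candidates)
    powers = select_fp_powers(y, ages, family="NO",
                              max_degree=config.fp_max_degree, seed=seed)
    X, names = build_fp_design(ages, powers)
    base = select_distribution(
        y, {"mu": X}, config.family_candidates, seed=seed,
        n_restarts=config.n_restarts, powers=powers,
        column_names={"mu": names})
    fit = select_covariates(y, ages, powers, optional, family=base.family,
                            seed=seed, n_restarts=config.n_restarts)
    fit.meta["bic_table"] = base.meta.get("bic_table", [])
    return fit


def fit_normative_models(features: pd.DataFrame, cohort: pd.DataFrame,
                         train_ids, config: PipelineConfig):
    """Fit one normative model per (location, band) on the training HC.

    Returns ``(fits, diagnostics)``: fits maps (location_id, band) ->
    NormativeModelFit; diagnostics is a per-model residual summary on the
    training data.
    """
    train_set = set(train_ids)
    sub = cohort[cohort["subject_id"].isin(train_set)].sort_values(
        "subject_id").reset_index(drop=True)
    feat = features[features["subject_id"].isin(train_set)]
    fits: dict[tuple[str, str], NormativeModelFit] = {}
    diag_rows = []
    for (loc, band), g in feat.groupby(["location_id", "band"], sort=True):
        g = g.set_index("subject_id").reindex(sub["subject_id"])
        y = g["value"].to_numpy(float)
        if np.any(~np.isfinite(y)):
            raise FitError(f"missing training values at {loc}/{band}")
        stable = zlib.crc32(f"{loc}|{band}".encode()) % 10000
        fit = fit_one_feature(y, sub, config, seed=config.seed + stable)
        fits[(loc, band)] = fit
        designs = _designs_for(fit, sub, config.n_sites)
        if fit.converged:
            d = model_diagnostics(fit, y, designs)
            d.update({"location_id": loc, "band": band,
                      "family": fit.family, "bic": fit.bic,
                      "converged": True})
        else:
            d = {"location_id": loc, "band": band, "family": fit.family,
                 "bic": fit.bic, "converged": False}
        diag_rows.append(d)
    return fits, pd.DataFrame(diag_rows)


def _designs_for(fit: NormativeModelFit, df: pd.DataFrame, n_sites: int):
    cov = _covariate_arrays(df, n_sites, ("sex", "site"))
    ages = df["age"].to_numpy(float)
    return {p: design_from_names(fit.column_names[p], ages, cov)
            for p in fit.column_names}


def score_deviations(features: pd.DataFrame, cohort: pd.DataFrame,
                     fits, subject_ids, config: PipelineConfig
                     ) -> DeviationTensor:
    """z-scores of the listed subjects against the trained models."""
    keep = set(subject_ids)
    sub = cohort[cohort["subject_id"].isin(keep)].sort_values(
        "subject_id").reset_index(drop=True)
    feat = features[features["subject_id"].isin(keep)]
    frames = []
    for (loc, band), fit in fits.items():
        if not fit.converged:
            continue
        g = feat[(feat["location_id"] == loc) & (feat["band"] == band)]
        g = g.set_index("subject_id").reindex(sub["subject_id"])
        y = g["value"].to_numpy(float)
        designs = _designs_for(fit, sub, config.n_sites)
        z = zscore(y, fit, designs)
        frames.append(pd.DataFrame({
            "subject_id": sub["subject_id"], "location_id": loc,
            "band": band, "z": z}))
    table = pd.concat(frames, ignore_index=True)
    return DeviationTensor(table, threshold=config.extreme_threshold)


def fits_from_records(df: pd.DataFrame) -> dict:
    """Rebuild the fitted models from a fits.csv table.

    Coefficient columns are named ``beta_<param>.<column>``; NaN cells mean
    the column does not belong to that model (different FP powers or
    covariates across locations).
    """
    beta_cols = [c for c in df.columns if c.startswith("beta_")]
    fits = {}
    for _, row in df.iterrows():
        coef: dict[str, list] = {}
        names: dict[str, list] = {}
        for col in beta_cols:
            if pd.isna(row[col]):
                continue
            pname, cname = col[5:].split(".", 1)
            coef.setdefault(pname, []).append(float(row[col]))
            names.setdefault(pname, []).append(cname)
        pw = () if pd.isna(row["powers"]) or row["powers"] == "" else tuple(
            float(x) for x in str(row["powers"]).split(","))
        cov = () if pd.isna(row.get("covariates")) else tuple(
            str(row["covariates"]).split(","))
        fits[(row["location_id"], row["band"])] = NormativeModelFit(
            family=row["family"], powers=pw,
            coef={p: np.asarray(v) for p, v in coef.items()},
            column_names=names, loglik=float(row["loglik"]),
            n=int(row["n"]), converged=bool(row["converged"]),
            covariates=cov)
    return fits


# ---------------------------------------------------------------------------
# feature generation per mode


def _make_features(cohort, config: PipelineConfig, seed: int):
    truth = config.truth(seed)
    if config.feature_mode == "tabular":
        return generate_features(cohort, truth, config.n_locations,
                                 config.bands, seed=seed + 1)
    # raw modes exercise the signal-processing path; deviant-location
    # injection (and hence the clinical link) applies to tabular mode only
    from .spectral import (DEFAULT_BAND_DEFS, relative_band_power, welch_psd)
    spec = SignalSpec(n_channels=min(config.n_locations, 19), n_epochs=3)
    raws = generate_raw_eeg(cohort, spec, seed=seed + 1)
    band_defs = [b for b in DEFAULT_BAND_DEFS if b.name in config.bands]
    if config.feature_mode == "raw-spectral":
        rows = []
        for sid, ep in raws.items():
            ps = welch_psd(ep)
            rel = relative_band_power(ps, DEFAULT_BAND_DEFS)
            for b in band_defs:
                for ci, ch in enumerate(ps.channels):
                    rows.append((sid, ch, b.name, float(rel[b.name][ci])))
        feats = pd.DataFrame(rows, columns=["subject_id", "location_id",
                                            "band", "value"])
        return feats, pd.DataFrame(columns=["subject_id", "location_id",
                                            "effect"])
    from .connectivity import connectivity_pipeline, connectivity_to_long
    lf = generate_leadfield(spec.n_channels, max(4 * spec.n_channels, 40),
                            seed=seed + 2)
    n_reg = min(8, spec.n_channels)
    labels = np.arange(lf.gain.shape[1]) % n_reg
    names = [f"reg{i:02d}" for i in range(n_reg)]
    frames = []
    for sid, ep in raws.items():
        mats = connectivity_pipeline(ep, lf, labels, band_defs)
        frames.append(connectivity_to_long(mats, names, sid))
    feats = pd.concat(frames, ignore_index=True)
    return feats, pd.DataFrame(columns=["subject_id", "location_id",
                                        "effect"])


# ---------------------------------------------------------------------------
# the full run


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> Path:
    """Execute every stage and write all artifacts under ``outdir``."""
    config.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    log.info("stage simulate: seed=%d", seed)

    cohort = generate_cohort(config.cohort_config(), seed=seed)
    features, registry = _make_features(cohort, config, seed)
    if len(registry):
        burden = registry.attrs.get("burden", {})
        cohort = generate_clinical_scores(cohort, burden, config.truth(seed),
                                          seed=seed + 3)
    features.to_csv(out / "features.csv", index=False)
    registry.to_csv(out / "registry.csv", index=False)

    train_ids, test_ids = split_train_test(cohort, config.train_fraction,
                                           seed=seed + 4)
    # relabel HC by the realized split so downstream group summaries and
    # the permutation control group reflect the ids actually held out
    hc = cohort["group"].str.startswith("HC")
    cohort.loc[hc & cohort["subject_id"].isin(set(train_ids)),
               "group"] = "HC_train"
    cohort.loc[hc & cohort["subject_id"].isin(set(test_ids)),
               "group"] = "HC_test"
    cohort.to_csv(out / "cohort.csv", index=False)
    pd.DataFrame({"subject_id": train_ids}).to_csv(out / "train_ids.csv",
                                                   index=False)
    pd.DataFrame({"subject_id": test_ids}).to_csv(out / "test_ids.csv",
                                                  index=False)

    log.info("stage fit: %d locations x %d bands", config.n_locations,
             len(config.bands))
    fits, diagnostics = fit_normative_models(features, cohort, train_ids,
                                             config)
    fit_rows = []
    for (loc, band), f in fits.items():
        rec = f.to_record()
        rec.update({"location_id": loc, "band": band})
        fit_rows.append(rec)
    pd.DataFrame(fit_rows).to_csv(out / "fits.csv", index=False)
    diagnostics.to_csv(out / "diagnostics.csv", index=False)

    grid = np.linspace(40, 92, 27)
    cent_rows = []
    for (loc, band), f in fits.items():
        if not f.converged:
            continue
        c = centile_curves(f, grid, age_range=(40, 92))
        for i, age in enumerate(grid):
            cent_rows.append({"location_id": loc, "band": band,
                              "age": age, "p5": c["p5"][i],
                              "p50": c["p50"][i], "p95": c["p95"][i]})
    pd.DataFrame(cent_rows).to_csv(out / "centiles.csv", index=False)

    log.info("stage deviate")
    score_ids = [s for s in cohort["subject_id"] if s not in set(train_ids)]
    tensor = score_deviations(features, cohort, fits, score_ids, config)
    tensor.table.to_csv(out / "deviations.csv", index=False)

    counts, group_pct = deviation_summary(tensor, cohort)
    counts.to_csv(out / "summary_counts.csv", index=False)
    group_pct.to_csv(out / "group_pct.csv", index=False)

    log.info("stage overlap + permutation (%d permutations)", config.n_perm)
    scored = cohort[cohort["subject_id"].isin(set(score_ids))]
    ov_rows, perm_rows, mw_rows = [], [], []
    hc_ids = scored.loc[scored["group"].str.startswith("HC"),
                        "subject_id"].tolist()
    for band in config.bands:
        for sign in ("positive", "negative"):
            for grp in ("HC_test", "PD", "AD"):
                gids = scored.loc[scored["group"] == grp, "subject_id"]
                if gids.empty:
                    continue
                om = overlap_map(tensor, cohort, grp, sign, band)
                for loc, pct in zip(om.locations, om.percentage):
                    ov_rows.append({"group": grp, "band": band, "sign": sign,
                                    "location_id": loc, "overlap_pct": pct,
                                    "denominator": om.denominator,
                                    "defined": om.defined})
            for grp in ("PD", "AD"):
                gids = scored.loc[scored["group"] == grp,
                                  "subject_id"].tolist()
                if not gids or not hc_ids:
                    continue
                Mg, locs = tensor.mask_matrix(gids, sign, band)
                Mh, _ = tensor.mask_matrix(hc_ids, sign, band, locations=locs)
                res = permutation_overlap_test(
                    Mg, Mh, locs, n_perm=config.n_perm,
                    seed=seed + 5, alpha=config.alpha)
                df = res.to_frame()
                df.insert(0, "sign", sign)
                df.insert(0, "band", band)
                df.insert(0, "group", grp)
                perm_rows.append(df)
                cg = counts[(counts["group"] == grp)
                            & (counts["band"] == band)]
                ch = counts[counts["group"].str.startswith("HC")
                            & (counts["band"] == band)]
                col = "n_pos" if sign == "positive" else "n_neg"
                U, p = compare_counts(cg[col].to_numpy(), ch[col].to_numpy())
                mw_rows.append({"group": grp, "band": band, "sign": sign,
                                "U": U, "p": p})
    pd.DataFrame(ov_rows).to_csv(out / "overlap_maps.csv", index=False)
    (pd.concat(perm_rows, ignore_index=True) if perm_rows
     else pd.DataFrame()).to_csv(out / "permutation.csv", index=False)
    pd.DataFrame(mw_rows).to_csv(out / "mannwhitney_counts.csv", index=False)

    log.info("stage associate")
    assoc = association_scan(tensor, features, cohort)
    assoc.to_csv(out / "associations.csv", index=False)

    manifest = {
        "config": config.to_dict(),
        "package_version": __version__,
        "versions": {m.__name__: m.__version__ for m in (np, pd)},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    log.info("pipeline complete: %s", out)
    return out


def run_from_manifest(manifest_path: str | Path, outdir: str | Path) -> Path:
    """Reproduce a run from its manifest."""
    manifest = json.loads(Path(manifest_path).read_text())
    config = PipelineConfig.from_dict(manifest["config"])
    return run_pipeline(config, outdir)


# ---------------------------------------------------------------------------
# LOSO robustness


def loso_robustness(features: pd.DataFrame, cohort: pd.DataFrame,
                    train_ids, fits, config: PipelineConfig) -> pd.DataFrame:
    """Leave-one-site-out refits and median-trajectory correlations.

    For each held-out site, every model is refitted (same family, powers
    and covariates as the full fit) on the remaining training subjects; the
    correlation r between full-data and reduced-data median curves over the
    common age grid measures trajectory robustness. Non-converged refits
    yield a missing r.
    """
    train = cohort[cohort["subject_id"].isin(set(train_ids))]
    sites = sorted(train["site"].unique())
    if len(sites) < 2:
        raise ValueError("LOSO requires >=2 sites")
    grid = np.linspace(41, 91, 26)
    rows = []
    for site in sites:
        keep = train[train["site"] != site]
        sub = keep.sort_values("subject_id").reset_index(drop=True)
        cov = _covariate_arrays(sub, config.n_sites, ("sex", "site"))
        for (loc, band), full in fits.items():
            if not full.converged:
                continue
            g = features[(features["location_id"] == loc)
                         & (features["band"] == band)]
            g = g.set_index("subject_id").reindex(sub["subject_id"])
            y = g["value"].to_numpy(float)
            designs = {p: design_from_names(full.column_names[p],
                                            sub["age"].to_numpy(float), cov)
                       for p in full.column_names}
            try:
                refit = fit_gamlss(y, designs, full.family,
                                   n_restarts=config.n_restarts,
                                   seed=config.seed, powers=full.powers,
                                   covariates=full.covariates,
                                   column_names=full.column_names)
            except FitError:
                refit = None
            if refit is None or not refit.converged:
                rows.append({"site": site, "location_id": loc, "band": band,
                             "r": np.nan, "converged": False})
                continue
            c_full = centile_curves(full, grid, percentiles=(50,))
            c_red = centile_curves(refit, grid, percentiles=(50,))
            r = float(np.corrcoef(c_full["p50"], c_red["p50"])[0, 1])
            rows.append({"site": site, "location_id": loc, "band": band,
                         "r": r, "converged": True})
    return pd.DataFrame(rows)
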