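"""Seeded synthetic cohorts with the statistical structure of a multi-site
aging EEG study.

The generator emulates what the downstream normative-modeling analysis
assumes about real data: feature values whose location, scale and shape
drift with age; additive sex and site effects; patient groups carrying
subject-specific sets of deviant locations (heterogeneous, with a tunable
degree of sharing); and clinical scores linked monotonically to each
patient's deviation burden. Everything is a pure function of (config, seed).

Default cohort sizes follow the study design this pipeline targets: 400
healthy controls for training, 99 held out, 237 Parkinson's disease and 197
Alzheimer's disease patients, ages 40-92 concentrated around the mid-60s
across 14 sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .families import get_family

__all__ = [
    "CohortConfig", "GroundTruthModel", "SignalSpec", "Leadfield",
    "EpochedSignals", "generate_cohort", "generate_features",
    "generate_raw_eeg", "generate_leadfield", "generate_clinical_scores",
    "DEFAULT_BANDS",
]

GROUPS = ("HC_train", "HC_test", "PD", "AD")
DEFAULT_BANDS = ("delta", "theta", "alpha", "beta", "gamma")


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class CohortConfig:
    """Sampling plan for a synthetic cohort."""

    n_hc_train: int = 400
    n_hc_test: int = 99
    n_pd: int = 237
    n_ad: int = 197
    age_range: tuple[float, float] = (40.0, 92.0)
    age_mean: float = 65.0
    age_sd: float = 10.0
    male_fraction: float = 0.46
    n_sites: int = 14

    def validate(self):
        lo, hi = self.age_range
        if not lo < hi:
            raise ConfigurationError(f"invalid age range {self.age_range}")
        for nm in ("n_hc_train", "n_hc_test", "n_pd", "n_ad"):
            if getattr(self, nm) < 0:
                raise ConfigurationError(f"{nm} must be >= 0")
        if not 0 <= self.male_fraction <= 1:
            raise ConfigurationError("male_fraction must be in [0,1]")
        if self.n_sites < 1:
            raise ConfigurationError("need at least one site")


def _default_mu(age):
    # gentle decline with age, resembling relative alpha power
    return 0.45 - 0.15 * (np.asarray(age, float) / 100.0)


def _default_sigma(age):
    return 0.05 + 0.02 * (np.asarray(age, float) / 100.0)


@dataclass(frozen=True)
class GroundTruthModel:
    """The generating law for one feature family across the cohort.

    Parameter functions map age (years) to the distribution parameters of
    ``family``; sex and site act additively on the mu link scale. Patients
    receive ``deviation_k`` deviant locations whose latent normal score is
    shifted by ``deviation_effect`` (in generating-sigma units);
    ``overlap_concentration`` in [0,1] interpolates the deviant-location
    sampling between uniform (0, maximally heterogeneous) and a single
    shared template set (1).
    """

    family: str = "NO"
    mu_fun: Callable = _default_mu
    sigma_fun: Callable = _default_sigma
    nu_fun: Callable = lambda age: np.full_like(np.asarray(age, float), 1.0)
    tau_fun: Callable = lambda age: np.full_like(np.asarray(age, float), 10.0)
    sex_effect: float = 0.0
    site_effects: tuple[float, ...] = ()
    deviation_effect: float = 3.0
    deviation_k: int = 10
    overlap_concentration: float = 0.2
    score_link_strength: float = 1.0
    score_noise: float = 0.5

    def validate(self):
        if not 0.0 <= self.overlap_concentration <= 1.0:
            raise ConfigurationError("overlap_concentration must be in [0,1]")
        if self.deviation_k < 0:
            raise ConfigurationError("deviation_k must be >= 0")
        get_family(self.family)

    def params_at(self, age, sex=None, site=None):
        """Natural-scale (mu, sigma[, nu, tau]) at the given covariates.

        Sex ('M' adds ``sex_effect``) and site offsets enter on the mu link
        scale, mirroring how the normative model represents them.
        """
        fam = get_family(self.family)
        age = np.asarray(age, float)
        eta = fam.link("mu", self.mu_fun(age))
        if sex is not None and self.sex_effect:
            eta = eta + self.sex_effect * (np.asarray(sex) == "M")
        if site is not None and len(self.site_effects):
            offs = np.asarray(self.site_effects, float)
            idx = np.asarray(site, int) - 1
            eta = eta + offs[np.clip(idx, 0, len(offs) - 1)]
        mu = fam.link_inverse("mu", eta)
        params = [mu, self.sigma_fun(age)]
        if fam.n_params >= 3:
            params.append(self.nu_fun(age))
        if fam.n_params >= 4:
            params.append(self.tau_fun(age))
        return params


def generate_cohort(config: CohortConfig | None = None, seed: int = 0) -> pd.DataFrame:
    """Sample a subject table: id, age, sex, site, group, empty scores.

    Ages are truncated-normal within ``age_range``; sex and site are drawn
    with the configured proportions (sites uniform). Deterministic given
    (config, seed).
    """
    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    sizes = {"HC_train": config.n_hc_train, "HC_test": config.n_hc_test,
             "PD": config.n_pd, "AD": config.n_ad}
    rows = []
    lo, hi = config.age_range
    a = (lo - config.age_mean) / config.age_sd
    b = (hi - config.age_mean) / config.age_sd
    counter = 0
    for group in GROUPS:
        n = sizes[group]
        ages = stats.truncnorm.rvs(a, b, loc=config.age_mean,
                                   scale=config.age_sd, size=n,
                                   random_state=rng)
        sexes = np.where(rng.random(n) < config.male_fraction, "M", "F")
        sites = rng.integers(1, config.n_sites + 1, size=n)
        for i in range(n):
            rows.append({
                "subject_id": f"sub-{counter:04d}", "age": float(ages[i]),
                "sex": sexes[i], "site": int(sites[i]), "group": group,
                "updrs": np.nan, "mmse": np.nan,
            })
            counter += 1
    cols = ["subject_id", "age", "sex", "site", "group", "updrs", "mmse"]
    return pd.DataFrame(rows, columns=cols)


def _deviant_locations(rng, n_patients, n_locations, k, concentration):
    """Per-patient deviant-location sets from a template/uniform urn mix.

    With probability ``concentration`` each of a patient's k slots comes
    from a fixed template set of size k; sampling is without replacement via
    a mixed weight vector, so concentration 1 reproduces the template
    exactly and 0 is uniform.
    """
    template = rng.choice(n_locations, size=min(k, n_locations), replace=False)
    w_template = np.zeros(n_locations)
    if len(template):
        w_template[template] = 1.0 / len(template)
    w_uniform = np.full(n_locations, 1.0 / n_locations)
    if concentration >= 1.0:
        return [np.sort(template)] * n_patients, template
    w = concentration * w_template + (1.0 - concentration) * w_uniform
    w = w / w.sum()
    sets = [np.sort(rng.choice(n_locations, size=min(k, n_locations),
                               replace=False, p=w))
            for _ in range(n_patients)]
    return sets, template


def generate_features(cohort: pd.DataFrame, truth: GroundTruthModel,
                      n_locations: int, bands: Sequence[str] = DEFAULT_BANDS,
                      seed: int = 0):
    """Feature table (long format) plus the ground-truth deviant registry.

    Healthy subjects draw from the truth's family at their covariates.
    Each patient carries ``truth.deviation_k`` deviant locations (shared
    according to ``overlap_concentration``, same set across bands) whose
    draws are shifted by ``deviation_effect`` on the latent standard-normal
    scale: y = Q_F(Phi(z + delta)), which for a normal family is exactly a
    delta-sigma shift.

    Returns ``(features, registry)``; the registry has one row per
    (patient, location), and each patient's realized deviation burden —
    the mean |z + delta| over their deviant cells, a severity measure the
    clinical-score generator links to — is in ``registry.attrs['burden']``.
    """
    truth.validate()
    if n_locations < 1:
        raise ConfigurationError("n_locations must be >= 1")
    fam = get_family(truth.family)
    rng = np.random.default_rng(seed)
    bands = list(bands)
    n_bands = len(bands)

    is_patient = cohort["group"].isin(["PD", "AD"]).to_numpy()
    patients = cohort.loc[is_patient, "subject_id"].to_numpy()
    sets, template = _deviant_locations(
        rng, len(patients), n_locations, truth.deviation_k,
        truth.overlap_concentration)
    dev_lookup = {sid: s for sid, s in zip(patients, sets)}

    records = []
    reg_rows = []
    burden: dict[str, int] = {}
    eps = 1e-12
    for row in cohort.itertuples(index=False):
        params = truth.params_at(row.age, row.sex, row.site)
        dev = dev_lookup.get(row.subject_id)
        z = rng.standard_normal((n_locations, n_bands))
        shift = np.zeros((n_locations, n_bands))
        if dev is not None and len(dev):
            shift[dev, :] = truth.deviation_effect
        zs = z + shift
        y = fam.ppf(np.clip(stats.norm.cdf(zs), eps, 1 - eps),
                    [np.asarray(p, float) for p in params])
        for li in range(n_locations):
            for bi, band in enumerate(bands):
                records.append((row.subject_id, f"loc{li:03d}", band,
                                float(y[li, bi])))
        if dev is not None:
            burden[row.subject_id] = (float(np.mean(np.abs(zs[dev, :])))
                                      if len(dev) else 0.0)
            for li in dev:
                reg_rows.append({"subject_id": row.subject_id,
                                 "location_id": f"loc{li:03d}",
                                 "effect": truth.deviation_effect})
    features = pd.DataFrame(records,
                            columns=["subject_id", "location_id", "band", "value"])
    registry = pd.DataFrame(reg_rows,
                            columns=["subject_id", "location_id", "effect"])
    registry.attrs["burden"] = burden
    registry.attrs["template"] = [f"loc{li:03d}" for li in np.sort(template)]
    return features, registry


# ---------------------------------------------------------------------------
# raw signals and leadfields


@dataclass(frozen=True)
class SignalSpec:
    """Recipe for synthetic multichannel EEG.

    Band oscillation amplitudes are in µV (optionally callables of age);
    1/f background noise has amplitude ``noise_level``. ``coupled_pairs``
    entries (i, j, band) give channels i and j narrowband carriers in that
    band sharing one slow amplitude envelope — the ground truth for
    envelope-correlation connectivity.
    """

    n_channels: int = 19
    n_epochs: int = 6
    rate: float = 200.0
    epoch_seconds: float = 10.0
    osc_amplitudes: Mapping[str, float | Callable] = field(
        default_factory=lambda: {"alpha": 2.0})
    band_edges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"delta": (1, 4), "theta": (4, 8),
                                 "alpha": (8, 13), "beta": (13, 30),
                                 "gamma": (30, 45)})
    noise_level: float = 1.0
    coupled_pairs: tuple[tuple[int, int, str], ...] = ()
    envelope_strength: float = 1.0

    def validate(self):
        if self.rate <= 0 or self.epoch_seconds <= 0:
            raise ConfigurationError("rate and epoch length must be positive")
        if self.n_channels < 1 or self.n_epochs < 1:
            raise ConfigurationError("need >=1 channel and epoch")


@dataclass
class EpochedSignals:
    """Epoch x channel x sample array with labels and sampling rate."""

    subject_id: str
    rate: float
    data: np.ndarray  # (n_epochs, n_channels, n_samples), µV
    channels: list[str]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]


def _pink_noise(rng, n, level):
    """1/f-power noise via spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0)
    scale = np.ones_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:] / f[1])
    x = np.fft.irfft(spec * scale, n)
    sd = x.std()
    return level * x / (sd if sd > 0 else 1.0)


def _narrowband(rng, n, rate, band):
    """Unit-variance Gaussian noise band-limited to ``band`` (FFT mask)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / rate)
    mask = (f >= band[0]) & (f <= band[1])
    x = np.fft.irfft(spec * mask, n)
    sd = x.std()
    return x / (sd if sd > 0 else 1.0)


def _slow_envelope(rng, n, rate, cutoff=1.0):
    """Nonnegative slow modulation, mean ~1."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / rate)
    x = np.fft.irfft(spec * (f <= cutoff), n)
    sd = x.std()
    x = x / (sd if sd > 0 else 1.0)
    return np.clip(1.0 + 0.8 * x, 0.0, None)


def generate_raw_eeg(cohort: pd.DataFrame, spec: SignalSpec | None = None,
                     seed: int = 0) -> dict[str, EpochedSignals]:
    """Synthetic epoched EEG per subject: 1/f noise + band oscillations.

    Oscillations are narrowband noise carriers at the configured amplitude
    (age-dependent if a callable); coupled channel pairs share a slow
    envelope on independent carriers, so orthogonalized envelope
    correlation — but not zero-lag leakage — links them.
    """
    spec = spec or SignalSpec()
    spec.validate()
    rng = np.random.default_rng(seed)
    n = int(round(spec.rate * spec.epoch_seconds))
    channels = [f"ch{c:02d}" for c in range(spec.n_channels)]
    out = {}
    for row in cohort.itertuples(index=False):
        data = np.empty((spec.n_epochs, spec.n_channels, n))
        for e in range(spec.n_epochs):
            for c in range(spec.n_channels):
                data[e, c] = _pink_noise(rng, n, spec.noise_level)
            for band, amp in spec.osc_amplitudes.items():
                a = amp(row.age) if callable(amp) else amp
                if a == 0:
                    continue
                edges = spec.band_edges[band]
                for c in range(spec.n_channels):
                    data[e, c] += a * _narrowband(rng, n, spec.rate, edges)
            for (i, j, band) in spec.coupled_pairs:
                env = _slow_envelope(rng, n, spec.rate)
                edges = spec.band_edges[band]
                for c in (i, j):
                    carrier = _narrowband(rng, n, spec.rate, edges)
                    data[e, c] += spec.envelope_strength * env * carrier
        out[row.subject_id] = EpochedSignals(row.subject_id, spec.rate,
                                             data, list(channels))
    return out


def save_epoched(signals: EpochedSignals, stem: str | "Path"):
    """Write epochs as a raw array file plus a plain-text sidecar header.

    ``<stem>.npy`` holds the epoch x channel x sample array; ``<stem>.hdr``
    records subject, rate and channel labels, one per line.
    """
    from pathlib import Path
    stem = Path(stem)
    np.save(stem.with_suffix(".npy"), signals.data)
    lines = [f"subject_id {signals.subject_id}", f"rate {signals.rate}",
             "channels " + " ".join(signals.channels)]
    stem.with_suffix(".hdr").write_text("\n".join(lines) + "\n")


def load_epoched(stem: str | "Path") -> EpochedSignals:
    """Inverse of :func:`save_epoched`."""
    from pathlib import Path
    stem = Path(stem)
    data = np.load(stem.with_suffix(".npy"))
    meta = {}
    for line in stem.with_suffix(".hdr").read_text().splitlines():
        key, _, val = line.partition(" ")
        meta[key] = val
    return EpochedSignals(meta["subject_id"], float(meta["rate"]), data,
                          meta["channels"].split())


@dataclass
class Leadfield:
    """Gain matrix (channels x sources) with labels and source positions."""

    gain: np.ndarray
    channels: list[str]
    source_positions: np.ndarray  # (n_sources, 3)

    def validate(self):
        if not np.all(np.isfinite(self.gain)):
            raise ConfigurationError("leadfield contains non-finite entries")
        if np.any(np.all(self.gain == 0, axis=1)):
            raise ConfigurationError("leadfield has an all-zero channel row")
        if np.any(np.all(self.gain == 0, axis=0)):
            raise ConfigurationError("leadfield has an all-zero source column")


def generate_leadfield(n_channels: int = 19, n_sources: int = 200,
                       seed: int = 0, max_retries: int = 5) -> Leadfield:
    """Smooth distance-decayed synthetic leadfield of full row rank.

    Sensors sit on a unit sphere, sources on a smaller interior sphere;
    gain decays with sensor-source distance (plus mild random orientation
    gain), which yields the spatial smoothness a head volume conductor
    imposes. Redraws up to ``max_retries`` times if rank-deficient.
    """
    if n_channels < 4:
        raise ConfigurationError("need at least 4 channels")
    if n_sources < n_channels:
        raise ConfigurationError("need n_sources >= n_channels")
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        sensors = rng.standard_normal((n_channels, 3))
        sensors /= np.linalg.norm(sensors, axis=1, keepdims=True)
        sources = rng.standard_normal((n_sources, 3))
        sources = 0.7 * sources / np.linalg.norm(sources, axis=1, keepdims=True)
        sources *= rng.uniform(0.4, 1.0, size=(n_sources, 1))
        d = np.linalg.norm(sensors[:, None, :] - sources[None, :, :], axis=2)
        gain = 1.0 / (0.1 + d) ** 2
        gain *= rng.uniform(0.5, 1.5, size=(1, n_sources))
        if np.linalg.matrix_rank(gain) == n_channels:
            labels = [f"ch{c:02d}" for c in range(n_channels)]
            return Leadfield(gain, labels, sources)
    raise ConfigurationError("could not draw a full-rank leadfield")


def generate_clinical_scores(cohort: pd.DataFrame,
                             deviation_burden: Mapping[str, float],
                             truth: GroundTruthModel,
                             seed: int = 0) -> pd.DataFrame:
    """Fill patient UPDRS/MMSE linked monotonically to deviation burden.

    A latent score = link_strength * standardized burden + noise maps to
    UPDRS (increasing, clipped at 0) and MMSE (decreasing, integers 0-30).
    Healthy controls keep missing scores.
    """
    rng = np.random.default_rng(seed)
    out = cohort.copy()
    pat = out["group"].isin(["PD", "AD"])
    sids = out.loc[pat, "subject_id"].to_numpy()
    missing = [s for s in sids if s not in deviation_burden]
    if missing:
        raise ConfigurationError(
            f"deviation burden undefined for {len(missing)} patients")
    b = np.array([deviation_burden[s] for s in sids], float)
    sd = b.std()
    zb = (b - b.mean()) / (sd if sd > 0 else 1.0)
    latent_u = truth.score_link_strength * zb + truth.score_noise * rng.standard_normal(len(b))
    latent_m = truth.score_link_strength * zb + truth.score_noise * rng.standard_normal(len(b))
    updrs = np.clip(35.0 + 12.0 * latent_u, 0.0, None)
    mmse = np.clip(np.round(26.0 - 3.0 * latent_m), 0, 30)
    out.loc[pat, "updrs"] = updrs
    out.loc[pat, "mmse"] = mmse
    return out
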