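# Methods

## The model

`eegnorm` builds normative ("brain chart") models of EEG-derived features
across adult aging (40–92 years) and scores individual patients against
them. A feature — relative band power at a scalp electrode, or
orthogonalized amplitude-envelope correlation (AEC) between two cortical
regions, in one of five frequency bands — is treated as a response
variable y following a four-parameter distribution family

    y ~ F(μ, σ, ν, τ)

with each used parameter given its own linear predictor on a link scale
(identity for μ of symmetric families, log for positive-constrained
parameters, identity for skew ν):

    g_μ(μ) = X_μ β_μ,   g_σ(σ) = X_σ β_σ,   …

This is distributional (location–scale–shape) regression in the GAMLSS
sense. The μ design matrix holds an intercept, fractional-polynomial (FP)
terms in age, and optionally sex and site indicator columns; σ, ν, τ are
intercept-only by default (age terms in σ can be enabled). FP bases use
the standard power set {−2, −1, −0.5, 0, 0.5, 1, 2, 3}, power 0 meaning
log, a repeated power p contributing a^p·log a; age is divided by 100 so
power terms are well conditioned.

Candidate families: NO (normal), BCCG (Box–Cox Cole–Green / LMS), BCT
(Box–Cox t), BCPE (Box–Cox power exponential) and JSU (Johnson SU in its
original location/scale/skew/shape parameterization). The Box–Cox
families include the positive-support truncation adjustment in both
density and CDF, so quantile residuals remain exactly calibrated.

### Estimation and selection

All coefficients are estimated jointly by maximizing the exact
log-likelihood (L-BFGS on the link scale, method-of-moments starting
values plus random restarts; non-finite or overflowing parameter
proposals are rejected by barrier values). A fit is declared converged
when the optimizer reports success or the scaled gradient sup-norm falls
below 1e−3; fits that end below their initialization likelihood are
flagged non-converged and excluded from selection.

Model selection is by BIC = −2·loglik + k·log n throughout, in three
stages per feature: (1) FP powers for the age smooth are chosen with fast
normal-family fits (FP1 by default, FP2 optional) — fitting every family
at every power set would multiply cost for no selection benefit at this
noise level; (2) the family is chosen among the five candidates at the
selected powers; (3) sex, then site indicators are added to the μ
predictor and kept only when BIC decreases. Site enters as fixed-effect
indicators; random site effects are out of scope (a coherent marginal
likelihood would require an approximate-integration subsystem, and BIC
comparison across fixed-effect fits remains well defined).

### Deviation scores and overlap maps

A scored subject's z at one location/band is the normalized quantile
residual z = Φ⁻¹(F(y; μ̂, σ̂, ν̂, τ̂)) under the model fitted on the healthy
training sample only (80% of controls, split stratified by site and sex;
patients and held-out controls never enter any fit). For a continuous
response no randomization is involved. z is clipped at ±8, where
double-precision CDFs saturate. An extreme deviation is |z| > 2, with the
positive and negative tails tracked separately.

The overlap map of a group reports, per location, the percentage of
subjects with an extreme deviation there among the group's subjects with
at least one extreme deviation of that sign anywhere. That denominator is
the operative definition; a full-group denominator is available via an
option.

### Permutation inference

Group differences in overlap maps (patients vs held-out controls, per
band and sign) are tested by shuffling the case/control labels of the
subject-level masks; each iteration recomputes both overlap maps and
their difference, building a per-location null. Two-sided p-values use
the add-one convention, so p is never 0. Because the overlap statistic is
discrete (percentages over small integer denominators), ties between
|null| and |observed| carry real probability mass: counting them fully
makes the test visibly conservative (measured null rejection ≈ 0.02 at
nominal 0.05), while ignoring them would assign spuriously small p to
degenerate all-tied locations. The default is therefore the mid-p
convention (ties half-weighted), which measures ≈ 0.037 under an
exchangeable null at this scale; `tie_policy="conservative"` restores the
fully counted version. Benjamini–Hochberg FDR at 0.05 is applied per
contrast. Deviation counts between groups are compared with Mann–Whitney
U (exact enumeration for tie-free samples of ≤ 8 per group, tie-corrected
normal approximation otherwise).

### Clinical markers

The extreme deviations index (EDI) of a patient, per band and sign, is
the mean raw feature value over that patient's extremely deviated
locations; z-EDI averages the z-scores instead. A patient with no extreme
deviation of the requested sign has an undefined marker and is excluded
pairwise (imputing 0 would conflate absence of deviation with low
connectivity). Markers are Spearman-correlated with UPDRS and MMSE
(exact permutation p for n ≤ 7, t approximation otherwise); the scan is
reported uncorrected per cell, with an optional BH flag across cells.

## Signal-processing front end

Welch PSD: 1-s Hann segments, 50% overlap, per-segment mean removal,
zero-padded to 2·rate points before the FFT — the only way to honor a 1-s
window and a 0.5 Hz grid simultaneously — averaged within and then across
10-s, 200 Hz epochs. Relative band power integrates the PSD (rectangle
rule) over delta [1–4), theta [4–8), alpha [8–13), beta [13–30) and gamma
[30–45] Hz, divided by total [1–45] Hz power; the half-open edges (last
band closed) make the five bands a partition, so fractions sum to 1.
Montage reduction to the 19-channel 10–20 reference is pure selection and
renaming; a missing reference channel is an explicit error, never
silently interpolated.

Source connectivity: a scalar-orientation eLORETA inverse is built from a
supplied leadfield by the standard fixed-point iteration on per-source
weights, with identity noise covariance and Tikhonov term
λ·tr(L W⁻¹ Lᵀ)/n_ch·I (λ = 0.1 default; the trace-scaled convention is
recorded in output metadata). The resulting operator has the exact
zero-localization-error property for noiseless point sources, which the
tests exercise directly. Source series are averaged within atlas regions
(68 by default) without sign flipping — anti-phase sources cancel, and
that behavior is documented and tested rather than hidden. Per band,
region series are band-passed with a zero-phase FIR filter (Hamming
window, transition width 25% of the band edge; one filter length trimmed
from each end), Hilbert-transformed, pairwise-orthogonalized
(imag(Y·conj(X)/|X|), both directions averaged — the symmetrized
leakage correction), and the envelopes Pearson-correlated. Envelopes are
used linearly (no log transform). Epoch-level matrices are averaged
arithmetically, matching the PSD convention.

## The synthetic cohort generator

The generator is first-class code that emulates the statistical structure
the analysis assumes, so every stage is testable without recordings:

- **Cohort**: default 400 training controls, 99 held-out controls, 237 PD
  and 197 AD patients over 14 sites; ages truncated-normal (mean 65,
  sd 10, bounds 40–92), concentrating subjects in the 60–70 band as aging
  cohorts do; sex M with probability 0.46.
- **Features**: drawn from a configurable family with age-dependent
  location/scale (default: a mildly declining mean resembling relative
  alpha power, μ = 0.45 − 0.15·age/100, σ ≈ 0.05–0.07), additive sex and
  site effects on the μ link scale.
- **Patient heterogeneity**: each patient carries k deviant locations
  (default 5–10) whose draws are shifted on the latent standard-normal
  scale, y = Q_F(Φ(z + δ)); for a normal family this is exactly a
  δ-σ-unit shift, and for any family it preserves the analytic detection
  rate Φ(δ−2) + Φ(−δ−2) used as a test oracle. Deviant-location sets are
  drawn from an urn whose weights interpolate between uniform
  (overlap_concentration 0, maximally heterogeneous) and one fixed
  template set (1, fully shared).
- **Clinical scores**: a patient's deviation burden is the realized mean
  |z + δ| over their deviant cells; UPDRS increases and MMSE decreases
  in a latent Gaussian link with configurable strength and noise, then
  clip/round to instrument ranges (MMSE integers 0–30).
- **Raw signals**: 10-s epochs at 200 Hz of 1/f background plus
  narrowband oscillation carriers (alpha amplitude optionally declining
  with age); designated channel pairs share a slow (≤ 1 Hz) amplitude
  envelope on independent carriers — detectable by orthogonalized AEC but
  carrying no zero-lag component.
- **Leadfield**: distance-decayed sensitivities from random
  sensor/source geometry on nested spheres, full row rank by
  construction (with bounded redraws).

What the generator does **not** emulate: artifacts and their removal,
volume-conduction physics beyond the synthetic leadfield, spatial
autocorrelation of features, non-stationarity within epochs, or realistic
between-site covariance beyond additive μ offsets. Passing tests
therefore demonstrate the correctness and calibration of the machinery
under the stated generative assumptions, not clinical validity on real
recordings.

## Problem sizes and numerical choices

The reduced default study — 200 controls (160/40 split), 50 PD, 50 AD, 4
sites, 24 locations × 2 bands, FP1 search, 1000 permutations — runs in
about 40 s on one CPU; `PipelineConfig.paper_scale()` documents the
full-size settings (14 sites, 19 channels / 2278 connections, 5 bands,
5000 permutations). Optimizer: L-BFGS-B, ftol 1e−12, 1 restart in the
pipeline (3 in standalone fits). Centile curves are evaluated on a
27-point age grid; LOSO refits reuse each model's selected family, powers
and covariates and correlate median trajectories on a common grid.

Known limitations: when a feature's age trend is small relative to its
noise floor (as happens by construction for some synthetic locations),
the median trajectory is nearly flat and the Pearson correlation between
two nearly constant curves is sign-unstable — the minimum LOSO r can then
be meaningless even though trajectories agree to within a fraction of σ;
the acceptance report therefore lists the median alongside the minimum.
BIC-based family selection at n = 160–400 reliably separates NO from
strongly skewed alternatives but will not resolve subtle tail
differences; the full BIC table is retained per fit for audit.
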