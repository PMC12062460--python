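"""Location-scale-shape distributional regression with fractional-polynomial
age smooths.

The model: a response y (an EEG feature at one location and band) follows a
family F(mu, sigma, nu, tau); each used parameter gets its own linear
predictor on its link scale,

    g_mu(mu) = X_mu beta_mu,   g_sigma(sigma) = X_sigma beta_sigma, ...

where X_mu contains an intercept, fractional-polynomial (FP) terms in age,
and optional sex/site indicator columns. All coefficients are estimated
jointly by maximizing the exact log-likelihood with quasi-Newton iterations
from method-of-moments starting values (plus random restarts). Family and
covariates are chosen by BIC = -2 loglik + k log n.

Fractional polynomials use the standard power set {-2, -1, -0.5, 0, 0.5, 1,
2, 3} with power 0 meaning log(a) and a repeated power p contributing
a^p * log(a); ages are shifted/scaled to a strictly positive covariate
a = (age + shift) / scale before powering.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .families import Family, FamilyError, get_family

__all__ = [
    "FP_POWERS", "fp_basis", "build_fp_design", "fit_gamlss",
    "select_distribution", "select_covariates", "select_fp_powers",
    "centile_curves", "model_diagnostics", "NormativeModelFit", "FitError",
]

FP_POWERS: tuple[float, ...] = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0)

#: default age normalization: strictly positive and O(1) over 40-92 years
AGE_SHIFT = 0.0
AGE_SCALE = 100.0


class FitError(RuntimeError):
    pass


def _scaled_age(ages, shift=AGE_SHIFT, scale=AGE_SCALE):
    a = (np.asarray(ages, float) + shift) / scale
    if np.any(a <= 0):
        raise ValueError("scaled age must be strictly positive; adjust shift")
    return a


def fp_basis(ages, powers: Sequence[float], shift=AGE_SHIFT, scale=AGE_SCALE):
    """Fractional-polynomial columns for the given powers (no intercept).

    Power 0 is log(a); a power repeated m times contributes
    a^p * log(a)^j for j = 0..m-1 (the standard FP repetition rule).
    """
    a = _scaled_age(ages, shift, scale)
    cols = []
    seen: dict[float, int] = {}
    for p in powers:
        j = seen.get(p, 0)
        base = np.log(a) if p == 0 else a ** p
        cols.append(base * np.log(a) ** j if j else base)
        seen[p] = j + 1
    return np.column_stack(cols) if cols else np.empty((len(a), 0))


def build_fp_design(ages, powers: Sequence[float],
                    extra_covariates: Mapping[str, np.ndarray] | None = None,
                    shift=AGE_SHIFT, scale=AGE_SCALE):
    """Design matrix: intercept + FP(age) terms + indicator columns.

    Returns ``(X, names)``. Raises on rank deficiency, naming the columns.
    """
    n = len(np.asarray(ages))
    blocks = [np.ones((n, 1))]
    names = ["intercept"]
    B = fp_basis(ages, powers, shift, scale)
    for j, p in enumerate(powers):
        blocks.append(B[:, j:j + 1])
        names.append(f"age^{p:g}" if p != 0 else "log(age)")
    for key, col in (extra_covariates or {}).items():
        col = np.asarray(col, float).reshape(n, -1)
        blocks.append(col)
        names.extend([key] if col.shape[1] == 1 else
                     [f"{key}[{k}]" for k in range(col.shape[1])])
    X = np.hstack(blocks)
    if not np.all(np.isfinite(X)):
        raise ValueError("design matrix contains non-finite entries")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"rank-deficient design; columns: {names}")
    return X, names


@dataclass
class NormativeModelFit:
    """A fitted distributional regression for one feature.

    Coefficients live on the link scale; ``designs`` records the column
    names per parameter so new subjects can be scored.
    """

    family: str
    powers: tuple[float, ...]
    coef: dict[str, np.ndarray]
    column_names: dict[str, list[str]]
    loglik: float
    n: int
    converged: bool
    covariates: tuple[str, ...] = ()
    meta: dict = field(default_factory=dict)

    @property
    def k(self) -> int:
        return int(sum(len(v) for v in self.coef.values()))

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + self.k * np.log(self.n)

    def predict_params(self, designs: Mapping[str, np.ndarray]) -> list[np.ndarray]:
        fam = get_family(self.family)
        out = []
        for pname in fam.param_names:
            X = np.asarray(designs[pname], float)
            eta = X @ self.coef[pname]
            out.append(fam.link_inverse(pname, eta))
        return out

    def to_record(self) -> dict:
        rec = {
            "family": self.family,
            "powers": ",".join(f"{p:g}" for p in self.powers),
            "covariates": ",".join(self.covariates),
            "loglik": self.loglik, "bic": self.bic, "n": self.n,
            "converged": self.converged,
        }
        for pname, beta in self.coef.items():
            for name, b in zip(self.column_names[pname], beta):
                rec[f"beta_{pname}.{name}"] = b
        return rec


def _pack(coefs: Sequence[np.ndarray]) -> np.ndarray:
    return np.concatenate([np.asarray(c, float).ravel() for c in coefs])


def _unpack(theta: np.ndarray, sizes: Sequence[int]) -> list[np.ndarray]:
    out, i = [], 0
    for s in sizes:
        out.append(theta[i:i + s])
        i += s
    return out


def fit_gamlss(y, designs: Mapping[str, np.ndarray], family: Family | str,
               n_restarts: int = 3, seed: int = 0, powers=(),
               covariates=(), column_names=None) -> NormativeModelFit:
    """Maximum-likelihood fit of all link-scale coefficients jointly.

    ``designs`` maps parameter name -> design matrix; omitted parameters get
    an intercept-only column. Multi-start: method-of-moments initialization
    plus ``n_restarts`` perturbed starts; the best finite optimum wins.
    """
    fam = get_family(family) if isinstance(family, str) else family
    y = np.asarray(y, float)
    n = y.size
    if not fam.check_support(y):
        raise FitError(f"response outside {fam.name} support")

    X = {}
    for pname in fam.param_names:
        M = np.asarray(designs.get(pname, np.ones((n, 1))), float)
        if M.ndim == 1:
            M = M.reshape(-1, 1)
        X[pname] = M
    sizes = [X[p].shape[1] for p in fam.param_names]
    k_total = sum(sizes)
    if n <= k_total:
        raise FitError(f"n={n} too small for {k_total} coefficients")

    def nll(theta):
        betas = _unpack(theta, sizes)
        params = []
        try:
            for pname, beta in zip(fam.param_names, betas):
                eta = X[pname] @ beta
                if np.any(np.abs(eta) > 50):  # guard exp overflow on log links
                    return 1e12
                params.append(fam.link_inverse(pname, eta))
            ll = fam.logpdf(y, params)
        except (FamilyError, FloatingPointError):
            return 1e12
        if not np.all(np.isfinite(ll)):
            return 1e12
        return -float(np.sum(ll))

    init_nat = fam.initial_params(y)
    theta0 = np.zeros(k_total)
    offset = 0
    for pname, nat, s in zip(fam.param_names, init_nat, sizes):
        theta0[offset] = fam.link(pname, nat)
        offset += s

    rng = np.random.default_rng(seed)
    starts = [theta0]
    for _ in range(n_restarts):
        starts.append(theta0 + rng.normal(scale=0.3, size=k_total))

    best = None
    for s0 in starts:
        res = optimize.minimize(nll, s0, method="L-BFGS-B",
                                options={"maxiter": 500, "ftol": 1e-12,
                                         "gtol": 1e-8})
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None

    f0 = nll(theta0)
    ll = -best.fun
    grad = best.jac if best.jac is not None else np.array([np.inf])
    gnorm = float(np.max(np.abs(grad)))
    converged = bool(
        np.isfinite(ll) and best.fun < 1e11
        and (best.success or gnorm < 1e-3 * max(1.0, abs(best.fun))))
    # likelihood at optimum must not fall below the initialization
    if converged and best.fun > f0 + 1e-6:
        converged = False

    betas = _unpack(best.x, sizes)

    def _default_names(p):
        m = X[p].shape[1]
        return ["intercept"] if m == 1 else [f"c{j}" for j in range(m)]

    colnames = dict(column_names or {})
    for p in fam.param_names:
        colnames.setdefault(p, _default_names(p))
    return NormativeModelFit(
        family=fam.name, powers=tuple(powers),
        coef={p: np.asarray(b) for p, b in zip(fam.param_names, betas)},
        column_names={p: list(colnames[p]) for p in fam.param_names},
        loglik=float(ll), n=n, converged=converged, covariates=tuple(covariates),
        meta={"grad_norm": gnorm})


def select_distribution(y, designs, candidates: Iterable[str | Family],
                        seed: int = 0, **kw) -> NormativeModelFit:
    """Fit every candidate family and return the lowest-BIC converged fit.

    The full BIC table is kept in ``fit.meta['bic_table']``.
    """
    fits, table = [], []
    for cand in candidates:
        fam = get_family(cand) if isinstance(cand, str) else cand
        try:
            f = fit_gamlss(y, designs, fam, seed=seed, **kw)
        except FitError:
            table.append((fam.name, np.nan, False))
            continue
        table.append((fam.name, f.bic, f.converged))
        if f.converged:
            fits.append(f)
    if not fits:
        raise FitError("no candidate family converged")
    best = min(fits, key=lambda f: f.bic)
    best.meta["bic_table"] = table
    return best


def select_fp_powers(y, ages, family: Family | str = "NO",
                     max_degree: int = 2, seed: int = 0,
                     extra=None) -> tuple[float, ...]:
    """Choose FP powers for the mu predictor by BIC.

    Searches FP1 over the 8-power set and (``max_degree`` >= 2) FP2 over
    unordered pairs with repetition, fitting the given (fast) family with
    intercept-only sigma.
    """
    cands: list[tuple[float, ...]] = [(p,) for p in FP_POWERS]
    if max_degree >= 2:
        cands += [tuple(c) for c in
                  itertools.combinations_with_replacement(FP_POWERS, 2)]
    best_bic, best = np.inf, (1.0,)
    for pw in cands:
        try:
            X, names = build_fp_design(ages, pw, extra)
            f = fit_gamlss(y, {"mu": X}, family, n_restarts=0, seed=seed,
                           powers=pw)
        except (ValueError, FitError):
            continue
        if f.converged and f.bic < best_bic:
            best_bic, best = f.bic, pw
    return best


def select_covariates(y, ages, powers, optional: Mapping[str, np.ndarray],
                      family="NO", order=("sex", "site"), seed: int = 0,
                      **kw) -> NormativeModelFit:
    """Greedy sequential covariate inclusion on the mu predictor.

    Age FP terms are always present; each optional covariate (in ``order``)
    is kept iff adding its indicator column(s) lowers BIC.
    """
    kept: dict[str, np.ndarray] = {}
    chosen: list[str] = []

    def _fit(extra):
        X, names = build_fp_design(ages, powers, extra)
        return fit_gamlss(y, {"mu": X}, family, powers=powers, seed=seed,
                          covariates=tuple(chosen),
                          column_names={"mu": names}, **kw)

    current = _fit(kept or None)
    for name in order:
        if name not in optional:
            continue
        trial = dict(kept)
        trial[name] = optional[name]
        try:
            cand = _fit(trial)
        except (ValueError, FitError):
            continue
        if cand.converged and cand.bic < current.bic:
            kept = trial
            chosen.append(name)
            cand.covariates = tuple(chosen)
            current = cand
    return current


def centile_curves(fit: NormativeModelFit, age_grid,
                   percentiles=(5, 50, 95), reference_covariates=None,
                   age_range=None):
    """Centile trajectories over an age grid at reference covariate levels.

    Returns a dict with the grid, one curve per percentile, and an
    ``extrapolated`` flag array when ``age_range`` (the fitted range) is
    given. Covariate columns absent from ``reference_covariates`` are set
    to 0 (the reference level).
    """
    fam = get_family(fit.family)
    age_grid = np.asarray(age_grid, float)
    ref = reference_covariates or {}
    designs = {}
    for pname in fam.param_names:
        names = fit.column_names[pname]
        cols = []
        for nm in names:
            if nm == "intercept":
                cols.append(np.ones_like(age_grid))
            elif nm.startswith("age^") or nm == "log(age)":
                p = 0.0 if nm == "log(age)" else float(nm.split("^")[1])
                cols.append(fp_basis(age_grid, (p,)).ravel())
            else:
                cols.append(np.full_like(age_grid, float(ref.get(nm, 0.0))))
        # repeated powers need the joint basis, rebuild if duplicates present
        fp_names = [nm for nm in names if nm.startswith("age^") or nm == "log(age)"]
        if len(fp_names) != len(set(fp_names)):
            pw = [0.0 if nm == "log(age)" else float(nm.split("^")[1])
                  for nm in fp_names]
            B = fp_basis(age_grid, pw)
            j = 0
            for i, nm in enumerate(names):
                if nm in fp_names:
                    cols[i] = B[:, j]
                    j += 1
        designs[pname] = np.column_stack(cols)
    params = fit.predict_params(designs)
    out = {"age": age_grid}
    for p in percentiles:
        out[f"p{p:g}"] = fam.ppf(np.full_like(age_grid, p / 100.0), params)
    if age_range is not None:
        lo, hi = age_range
        out["extrapolated"] = (age_grid < lo) | (age_grid > hi)
    return out


def quantile_residuals(fit: NormativeModelFit, y, designs, clip=8.0):
    """Normalized quantile residuals z = Phi^-1(F(y; theta_hat)).

    Parameters missing from ``designs`` default to intercept-only columns.
    """
    fam = get_family(fit.family)
    n = np.asarray(y).size
    designs = {p: designs.get(p, np.ones((n, 1))) for p in fam.param_names}
    params = fit.predict_params(designs)
    u = np.clip(fam.cdf(np.asarray(y, float), params),
                stats.norm.cdf(-clip), stats.norm.cdf(clip))
    return np.clip(stats.norm.ppf(u), -clip, clip)


def filliben_correlation(z):
    """Correlation of sorted residuals with normal order-statistic medians."""
    z = np.sort(np.asarray(z, float))
    n = z.size
    m = np.empty(n)
    i = np.arange(1, n + 1)
    m[:] = (i - 0.3175) / (n + 0.365)
    m[0] = 1 - 0.5 ** (1.0 / n)
    m[-1] = 0.5 ** (1.0 / n)
    q = stats.norm.ppf(m)
    return float(np.corrcoef(z, q)[0, 1])


def model_diagnostics(fit: NormativeModelFit, y, designs) -> dict:
    """Residual summary for a converged fit.

    Reports moments of the quantile residuals, the Filliben Q-Q
    correlation, and the correlation of |residual| with the fitted mu
    (a flat-scale check).
    """
    if not fit.converged:
        raise FitError("diagnostics require a converged fit")
    z = quantile_residuals(fit, y, designs)
    fam = get_family(fit.family)
    n = np.asarray(y).size
    designs = {p: designs.get(p, np.ones((n, 1))) for p in fam.param_names}
    mu_hat = fit.predict_params(designs)[0]
    mu_b = np.broadcast_to(np.asarray(mu_hat, float), z.shape)
    scale_corr = (0.0 if np.ptp(mu_b) < 1e-12 else
                  float(np.corrcoef(np.abs(z), mu_b)[0, 1]))
    return {
        "mean": float(np.mean(z)),
        "variance": float(np.var(z)),
        "skewness": float(stats.skew(z)),
        "excess_kurtosis": float(stats.kurtosis(z)),
        "filliben": filliben_correlation(z),
        "abs_resid_vs_fitted_corr": scale_corr,
        "n": int(z.size),
    }
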