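"""Distribution families for location-scale-shape regression.

Each family exposes the response distribution F(mu, sigma, nu, tau) through
``logpdf``, ``cdf`` and ``ppf``, together with the link functions that map
each parameter onto an unconstrained scale for optimization:

* ``NO``   — normal: mu (identity), sigma (log).
* ``BCCG`` — Box-Cox Cole-Green (the LMS model): a power transform of a
  positive response to a truncated standard normal; mu (log), sigma (log),
  nu (identity).
* ``BCT``  — Box-Cox t: as BCCG but with a truncated Student-t kernel and a
  tail parameter tau (log).
* ``BCPE`` — Box-Cox power exponential: power-exponential kernel, kurtosis
  parameter tau (log).
* ``JSU``  — Johnson SU in its original parameterization: location mu
  (identity), scale sigma (log), skew nu (identity), shape tau (log).

The Box-Cox families apply the usual truncation adjustment so that the CDF
integrates to one on the positive half-line.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import special, stats

__all__ = ["Family", "get_family", "FAMILIES", "FamilyError"]

_SQRT2PI = np.sqrt(2.0 * np.pi)


class FamilyError(ValueError):
    """Raised for unknown family ids or out-of-domain parameters."""


# ---------------------------------------------------------------------------
# link functions


def _identity(x):
    return np.asarray(x, dtype=float)


def _log(x):
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise FamilyError("log link requires a strictly positive parameter")
    return np.log(x)


def _exp(x):
    return np.exp(np.asarray(x, dtype=float))


LINKS: dict[str, tuple[Callable, Callable]] = {
    "identity": (_identity, _identity),
    "log": (_log, _exp),
}


# ---------------------------------------------------------------------------
# Box-Cox transform helpers


def _bc_z(y, mu, sigma, nu):
    """Box-Cox transform z of a positive response (vectorized in y)."""
    y, mu, sigma, nu = np.broadcast_arrays(
        np.asarray(y, float), np.asarray(mu, float),
        np.asarray(sigma, float), np.asarray(nu, float))
    r = y / mu
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(
            np.abs(nu) > 1e-12,
            (np.power(r, nu) - 1.0) / (sigma * np.where(np.abs(nu) > 1e-12, nu, 1.0)),
            np.log(r) / sigma,
        )
    return z


def _bc_inv(z, mu, sigma, nu):
    """Inverse Box-Cox transform: z -> y."""
    z, mu, sigma, nu = np.broadcast_arrays(
        np.asarray(z, float), np.asarray(mu, float),
        np.asarray(sigma, float), np.asarray(nu, float))
    small = np.abs(nu) <= 1e-12
    base = 1.0 + sigma * np.where(small, 1.0, nu) * z
    base = np.maximum(base, 1e-300)
    with np.errstate(over="ignore"):
        y = np.where(
            small,
            mu * np.exp(sigma * z),
            mu * np.power(base, 1.0 / np.where(small, 1.0, nu)),
        )
    return y


@dataclass(frozen=True)
class Family:
    """A response distribution with per-parameter link functions.

    ``param_names`` lists the distribution parameters actually used (2-4 of
    mu, sigma, nu, tau); ``links`` maps parameter name -> link id in LINKS.
    ``positive_support`` marks families defined on y > 0 only.
    """

    name: str
    param_names: tuple[str, ...]
    links: dict[str, str] = field(hash=False)
    positive_support: bool
    _logpdf: Callable = field(repr=False, hash=False)
    _cdf: Callable = field(repr=False, hash=False)
    _ppf: Callable = field(repr=False, hash=False)
    _init: Callable = field(repr=False, hash=False)

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def link(self, name: str, value):
        return LINKS[self.links[name]][0](value)

    def link_inverse(self, name: str, eta):
        return LINKS[self.links[name]][1](eta)

    def _full(self, params: Sequence) -> tuple:
        """Pad the used parameters out to (mu, sigma, nu, tau)."""
        p = list(params) + [None] * (4 - len(params))
        return tuple(p)

    def check_support(self, y) -> bool:
        y = np.asarray(y, float)
        if self.positive_support:
            return bool(np.all(y > 0))
        return bool(np.all(np.isfinite(y)))

    def logpdf(self, y, params: Sequence):
        if len(params) != self.n_params:
            raise FamilyError(
                f"{self.name} takes {self.n_params} parameters, got {len(params)}")
        return self._logpdf(np.asarray(y, float), *params)

    def pdf(self, y, params: Sequence):
        return np.exp(self.logpdf(y, params))

    def cdf(self, y, params: Sequence):
        if len(params) != self.n_params:
            raise FamilyError(
                f"{self.name} takes {self.n_params} parameters, got {len(params)}")
        return self._cdf(np.asarray(y, float), *params)

    def ppf(self, p, params: Sequence):
        if len(params) != self.n_params:
            raise FamilyError(
                f"{self.name} takes {self.n_params} parameters, got {len(params)}")
        p = np.asarray(p, float)
        if np.any((p <= 0) | (p >= 1)):
            raise FamilyError("quantile probabilities must lie in (0, 1)")
        return self._ppf(p, *params)

    def initial_params(self, y) -> list:
        """Method-of-moments starting values on the natural scale."""
        return self._init(np.asarray(y, float))


# ---------------------------------------------------------------------------
# NO — normal


def _no_logpdf(y, mu, sigma):
    return stats.norm.logpdf(y, loc=mu, scale=sigma)


def _no_cdf(y, mu, sigma):
    return stats.norm.cdf(y, loc=mu, scale=sigma)


def _no_ppf(p, mu, sigma):
    return stats.norm.ppf(p, loc=mu, scale=sigma)


def _no_init(y):
    return [float(np.mean(y)), float(max(np.std(y), 1e-8))]


# ---------------------------------------------------------------------------
# BCCG / BCT / BCPE — Box-Cox families with different kernels
#
# Each kernel supplies (logpdf, cdf, ppf) of the standardized variable z.
# The truncation constant is C = P(z < 1/(sigma*|nu|)); for nu > 0 the
# support is z > -1/(sigma*nu) and the CDF is shifted accordingly.


def _bc_logpdf(kernel_logpdf, kernel_cdf, y, mu, sigma, nu, *shape):
    z = _bc_z(y, mu, sigma, nu)
    lo = 1.0 / (np.asarray(sigma, float) * np.maximum(np.abs(np.asarray(nu, float)), 1e-12))
    logC = np.log(np.clip(kernel_cdf(lo, *shape), 1e-300, 1.0))
    # Jacobian of the Box-Cox transform: y^(nu-1) / (mu^nu * sigma)
    logjac = (np.asarray(nu, float) - 1.0) * np.log(y) \
        - np.asarray(nu, float) * np.log(np.asarray(mu, float)) \
        - np.log(np.asarray(sigma, float))
    out = kernel_logpdf(z, *shape) + logjac - logC
    return np.where(np.asarray(y, float) > 0, out, -np.inf)


def _bc_cdf(kernel_cdf, y, mu, sigma, nu, *shape):
    z = _bc_z(y, mu, sigma, nu)
    nu_b = np.broadcast_to(np.asarray(nu, float), z.shape)
    sig_b = np.broadcast_to(np.asarray(sigma, float), z.shape)
    lo = 1.0 / (sig_b * np.maximum(np.abs(nu_b), 1e-12))
    C = np.clip(kernel_cdf(lo, *shape), 1e-300, 1.0)
    F = kernel_cdf(z, *shape)
    low_trunc = np.clip(kernel_cdf(-lo, *shape), 0.0, 1.0)
    out = np.where(nu_b > 1e-12, (F - low_trunc) / C, F / C)
    return np.clip(out, 0.0, 1.0)


def _bc_ppf(kernel_cdf, kernel_ppf, p, mu, sigma, nu, *shape):
    p = np.asarray(p, float)
    nu_b = np.broadcast_to(np.asarray(nu, float), np.broadcast_shapes(p.shape, np.shape(nu)))
    sig_b = np.broadcast_to(np.asarray(sigma, float), nu_b.shape)
    p_b = np.broadcast_to(p, nu_b.shape)
    lo = 1.0 / (sig_b * np.maximum(np.abs(nu_b), 1e-12))
    C = np.clip(kernel_cdf(lo, *shape), 1e-300, 1.0)
    low_trunc = np.clip(kernel_cdf(-lo, *shape), 0.0, 1.0)
    target = np.where(nu_b > 1e-12, p_b * C + low_trunc, p_b * C)
    z = kernel_ppf(np.clip(target, 1e-300, 1 - 1e-16), *shape)
    return _bc_inv(z, mu, sigma, nu)


# power-exponential kernel standardized to unit variance (gamlss PE convention)


def _pe_c(tau):
    tau = np.asarray(tau, float)
    lg = special.gammaln(1.0 / tau) - special.gammaln(3.0 / tau)
    return np.sqrt(np.exp(lg) * np.power(2.0, -2.0 / tau))


def _pe_logpdf(z, tau):
    tau = np.asarray(tau, float)
    with np.errstate(all="ignore"):  # extreme tau handled by fit guards
        c = _pe_c(tau)
        return (np.log(tau) - np.abs(z / c) ** tau / 2.0
                - np.log(c) - (1.0 + 1.0 / tau) * np.log(2.0)
                - special.gammaln(1.0 / tau))


def _pe_cdf(z, tau):
    tau = np.asarray(tau, float)
    with np.errstate(all="ignore"):
        c = _pe_c(tau)
        s = np.abs(np.asarray(z, float) / c) ** tau / 2.0
        g = special.gammainc(1.0 / tau, s)
    return 0.5 * (1.0 + np.sign(z) * g)


def _pe_ppf(p, tau):
    tau = np.asarray(tau, float)
    c = _pe_c(tau)
    p = np.asarray(p, float)
    s = special.gammaincinv(1.0 / tau, np.abs(2.0 * p - 1.0))
    return np.sign(p - 0.5) * c * np.power(2.0 * s, 1.0 / tau)


def _bc_init(y, extra):
    y = np.asarray(y, float)
    mu = float(np.median(y))
    sigma = float(max(np.std(np.log(np.maximum(y, 1e-300))), 1e-6))
    return [max(mu, 1e-8), sigma, 0.5] + extra


def _bccg_logpdf(y, mu, sigma, nu):
    return _bc_logpdf(stats.norm.logpdf, lambda z: stats.norm.cdf(z), y, mu, sigma, nu)


def _bccg_cdf(y, mu, sigma, nu):
    return _bc_cdf(lambda z: stats.norm.cdf(z), y, mu, sigma, nu)


def _bccg_ppf(p, mu, sigma, nu):
    return _bc_ppf(lambda z: stats.norm.cdf(z), lambda q: stats.norm.ppf(q),
                   p, mu, sigma, nu)


def _bct_logpdf(y, mu, sigma, nu, tau):
    return _bc_logpdf(lambda z, t: stats.t.logpdf(z, df=t),
                      lambda z, t: stats.t.cdf(z, df=t), y, mu, sigma, nu, tau)


def _bct_cdf(y, mu, sigma, nu, tau):
    return _bc_cdf(lambda z, t: stats.t.cdf(z, df=t), y, mu, sigma, nu, tau)


def _bct_ppf(p, mu, sigma, nu, tau):
    return _bc_ppf(lambda z, t: stats.t.cdf(z, df=t),
                   lambda q, t: stats.t.ppf(q, df=t), p, mu, sigma, nu, tau)


def _bcpe_logpdf(y, mu, sigma, nu, tau):
    return _bc_logpdf(_pe_logpdf, _pe_cdf, y, mu, sigma, nu, tau)


def _bcpe_cdf(y, mu, sigma, nu, tau):
    return _bc_cdf(_pe_cdf, y, mu, sigma, nu, tau)


def _bcpe_ppf(p, mu, sigma, nu, tau):
    return _bc_ppf(_pe_cdf, _pe_ppf, p, mu, sigma, nu, tau)


# ---------------------------------------------------------------------------
# JSU — Johnson SU (original parameterization)


def _jsu_logpdf(y, mu, sigma, nu, tau):
    return stats.johnsonsu.logpdf(y, a=nu, b=tau, loc=mu, scale=sigma)


def _jsu_cdf(y, mu, sigma, nu, tau):
    return stats.johnsonsu.cdf(y, a=nu, b=tau, loc=mu, scale=sigma)


def _jsu_ppf(p, mu, sigma, nu, tau):
    return stats.johnsonsu.ppf(p, a=nu, b=tau, loc=mu, scale=sigma)


def _jsu_init(y):
    return [float(np.median(y)), float(max(np.std(y), 1e-8)), 0.0, 1.5]


FAMILIES: dict[str, Family] = {
    "NO": Family("NO", ("mu", "sigma"),
                 {"mu": "identity", "sigma": "log"}, False,
                 _no_logpdf, _no_cdf, _no_ppf, _no_init),
    "BCCG": Family("BCCG", ("mu", "sigma", "nu"),
                   {"mu": "log", "sigma": "log", "nu": "identity"}, True,
                   _bccg_logpdf, _bccg_cdf, _bccg_ppf,
                   lambda y: _bc_init(y, [])),
    "BCT": Family("BCT", ("mu", "sigma", "nu", "tau"),
                  {"mu": "log", "sigma": "log", "nu": "identity", "tau": "log"}, True,
                  _bct_logpdf, _bct_cdf, _bct_ppf,
                  lambda y: _bc_init(y, [10.0])),
    "BCPE": Family("BCPE", ("mu", "sigma", "nu", "tau"),
                   {"mu": "log", "sigma": "log", "nu": "identity", "tau": "log"}, True,
                   _bcpe_logpdf, _bcpe_cdf, _bcpe_ppf,
                   lambda y: _bc_init(y, [2.0])),
    "JSU": Family("JSU", ("mu", "sigma", "nu", "tau"),
                  {"mu": "identity", "sigma": "log", "nu": "identity", "tau": "log"},
                  False, _jsu_logpdf, _jsu_cdf, _jsu_ppf, _jsu_init),
}


def get_family(name: str) -> Family:
    try:
        return FAMILIES[name.upper()]
    except KeyError:
        raise FamilyError(
            f"unknown family {name!r}; available: {sorted(FAMILIES)}") from None
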