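"""Maximum-likelihood estimation for plain, hurdle, and zero-inflated models.

Estimation strategy
-------------------
* Plain baselines with closed-form MLEs (normal, log-normal, half-normal,
  exponential, Poisson, geometric) are solved directly; the remaining count
  families (negative binomial, beta binomial, beta negative binomial) use
  bounded quasi-Newton optimization (L-BFGS-B on log-parameters) with
  multiple restarts from jittered moment-based initial values.
* Hurdle models factorize: ``phi_hat = n0 / N`` and the non-zero part is the
  baseline MLE on the non-zero values (continuous) or the zero-truncated MLE
  maximizing ``sum_{y != 0} [log f_theta(y) - log(1 - p0(theta))]`` (discrete).
* Zero-inflated models profile phi out of the likelihood.  For fixed theta
  the zero-inflated log-likelihood

      n0 log(phi + (1 - phi) p0) + (N - n0) log(1 - phi) + sum_{y!=0} log f

  is maximized at ``phi*(theta) = clip((n0/N - p0) / (1 - p0), 0, 1)``.  When
  the profiled phi is interior the theta-part of the profiled likelihood is
  exactly the zero-truncated likelihood, so the joint MLE is either the
  truncated-MLE theta with its profiled phi, or the plain-baseline MLE with
  phi = 0; the better of the two is returned.  Boundary solutions (phi = 0)
  are therefore representable, and phi is still counted in k.
* Continuous baselines have p0 = 0, so the zero-inflated fit delegates to the
  hurdle fit (the two structures are the same distribution).

The convention ``0 * log 0 := 0`` applies wherever phi or 1 - phi vanishes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .families import (
    BASELINES,
    ModelFamily,
    ParamVector,
    ParameterError,
    log_density,
    parse_family,
)

__all__ = [
    "FitResult",
    "EstimationError",
    "fit_baseline",
    "fit_hurdle",
    "fit_zi",
    "fit_model",
    "log_likelihood",
]

_LOWER = 1e-10
_UPPER = 1e5


class EstimationError(RuntimeError):
    """Raised when a sample cannot be fitted by the requested family."""


@dataclass
class FitResult:
    """MLE of one model on one sample, with log-likelihood and AIC/BIC."""

    family: ModelFamily
    params: ParamVector
    loglik: float
    k: int
    n: int
    converged: bool = True
    n_restarts_used: int = 0
    aic: float = field(init=False)
    bic: float = field(init=False)

    def __post_init__(self):
        self.aic = -2.0 * self.loglik + 2.0 * self.k
        self.bic = -2.0 * self.loglik + math.log(self.n) * self.k

    def to_dict(self) -> dict:
        return {
            "family": self.family.code,
            "baseline": self.family.baseline,
            "structure": self.family.structure,
            "params": self.params.as_dict(),
            "loglik": self.loglik,
            "k": self.k,
            "N": self.n,
            "aic": self.aic,
            "bic": self.bic,
            "converged": self.converged,
            "n_restarts_used": self.n_restarts_used,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


def log_likelihood(family, params, values) -> float:
    """Sum of model log-density over the sample (0 * log 0 := 0 at the atom)."""
    family = parse_family(family)
    values = np.asarray(values, dtype=float)
    ll = log_density(family, params, values)
    # the hurdle/ZI atom contributes 0 when phi (resp. zero mass) is 0 and
    # there are no zeros; -inf terms only arise for genuinely impossible data
    return float(np.sum(ll))


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _validate_sample(values, baseline: str) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size == 0:
        raise EstimationError("sample must be a non-empty 1-D array")
    if not np.all(np.isfinite(values)):
        raise EstimationError("sample contains non-finite values")
    b = BASELINES[baseline]
    if b.discrete:
        if np.any(values != np.floor(values)) or np.any(values < 0):
            raise EstimationError(
                f"{baseline}: sample must contain non-negative integers"
            )
    return values


def _jitter(x0: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    return x0 * np.exp(rng.normal(0.0, 0.4, size=x0.shape))


def _maximize(negll, inits, bounds, n_restarts: int, rng) -> tuple:
    """L-BFGS-B on log-parameters from several starting points."""
    log_bounds = [(math.log(lo), math.log(hi)) for lo, hi in bounds]

    def f(z):
        with np.errstate(over="ignore", invalid="ignore"):
            v = negll(np.exp(z))
        if not np.isfinite(v):
            return 1e12
        return v

    best = None
    starts = [np.asarray(x, dtype=float) for x in inits]
    while len(starts) < max(n_restarts, len(inits)):
        starts.append(_jitter(starts[0], rng))
    n_used = 0
    for x0 in starts:
        z0 = np.log(np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds]))
        res = optimize.minimize(f, z0, method="L-BFGS-B", bounds=log_bounds)
        n_used += 1
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise EstimationError("numerical likelihood maximization failed")
    return np.exp(best.x), -float(best.fun), bool(best.success), n_used


def _counts(values: np.ndarray) -> tuple:
    u, c = np.unique(values, return_counts=True)
    return u, c.astype(float)


# ---------------------------------------------------------------------------
# plain-baseline MLEs
# ---------------------------------------------------------------------------


def _moment_inits(baseline: str, values: np.ndarray) -> list:
    m = float(np.mean(values))
    v = float(np.var(values))
    if baseline == "negative-binomial":
        if v > m > 0:
            r0 = m * m / (v - m)
            p0_ = m / v
        else:
            r0, p0_ = 10.0, 0.5
        return [[max(r0, 0.1), min(max(p0_, 0.01), 0.99)]]
    if baseline == "beta-binomial":
        nmax = float(np.max(values))
        return [[max(2.0 * m, nmax + 1.0), 2.0, 2.0], [nmax + 2.0, 1.0, 1.0]]
    if baseline == "beta-negative-binomial":
        return [[max(m, 1.0), 3.0, 3.0], [5.0, 2.0, 5.0]]
    raise AssertionError(baseline)


def _numeric_bounds(baseline: str, values: np.ndarray, bounds) -> list:
    b = BASELINES[baseline]
    out = [(_LOWER, _UPPER)] * len(b.param_names)
    if baseline == "beta-binomial":
        # n >= max(y) keeps every observation inside the support and the
        # generalized likelihood bounded (it diverges on n - y + beta -> 0+)
        out[0] = (max(float(np.max(values)), 1.0), _UPPER)
    if baseline == "negative-binomial":
        out[1] = (1e-8, 1.0 - 1e-8)
    if bounds is not None:
        out = [tuple(bd) for bd in bounds]
    return out


def _fit_plain_theta(values, baseline, init, bounds, n_restarts, rng):
    """MLE of the plain baseline; returns (theta, loglik, converged, restarts)."""
    b = BASELINES[baseline]
    n = values.size
    if baseline == "normal":
        if np.unique(values).size < 2:
            raise EstimationError("normal: need >= 2 distinct values")
        mu = float(np.mean(values))
        sigma = float(np.sqrt(np.mean((values - mu) ** 2)))
        theta = {"mu": mu, "sigma": sigma}
    elif baseline == "lognormal":
        if np.any(values < 0):
            raise EstimationError("lognormal: values must be >= 0")
        pos = values[values > 0]
        if np.unique(pos).size < 2:
            raise EstimationError("lognormal: need >= 2 distinct positive values")
        ly = np.log(pos)
        mu = float(np.mean(ly))
        sigma = float(np.sqrt(np.mean((ly - mu) ** 2)))
        theta = {"mu": mu, "sigma": sigma}
        if pos.size < n:
            # zeros are impossible under a plain log-normal: parameters come
            # from the positive part, the data log-likelihood is -inf, and a
            # KS test against this fit rejects through the unmatched atom
            return theta, -np.inf, True, 0
    elif baseline == "halfnormal":
        if np.any(values < 0):
            raise EstimationError("halfnormal: values must be >= 0")
        s2 = float(np.mean(values**2))
        if s2 <= 0:
            raise EstimationError("halfnormal: degenerate all-zero sample")
        theta = {"sigma": float(np.sqrt(s2))}
    elif baseline == "exponential":
        if np.any(values < 0):
            raise EstimationError("exponential: values must be >= 0")
        m = float(np.mean(values))
        if m <= 0:
            raise EstimationError("exponential: degenerate all-zero sample")
        theta = {"lambda": 1.0 / m}
    elif baseline == "poisson":
        m = float(np.mean(values))
        theta = {"lambda": max(m, _LOWER)}
    elif baseline == "geometric":
        m = float(np.mean(values))
        p = 1.0 / (1.0 + m)
        theta = {"p": min(max(p, 1e-8), 1.0 - 1e-8)}
    else:
        names = b.param_names
        u, c = _counts(values)
        ymax = float(np.max(values))

        def negll(x):
            theta_x = dict(zip(names, x))
            return -float(np.sum(c * b.logpmf(u, theta_x)))

        inits = _moment_inits(baseline, values)
        if init is not None:
            inits = [[init[p] for p in names]] + inits
        nb_bounds = _numeric_bounds(baseline, values, bounds)
        x, ll, ok, used = _maximize(negll, inits, nb_bounds, n_restarts, rng)
        return dict(zip(names, x)), ll, ok, used
    ll = log_likelihood(ModelFamily(baseline), {**theta}, values)
    return theta, ll, True, 0


def fit_baseline(values, baseline, init=None, bounds=None, n_restarts=3, seed=None):
    """MLE of a plain baseline distribution.

    Parameters
    ----------
    values : array-like of non-negative reals (non-negative integers for
        discrete baselines; normal baseline accepts any reals)
    baseline : family name (long form or short code)
    init : optional dict of starting values for numerically fitted families
    bounds : optional per-parameter (lower, upper) bounds, default
        ``[1e-10, 1e5]`` for positive parameters
    """
    fam = parse_family(baseline)
    if fam.structure != "plain":
        raise ParameterError("fit_baseline expects a plain baseline family")
    values = _validate_sample(values, fam.baseline)
    rng = np.random.default_rng(seed)
    theta, ll, ok, used = _fit_plain_theta(
        values, fam.baseline, init, bounds, n_restarts, rng
    )
    return FitResult(
        family=fam,
        params=ParamVector(theta=theta),
        loglik=ll,
        k=fam.k,
        n=values.size,
        converged=ok,
        n_restarts_used=used,
    )


# ---------------------------------------------------------------------------
# zero-truncated MLE (discrete non-zero part)
# ---------------------------------------------------------------------------


def _fit_truncated_theta(nonzero, baseline, init, bounds, n_restarts, rng):
    """Maximize sum log f_theta(y) - M log(1 - p0(theta)) over theta."""
    b = BASELINES[baseline]
    names = b.param_names
    u, c = _counts(nonzero)
    M = float(np.sum(c))

    if baseline == "geometric":
        # truncated geometric on {1, 2, ...} is a shifted geometric
        m = float(np.mean(nonzero))
        p = min(max(1.0 / m, 1e-8), 1.0 - 1e-8)
        theta = {"p": p}
        ll = float(np.sum(c * b.logpmf(u, theta)) - M * np.log1p(-b.p0(theta)))
        return theta, ll, True, 0

    if baseline == "poisson":
        # lambda solves lambda / (1 - exp(-lambda)) = mean of non-zero values
        m = float(np.mean(nonzero))

        def g(lam):
            return lam / -np.expm1(-lam) - m

        if m <= 1.0 + 1e-12:
            lam = _LOWER
        else:
            lo, hi = 1e-8, max(m, 1.0)
            lam = optimize.brentq(g, lo, hi, xtol=1e-12)
        theta = {"lambda": max(lam, _LOWER)}
        ll = float(np.sum(c * b.logpmf(u, theta)) - M * np.log1p(-b.p0(theta)))
        return theta, ll, True, 0

    def negll(x):
        theta_x = dict(zip(names, x))
        pz = b.p0(theta_x)
        if pz >= 1.0 - 1e-12:
            return 1e12
        return -float(np.sum(c * b.logpmf(u, theta_x)) - M * np.log1p(-pz))

    inits = _moment_inits(baseline, nonzero)
    if init is not None:
        inits = [[init[p] for p in names]] + inits
    nb_bounds = _numeric_bounds(baseline, nonzero, bounds)
    x, ll, ok, used = _maximize(negll, inits, nb_bounds, n_restarts, rng)
    return dict(zip(names, x)), ll, ok, used


def _xlogy(x: float, y: float) -> float:
    return 0.0 if x == 0 else x * math.log(y)


def fit_hurdle(values, baseline, init=None, bounds=None, n_restarts=3, seed=None):
    """MLE of a hurdle model; the likelihood factorizes so phi_hat = n0 / N."""
    fam = ModelFamily(parse_family(baseline).baseline, "hurdle")
    values = _validate_sample(values, fam.baseline)
    rng = np.random.default_rng(seed)
    n = values.size
    nonzero = values[values != 0]
    n0 = n - nonzero.size
    if nonzero.size == 0:
        raise EstimationError(
            "all-zero sample: phi_hat = 1 and the baseline part is unestimable"
        )
    phi = n0 / n
    if fam.is_discrete:
        theta, tll, ok, used = _fit_truncated_theta(
            nonzero, fam.baseline, init, bounds, n_restarts, rng
        )
    else:
        theta, tll, ok, used = _fit_plain_theta(
            nonzero, fam.baseline, init, bounds, n_restarts, rng
        )
    ll = _xlogy(n0, phi) + _xlogy(n - n0, 1.0 - phi) + tll
    return FitResult(
        family=fam,
        params=ParamVector(theta=theta, phi=phi),
        loglik=ll,
        k=fam.k,
        n=n,
        converged=ok,
        n_restarts_used=used,
    )


def fit_zi(values, baseline, init=None, bounds=None, n_restarts=3, seed=None):
    """Joint MLE of a zero-inflated model (phi profiled out of the likelihood)."""
    fam = ModelFamily(parse_family(baseline).baseline, "zero-inflated")
    values = _validate_sample(values, fam.baseline)
    n = values.size
    nonzero = values[values != 0]
    n0 = n - nonzero.size
    if nonzero.size == 0:
        raise EstimationError(
            "all-zero sample: phi_hat = 1 and the baseline part is unestimable"
        )
    if not fam.is_discrete:
        h = fit_hurdle(values, fam.baseline, init, bounds, n_restarts, seed)
        return FitResult(
            family=fam,
            params=h.params,
            loglik=h.loglik,
            k=fam.k,
            n=n,
            converged=h.converged,
            n_restarts_used=h.n_restarts_used,
        )

    rng = np.random.default_rng(seed)
    b = BASELINES[fam.baseline]

    def profiled(theta) -> tuple:
        """Zero-inflated log-likelihood at theta with phi profiled (clipped)."""
        pz = b.p0(theta)
        if pz >= 1.0:
            return -np.inf, 0.0
        phi = (n0 / n - pz) / (1.0 - pz)
        phi = min(max(phi, 0.0), 1.0)
        zmass = phi + (1.0 - phi) * pz
        ll = _xlogy(n0, zmass) if n0 else 0.0
        ll += (n - n0) * math.log1p(-phi) if phi < 1 else -np.inf
        ll += float(np.sum(b.logpmf(nonzero, theta)))
        return ll, phi

    candidates = []
    try:
        theta_t, _, ok_t, used_t = _fit_truncated_theta(
            nonzero, fam.baseline, init, bounds, n_restarts, rng
        )
        candidates.append((theta_t, ok_t, used_t))
    except EstimationError:
        pass
    try:
        theta_p, _, ok_p, used_p = _fit_plain_theta(
            values, fam.baseline, init, bounds, n_restarts, rng
        )
        candidates.append((theta_p, ok_p, used_p))
    except EstimationError:
        pass
    if not candidates:
        raise EstimationError(f"{fam.baseline}: zero-inflated fit failed")

    best = None
    for theta, ok, used in candidates:
        ll, phi = profiled(theta)
        if best is None or ll > best[0]:
            best = (ll, phi, theta, ok, used)
    ll, phi, theta, ok, used = best
    if not np.isfinite(ll):
        raise EstimationError(f"{fam.baseline}: zero-inflated likelihood degenerate")
    return FitResult(
        family=fam,
        params=ParamVector(theta=theta, phi=phi),
        loglik=ll,
        k=fam.k,
        n=n,
        converged=ok,
        n_restarts_used=used,
    )


def fit_model(values, family, init=None, bounds=None, n_restarts=3, seed=None):
    """Dispatch to the fitter matching the family's structure."""
    fam = parse_family(family)
    if fam.structure == "plain":
        return fit_baseline(values, fam.baseline, init, bounds, n_restarts, seed)
    if fam.structure == "hurdle":
        return fit_hurdle(values, fam.baseline, init, bounds, n_restarts, seed)
    return fit_zi(values, fam.baseline, init, bounds, n_restarts, seed)
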