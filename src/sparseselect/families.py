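"""Zero-inflated and hurdle distributions over nine baseline families.

A *hurdle* (zero-altered) model places a point mass ``phi`` at zero and
rescales a baseline distribution over the non-zero values::

    f_ZA(y | phi, theta) = phi * 1{y=0}
                           + (1 - phi) / (1 - p0(theta)) * f_theta(y) * 1{y!=0}

A *zero-inflated* model mixes structural zeros with the untruncated baseline::

    f_ZI(y | phi, theta) = [phi + (1 - phi) * p0(theta)] * 1{y=0}
                           + (1 - phi) * f_theta(y) * 1{y!=0}

where ``p0(theta) = f_theta(0)`` for discrete baselines and 0 for continuous
ones.  For continuous baselines the two structures therefore define the same
distribution (a single atom at zero plus a continuous non-zero part).

Baselines: normal, log-normal, half-normal, exponential (continuous);
Poisson, geometric, negative binomial, beta binomial, beta negative binomial
(discrete).  With the three structures (plain / zero-inflated / hurdle) this
yields the toolkit's 27 models.

Parameterizations
-----------------
* exponential: rate ``lambda`` (mean ``1/lambda``)
* geometric: failures before the first success, support {0, 1, 2, ...},
  success probability ``p``
* negative binomial: ``(r, p)``, failures before the ``r``-th success
* beta binomial: ``(n, alpha, beta)`` with the size ``n`` treated as a
  continuous positive parameter during estimation (the generalized pmf uses
  gamma functions and is evaluated at integers ``y < n + 1``)
* beta negative binomial: ``(r, alpha, beta)``
* half-normal: scale ``sigma`` (density ``2 phi0(y/sigma)/sigma`` for y >= 0)
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import special, stats

__all__ = [
    "ModelFamily",
    "ParamVector",
    "ParameterError",
    "parse_family",
    "density",
    "log_density",
    "cdf",
    "point_mass",
    "p0",
    "sample",
    "sample_plain",
    "sample_hurdle",
    "sample_zi",
    "CONTINUOUS_BASELINES",
    "DISCRETE_BASELINES",
    "BASELINES",
    "STRUCTURES",
]

STRUCTURES = ("plain", "zero-inflated", "hurdle")

CONTINUOUS_BASELINES = ("normal", "lognormal", "halfnormal", "exponential")
DISCRETE_BASELINES = (
    "poisson",
    "geometric",
    "negative-binomial",
    "beta-binomial",
    "beta-negative-binomial",
)


class ParameterError(ValueError):
    """Raised when parameters fall outside a family's domain."""


def _req(cond: bool, msg: str) -> None:
    if not cond:
        raise ParameterError(msg)


# ---------------------------------------------------------------------------
# baseline implementations
# ---------------------------------------------------------------------------


class _Normal:
    name = "normal"
    discrete = False
    param_names = ("mu", "sigma")

    @staticmethod
    def validate(t):
        _req(np.isfinite(t["mu"]), "normal: mu must be finite")
        _req(t["sigma"] > 0, "normal: sigma must be > 0")

    @staticmethod
    def logpdf(y, t):
        return stats.norm.logpdf(y, loc=t["mu"], scale=t["sigma"])

    @staticmethod
    def cdf(y, t):
        return stats.norm.cdf(y, loc=t["mu"], scale=t["sigma"])

    @staticmethod
    def p0(t):
        return 0.0

    @staticmethod
    def rvs(n, t, rng):
        return rng.normal(t["mu"], t["sigma"], n)


class _LogNormal:
    name = "lognormal"
    discrete = False
    param_names = ("mu", "sigma")

    @staticmethod
    def validate(t):
        _req(np.isfinite(t["mu"]), "lognormal: mu must be finite")
        _req(t["sigma"] > 0, "lognormal: sigma must be > 0")

    @staticmethod
    def logpdf(y, t):
        return stats.lognorm.logpdf(y, t["sigma"], scale=np.exp(t["mu"]))

    @staticmethod
    def cdf(y, t):
        return stats.lognorm.cdf(y, t["sigma"], scale=np.exp(t["mu"]))

    @staticmethod
    def p0(t):
        return 0.0

    @staticmethod
    def rvs(n, t, rng):
        return rng.lognormal(t["mu"], t["sigma"], n)


class _HalfNormal:
    name = "halfnormal"
    discrete = False
    param_names = ("sigma",)

    @staticmethod
    def validate(t):
        _req(t["sigma"] > 0, "halfnormal: sigma must be > 0")

    @staticmethod
    def logpdf(y, t):
        return stats.halfnorm.logpdf(y, scale=t["sigma"])

    @staticmethod
    def cdf(y, t):
        return stats.halfnorm.cdf(y, scale=t["sigma"])

    @staticmethod
    def p0(t):
        return 0.0

    @staticmethod
    def rvs(n, t, rng):
        return np.abs(rng.normal(0.0, t["sigma"], n))


class _Exponential:
    name = "exponential"
    discrete = False
    param_names = ("lambda",)

    @staticmethod
    def validate(t):
        _req(t["lambda"] > 0, "exponential: rate lambda must be > 0")

    @staticmethod
    def logpdf(y, t):
        return stats.expon.logpdf(y, scale=1.0 / t["lambda"])

    @staticmethod
    def cdf(y, t):
        return stats.expon.cdf(y, scale=1.0 / t["lambda"])

    @staticmethod
    def p0(t):
        return 0.0

    @staticmethod
    def rvs(n, t, rng):
        return rng.exponential(1.0 / t["lambda"], n)


class _Poisson:
    name = "poisson"
    discrete = True
    param_names = ("lambda",)

    @staticmethod
    def validate(t):
        _req(t["lambda"] > 0, "poisson: lambda must be > 0")

    @staticmethod
    def logpmf(y, t):
        return stats.poisson.logpmf(y, t["lambda"])

    @staticmethod
    def cdf(y, t):
        return stats.poisson.cdf(y, t["lambda"])

    @staticmethod
    def p0(t):
        return float(np.exp(-t["lambda"]))

    @staticmethod
    def rvs(n, t, rng):
        return rng.poisson(t["lambda"], n)


class _Geometric:
    name = "geometric"
    discrete = True
    param_names = ("p",)

    @staticmethod
    def validate(t):
        _req(0 < t["p"] < 1, "geometric: p must be in (0, 1)")

    @staticmethod
    def logpmf(y, t):
        # failures before the first success
        return stats.nbinom.logpmf(y, 1, t["p"])

    @staticmethod
    def cdf(y, t):
        return stats.nbinom.cdf(y, 1, t["p"])

    @staticmethod
    def p0(t):
        return float(t["p"])

    @staticmethod
    def rvs(n, t, rng):
        return rng.geometric(t["p"], n) - 1


class _NegBinomial:
    name = "negative-binomial"
    discrete = True
    param_names = ("r", "p")

    @staticmethod
    def validate(t):
        _req(t["r"] > 0, "negative-binomial: r must be > 0")
        _req(0 < t["p"] < 1, "negative-binomial: p must be in (0, 1)")

    @staticmethod
    def logpmf(y, t):
        return stats.nbinom.logpmf(y, t["r"], t["p"])

    @staticmethod
    def cdf(y, t):
        return stats.nbinom.cdf(y, t["r"], t["p"])

    @staticmethod
    def p0(t):
        return float(t["p"] ** t["r"])

    @staticmethod
    def rvs(n, t, rng):
        return rng.negative_binomial(t["r"], t["p"], n)


def _bb_support_max(n: float) -> int:
    # generalized binomial coefficient requires y < n + 1
    if float(n).is_integer():
        return int(n)
    return int(np.ceil(n))


class _BetaBinomial:
    name = "beta-binomial"
    discrete = True
    param_names = ("n", "alpha", "beta")

    @staticmethod
    def validate(t):
        _req(t["n"] > 0, "beta-binomial: size n must be > 0")
        _req(t["alpha"] > 0, "beta-binomial: alpha must be > 0")
        _req(t["beta"] > 0, "beta-binomial: beta must be > 0")

    @staticmethod
    def logpmf(y, t):
        n, a, b = t["n"], t["alpha"], t["beta"]
        y = np.asarray(y, dtype=float)
        valid = (y >= 0) & (y == np.floor(y)) & (y < n + 1)
        ys = np.where(valid, y, 0.0)
        out = (
            special.gammaln(n + 1)
            - special.gammaln(ys + 1)
            - special.gammaln(n - ys + 1)
            + special.betaln(ys + a, n - ys + b)
            - special.betaln(a, b)
        )
        return np.where(valid, out, -np.inf)

    @staticmethod
    def cdf(y, t):
        kmax = _bb_support_max(t["n"])
        ks = np.arange(kmax + 1)
        cum = np.cumsum(np.exp(_BetaBinomial.logpmf(ks, t)))
        cum = np.minimum(cum, 1.0)
        y = np.asarray(y, dtype=float)
        idx = np.clip(np.floor(y).astype(int), -1, kmax)
        out = np.where(idx >= 0, cum[np.maximum(idx, 0)], 0.0)
        return out

    @staticmethod
    def p0(t):
        n, a, b = t["n"], t["alpha"], t["beta"]
        return float(np.exp(special.betaln(a, n + b) - special.betaln(a, b)))

    @staticmethod
    def rvs(n, t, rng):
        size = t["n"]
        if not float(size).is_integer():
            raise ParameterError(
                "beta-binomial sampling requires an integer size n"
            )
        p = rng.beta(t["alpha"], t["beta"], n)
        return rng.binomial(int(size), p)


class _BetaNegBinomial:
    name = "beta-negative-binomial"
    discrete = True
    param_names = ("r", "alpha", "beta")

    @staticmethod
    def validate(t):
        _req(t["r"] > 0, "beta-negative-binomial: r must be > 0")
        _req(t["alpha"] > 0, "beta-negative-binomial: alpha must be > 0")
        _req(t["beta"] > 0, "beta-negative-binomial: beta must be > 0")

    @staticmethod
    def logpmf(y, t):
        r, a, b = t["r"], t["alpha"], t["beta"]
        y = np.asarray(y, dtype=float)
        valid = (y >= 0) & (y == np.floor(y))
        ys = np.where(valid, y, 0.0)
        out = (
            special.gammaln(r + ys)
            - special.gammaln(ys + 1)
            - special.gammaln(r)
            + special.betaln(r + a, ys + b)
            - special.betaln(a, b)
        )
        return np.where(valid, out, -np.inf)

    @staticmethod
    def cdf(y, t):
        y = np.asarray(y, dtype=float)
        kmax = int(max(np.max(np.floor(y), initial=0), 0))
        ks = np.arange(kmax + 1)
        cum = np.cumsum(np.exp(_BetaNegBinomial.logpmf(ks, t)))
        cum = np.minimum(cum, 1.0)
        idx = np.clip(np.floor(y).astype(int), -1, kmax)
        return np.where(idx >= 0, cum[np.maximum(idx, 0)], 0.0)

    @staticmethod
    def p0(t):
        r, a, b = t["r"], t["alpha"], t["beta"]
        return float(np.exp(special.betaln(r + a, b) - special.betaln(a, b)))

    @staticmethod
    def rvs(n, t, rng):
        p = rng.beta(t["alpha"], t["beta"], n)
        # guard against p == 0 from beta underflow
        p = np.clip(p, 1e-12, 1.0)
        return rng.negative_binomial(t["r"], p, n)


BASELINES = {
    b.name: b
    for b in (
        _Normal,
        _LogNormal,
        _HalfNormal,
        _Exponential,
        _Poisson,
        _Geometric,
        _NegBinomial,
        _BetaBinomial,
        _BetaNegBinomial,
    )
}

# short codes used in result tables (plain / ZI prefix / H suffix)
_BASELINE_CODES = {
    "normal": "N",
    "halfnormal": "HN",
    "lognormal": "LN",
    "exponential": "E",
    "poisson": "P",
    "geometric": "G",
    "negative-binomial": "NB",
    "beta-binomial": "BB",
    "beta-negative-binomial": "BNB",
}


# ---------------------------------------------------------------------------
# family handling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelFamily:
    """A (baseline, structure) pair identifying one of the 27 models."""

    baseline: str
    structure: str = "plain"

    def __post_init__(self):
        if self.baseline not in BASELINES:
            raise ParameterError(f"unknown baseline {self.baseline!r}")
        if self.structure not in STRUCTURES:
            raise ParameterError(f"unknown structure {self.structure!r}")

    @property
    def is_discrete(self) -> bool:
        return BASELINES[self.baseline].discrete

    @property
    def param_names(self) -> tuple:
        names = BASELINES[self.baseline].param_names
        if self.structure == "plain":
            return names
        return names + ("phi",)

    @property
    def k(self) -> int:
        """Number of free parameters (phi counted for non-plain structures)."""
        return len(self.param_names)

    @property
    def code(self) -> str:
        base = _BASELINE_CODES[self.baseline]
        if self.structure == "zero-inflated":
            return "ZI" + base
        if self.structure == "hurdle":
            return base + "H"
        return base

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.code


@dataclass(frozen=True)
class ParamVector:
    """Named baseline parameters plus (optional) zero weight phi."""

    theta: Mapping[str, float]
    phi: float | None = None

    def as_dict(self) -> dict:
        d = dict(self.theta)
        if self.phi is not None:
            d["phi"] = self.phi
        return d


_EXTRA_ALIASES = {
    # spellings used by R packages in this space
    "normalh": ("normal", "hurdle"),
    "zinormal": ("normal", "zero-inflated"),
    "zinorm": ("normal", "zero-inflated"),
    "lognorm": ("lognormal", "plain"),
    "zilognorm": ("lognormal", "zero-inflated"),
    "lognormalh": ("lognormal", "hurdle"),
    "halfnorm": ("halfnormal", "plain"),
    "exp": ("exponential", "plain"),
    "poisson": ("poisson", "plain"),
    "geom": ("geometric", "plain"),
    "geometric": ("geometric", "plain"),
    "nbinom": ("negative-binomial", "plain"),
    "bbinom": ("beta-binomial", "plain"),
    "bnbinom": ("beta-negative-binomial", "plain"),
}

_LONG_BASELINES = {
    "normal": "normal",
    "gaussian": "normal",
    "lognormal": "lognormal",
    "log-normal": "lognormal",
    "halfnormal": "halfnormal",
    "half-normal": "halfnormal",
    "exponential": "exponential",
    "poisson": "poisson",
    "geometric": "geometric",
    "negative-binomial": "negative-binomial",
    "negativebinomial": "negative-binomial",
    "beta-binomial": "beta-binomial",
    "betabinomial": "beta-binomial",
    "beta-negative-binomial": "beta-negative-binomial",
    "betanegativebinomial": "beta-negative-binomial",
}


def _alias_table() -> dict:
    table = {}
    for baseline, code in _BASELINE_CODES.items():
        table[code.lower()] = (baseline, "plain")
        table[("zi" + code).lower()] = (baseline, "zero-inflated")
        table[(code + "h").lower()] = (baseline, "hurdle")
    table.update(_EXTRA_ALIASES)
    return table


_ALIASES = _alias_table()


def parse_family(name) -> ModelFamily:
    """Resolve a family given long form, short code, or ModelFamily."""
    if isinstance(name, ModelFamily):
        return name
    if isinstance(name, tuple) and len(name) == 2:
        return ModelFamily(*name)
    key = str(name).strip().lower()
    if key in _ALIASES:
        return ModelFamily(*_ALIASES[key])
    norm = key.replace("_", "-").replace(" ", "-")
    if norm in _LONG_BASELINES:
        return ModelFamily(_LONG_BASELINES[norm], "plain")
    for prefix, structure in (
        ("zero-inflated-", "zero-inflated"),
        ("zi-", "zero-inflated"),
        ("hurdle-", "hurdle"),
    ):
        if norm.startswith(prefix) and norm[len(prefix):] in _LONG_BASELINES:
            return ModelFamily(_LONG_BASELINES[norm[len(prefix):]], structure)
    for suffix, structure in (("-hurdle", "hurdle"), ("-zero-inflated", "zero-inflated")):
        if norm.endswith(suffix) and norm[: -len(suffix)] in _LONG_BASELINES:
            return ModelFamily(_LONG_BASELINES[norm[: -len(suffix)]], structure)
    raise ParameterError(f"unknown model family {name!r}")


def _split_params(family: ModelFamily, params) -> tuple:
    """Return (theta dict, phi) from a ParamVector, dict, or (theta, phi)."""
    if isinstance(params, ParamVector):
        theta, phi = dict(params.theta), params.phi
    elif isinstance(params, Mapping):
        d = dict(params)
        phi = d.pop("phi", None)
        theta = d
    else:
        raise ParameterError(f"cannot interpret parameters {params!r}")
    b = BASELINES[family.baseline]
    missing = [p for p in b.param_names if p not in theta]
    if missing:
        raise ParameterError(f"{family.baseline}: missing parameters {missing}")
    b.validate(theta)
    if family.structure == "plain":
        if phi not in (None, 0, 0.0):
            raise ParameterError("plain structure takes no phi parameter")
        phi = 0.0
    else:
        if phi is None:
            raise ParameterError(f"{family.structure} structure requires phi")
        if not 0.0 <= phi <= 1.0:
            raise ParameterError("phi must lie in [0, 1]")
    return theta, float(phi)


def _base_logf(family: ModelFamily, theta, y):
    b = BASELINES[family.baseline]
    if b.discrete:
        return b.logpmf(y, theta)
    return b.logpdf(y, theta)


def p0(baseline, theta) -> float:
    """Baseline probability of zero: f_theta(0) (discrete) or 0 (continuous)."""
    fam = parse_family(baseline)
    b = BASELINES[fam.baseline]
    b.validate(theta)
    return float(b.p0(theta))


def log_density(family, params, y):
    """Log pmf / log pdf of the model; the atom at zero is reported as a mass."""
    family = parse_family(family)
    theta, phi = _split_params(family, params)
    b = BASELINES[family.baseline]
    y = np.asarray(y, dtype=float)
    scalar = y.ndim == 0
    y = np.atleast_1d(y)
    base = _base_logf(family, theta, y)
    pz = b.p0(theta)
    with np.errstate(divide="ignore"):
        if family.structure == "plain":
            out = base
        elif family.structure == "hurdle":
            nz = np.log1p(-phi) - np.log1p(-pz) + base
            out = np.where(y == 0, np.log(phi) if phi > 0 else -np.inf, nz)
        else:  # zero-inflated
            z_mass = phi + (1.0 - phi) * pz
            nz = np.log1p(-phi) + base
            out = np.where(y == 0, np.log(z_mass) if z_mass > 0 else -np.inf, nz)
    if scalar:
        return float(out[0])
    return out


def density(family, params, y):
    """Pmf (discrete) or pdf (continuous, with the zero atom reported as phi)."""
    out = np.exp(log_density(family, params, y))
    return float(out) if np.ndim(out) == 0 else out


def cdf(family, params, y):
    """Right-continuous CDF of the mixture, including the jump at zero."""
    family = parse_family(family)
    theta, phi = _split_params(family, params)
    b = BASELINES[family.baseline]
    y = np.asarray(y, dtype=float)
    scalar = y.ndim == 0
    y = np.atleast_1d(y)
    Fb = np.asarray(b.cdf(y, theta), dtype=float)
    pz = b.p0(theta)
    atzero = (y >= 0).astype(float)
    if family.structure == "plain":
        out = Fb
    elif family.structure == "hurdle":
        out = phi * atzero + (1.0 - phi) * (Fb - pz * atzero) / (1.0 - pz)
    else:  # zero-inflated
        out = phi * atzero + (1.0 - phi) * Fb
    out = np.clip(out, 0.0, 1.0)
    if scalar:
        return float(out[0])
    return out


def point_mass(family, params, y):
    """P(Y = y) — the size of the CDF jump at y (0 for continuous y != 0)."""
    family = parse_family(family)
    y = np.asarray(y, dtype=float)
    scalar = y.ndim == 0
    y = np.atleast_1d(y)
    if family.is_discrete:
        is_int = y == np.floor(y)
        out = np.where(is_int, density(family, params, np.where(is_int, y, 0.0)), 0.0)
    else:
        _, phi = _split_params(family, params)
        mass0 = phi if family.structure != "plain" else 0.0
        out = np.where(y == 0, mass0, 0.0)
    if scalar:
        return float(out[0])
    return out


# ---------------------------------------------------------------------------
# samplers
# ---------------------------------------------------------------------------


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_plain(n, baseline, theta, seed=None):
    """n iid draws from the plain baseline."""
    fam = parse_family(baseline)
    b = BASELINES[fam.baseline]
    b.validate(theta)
    rng = _as_rng(seed)
    return np.asarray(b.rvs(int(n), theta, rng), dtype=float)


def _truncated_draws(b, theta, n, rng):
    """n draws from the baseline conditioned on y != 0 (rejection sampling)."""
    pz = b.p0(theta)
    if pz >= 1.0 - 1e-12:
        raise ParameterError("baseline places essentially all mass at zero")
    out = np.empty(n, dtype=float)
    filled = 0
    while filled < n:
        need = n - filled
        batch = int(np.ceil(need / max(1.0 - pz, 1e-6))) + 8
        draws = np.asarray(b.rvs(batch, theta, rng), dtype=float)
        draws = draws[draws != 0]
        take = min(need, draws.size)
        out[filled : filled + take] = draws[:take]
        filled += take
    return out


def sample_hurdle(n, phi, baseline, theta, seed=None):
    """n draws from the hurdle model: P(Y=0) = phi exactly."""
    fam = parse_family(baseline)
    b = BASELINES[fam.baseline]
    b.validate(theta)
    _req(0.0 <= phi <= 1.0, "phi must lie in [0, 1]")
    rng = _as_rng(seed)
    n = int(n)
    zeros = rng.random(n) < phi
    out = np.zeros(n, dtype=float)
    m = int((~zeros).sum())
    if m:
        out[~zeros] = _truncated_draws(b, theta, m, rng)
    return out


def sample_zi(n, phi, baseline, theta, seed=None):
    """n draws from the zero-inflated model: P(Y=0) = phi + (1-phi) p0(theta)."""
    fam = parse_family(baseline)
    b = BASELINES[fam.baseline]
    b.validate(theta)
    _req(0.0 <= phi <= 1.0, "phi must lie in [0, 1]")
    rng = _as_rng(seed)
    n = int(n)
    structural = rng.random(n) < phi
    out = np.zeros(n, dtype=float)
    m = int((~structural).sum())
    if m:
        out[~structural] = np.asarray(b.rvs(m, theta, rng), dtype=float)
    return out


def sample(family, params, n, seed=None):
    """Draw n values from any of the 27 models."""
    family = parse_family(family)
    theta, phi = _split_params(family, params)
    if family.structure == "plain":
        return sample_plain(n, family.baseline, theta, seed)
    if family.structure == "hurdle":
        return sample_hurdle(n, phi, family.baseline, theta, seed)
    return sample_zi(n, phi, family.baseline, theta, seed)
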