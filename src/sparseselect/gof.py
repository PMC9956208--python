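"""Kolmogorov–Smirnov goodness of fit with Monte-Carlo bootstrapped p-values.

The KS statistic is computed against the fitted model's CDF *including* its
jump at zero (and at every support point for discrete baselines):

    D = sup_y max(|F_n(y) - F(y)|, |F_n(y-) - F(y-)|)

evaluated at the observed points, which is where the supremum of the
discrepancy between a step function and a (possibly jumpy) CDF is attained.

Because the null parameters are estimated, the null distribution of D is
obtained by a parametric bootstrap: simulate ``nsim`` samples of size N from
the fitted model, re-fit the MLE on each replicate, and compare each
replicate's KS statistic (against its own re-fit) with the observed one.
The p-value is the plain proportion of replicate statistics >= D_obs, so
exact 0 and 1 are possible.

Two variants are provided.  Method A simulates every replicate from the one
model fitted to the original data; method B (small-sample variant,
recommended for N <= 50) re-estimates each replicate's generating parameters
from a with-replacement resample of the original data before simulating.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .families import ModelFamily, cdf, parse_family, point_mass, sample
from .fit import EstimationError, FitResult, fit_model

__all__ = [
    "GofResult",
    "ModelSelection",
    "SelectionError",
    "ks_statistic",
    "ks_test",
    "select_model",
    "CONTINUOUS_CANDIDATES",
    "DISCRETE_CANDIDATES",
    "default_method",
]

#: Table-1-style 12-model candidate list for continuous data.  Order matters:
#: ties in the selection p-value are broken toward the *last* family listed.
CONTINUOUS_CANDIDATES = (
    "N", "ZIN", "NH", "HN", "ZIHN", "HNH", "LN", "ZILN", "LNH", "E", "ZIE", "EH",
)

#: The 15 count models.
DISCRETE_CANDIDATES = (
    "P", "ZIP", "PH", "G", "ZIG", "GH", "NB", "ZINB", "NBH",
    "BB", "ZIBB", "BBH", "BNB", "ZIBNB", "BNBH",
)


class SelectionError(RuntimeError):
    """Raised when no candidate family can be fitted at all."""


def default_method(n: int) -> str:
    """Small samples (N <= 50) get the resampling variant B, else A."""
    return "B" if n <= 50 else "A"


def ks_statistic(values, family, params) -> float:
    """Two-sided KS distance between the empirical CDF and the model CDF."""
    family = parse_family(family)
    values = np.sort(np.asarray(values, dtype=float))
    n = values.size
    u, counts = np.unique(values, return_counts=True)
    fn_right = np.cumsum(counts) / n
    fn_left = fn_right - counts / n
    f_right = np.asarray(cdf(family, params, u), dtype=float)
    f_left = f_right - np.asarray(point_mass(family, params, u), dtype=float)
    d = max(
        float(np.max(np.abs(fn_right - f_right))),
        float(np.max(np.abs(fn_left - f_left))),
    )
    return min(max(d, 0.0), 1.0)


@dataclass
class GofResult:
    """One bootstrapped KS test: observed statistic plus Monte-Carlo p-value."""

    family: ModelFamily
    fit: FitResult
    d_obs: float
    nsim: int
    pvalue: float
    method: str
    seed: object = None
    n_failed: int = 0

    def to_dict(self) -> dict:
        return {
            "family": self.family.code,
            "d_obs": self.d_obs,
            "nsim": self.nsim,
            "pvalue": self.pvalue,
            "method": self.method,
            "n_failed": self.n_failed,
            "fit": self.fit.to_dict(),
        }


def ks_test(
    values,
    family,
    nsim: int = 100,
    method: str | None = None,
    bounds=None,
    seed=None,
    n_restarts: int = 3,
) -> GofResult:
    """Parametric-bootstrap KS test of ``family`` against the sample.

    Replicates whose re-fit fails are dropped; fewer than 10 survivors is an
    error.  The p-value is the surviving fraction of replicate statistics
    >= the observed one (no continuity correction), so ``pvalue * nsim`` is
    an integer when nothing is dropped.
    """
    family = parse_family(family)
    values = np.asarray(values, dtype=float)
    n = values.size
    if nsim < 1:
        raise ValueError("nsim must be >= 1")
    if method is None:
        method = default_method(n)
    if method not in ("A", "B"):
        raise ValueError("method must be 'A' or 'B'")
    rng = np.random.default_rng(seed)
    fit = fit_model(values, family, bounds=bounds, n_restarts=n_restarts, seed=rng)
    d_obs = ks_statistic(values, family, fit.params)

    d_rep = []
    n_failed = 0
    for _ in range(nsim):
        try:
            if method == "A":
                gen_params = fit.params
            else:
                boot = rng.choice(values, size=n, replace=True)
                gen_params = fit_model(
                    boot, family, bounds=bounds, n_restarts=n_restarts, seed=rng
                ).params
            sim = sample(family, gen_params, n, rng)
            refit = fit_model(
                sim, family, bounds=bounds, n_restarts=n_restarts, seed=rng
            )
            d_rep.append(ks_statistic(sim, family, refit.params))
        except EstimationError:
            n_failed += 1
    if len(d_rep) < 10:
        raise EstimationError(
            f"KS test for {family.code}: only {len(d_rep)} of {nsim} "
            "bootstrap replicates could be re-fitted"
        )
    d_rep = np.asarray(d_rep)
    pvalue = float(np.mean(d_rep >= d_obs))
    return GofResult(
        family=family,
        fit=fit,
        d_obs=d_obs,
        nsim=nsim,
        pvalue=pvalue,
        method=method,
        seed=seed,
        n_failed=n_failed,
    )


@dataclass
class CandidateResult:
    family: ModelFamily
    gof: GofResult | None
    fit: FitResult | None
    error: str | None = None

    @property
    def pvalue(self):
        return None if self.gof is None else self.gof.pvalue


@dataclass
class ModelSelection:
    """KS-screened candidate set with the max-p family chosen (last tie wins)."""

    candidates: list
    chosen: CandidateResult
    alpha: float = 0.05
    chosen_admissible: bool = True
    admissible: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "chosen": self.chosen.family.code,
            "chosen_admissible": self.chosen_admissible,
            "alpha": self.alpha,
            "pvalues": {
                c.family.code: c.pvalue for c in self.candidates
            },
        }


def select_model(
    values,
    candidate_families=CONTINUOUS_CANDIDATES,
    nsim: int = 100,
    method: str | None = None,
    alpha: float = 0.05,
    seed=None,
    bounds=None,
) -> ModelSelection:
    """Screen candidate families by bootstrapped KS tests and pick one.

    Admissible families have p-value >= ``alpha``; the chosen family has the
    maximal p-value, with ties broken by taking the *last* tied family in the
    candidate list.  If no family is admissible, the max-p family is still
    returned but flagged.  ``nsim=0`` skips the KS screen entirely (every
    fittable candidate counts as tied, so the last one listed is chosen) —
    used by the fixed-family shortcuts.
    """
    fams = [parse_family(c) for c in candidate_families]
    if not fams:
        raise SelectionError("need at least one candidate family")
    rng = np.random.default_rng(seed)
    values = np.asarray(values, dtype=float)
    results = []
    for fam in fams:
        try:
            if nsim == 0:
                fit = fit_model(values, fam, bounds=bounds, seed=rng)
                results.append(CandidateResult(fam, None, fit))
            else:
                gof = ks_test(
                    values, fam, nsim=nsim, method=method, bounds=bounds, seed=rng
                )
                results.append(CandidateResult(fam, gof, gof.fit))
        except (EstimationError, ValueError) as exc:
            results.append(CandidateResult(fam, None, None, error=str(exc)))
    fittable = [c for c in results if c.fit is not None]
    if not fittable:
        raise SelectionError("no candidate family could be fitted")
    if nsim == 0:
        chosen = fittable[-1]
        return ModelSelection(
            candidates=results, chosen=chosen, alpha=alpha,
            chosen_admissible=True, admissible=list(fittable),
        )
    best = None
    for c in fittable:
        if best is None or c.pvalue >= best.pvalue:  # >= : last tie wins
            best = c
    admissible = [c for c in fittable if c.pvalue >= alpha]
    return ModelSelection(
        candidates=results,
        chosen=best,
        alpha=alpha,
        chosen_admissible=best.pvalue >= alpha,
        admissible=admissible,
    )
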