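"""AIC-difference significance test for class-informative covariates.

For one covariate with N readings and class labels in {1, ..., m}:

* **Model I** — select (KS screen) and fit the best sparse model to all N
  readings pooled, ignoring labels; its AIC is ``model_I_aic``.
* **Model II** — independently select and fit a model per class; the classes
  may choose different families.  ``model_II_aic = sum_k AIC(k)``.
* The selection statistic is ``difference = model_I_aic - model_II_aic``.
  A larger difference means the covariate is more informative about the
  labels; a difference above 2 (the usual AIC rule of thumb) is flagged
  significant.

The model-II fit always gains log-likelihood but pays 2k extra penalty per
class, so for an uninformative covariate the difference is negative in
expectation.

``rank_features`` applies the test to every column of a feature matrix and
sorts by difference (descending, stable).  ``AICDifferenceSelector`` wraps
the ranking as a scikit-learn feature selector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from .fit import EstimationError, FitResult, fit_model
from .gof import (
    CONTINUOUS_CANDIDATES,
    ModelSelection,
    SelectionError,
    select_model,
)

__all__ = [
    "AicDifference",
    "RankingResult",
    "model_I_aic",
    "model_II_aic",
    "aic_difference",
    "rank_features",
    "AICDifferenceSelector",
    "LOGNORMAL_DICHOTOMY",
    "SIGNIFICANCE_THRESHOLD",
]

#: AIC-difference value above which a covariate is labeled significant.
SIGNIFICANCE_THRESHOLD = 2.0

#: Fixed-family shortcut: log-normal hurdle for samples with zeros,
#: plain log-normal otherwise.
LOGNORMAL_DICHOTOMY = ("LNH", "LN")


def _resolve_candidates(values, candidates, fixed_family):
    """Return the candidate list for one sample under the fixed-family rules."""
    if fixed_family is None:
        if callable(candidates):
            return candidates(values), None
        return candidates, None
    if isinstance(fixed_family, tuple) and len(fixed_family) == 2:
        fam = fixed_family[0] if np.any(values == 0) else fixed_family[1]
        return None, fam
    return None, fixed_family


def _select_and_fit(values, candidates, nsim, method, seed, fixed_family):
    cand, fixed = _resolve_candidates(values, candidates, fixed_family)
    if fixed is not None:
        sel = select_model(values, [fixed], nsim=0, seed=seed)
    else:
        sel = select_model(values, cand, nsim=nsim, method=method, seed=seed)
    return sel, sel.chosen.fit


def model_I_aic(
    values,
    candidates=CONTINUOUS_CANDIDATES,
    nsim: int = 100,
    method: str | None = None,
    seed=None,
    fixed_family=None,
) -> tuple[ModelSelection, FitResult]:
    """Step 1: best model for the pooled readings, labels ignored."""
    values = np.asarray(values, dtype=float)
    return _select_and_fit(values, candidates, nsim, method, seed, fixed_family)


def model_II_aic(
    values,
    labels,
    candidates=CONTINUOUS_CANDIDATES,
    nsim: int = 100,
    method: str | None = None,
    seed=None,
    fixed_family=None,
) -> tuple[dict, float]:
    """Step 2: per-class independent selection + fit; returns parts and AIC sum."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if labels.shape[0] != values.shape[0]:
        raise ValueError("values and labels must have matching length")
    parts = {}
    rng = np.random.default_rng(seed)
    for cls in np.unique(labels):
        sub = values[labels == cls]
        try:
            parts[cls] = _select_and_fit(
                sub, candidates, nsim, method, rng, fixed_family
            )
        except (EstimationError, SelectionError) as exc:
            raise EstimationError(f"class {cls!r}: {exc}") from exc
    aic_sum = float(sum(fit.aic for _, fit in parts.values()))
    return parts, aic_sum


@dataclass
class AicDifference:
    """Model I vs aggregated Model II AIC and their difference."""

    model_I: tuple
    model_II_parts: dict
    model_I_aic: float
    model_II_aic: float
    difference: float

    def significant(self, threshold: float = SIGNIFICANCE_THRESHOLD) -> bool:
        return self.difference > threshold


def aic_difference(
    values,
    labels,
    candidates=CONTINUOUS_CANDIDATES,
    nsim: int = 100,
    method: str | None = None,
    seed=None,
    fixed_family=None,
) -> AicDifference:
    """Step 3: ModelIAIC - ModelIIAIC for one labeled covariate."""
    rng = np.random.default_rng(seed)
    sel_I, fit_I = model_I_aic(
        values, candidates, nsim=nsim, method=method, seed=rng,
        fixed_family=fixed_family,
    )
    parts, aic_II = model_II_aic(
        values, labels, candidates, nsim=nsim, method=method, seed=rng,
        fixed_family=fixed_family,
    )
    return AicDifference(
        model_I=(sel_I, fit_I),
        model_II_parts=parts,
        model_I_aic=fit_I.aic,
        model_II_aic=aic_II,
        difference=fit_I.aic - aic_II,
    )


@dataclass
class RankingResult:
    """Features ordered by AIC difference (descending, stable)."""

    table: pd.DataFrame
    order: np.ndarray
    records: list

    def top(self, n: int) -> list:
        return list(self.table["feature"].iloc[:n])


def rank_features(
    X,
    y,
    feature_names=None,
    candidates=CONTINUOUS_CANDIDATES,
    nsim: int = 100,
    method: str | None = None,
    fixed_family=None,
    seed=None,
    threshold: float = SIGNIFICANCE_THRESHOLD,
) -> RankingResult:
    """Rank every column of X by its AIC difference for the labels y.

    Columns whose every candidate fails to fit get difference = NaN and are
    ranked last (stable, input order preserved among ties and failures).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] == 0:
        raise ValueError("X must be a non-empty 2-D matrix")
    y = np.asarray(y)
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(X.shape[1])]
    rng = np.random.default_rng(seed)
    rows = []
    records = []
    for j in range(X.shape[1]):
        try:
            d = aic_difference(
                X[:, j], y, candidates, nsim=nsim, method=method, seed=rng,
                fixed_family=fixed_family,
            )
            records.append(d)
            rows.append(
                {
                    "feature": feature_names[j],
                    "chosen_family_I": d.model_I[0].chosen.family.code,
                    "chosen_family_per_class": ";".join(
                        f"{k}:{sel.chosen.family.code}"
                        for k, (sel, _) in d.model_II_parts.items()
                    ),
                    "aic_I": d.model_I_aic,
                    "aic_II": d.model_II_aic,
                    "difference": d.difference,
                    "significant": d.significant(threshold),
                }
            )
        except (EstimationError, SelectionError) as exc:
            records.append(None)
            rows.append(
                {
                    "feature": feature_names[j],
                    "chosen_family_I": "",
                    "chosen_family_per_class": f"error: {exc}",
                    "aic_I": np.nan,
                    "aic_II": np.nan,
                    "difference": np.nan,
                    "significant": False,
                }
            )
    table = pd.DataFrame(rows)
    diffs = table["difference"].to_numpy()
    keys = np.where(np.isnan(diffs), -np.inf, diffs)
    order = np.argsort(-keys, kind="stable")
    table = table.iloc[order].reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return RankingResult(table=table, order=order, records=records)


class AICDifferenceSelector(SelectorMixin, BaseEstimator):
    """Select the top-n features by AIC difference (scikit-learn selector).

    Parameters
    ----------
    top_n : number of features kept by :meth:`transform`
    candidates : candidate family list for the KS screen
    fixed_family : optional family (or zeros/no-zeros family pair such as
        :data:`LOGNORMAL_DICHOTOMY`) that bypasses the per-feature KS screen
    nsim : bootstrap replicates for the KS screen (ignored when fixed)
    random_state : seed for the bootstrap
    """

    def __init__(
        self,
        top_n: int = 50,
        candidates=CONTINUOUS_CANDIDATES,
        fixed_family=None,
        nsim: int = 100,
        method: str | None = None,
        threshold: float = SIGNIFICANCE_THRESHOLD,
        random_state=None,
    ):
        self.top_n = top_n
        self.candidates = candidates
        self.fixed_family = fixed_family
        self.nsim = nsim
        self.method = method
        self.threshold = threshold
        self.random_state = random_state

    def fit(self, X, y):
        X = validate_data(self, X, ensure_2d=True, dtype=float)
        ranking = rank_features(
            X,
            y,
            candidates=self.candidates,
            nsim=self.nsim,
            method=self.method,
            fixed_family=self.fixed_family,
            seed=self.random_state,
            threshold=self.threshold,
        )
        self.ranking_ = ranking
        order = ranking.order
        diffs = ranking.table.set_index(ranking.table.index)["difference"]
        self.differences_ = np.empty(X.shape[1])
        self.differences_[order] = diffs.to_numpy()
        self.order_ = order
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.order_[: self.top_n]] = True
        return mask
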