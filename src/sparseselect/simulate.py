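"""Synthetic cohorts emulating the two application data shapes.

``gen_longitudinal`` emulates a two-group longitudinal cohort (a
pregnant-like "case" group of 22 subjects and a "control" group of 30,
matching the vaginal-microbiome cohort scale): per-subject visit weeks are an
irregular subset of a 38-week grid (3–8 visits), readings are draws from a
group- and segment-specific hurdle model, and the case group's distribution
shifts at a changepoint week (mean up, spread up, zeros vanish — the
qualitative post-week-22 behavior seen in such cohorts).  Both groups are
identical in distribution before the changepoint, and with all effect knobs
at zero they are identical throughout.

``gen_matrix`` emulates a sparse expression matrix: five unbalanced classes
(300/146/78/141/136 samples), noise features iid across classes from a
hurdle family with zero proportions spread over 5–50%, and a minority of
informative features whose location parameter is shifted by a class-indexed
amount.

Ground truth (segment parameters, changepoint, informative set) is returned
alongside every dataset so recovery can be scored.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np

from .expression import FeatureTable
from .families import sample_hurdle, sample_zi
from .longitudinal import LongitudinalSeries

__all__ = [
    "LongitudinalScenario",
    "MatrixScenario",
    "gen_longitudinal",
    "gen_matrix",
]


def _one_hurdle_draw(phi, baseline, theta, rng):
    return float(sample_hurdle(1, phi, baseline, theta, rng)[0])


@dataclass
class LongitudinalScenario:
    """Two-group longitudinal study conditions."""

    n_case: int = 22
    n_control: int = 30
    n_weeks: int = 38
    changepoint: int = 22
    baseline: str = "normal"
    phi: float = 0.10
    mu: float = 5.0
    sigma: float = 2.0
    # case-group shifts applied from the changepoint week onward
    mean_shift: float = 6.0
    sigma_ratio: float = 2.0
    phi_post: float = 0.0
    # visit schedule: enroll early, every 4 weeks to the changepoint region,
    # every 2 weeks afterwards; non-terminal visits are missed at miss_rate,
    # so realized visit counts are unequal (floored at visits_min)
    enroll_max: int = 13
    early_spacing: int = 4
    late_spacing: int = 2
    miss_rate: float = 0.15
    visits_min: int = 3

    def pre_theta(self) -> dict:
        return {"mu": self.mu, "sigma": self.sigma}

    def post_theta(self) -> dict:
        return {"mu": self.mu + self.mean_shift, "sigma": self.sigma * self.sigma_ratio}


def gen_longitudinal(config: LongitudinalScenario | None = None, seed=None):
    """Generate (list of LongitudinalSeries, ground-truth dict)."""
    cfg = config or LongitudinalScenario()
    rng = np.random.default_rng(seed)
    series = []
    for group, n_sub in (("case", cfg.n_case), ("control", cfg.n_control)):
        for i in range(n_sub):
            enroll = int(rng.integers(1, cfg.enroll_max + 1))
            sched = list(range(enroll, cfg.changepoint + cfg.early_spacing,
                               cfg.early_spacing))
            sched += list(range(sched[-1] + cfg.late_spacing, cfg.n_weeks + 1,
                                cfg.late_spacing))
            sched = np.asarray([w for w in sched if w <= cfg.n_weeks])
            keep = rng.random(sched.size) > cfg.miss_rate
            keep[0] = keep[-1] = True  # enrollment and final visits happen
            while keep.sum() < cfg.visits_min:
                keep[int(rng.integers(sched.size))] = True
            weeks = sched[keep]
            vals = []
            for w in weeks:
                if group == "case" and w >= cfg.changepoint:
                    vals.append(_one_hurdle_draw(cfg.phi_post, cfg.baseline,
                                                 cfg.post_theta(), rng))
                else:
                    vals.append(_one_hurdle_draw(cfg.phi, cfg.baseline,
                                                 cfg.pre_theta(), rng))
            series.append(
                LongitudinalSeries(
                    subject=f"{group}{i:02d}",
                    group=group,
                    times=weeks.astype(float),
                    values=np.asarray(vals),
                )
            )
    truth = {
        "changepoint": cfg.changepoint,
        "pre": {"phi": cfg.phi, **cfg.pre_theta()},
        "post_case": {"phi": cfg.phi_post, **cfg.post_theta()},
        "config": asdict(cfg),
        "seed": seed,
    }
    return series, truth


@dataclass
class MatrixScenario:
    """Sparse feature-matrix study conditions."""

    class_sizes: tuple = (300, 146, 78, 141, 136)
    n_features: int = 200
    n_informative: int = 10
    baseline: str = "lognormal"
    structure: str = "hurdle"
    zero_prop_range: tuple = (0.05, 0.50)
    informative_zero_prop_range: tuple = (0.05, 0.20)
    mu_range: tuple = (0.0, 2.0)
    sigma_range: tuple = (0.3, 0.8)
    # informative class shift: mu_jk = mu_j + effect * sigma_j * perm_j(k)
    effect: float = 2.0
    class_labels: tuple = field(default=None)

    def labels(self) -> tuple:
        if self.class_labels is not None:
            return self.class_labels
        return tuple(f"C{i + 1}" for i in range(len(self.class_sizes)))


def gen_matrix(config: MatrixScenario | None = None, seed=None):
    """Generate (FeatureTable, ground-truth dict)."""
    cfg = config or MatrixScenario()
    if cfg.n_informative > cfg.n_features:
        raise ValueError("n_informative cannot exceed n_features")
    rng = np.random.default_rng(seed)
    m = len(cfg.class_sizes)
    labels = np.repeat(cfg.labels(), cfg.class_sizes)
    n = labels.size
    sampler = sample_hurdle if cfg.structure == "hurdle" else sample_zi

    informative = np.sort(
        rng.choice(cfg.n_features, size=cfg.n_informative, replace=False)
    )
    info_set = set(int(j) for j in informative)
    X = np.empty((n, cfg.n_features))
    feat_params = []
    for j in range(cfg.n_features):
        sigma = float(rng.uniform(*cfg.sigma_range))
        mu = float(rng.uniform(*cfg.mu_range))
        if j in info_set:
            phi = float(rng.uniform(*cfg.informative_zero_prop_range))
            perm = rng.permutation(m)
            col = np.empty(n)
            start = 0
            for k, size in enumerate(cfg.class_sizes):
                theta = {"mu": mu + cfg.effect * sigma * perm[k], "sigma": sigma}
                col[start : start + size] = sampler(size, phi, cfg.baseline,
                                                    theta, rng)
                start += size
            X[:, j] = col
            feat_params.append(
                {"phi": phi, "mu": mu, "sigma": sigma, "perm": perm.tolist()}
            )
        else:
            phi = float(rng.uniform(*cfg.zero_prop_range))
            X[:, j] = sampler(n, phi, cfg.baseline, {"mu": mu, "sigma": sigma},
                              rng)
            feat_params.append({"phi": phi, "mu": mu, "sigma": sigma})
    table = FeatureTable(
        values=X,
        feature_names=[f"g{j}" for j in range(cfg.n_features)],
        labels=labels,
    )
    truth = {
        "informative": informative.tolist(),
        "features": feat_params,
        "config": {**asdict(cfg), "class_labels": list(cfg.labels())},
        "seed": seed,
    }
    return table, truth
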