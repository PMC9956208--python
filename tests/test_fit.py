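"""MLE layer: closed forms, grid-search oracles, recovery, AIC/BIC identities."""

import math

import numpy as np
import pytest

import sparseselect as ss
from sparseselect.fit import fit_model, log_likelihood

# 3 * (Monte-Carlo SD over a 50-replicate pilot at N=2000 per family), with a
# small floor for estimates pinned at a boundary (beta-binomial size n)
RECOVERY_TOL = {
    "N": {"mu": 0.12, "sigma": 0.10},
    "LN": {"mu": 0.05, "sigma": 0.04},
    "HN": {"sigma": 0.15},
    "E": {"lambda": 0.14},
    "P": {"lambda": 0.13},
    "G": {"p": 0.02},
    "NB": {"r": 0.92, "p": 0.05},
    "BB": {"n": 0.01, "alpha": 0.33, "beta": 0.46},
    "BNB": {"r": 7.5, "alpha": 1.2, "beta": 2.2},
    "NH": {"mu": 0.15, "sigma": 0.14, "phi": 0.03},
    "LNH": {"mu": 0.30, "sigma": 0.27, "phi": 0.03},
    "HNH": {"sigma": 0.20, "phi": 0.03},
    "EH": {"lambda": 1.32, "phi": 0.03},
    "PH": {"lambda": 0.15, "phi": 0.03},
    "GH": {"p": 0.022, "phi": 0.03},
    "NBH": {"r": 1.26, "p": 0.06, "phi": 0.03},
    "BBH": {"n": 0.01, "alpha": 0.74, "beta": 0.84, "phi": 0.03},
    "BNBH": {"r": 8.0, "alpha": 1.0, "beta": 2.5, "phi": 0.03},
    "ZIP": {"lambda": 0.16, "phi": 0.04},
    "ZIG": {"p": 0.028, "phi": 0.07},
    "ZINB": {"r": 1.28, "p": 0.06, "phi": 0.03},
    "ZIBB": {"n": 0.01, "alpha": 0.83, "beta": 1.04, "phi": 0.06},
    "ZIBNB": {"r": 12.0, "alpha": 1.5, "beta": 5.5, "phi": 0.05},
}

REF_POINT = {
    "N": {"mu": 5, "sigma": 2},
    "LN": {"mu": 1, "sigma": 0.8},
    "HN": {"sigma": 3},
    "E": {"lambda": 2},
    "P": {"lambda": 4},
    "G": {"p": 0.35},
    "NB": {"r": 5, "p": 0.4},
    "BB": {"n": 6, "alpha": 2, "beta": 3},
    "BNB": {"r": 5, "alpha": 3, "beta": 3},
    "NH": {"mu": 10, "sigma": 2, "phi": 0.3},
    "LNH": {"mu": 1, "sigma": 4, "phi": 0.3},
    "HNH": {"sigma": 3, "phi": 0.3},
    "EH": {"lambda": 20, "phi": 0.3},
    "PH": {"lambda": 3, "phi": 0.3},
    "GH": {"p": 0.35, "phi": 0.3},
    "NBH": {"r": 5, "p": 0.4, "phi": 0.3},
    "BBH": {"n": 6, "alpha": 2, "beta": 3, "phi": 0.3},
    "BNBH": {"r": 5, "alpha": 3, "beta": 3, "phi": 0.3},
    "ZIP": {"lambda": 3, "phi": 0.3},
    "ZIG": {"p": 0.35, "phi": 0.3},
    "ZINB": {"r": 5, "p": 0.4, "phi": 0.3},
    "ZIBB": {"n": 6, "alpha": 2, "beta": 3, "phi": 0.3},
    "ZIBNB": {"r": 5, "alpha": 3, "beta": 3, "phi": 0.3},
}


class TestClosedForms:
    def test_exponential_unit_sample(self):
        r = ss.fit_baseline([1, 1, 1, 1], "exponential")
        assert r.params.theta["lambda"] == pytest.approx(1.0)
        assert r.loglik == pytest.approx(-4.0)

    def test_normal_sigma_is_1_over_n_mle(self):
        vals = np.array([1.0, 2.0, 3.0, 6.0])
        r = ss.fit_baseline(vals, "normal")
        assert r.params.theta["sigma"] == pytest.approx(
            float(np.sqrt(np.mean((vals - vals.mean()) ** 2)))
        )

    def test_geometric_moment_form(self):
        vals = np.array([0, 0, 1, 3])
        r = ss.fit_baseline(vals, "geometric")
        assert r.params.theta["p"] == pytest.approx(1.0 / 2.0)

    def test_degenerate_samples_error(self):
        with pytest.raises(ss.EstimationError):
            ss.fit_baseline([2.0, 2.0, 2.0], "normal")
        with pytest.raises(ss.EstimationError):
            ss.fit_baseline([0.0, 0.0], "exponential")
        with pytest.raises(ss.EstimationError):
            ss.fit_baseline([0.5, 1.5], "poisson")  # non-integer for discrete


class TestHurdle:
    def test_no_zeros_reduces_to_baseline(self):
        vals = ss.sample_plain(200, "normal", {"mu": 5, "sigma": 1}, seed=0)
        vals = vals[vals != 0]
        h = ss.fit_hurdle(vals, "normal")
        b = ss.fit_baseline(vals, "normal")
        assert h.params.phi == 0.0
        assert h.params.theta == b.params.theta
        assert h.loglik == pytest.approx(b.loglik)

    def test_poisson_hurdle_grid_oracle(self):
        vals = np.array([0, 0, 1, 1, 2])
        r = ss.fit_hurdle(vals, "poisson")
        assert r.params.phi == pytest.approx(0.4)
        # 1-D dense grid oracle for the zero-truncated MLE: with non-zero
        # values {1, 1, 2}, ll(lam) = 4 log lam - 3 lam - 3 log(1 - e^-lam) + c
        lams = np.linspace(1e-4, 20, 200_001)
        ll = 4 * np.log(lams) - 3 * lams - 3 * np.log1p(-np.exp(-lams))
        grid_lam = lams[np.argmax(ll)]
        assert r.params.theta["lambda"] == pytest.approx(grid_lam, abs=1e-4)

    def test_all_zero_sample_errors(self):
        with pytest.raises(ss.EstimationError, match="phi"):
            ss.fit_hurdle(np.zeros(10), "poisson")

    def test_factorization_identity(self):
        vals = ss.sample_hurdle(300, 0.25, "poisson", {"lambda": 3}, seed=1)
        r = ss.fit_hurdle(vals, "poisson")
        n0 = int(np.sum(vals == 0))
        n = vals.size
        phi = r.params.phi
        nz = vals[vals != 0]
        p0 = ss.p0("poisson", r.params.theta)
        trunc = float(
            np.sum(ss.log_density("P", r.params.theta, nz)) - nz.size * np.log1p(-p0)
        )
        expected = n0 * math.log(phi) + (n - n0) * math.log(1 - phi) + trunc
        assert r.loglik == pytest.approx(expected, abs=1e-8)


class TestZeroInflated:
    def test_zip_grid_oracle(self):
        vals = np.array([0, 0, 1, 2])
        r = ss.fit_zi(vals, "poisson")
        phis = np.linspace(0, 0.999, 1000)
        lams = np.linspace(1e-4, 10, 2001)
        P, L = np.meshgrid(phis, lams, indexing="ij")
        ll = (
            2 * np.log(P + (1 - P) * np.exp(-L))
            + 2 * np.log1p(-P)
            + (np.log(L) - L) + (2 * np.log(L) - L - np.log(2))
        )
        assert r.loglik >= ll.max() - 1e-3

    def test_bb_grid_oracle(self):
        vals = np.array([0, 0, 1, 1, 2, 2, 3, 4])
        r = ss.fit_baseline(vals, "bb")
        # dense grid-search oracle over (n, alpha, beta)
        ns = np.linspace(4.0, 50, 47)
        als = np.geomspace(0.01, 50, 60)
        bes = np.geomspace(0.01, 50, 60)
        grid = np.array(
            [
                float(np.sum(ss.log_density("BB", {"n": n, "alpha": a, "beta": b}, vals)))
                for n in ns
                for a in als
                for b in bes
            ]
        )
        assert r.loglik >= np.nanmax(grid) - 1e-3

    def test_continuous_zi_delegates_to_hurdle(self):
        vals = ss.sample_zi(500, 0.3, "exponential", {"lambda": 5}, seed=2)
        z = ss.fit_zi(vals, "exponential")
        h = ss.fit_hurdle(vals, "exponential")
        assert z.params.theta == h.params.theta
        assert z.params.phi == h.params.phi
        assert z.family.structure == "zero-inflated"

    def test_boundary_phi_zero_allowed(self):
        vals = ss.sample_plain(500, "poisson", {"lambda": 0.5}, seed=3)
        z = ss.fit_zi(vals, "poisson")
        b = ss.fit_baseline(vals, "poisson")
        assert z.params.phi == pytest.approx(0.0, abs=0.05)
        assert z.loglik >= b.loglik - 1e-8  # likelihood dominance (nested)
        assert z.k == 2  # phi still counted


class TestResultInvariants:
    @pytest.mark.parametrize("code", ["N", "NH", "ZIP", "BB", "ZIBNB"])
    def test_aic_bic_formulas_and_loglik_recompute(self, code):
        params = REF_POINT[code]
        vals = ss.sample(code, params, 400, seed=7)
        r = fit_model(vals, code, seed=7)
        assert r.aic == pytest.approx(-2 * r.loglik + 2 * r.k, abs=1e-12)
        assert r.bic == pytest.approx(-2 * r.loglik + math.log(r.n) * r.k, abs=1e-12)
        recomputed = log_likelihood(r.family, r.params, vals)
        assert r.loglik == pytest.approx(recomputed, abs=1e-6)

    def test_serialization_round_trip(self):
        import json

        vals = ss.sample("NH", {"mu": 5, "sigma": 1, "phi": 0.2}, 100, seed=8)
        r = fit_model(vals, "NH")
        d = json.loads(r.to_json())
        assert d["family"] == "NH"
        assert d["k"] == 3 and d["N"] == 100
        assert d["aic"] == pytest.approx(r.aic)


class TestParameterRecovery:
    @pytest.mark.parametrize("code", list(REF_POINT))
    def test_reference_point_recovered_within_3_mc_se(self, code):
        params = REF_POINT[code]
        rng = np.random.default_rng(77_100)
        vals = ss.sample(code, params, 2000, rng)
        r = fit_model(vals, code, seed=rng)
        est = r.params.as_dict()
        for name, tol in RECOVERY_TOL[code].items():
            assert est[name] == pytest.approx(params[name], abs=tol), (
                f"{code}.{name}: {est[name]} vs {params[name]} (tol {tol})"
            )
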