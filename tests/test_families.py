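"""Distribution layer: densities, CDFs, zero masses, samplers."""

import numpy as np
import pytest
from scipy import integrate, stats

import sparseselect as ss
from sparseselect.families import BASELINES, parse_family

REF_PARAMS = {
    "N": {"mu": 5, "sigma": 2},
    "LN": {"mu": 1, "sigma": 0.8},
    "HN": {"sigma": 3},
    "E": {"lambda": 2},
    "P": {"lambda": 3},
    "G": {"p": 0.35},
    "NB": {"r": 5, "p": 0.4},
    "BB": {"n": 6, "alpha": 2, "beta": 3},
    "BNB": {"r": 10, "alpha": 3, "beta": 5},
}


def with_phi(params, phi=0.3):
    return {**params, "phi": phi}


class TestDensity:
    @pytest.mark.parametrize("code", list(REF_PARAMS))
    def test_hurdle_density_at_zero_is_phi(self, code):
        fam = parse_family(code + "H" if code != "HN" else "HNH")
        assert ss.density(fam, with_phi(REF_PARAMS[code], 0.37), 0.0) == pytest.approx(0.37)

    def test_zip_closed_form(self):
        val = ss.density("ZIP", {"lambda": 1, "phi": 0.4}, 0)
        assert val == pytest.approx(0.4 + 0.6 * np.exp(-1), abs=1e-9)

    def test_zibnb_sums_to_one(self):
        # numeric summation oracle over the (heavy-tailed) support
        ys = np.arange(0, 200_000)
        total = ss.density("ZIBNB", with_phi(REF_PARAMS["BNB"], 0.4), ys).sum()
        assert total == pytest.approx(1.0, abs=1e-8)

    @pytest.mark.parametrize("code", list(REF_PARAMS))
    @pytest.mark.parametrize("structure", ["", "ZI", "H"])
    def test_normalization(self, code, structure):
        """Discrete mass sums to 1; continuous: phi + integral over y != 0."""
        if structure == "ZI":
            name = "ZI" + code
        elif structure == "H":
            name = code + "H"
        else:
            name = code
        fam = parse_family(name)
        params = REF_PARAMS[code] if fam.structure == "plain" else with_phi(REF_PARAMS[code])
        if fam.is_discrete:
            ys = np.arange(0, 200_000)
            assert ss.density(fam, params, ys).sum() == pytest.approx(1.0, abs=1e-8)
        else:
            phi = params.get("phi", 0.0)
            pdf = lambda y: ss.density(fam, params, y)  # noqa: E731
            mass, _ = integrate.quad(pdf, -np.inf, np.inf, limit=200)
            assert phi + mass == pytest.approx(1.0, abs=1e-7)

    def test_negative_y_gives_zero_for_nonnegative_support(self):
        assert ss.density("EH", {"lambda": 2, "phi": 0.3}, -1.0) == 0.0
        assert ss.density("ZIP", {"lambda": 2, "phi": 0.3}, -3) == 0.0

    def test_invalid_params_raise(self):
        with pytest.raises(ss.ParameterError):
            ss.density("N", {"mu": 0, "sigma": -1}, 0.0)
        with pytest.raises(ss.ParameterError):
            ss.density("ZIP", {"lambda": 1, "phi": 1.4}, 0)


class TestCdf:
    def test_hurdle_normal_limits_and_jump(self):
        params = {"mu": 10, "sigma": 2, "phi": 0.3}
        assert ss.cdf("NH", params, 1e9) == pytest.approx(1.0)
        assert ss.cdf("NH", params, -1e9) == pytest.approx(0.0)
        expected = 0.3 + 0.7 * stats.norm.cdf(-5)
        assert ss.cdf("NH", params, 0.0) == pytest.approx(expected, abs=1e-12)

    def test_zip_cdf_by_pmf_summation(self):
        # oracle: jump at 0 plus two Poisson terms
        assert ss.cdf("ZIP", {"lambda": 1, "phi": 0.4}, 1) == pytest.approx(
            0.4 + 0.6 * (np.exp(-1) + np.exp(-1)), abs=1e-12
        )

    @pytest.mark.parametrize("name", ["NH", "ZIP", "ZIBNB", "GH", "LNH"])
    def test_monotone_in_unit_interval(self, name):
        fam = parse_family(name)
        base = {"NH": "N", "ZIP": "P", "ZIBNB": "BNB", "GH": "G", "LNH": "LN"}[name]
        params = with_phi(REF_PARAMS[base])
        ys = np.linspace(-2, 60, 301)
        F = ss.cdf(fam, params, ys)
        assert np.all(np.diff(F) >= -1e-12)
        assert np.all((F >= 0) & (F <= 1))

    def test_cdf_jump_matches_point_mass(self):
        params = with_phi(REF_PARAMS["P"])
        eps = 1e-9
        jump = ss.cdf("ZIP", params, 0) - ss.cdf("ZIP", params, -eps)
        assert jump == pytest.approx(ss.point_mass("ZIP", params, 0), abs=1e-9)


class TestP0:
    def test_continuous_rule(self):
        assert ss.p0("exponential", {"lambda": 20}) == 0.0
        assert ss.p0("normal", {"mu": 3, "sigma": 1}) == 0.0

    def test_poisson(self):
        assert ss.p0("poisson", {"lambda": 1}) == pytest.approx(np.exp(-1))

    def test_beta_binomial_direct_evaluation(self):
        # direct pmf oracle: B(alpha, n + beta) / B(alpha, beta) = 3/14
        expected = 3.0 / 14.0
        assert ss.p0("bb", {"n": 4, "alpha": 2, "beta": 3}) == pytest.approx(
            expected, abs=1e-12
        )
        direct = float(stats.betabinom.pmf(0, 4, 2, 3))
        assert ss.p0("bb", {"n": 4, "alpha": 2, "beta": 3}) == pytest.approx(direct)


class TestContinuousZiHurdleEquivalence:
    @pytest.mark.parametrize("base", ["N", "LN", "HN", "E"])
    @pytest.mark.parametrize("phi", [0.0, 0.25, 0.7])
    def test_density_and_cdf_agree(self, base, phi):
        params = with_phi(REF_PARAMS[base], phi)
        zi = parse_family("ZI" + base)
        h = parse_family(base + "H")
        ys = np.array([-1.0, 0.0, 0.3, 1.0, 2.5, 7.0, 30.0])
        np.testing.assert_allclose(
            ss.density(zi, params, ys), ss.density(h, params, ys), rtol=0, atol=1e-12
        )
        np.testing.assert_allclose(
            ss.cdf(zi, params, ys), ss.cdf(h, params, ys), rtol=0, atol=1e-12
        )


class TestSamplers:
    def test_hurdle_zero_count_binomial_bounds(self):
        vals = ss.sample_hurdle(2000, 0.3, "normal", {"mu": 10, "sigma": 2}, seed=11)
        n0 = int(np.sum(vals == 0))
        lo, hi = stats.binom.ppf([0.0005, 0.9995], 2000, 0.3)
        assert lo <= n0 <= hi

    def test_phi_extremes(self):
        none = ss.sample_hurdle(500, 0.0, "poisson", {"lambda": 3}, seed=1)
        assert np.all(none != 0)
        allz = ss.sample_hurdle(500, 1.0, "poisson", {"lambda": 3}, seed=1)
        assert np.all(allz == 0)
        plain = ss.sample_zi(2000, 0.0, "poisson", {"lambda": 3}, seed=2)
        dkw = np.sqrt(np.log(2 / 0.001) / (2 * 2000))
        assert ss.ks_statistic(plain, "P", {"lambda": 3}) < dkw

    def test_zi_zero_fraction_closed_form(self):
        vals = ss.sample_zi(100_000, 0.4, "poisson", {"lambda": 1}, seed=3)
        expected = 0.4 + 0.6 * np.exp(-1)
        assert np.mean(vals == 0) == pytest.approx(expected, abs=0.006)
        cont = ss.sample_zi(2000, 0.3, "exponential", {"lambda": 20}, seed=4)
        lo, hi = stats.binom.ppf([0.0005, 0.9995], 2000, 0.3) / 2000
        assert lo <= np.mean(cont == 0) <= hi

    @pytest.mark.parametrize("name,params", [
        ("NH", {"mu": 10, "sigma": 2, "phi": 0.3}),
        ("ZIP", {"lambda": 3, "phi": 0.3}),
        ("ZIBNB", {"r": 10, "alpha": 3, "beta": 5, "phi": 0.3}),
        ("LNH", {"mu": 1, "sigma": 1.5, "phi": 0.2}),
    ])
    def test_sampler_matches_cdf_within_dkw(self, name, params):
        n = 100_000
        vals = np.sort(ss.sample(name, params, n, seed=5))
        fam = parse_family(name)
        u, counts = np.unique(vals, return_counts=True)
        fn = np.cumsum(counts) / n
        F = ss.cdf(fam, params, u)
        sup = np.max(np.abs(fn - F))
        dkw = np.sqrt(np.log(2 / 0.001) / (2 * n))
        assert sup < dkw

    def test_hurdle_zero_probability_exact(self):
        # P(Y=0) is exactly phi under the hurdle structure
        assert ss.density("PH", {"lambda": 3, "phi": 0.42}, 0) == pytest.approx(0.42)
        # and phi + (1-phi) p0 under zero inflation
        zi0 = ss.density("ZIG", {"p": 0.35, "phi": 0.42}, 0)
        assert zi0 == pytest.approx(0.42 + 0.58 * 0.35, abs=1e-12)


class TestDistributionProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        phi=st.floats(0.0, 1.0),
        lam=st.floats(0.05, 30.0),
        mu=st.floats(-5.0, 15.0),
        sigma=st.floats(0.1, 8.0),
    )
    def test_cdf_monotone_and_consistent_with_mass(self, phi, lam, mu, sigma):
        ys = np.concatenate([np.linspace(-3, 40, 87), np.arange(0, 41)])
        ys = np.sort(ys)
        for name, params in (
            ("ZIP", {"lambda": lam, "phi": phi}),
            ("NH", {"mu": mu, "sigma": sigma, "phi": phi}),
        ):
            F = ss.cdf(name, params, ys)
            assert np.all(np.diff(F) >= -1e-9)
            assert np.all((F >= -1e-12) & (F <= 1 + 1e-12))
            assert np.all(ss.density(name, params, ys) >= 0)
            # the jump at zero equals the point mass there
            jump = ss.cdf(name, params, 0.0) - ss.cdf(name, params, -1e-12)
            assert jump == pytest.approx(ss.point_mass(name, params, 0.0), abs=1e-9)


class TestFamilyParsing:
    @pytest.mark.parametrize("name,expected", [
        ("NH", ("normal", "hurdle")),
        ("normalh", ("normal", "hurdle")),
        ("zilognorm", ("lognormal", "zero-inflated")),
        ("zip", ("poisson", "zero-inflated")),
        ("zibnb", ("beta-negative-binomial", "zero-inflated")),
        ("zero-inflated beta-negative-binomial", ("beta-negative-binomial", "zero-inflated")),
        ("lognormal hurdle", ("lognormal", "hurdle")),
        ("E", ("exponential", "plain")),
        ("bb", ("beta-binomial", "plain")),
    ])
    def test_aliases(self, name, expected):
        fam = parse_family(name)
        assert (fam.baseline, fam.structure) == expected

    def test_unknown_name_rejected(self):
        with pytest.raises(ss.ParameterError):
            parse_family("weibull")

    def test_k_counts_phi(self):
        assert parse_family("N").k == 2
        assert parse_family("NH").k == 3
        assert parse_family("ZIBNB").k == 4

    def test_all_27_models_enumerate(self):
        fams = {
            ss.ModelFamily(b, s)
            for b in BASELINES
            for s in ("plain", "zero-inflated", "hurdle")
        }
        assert len(fams) == 27
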