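"""Embryo scaling, mean-SD structure, the telegraph model, and the
variance-homogeneity test."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

import slmdesign as sd
from slmdesign.profiles import ExpressionProfile
from slmdesign.variability import (TelegraphParams, fit_embryo_scales,
                                   apply_embryo_scales, mean_normalize,
                                   mean_sd_regression, telegraph_pmf,
                                   variance_homogeneity_test)


def nucleus_table(embryo_values: dict[str, np.ndarray], ap_start=60.0):
    """Build a nucleus table with one nucleus per 1% bin per embryo."""
    rows = []
    for e, values in embryo_values.items():
        for k, v in enumerate(values):
            rows.append({"embryo": e, "nucleus": f"{e}_{k}",
                         "ap_percent": ap_start + k + 0.5,
                         "fluorescence": float(v), "line": "test"})
    return pd.DataFrame(rows)


class TestEmbryoScales:
    def test_identical_embryos_get_unit_scales(self):
        f = np.array([5.0, 8.0, 3.0, 10.0])
        t = nucleus_table({"a": f, "b": f, "c": f})
        scaling = fit_embryo_scales(t)
        assert np.allclose(list(scaling.scales.values()), 1.0)
        assert scaling.objective == pytest.approx(0.0, abs=1e-18)

    @pytest.mark.parametrize("c", [2.0, 0.5, 3.7])
    def test_two_embryo_closed_form(self, c):
        # profiles f and c*f: minimiser is s = (2c/(1+c), 2/(1+c))
        f = np.array([4.0, 9.0, 2.0])
        t = nucleus_table({"a": f, "b": c * f})
        scaling = fit_embryo_scales(t)
        assert scaling.scales["a"] == pytest.approx(2 * c / (1 + c))
        assert scaling.scales["b"] == pytest.approx(2 / (1 + c))

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_numeric_optimizer(self, seed):
        """Exact KKT solution agrees with a black-box constrained optimiser."""
        rng = np.random.default_rng(seed)
        embryos = {f"e{i}": rng.uniform(1, 10, size=8) for i in range(4)}
        t = nucleus_table(embryos)
        scaling = fit_embryo_scales(t)
        names = sorted(embryos)
        m = np.array([embryos[e] for e in names])

        def objective(s):
            tot = 0.0
            for b in range(m.shape[1]):
                for i in range(len(names)):
                    for j in range(i + 1, len(names)):
                        tot += (s[i] * m[i, b] - s[j] * m[j, b]) ** 2
            return tot

        res = optimize.minimize(
            objective, np.ones(len(names)),
            constraints={"type": "eq", "fun": lambda s: s.sum() - len(names)},
            method="SLSQP", options={"ftol": 1e-14, "maxiter": 500},
        )
        fitted = np.array([scaling.scales[e] for e in names])
        assert np.allclose(fitted, res.x, atol=1e-6)
        assert fitted.sum() == pytest.approx(len(names))

    def test_order_invariance(self):
        rng = np.random.default_rng(7)
        embryos = {f"e{i}": rng.uniform(1, 10, size=6) for i in range(3)}
        t = nucleus_table(embryos)
        shuffled = t.sample(frac=1.0, random_state=1).reset_index(drop=True)
        s1 = fit_embryo_scales(t).scales
        s2 = fit_embryo_scales(shuffled).scales
        assert s1.keys() == s2.keys()
        assert np.allclose(list(s1.values()), list(s2.values()))

    def test_empty_embryo_rejected(self):
        t = nucleus_table({"a": np.ones(4), "b": np.ones(4)})
        t = pd.concat([t, pd.DataFrame([{
            "embryo": "ghost", "nucleus": "g0", "ap_percent": 10.5,
            "fluorescence": np.nan, "line": "test"}])])
        t = t.dropna()  # ghost now has no rows at all -> not an embryo
        single = nucleus_table({"a": np.ones(4)})
        with pytest.raises(ValueError, match="at least 2"):
            fit_embryo_scales(single)


class TestMeanSdRegression:
    def test_constant_spread_gives_zero_slope(self):
        # each bin has values mu_k +/- delta -> population SD = delta
        rows = []
        delta = 2.0
        for k, mu in enumerate([10.0, 20.0, 30.0, 40.0]):
            for e, v in (("a", mu - delta), ("b", mu + delta)):
                rows.append({"embryo": e, "nucleus": f"{e}{k}",
                             "ap_percent": 60 + k + 0.5, "fluorescence": v,
                             "line": "t"})
        slope, intercept, _ = mean_sd_regression(pd.DataFrame(rows))
        assert slope == pytest.approx(0.0, abs=1e-12)
        assert intercept == pytest.approx(delta)

    def test_too_few_bins_rejected(self):
        t = nucleus_table({"a": np.ones(2), "b": np.ones(2)})
        with pytest.raises(ValueError, match="3 populated"):
            mean_sd_regression(t)

    def test_low_on_probability_gives_larger_slope(self):
        """Telegraph data at p=0.5 vs p=0.9, means matched bin-by-bin by
        varying N: the noisy (low-p) line has the larger mean-SD slope."""
        grid = np.arange(60.5, 80.5, 1.0)
        profile = ExpressionProfile("t", grid, np.linspace(50, 250, grid.size))
        noisy = sd.make_embryos("noisy", profile, TelegraphParams(20, 0.5),
                                n_embryos=1, nuclei_per_bin=150,
                                embryo_scale_sd=0.0, seed=11)
        quiet = sd.make_embryos("quiet", profile, TelegraphParams(11, 0.9),
                                n_embryos=1, nuclei_per_bin=150,
                                embryo_scale_sd=0.0, seed=12)
        slope_noisy, _, _ = mean_sd_regression(noisy)
        slope_quiet, _, _ = mean_sd_regression(quiet)
        assert slope_noisy > slope_quiet


class TestMeanNormalize:
    def test_constant_input_gives_ones(self):
        t = nucleus_table({"a": np.full(20, 7.0), "b": np.full(20, 7.0)})
        out = mean_normalize(t, (60.0, 80.0))
        assert np.allclose(out, 1.0)

    def test_per_bin_mean_is_one(self):
        rng = np.random.default_rng(3)
        t = nucleus_table({e: rng.uniform(1, 9, 20) for e in "abcd"})
        out = mean_normalize(t, (60.0, 80.0))
        sub = t[(t.ap_percent >= 60) & (t.ap_percent < 80)].copy()
        sub["norm"] = out
        means = sub.groupby(np.floor(sub.ap_percent))["norm"].mean()
        assert np.allclose(means, 1.0, atol=1e-12)

    def test_empty_window_bin_rejected(self):
        t = nucleus_table({"a": np.ones(5), "b": np.ones(5)})  # bins 60-64 only
        with pytest.raises(ValueError, match="empty"):
            mean_normalize(t, (60.0, 80.0))


def gillespie_telegraph(params, total_time, seed, burn_in=50.0):
    """Independent stochastic-simulation oracle: one long trajectory of the
    two-state model; returns time-weighted occupancy of each mRNA count."""
    rng = np.random.default_rng(seed)
    k_on, k_off = params.b * params.p, params.b * (1 - params.p)
    t, g, n = 0.0, 0, 0
    occupancy = {}
    events = 0
    while t < total_time:
        rates = [k_on if g == 0 else k_off, params.N if g == 1 else 0.0, n]
        total = sum(rates)
        dt = rng.exponential(1.0 / total)
        if t > burn_in:
            occupancy[n] = occupancy.get(n, 0.0) + min(dt, total_time - t)
        t += dt
        u = rng.random() * total
        if u < rates[0]:
            g = 1 - g
        elif u < rates[0] + rates[1]:
            n += 1
        else:
            n -= 1
        events += 1
    weights = np.zeros(max(occupancy) + 1)
    for k, w in occupancy.items():
        weights[k] = w
    return weights / weights.sum(), events


class TestTelegraphPmf:
    def test_normalisation_and_mean_np(self):
        dist = telegraph_pmf(TelegraphParams(20, 0.5, 4), n_max=120)
        assert dist.phi.sum() == pytest.approx(1.0, abs=1e-8)
        assert np.all(dist.phi >= 0)
        assert dist.mean == pytest.approx(10.0, abs=1e-6)

    def test_mean_np_other_parameters(self):
        dist = telegraph_pmf(TelegraphParams(11, 0.9, 4), n_max=80)
        assert dist.mean == pytest.approx(11 * 0.9, abs=1e-6)

    def test_poisson_limit_as_p_to_one(self):
        dist = telegraph_pmf(TelegraphParams(5, 0.999, 4), n_max=60)
        pois = stats.poisson.pmf(np.arange(61), 5)
        tv = 0.5 * np.abs(dist.phi - pois).sum()
        assert tv < 1e-3

    def test_matches_gillespie_simulation(self):
        """The master-equation solution matches a long exact-stochastic
        trajectory at the quiet-reporter parameters (N=11, p=0.9, b=4)."""
        params = TelegraphParams(11, 0.9, 4)
        dist = telegraph_pmf(params, n_max=80)
        emp, events = gillespie_telegraph(params, total_time=6000.0, seed=42)
        assert events > 1e5
        k = min(len(emp), len(dist.phi))
        tv = 0.5 * np.abs(emp[:k] - dist.phi[:k]).sum()
        assert tv < 0.02
        # chi-square goodness of fit on pooled tail bins
        edges = np.arange(0, 25, 2)
        obs = np.add.reduceat(emp[:24], edges[:-1])
        exp = np.add.reduceat(dist.phi[:24], edges[:-1])
        chi2 = np.sum((obs - exp) ** 2 / exp)
        assert chi2 < 0.05  # proportions, not counts: tiny discrepancy

    def test_variance_falls_with_p_at_fixed_mean(self):
        mean = 10.0
        variances = []
        for p in (0.4, 0.6, 0.8, 0.95):
            dist = telegraph_pmf(TelegraphParams(mean / p, p, 4),
                                 n_max=int(10 * mean / p))
            assert dist.mean == pytest.approx(mean, abs=1e-6)
            variances.append(dist.variance)
        assert variances == sorted(variances, reverse=True)

    def test_truncation_guard(self):
        with pytest.raises(ValueError, match="n_max"):
            telegraph_pmf(TelegraphParams(20, 0.5, 4), n_max=50)


class TestVarianceHomogeneity:
    def test_matches_scipy_fligner(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 200)
        y = rng.normal(0, 2, 180)
        stat, p = variance_homogeneity_test(x, y)
        ref_stat, ref_p = stats.fligner(x, y)
        assert stat == pytest.approx(ref_stat, rel=1e-10)
        assert p == pytest.approx(ref_p, rel=1e-10)

    def test_shift_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 50)
        y = rng.normal(0, 1.5, 60)
        s1, _ = variance_homogeneity_test(x, y)
        s2, _ = variance_homogeneity_test(x + 100.0, y - 7.0)
        # analytic invariance; numerically limited by rounding of x+100-median
        assert s1 == pytest.approx(s2, rel=1e-3)

    def test_power_at_fourfold_variance(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 2, 500)
        y = rng.normal(0, 1, 500)
        _, p = variance_homogeneity_test(x, y)
        assert p < 0.01

    def test_type_one_error_calibration(self):
        """Under the null (identical distributions) the test rejects at the
        nominal 5% level: empirical rate within [0.03, 0.07] over 1,000
        seeded replicates."""
        rng = np.random.default_rng(12345)
        rejections = 0
        for _ in range(1000):
            x = rng.normal(0, 1, 40)
            y = rng.normal(0, 1, 40)
            _, p = variance_homogeneity_test(x, y)
            rejections += p < 0.05
        assert 0.03 <= rejections / 1000 <= 0.07

    def test_degenerate_samples_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            variance_homogeneity_test(np.ones(10), np.ones(10))
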