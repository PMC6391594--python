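import math

import numpy as np
import pandas as pd
import pytest

from riverload.calibration import (DEFAULT_PATTERNS, DT50_GRID,
                                   CalibrationError, DegenerateProxyError,
                                   ProxyFit, apply_dt50_override,
                                   bootstrap_uncertainty, build_proxy_grid,
                                   calibrate_substance, grid_calibrate,
                                   r2_class, select_best, wls_fit)
from riverload.network import Reach, StreamNetwork
from riverload.observations import compute_observed_loads
from riverload.synthetic import (Substance, SyntheticScenario,
                                 generate_network, generate_observations,
                                 generate_patterns, generate_true_state)


def closed_form_wls(x, y, w):
    """Independent oracle: weighted normal equations in closed form."""
    sw = np.sum(w)
    xbar = np.sum(w * x) / sw
    ybar = np.sum(w * y) / sw
    sxx = np.sum(w * (x - xbar) ** 2)
    sxy = np.sum(w * (x - xbar) * (y - ybar))
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    rss = np.sum(w * (y - intercept - slope * x) ** 2)
    tss = np.sum(w * (y - ybar) ** 2)
    r2 = 0.0 if tss == 0 else max(0.0, min(1.0, 1.0 - rss / tss))
    return slope, intercept, r2


def _noiseless_setup(seed, true_pattern="pop", true_dt50=10.0, true_ef=20.0,
                     n_reaches=250):
    scenario = SyntheticScenario(
        seed=seed, n_reaches=n_reaches, noise_sigma=0.0,
        substances=(Substance("s", true_pattern, true_ef, true_dt50),))
    network = generate_patterns(generate_network(scenario), scenario)
    truth = generate_true_state(network, scenario)
    observations = generate_observations(truth, scenario)
    loads, _ = compute_observed_loads(observations)
    proxies = build_proxy_grid(network)
    return network, proxies, loads


class TestWLSFit:
    def test_exact_linear(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        fit = wls_fit(x, 2 * x, np.ones(4))
        assert fit.slope == pytest.approx(2.0, rel=1e-12)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_constant_y(self):
        x = np.array([1.0, 2.0, 3.0])
        fit = wls_fit(x, np.full(3, 5.0), np.ones(3))
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.r_squared == 0.0

    def test_derived_normal_equation_case(self):
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([1.0, 3.0, 4.0])
        w = np.sqrt(y)
        fit = wls_fit(x, y, w)
        slope, intercept, r2 = closed_form_wls(x, y, w)
        assert fit.slope == pytest.approx(slope, rel=1e-12)
        assert fit.intercept == pytest.approx(intercept, rel=1e-12)
        assert fit.r_squared == pytest.approx(r2, rel=1e-12)

    def test_degenerate_proxy(self):
        with pytest.raises(DegenerateProxyError, match="degenerate proxy"):
            wls_fit(np.ones(5), np.arange(5.0), np.ones(5))

    def test_too_few_points(self):
        with pytest.raises(CalibrationError, match="3 points"):
            wls_fit(np.array([1.0, 2.0]), np.array([1.0, 2.0]),
                    np.array([1.0, 1.0]))

    def test_nonpositive_weights(self):
        with pytest.raises(ValueError, match="weights"):
            wls_fit(np.arange(3.0), np.arange(3.0), np.array([1.0, 0.0, 1.0]))

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_normal_equation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 60))
        x = rng.lognormal(2.0, 1.0, n)
        y = rng.lognormal(3.0, 1.0, n)
        w = rng.uniform(0.1, 5.0, n)
        fit = wls_fit(x, y, w)
        slope, intercept, r2 = closed_form_wls(x, y, w)
        assert fit.slope == pytest.approx(slope, rel=1e-10)
        assert fit.intercept == pytest.approx(intercept, rel=1e-10,
                                              abs=1e-10 * abs(y).max())
        assert fit.r_squared == pytest.approx(r2, abs=1e-10)


class TestProxyGrid:
    def test_four_patterns_nine_dt50_gives_36(self):
        scenario = SyntheticScenario(seed=1, n_reaches=40)
        network = generate_patterns(generate_network(scenario), scenario)
        proxies = build_proxy_grid(network)
        assert proxies.shape == (40, 36)
        assert len(DEFAULT_PATTERNS) * len(DT50_GRID) == 36

    def test_single_combination(self):
        net = StreamNetwork([Reach("a", None, travel_time=1.0,
                                   pattern_values={"pop": 10.0})])
        proxies = build_proxy_grid(net, patterns=["pop"], dt50_grid=[10.0])
        assert proxies.shape == (1, 1)
        assert proxies.loc["a", ("pop", 10.0)] == \
            pytest.approx(10.0 * 0.5 ** 0.1)

    def test_uniform_pattern_supported(self):
        scenario = SyntheticScenario(seed=1, n_reaches=20)
        network = generate_patterns(generate_network(scenario), scenario)
        proxies = build_proxy_grid(network, include_uniform=True)
        assert proxies.shape[1] == 45  # (4 + 1 uniform) x 9
        assert "uniform" in proxies.columns.get_level_values("pattern")

    def test_unknown_pattern(self, chain3):
        with pytest.raises(Exception, match="unknown pattern"):
            build_proxy_grid(chain3, patterns=["nope"])


class TestGridCalibrate:
    def test_noiseless_recovery(self):
        _net, proxies, loads = _noiseless_setup(seed=123)
        grid = grid_calibrate(proxies, loads)
        assert grid.selected.pattern == "pop"
        assert grid.selected.dt50 == 10.0
        assert grid.selected.slope == pytest.approx(20.0, rel=1e-6)
        assert grid.selected.distance_to_ideal < 1e-9

    def test_all_zero_loads_error(self):
        loads = pd.DataFrame({"reach_id": ["a", "b", "c"],
                              "load_ng_s": [0.0, 0.0, 0.0]})
        proxies = pd.DataFrame(
            {("pop", 10.0): [1.0, 2.0, 3.0]}, index=["a", "b", "c"])
        proxies.columns = pd.MultiIndex.from_tuples(proxies.columns)
        with pytest.raises(CalibrationError, match="fewer than 3"):
            grid_calibrate(proxies, loads)

    def test_tie_broken_by_smaller_dt50(self):
        # identical proxy columns at two DT50 values -> exact tie on both
        # distance and r2 -> smaller DT50 wins
        values = [1.0, 2.0, 3.0, 4.0]
        proxies = pd.DataFrame({("pop", 20.0): values, ("pop", 5.0): values},
                               index=list("abcd"))
        proxies.columns = pd.MultiIndex.from_tuples(proxies.columns)
        loads = pd.DataFrame({"reach_id": list("abcd"),
                              "load_ng_s": [2.0, 4.0, 6.0, 8.0]})
        grid = grid_calibrate(proxies, loads)
        assert grid.selected.dt50 == 5.0

    def test_tie_broken_by_higher_r2(self):
        fits = [
            ProxyFit("a", 10.0, 1.0, 0.0, 0.8, 0.5, 10),
            ProxyFit("b", 10.0, 1.0, 0.0, 0.9, 0.5, 10),
        ]
        assert select_best(fits).pattern == "b"

    def test_distance_zero_iff_ideal(self):
        _net, proxies, loads = _noiseless_setup(seed=9)
        grid = grid_calibrate(proxies, loads)
        for fit in grid.fits:
            ideal = (fit.r_squared == pytest.approx(1.0, abs=1e-12)
                     and fit.intercept == pytest.approx(0.0, abs=1e-9))
            if fit.distance_to_ideal == 0.0:
                assert ideal

    def test_selection_invariant_to_relabeling(self):
        _net, proxies, loads = _noiseless_setup(seed=5)
        shuffled = proxies[list(reversed(list(proxies.columns)))]
        a = grid_calibrate(proxies, loads).selected
        b = grid_calibrate(shuffled, loads).selected
        assert (a.pattern, a.dt50) == (b.pattern, b.dt50)


class TestBootstrap:
    def test_noiseless_ci_width_zero(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = 3.0 * x
        boot = bootstrap_uncertainty(x, y, n_boot=100, seed=0)
        lo, hi = boot.slope_interval
        assert hi - lo == pytest.approx(0.0, abs=1e-9)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(0)
        x = rng.lognormal(1.0, 1.0, 50)
        y = 2.0 * x * np.exp(rng.normal(0, 0.3, 50))
        a = bootstrap_uncertainty(x, y, n_boot=200, seed=42)
        b = bootstrap_uncertainty(x, y, n_boot=200, seed=42)
        assert a == b

    def test_interval_contains_true_slope_typical_case(self):
        rng = np.random.default_rng(1)
        x = rng.lognormal(2.0, 1.0, 200)
        y = 5.0 * x * np.exp(rng.normal(0, 0.3, 200))
        boot = bootstrap_uncertainty(x, y, n_boot=300, seed=1)
        assert boot.covers_slope(5.0)

    def test_n_boot_validation(self):
        with pytest.raises(ValueError, match="n_boot"):
            bootstrap_uncertainty(np.arange(5.0), np.arange(1.0, 6.0),
                                  n_boot=1)


class TestOverride:
    def test_override_equal_to_modelled_is_identity(self):
        _net, proxies, loads = _noiseless_setup(seed=11)
        base = calibrate_substance(proxies, loads, "s", "pop", n_boot=0)
        same = apply_dt50_override(base, base.modelled_dt50)
        assert same.emission_factor == base.emission_factor
        assert same.r2_drop == 0.0
        assert same.selected_dt50 == base.selected_dt50

    def test_override_off_grid_rejected(self):
        _net, proxies, loads = _noiseless_setup(seed=11)
        base = calibrate_substance(proxies, loads, "s", "pop", n_boot=0)
        with pytest.raises(CalibrationError, match="not on the grid"):
            apply_dt50_override(base, 12.0)

    def test_flat_likelihood_accepts_override(self):
        # all travel times zero -> proxies identical across DT50 -> r2 flat
        reaches = [Reach("r0", None, travel_time=0.0, drainage_area=50.0,
                         pattern_values={"pop": 5.0})]
        for i in range(1, 10):
            reaches.append(Reach(f"r{i}", "r0", travel_time=0.0,
                                 drainage_area=1.0 + i * 0.1,
                                 pattern_values={"pop": float(i * i)}))
        net = StreamNetwork(reaches)
        proxies = build_proxy_grid(net, patterns=["pop"])
        loads = pd.DataFrame({
            "reach_id": [f"r{i}" for i in range(10)],
            "load_ng_s": (2.0 * proxies[("pop", 10.0)]).to_numpy(),
        })
        base = calibrate_substance(proxies, loads, "s", "pop", n_boot=0)
        overridden = apply_dt50_override(base, 1000.0)
        assert overridden.r2_drop == pytest.approx(0.0, abs=1e-9)
        assert overridden.emission_factor == pytest.approx(2.0, rel=1e-9)

    def test_peaked_case_reports_large_r2_drop(self):
        # long travel times sharply separate DT50 values; pushing the
        # override to the grid extreme must cost explained variance
        scenario = SyntheticScenario(
            seed=21, n_reaches=200, noise_sigma=0.0, travel_time_mean=8.0,
            substances=(Substance("s", "pop", 20.0, 3.0),))
        network = generate_patterns(generate_network(scenario), scenario)
        truth = generate_true_state(network, scenario)
        observations = generate_observations(truth, scenario)
        loads, _ = compute_observed_loads(observations)
        proxies = build_proxy_grid(network)
        base = calibrate_substance(proxies, loads, "s", "pop", n_boot=0)
        assert base.modelled_dt50 == 3.0
        overridden = apply_dt50_override(base, 1000.0)
        assert overridden.r2_drop > 0.05
        assert overridden.selected_dt50 == 1000.0
        assert overridden.modelled_dt50 == 3.0  # retained


class TestCalibrateSubstance:
    def test_bootstrap_attached_and_deterministic(self):
        _net, proxies, loads = _noiseless_setup(seed=2)
        a = calibrate_substance(proxies, loads, "s", "pop", n_boot=50, seed=3)
        b = calibrate_substance(proxies, loads, "s", "pop", n_boot=50, seed=3)
        assert a.bootstrap == b.bootstrap
        lo, hi = a.bootstrap.slope_interval
        assert lo <= a.emission_factor <= hi

    def test_r2_class_thresholds(self):
        assert r2_class(0.6) == "high"
        assert r2_class(0.59) == "medium"
        assert r2_class(0.41) == "medium"
        assert r2_class(0.4) == "low"
        assert r2_class(0.1) == "low"
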