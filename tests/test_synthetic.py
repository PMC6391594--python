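import numpy as np
import pandas as pd
import pytest

from riverload.network import StreamNetwork
from riverload.synthetic import (Substance, SyntheticScenario,
                                 generate_exceedances, generate_network,
                                 generate_observations, generate_patterns,
                                 generate_point_sources, generate_true_state)


def _scenario(**kwargs):
    defaults = dict(seed=1, n_reaches=120)
    defaults.update(kwargs)
    return SyntheticScenario(**defaults)


def _full(scenario):
    network = generate_patterns(generate_network(scenario), scenario)
    truth = generate_true_state(network, scenario)
    return network, truth


class TestScenario:
    def test_validation(self):
        with pytest.raises(ValueError):
            SyntheticScenario(n_reaches=0)
        with pytest.raises(ValueError):
            SyntheticScenario(loq_fraction=1.5)
        with pytest.raises(ValueError):
            SyntheticScenario(agri_fraction_range=(0.5, 0.1))

    def test_dict_round_trip(self):
        scenario = _scenario(n_facilities=3)
        back = SyntheticScenario.from_dict(scenario.to_dict())
        assert back == scenario

    def test_substance_validation(self):
        with pytest.raises(ValueError, match="dt50"):
            Substance("x", "pop", 1.0, 0.0)


class TestGenerateNetwork:
    def test_single_reach(self):
        net = generate_network(_scenario(n_reaches=1))
        assert len(net) == 1
        assert net.outlets == net.reach_ids

    def test_deterministic(self):
        a = generate_network(_scenario(seed=7))
        b = generate_network(_scenario(seed=7))
        pd.testing.assert_frame_equal(a.to_frame(), b.to_frame())

    def test_different_seeds_differ(self):
        a = generate_network(_scenario(seed=1)).to_frame()
        b = generate_network(_scenario(seed=2)).to_frame()
        assert not a.equals(b)

    def test_structure_500_reaches(self):
        net = generate_network(_scenario(n_reaches=500))
        assert len(net) == 500
        assert len(net.outlets) == 1
        # acyclic by construction; topological order covers all reaches
        assert len(net.topological_order()) == 500
        # drainage areas honour the accumulation invariant (validated on
        # construction) and positive local areas
        assert (net.local_areas > 0).all()


class TestGeneratePatterns:
    def test_all_patterns_nonnegative(self):
        net, _ = _full(_scenario())
        for name in ("pop", "agri_km2", "livestock", "pop_connected"):
            assert (net.pattern(name) >= 0).all()

    def test_pairwise_correlations_not_degenerate(self):
        net, _ = _full(_scenario(n_reaches=400))
        table = pd.DataFrame({name: net.pattern(name) for name in
                              ("pop", "agri_km2", "livestock",
                               "pop_connected")})
        corr = table.corr().to_numpy()
        off_diag = corr[~np.eye(4, dtype=bool)]
        assert (np.abs(off_diag) < 1.0).all()

    def test_zero_agri_fraction(self):
        scenario = _scenario(agri_fraction_range=(0.0, 0.0))
        net = generate_patterns(generate_network(scenario), scenario)
        assert (net.pattern("agri_km2") == 0).all()

    def test_clustering_scales_urban_subset(self):
        flat = _scenario(seed=3, clustering_factor=1.0)
        clustered = _scenario(seed=3, clustering_factor=50.0)
        net_flat = generate_patterns(generate_network(flat), flat)
        net_clus = generate_patterns(generate_network(clustered), clustered)
        assert net_clus.pattern("pop").max() > net_flat.pattern("pop").max()


class TestGenerateTrueState:
    def test_zero_emission_factor(self):
        scenario = _scenario(substances=(Substance("z", "pop", 0.0, 10.0),))
        _, truth = _full(scenario)
        assert (truth.loads["z"] == 0).all()

    def test_linearity_in_emission_factor(self):
        s1 = _scenario(substances=(Substance("a", "pop", 10.0, 10.0),))
        s2 = _scenario(substances=(Substance("a", "pop", 20.0, 10.0),))
        _, t1 = _full(s1)
        _, t2 = _full(s2)
        pd.testing.assert_series_equal(2.0 * t1.loads["a"], t2.loads["a"])

    def test_single_reach_closed_form(self):
        scenario = SyntheticScenario(
            seed=5, n_reaches=1, n_stations=1,
            substances=(Substance("a", "pop", 7.0, 4.0),))
        net, truth = _full(scenario)
        rid = net.reach_ids[0]
        ep = net.pattern("pop")[rid]
        t = net[rid].travel_time
        assert truth.loads["a"][rid] == pytest.approx(
            7.0 * ep * 2 ** (-t / 4.0), rel=1e-12)

    def test_unknown_pattern_rejected(self):
        scenario = _scenario(substances=(Substance("a", "nope", 1.0, 10.0),))
        net = generate_patterns(generate_network(scenario), scenario)
        with pytest.raises(ValueError, match="unknown pattern"):
            generate_true_state(net, scenario)

    def test_point_sources_add_to_loads(self):
        scenario = _scenario(n_facilities=5)
        net = generate_patterns(generate_network(scenario), scenario)
        points = generate_point_sources(net, scenario)
        without = generate_true_state(net, scenario)
        with_points = generate_true_state(net, scenario, point_sources=points)
        outlet = net.outlets[0]
        for sub in points["substance"].unique():
            assert with_points.loads[sub][outlet] > without.loads[sub][outlet]


class TestGenerateObservations:
    def test_noiseless_observed_load_equals_true_load(self):
        scenario = _scenario(noise_sigma=0.0, discharge_day_sigma=0.0,
                             n_stations=10)
        _, truth = _full(scenario)
        obs = generate_observations(truth, scenario)
        for row in obs.itertuples(index=False):
            true_load = truth.loads[row.substance][row.reach_id]
            observed = row.concentration_ug_L * row.discharge_m3s * 1e6
            assert observed == pytest.approx(true_load, rel=1e-12)

    def test_full_censoring(self):
        scenario = _scenario(loq_fraction=1.0, n_stations=8)
        _, truth = _full(scenario)
        obs = generate_observations(truth, scenario)
        assert (obs["below_loq"] == 1).all()

    def test_noise_sigma_recovered(self):
        scenario = _scenario(
            n_reaches=300, n_stations=125, samples_per_station=4,
            noise_sigma=0.3,
            substances=(Substance("a", "pop", 20.0, 10.0),))
        _, truth = _full(scenario)
        obs = generate_observations(truth, scenario)  # 500 samples
        true_c = np.array([truth.concentrations[r.substance][r.reach_id]
                           for r in obs.itertuples(index=False)])
        log_ratio = np.log(obs["concentration_ug_L"].to_numpy() / true_c)
        assert len(log_ratio) == 500
        assert np.std(log_ratio) == pytest.approx(0.3, rel=0.15)

    def test_too_many_stations(self):
        scenario = _scenario(n_reaches=5, n_stations=10)
        _, truth = _full(scenario)
        with pytest.raises(ValueError, match="n_stations"):
            generate_observations(truth, scenario)

    def test_deterministic(self):
        scenario = _scenario()
        _, truth = _full(scenario)
        pd.testing.assert_frame_equal(generate_observations(truth, scenario),
                                      generate_observations(truth, scenario))


class TestGenerateExceedances:
    def test_unreachable_standard_gives_no_flags(self):
        scenario = _scenario(
            substances=(Substance("a", "pop", 10.0, 10.0, eqs_aa=1e12,
                                  eqs_mac=1e12),))
        _, truth = _full(scenario)
        exceed = generate_exceedances(truth, scenario)
        assert exceed.frame["exceed_aa"].sum() == 0
        assert exceed.frame["exceed_mac"].sum() == 0

    def test_zero_standard_flags_everything(self):
        scenario = _scenario(
            substances=(Substance("a", "pop", 10.0, 10.0, eqs_aa=0.0,
                                  eqs_mac=0.0),))
        _, truth = _full(scenario)
        exceed = generate_exceedances(truth, scenario)
        assert (exceed.frame["exceed_aa"] == 1).all()
        assert (exceed.frame["exceed_mac"] == 1).all()

    def test_label_noise_flip_rate(self):
        scenario = _scenario(
            n_reaches=1000, label_noise=0.1,
            substances=(Substance("a", "pop", 10.0, 10.0, eqs_aa=1e12,
                                  eqs_mac=1e12),))
        _, truth = _full(scenario)
        exceed = generate_exceedances(truth, scenario)
        # base flags are all zero, so every flag is a flip; 3-sigma
        # binomial band around 100/1000
        flipped = int(exceed.frame["exceed_aa"].sum())
        assert 70 <= flipped <= 130

    def test_quantile_thresholds_give_flags(self):
        scenario = _scenario(eqs_quantile_aa=0.9)
        _, truth = _full(scenario)
        exceed = generate_exceedances(truth, scenario)
        for sub in truth.substances:
            flags = exceed.flags(sub.name, "aa")
            assert 0 < flags.sum() < len(flags)


class TestMasterProperty:
    """Zero noise + true DT50 on the grid => exact pipeline recovery."""

    @pytest.mark.parametrize("pattern,dt50,ef", [
        ("pop", 10.0, 20.0),
        ("agri_km2", 50.0, 250.0),
        ("livestock", 5.0, 3.0),
    ])
    def test_recovery(self, pattern, dt50, ef):
        from riverload.calibration import build_proxy_grid, grid_calibrate
        from riverload.observations import compute_observed_loads
        scenario = _scenario(
            n_reaches=250, noise_sigma=0.0,
            substances=(Substance("s", pattern, ef, dt50),))
        net, truth = _full(scenario)
        obs = generate_observations(truth, scenario)
        loads, _ = compute_observed_loads(obs)
        grid = grid_calibrate(build_proxy_grid(net), loads)
        assert grid.selected.pattern == pattern
        assert grid.selected.dt50 == dt50
        assert grid.selected.slope == pytest.approx(ef, rel=1e-6)
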