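import numpy as np
import pytest

import adloop as al
from adloop.connectome import diffusion_laplacian, graph_laplacian
from adloop.proteins import (ABETA_SEED_AMOUNT, TAU_SEED_AMOUNT,
                             ProteinParams, ProteinState, build_seeding,
                             heterodimer_derivatives, initialize_proteins,
                             integrate_proteinopathy)


@pytest.fixture(scope="module")
def params():
    return ProteinParams()


class TestSeeding:
    def test_fixed_strategy_counts_on_bundled_annotation(self, cingulum_con):
        s = build_seeding(cingulum_con, "fixed")
        assert s.abeta_regions.size == 12
        assert s.tau_regions.size == 2
        assert s.abeta_amount == 0.0125 and s.tau_amount == 0.0025
        for i in s.tau_regions:
            assert cingulum_con.regions[i].braak_stage == "I"

    @pytest.mark.parametrize("strategy", ["abeta_random", "tau_random",
                                          "both_random"])
    def test_random_draws_are_hemisphere_symmetric(self, cingulum_con,
                                                   strategy):
        def stem(name):
            return name.split(" ", 1)[1]

        for seed in range(5):
            s = build_seeding(cingulum_con, strategy, rng_seed=seed)
            assert s.abeta_regions.size == 12 and s.tau_regions.size == 2
            for regions in (s.abeta_regions, s.tau_regions):
                names = {stem(cingulum_con.regions[i].name): []
                         for i in regions}
                for i in regions:
                    names[stem(cingulum_con.regions[i].name)].append(
                        cingulum_con.regions[i].hemisphere)
                for hemis in names.values():
                    assert sorted(hemis) == ["left", "right"]

    def test_tau_random_visits_multiple_pairs(self, cingulum_con):
        seen = {tuple(build_seeding(cingulum_con, "tau_random",
                                    rng_seed=k).tau_regions)
                for k in range(100)}
        assert len(seen) >= 2

    def test_deterministic_given_seed(self, cingulum_con):
        a = build_seeding(cingulum_con, "both_random", rng_seed=3)
        b = build_seeding(cingulum_con, "both_random", rng_seed=3)
        assert np.array_equal(a.abeta_regions, b.abeta_regions)
        assert np.array_equal(a.tau_regions, b.tau_regions)

    @pytest.mark.parametrize("strategy,cls", [("abeta_anterior", "anterior"),
                                              ("abeta_posterior",
                                               "posterior")])
    def test_restricted_class_draw_respects_ap_class(self, strategy, cls):
        con = al.synthetic_connectome(18, rng_seed=4)
        s = build_seeding(con, strategy, rng_seed=1)
        assert s.abeta_regions.size == 12
        assert all(con.regions[i].ap_class == cls
                   for i in s.abeta_regions)

    def test_restricted_draw_errors_when_too_few_pairs(self, cingulum_con):
        # the bundled annotation has only five posterior pairs for six seeds
        with pytest.raises(ValueError, match="eligible"):
            build_seeding(cingulum_con, "abeta_posterior", rng_seed=0)


class TestInitialization:
    def test_healthy_pools_at_production_clearance_equilibrium(
            self, cingulum_con, params):
        s = build_seeding(cingulum_con, "fixed")
        st = initialize_proteins(cingulum_con, s, params)
        assert np.allclose(st.ab, 1.0)
        assert np.allclose(st.t, 1.0)

    def test_seeds_receive_stated_amounts(self, cingulum_con, params):
        s = build_seeding(cingulum_con, "fixed")
        st = initialize_proteins(cingulum_con, s, params)
        assert np.allclose(st.tt[s.tau_regions], TAU_SEED_AMOUNT)
        assert np.allclose(st.abt[s.abeta_regions], ABETA_SEED_AMOUNT)
        others = np.setdiff1d(np.arange(cingulum_con.n), s.abeta_regions)
        assert np.all(st.abt[others] == 0)

    def test_negative_concentrations_rejected(self):
        with pytest.raises(ValueError):
            ProteinState(np.array([-0.1]), np.zeros(1), np.ones(1),
                         np.zeros(1))


class TestDerivatives:
    def test_healthy_equilibrium_is_stationary(self, cingulum_con, params):
        n = cingulum_con.n
        st = ProteinState(np.ones(n), np.zeros(n), np.ones(n), np.zeros(n))
        L = diffusion_laplacian(cingulum_con.weights, cingulum_con.lengths)
        d = heterodimer_derivatives(st, params, L, qha=1.0)
        assert np.all(np.abs(d.as_vector()) < 1e-14)

    def test_isolated_node_toxic_amyloid_growth_rate(self, params):
        # trans_ab * Ab - clear_abt = 3 - 2.4 = 0.6 per year
        st = ProteinState(np.ones(1), np.array([1e-3]), np.ones(1),
                          np.zeros(1))
        d = heterodimer_derivatives(st, params, np.zeros((1, 1)), 1.0)
        assert d.abt[0] == pytest.approx(0.6e-3, rel=1e-12)
        assert d.abt[0] > 0

    def test_diffusion_conserves_mass_except_biased_toxic_tau(self, rng,
                                                              params):
        n = 6
        w = rng.uniform(0, 1, (n, n))
        w = 0.5 * (w + w.T)
        np.fill_diagonal(w, 0)
        L = graph_laplacian(w)
        st = ProteinState(rng.uniform(0.5, 1.5, n), rng.uniform(0, .2, n),
                          rng.uniform(0.5, 1.5, n), rng.uniform(0, .2, n))
        zero = ProteinParams(prod_ab=1e-300, clear_ab=1e-300,
                             trans_ab=1e-300, clear_abt=1e-300,
                             prod_t=1e-300, clear_t=1e-300, trans_t=1e-300,
                             clear_tt=1e-300, syn=1e-300, rho=params.rho)
        d_neutral = heterodimer_derivatives(st, zero, L, qha=1.0)
        for pool in (d_neutral.ab, d_neutral.abt, d_neutral.t):
            assert abs(pool.sum()) < 1e-9
        assert abs(d_neutral.tt.sum()) < 1e-9
        qha = rng.uniform(0.5, 1.8, n)
        d_biased = heterodimer_derivatives(st, zero, L, qha=qha)
        assert abs(d_biased.tt.sum()) > 1e-6  # bias breaks conservation


class TestIntegration:
    def test_unseeded_state_constant_over_forty_years(self, cingulum_con,
                                                      params):
        n = cingulum_con.n
        st = ProteinState(np.ones(n), np.zeros(n), np.ones(n), np.zeros(n))
        L = diffusion_laplacian(cingulum_con.weights, cingulum_con.lengths)
        traj = integrate_proteinopathy(st, params, L, 1.0, (0, 40))
        drift = np.abs(traj.states - traj.states[0]).max()
        assert drift < 1e-6

    def test_toxic_tau_rises_sigmoidally_to_plateau(self, cingulum_con,
                                                    params):
        s = build_seeding(cingulum_con, "fixed")
        st = initialize_proteins(cingulum_con, s, params)
        L = diffusion_laplacian(cingulum_con.weights, cingulum_con.lengths)
        traj = integrate_proteinopathy(st, params, L, 1.0, (0, 40))
        tt = traj.tt
        assert np.all(tt >= 0)
        assert np.all(traj.states <= 10.0)  # bounded
        for i in range(cingulum_con.n):
            series = tt[:, i]
            k_peak = int(np.argmax(series))
            rises = np.diff(series[:k_peak + 1])
            assert np.all(rises >= -1e-9)  # non-decreasing up to its peak

    def test_wavefront_orders_arrival_times_by_graph_distance(self, path_con,
                                                              params):
        s = build_seeding(path_con, "fixed")
        st = initialize_proteins(path_con, s, params)
        L = diffusion_laplacian(path_con.weights, path_con.lengths)
        traj = integrate_proteinopathy(st, params, L, 1.0, (0, 40),
                                       dt_years=0.125)
        # hop distance from the tau seed along the stage-ordered path
        import networkx as nx
        G = nx.from_numpy_array(path_con.weights > 0)
        seed = int(s.tau_regions[0])
        dist = nx.single_source_shortest_path_length(G, seed)
        arrival = {}
        for i in range(path_con.n):
            above = np.flatnonzero(traj.tt[:, i] > 0.1)
            arrival[i] = traj.times[above[0]] if above.size else np.inf
        nodes = sorted(dist, key=dist.get)
        arr = [arrival[i] for i in nodes]
        d = [dist[i] for i in nodes]
        for a, b in zip(range(len(nodes) - 1), range(1, len(nodes))):
            if d[a] < d[b]:
                assert arr[a] <= arr[b] + 1e-9

    def test_halving_recording_step_barely_changes_endpoint(
            self, small_con, params):
        s = build_seeding(small_con, "fixed")
        st = initialize_proteins(small_con, s, params)
        L = diffusion_laplacian(small_con.weights, small_con.lengths)
        a = integrate_proteinopathy(st, params, L, 1.0, (0, 20),
                                    dt_years=0.25).final_state()
        b = integrate_proteinopathy(st, params, L, 1.0, (0, 20),
                                    dt_years=0.125).final_state()
        rel = np.abs(a.as_vector() - b.as_vector()) / (
            np.abs(b.as_vector()) + 1e-12)
        assert rel.max() < 0.01

    def test_tidy_frame_layout(self, small_con, params):
        s = build_seeding(small_con, "fixed")
        st = initialize_proteins(small_con, s, params)
        L = diffusion_laplacian(small_con.weights, small_con.lengths)
        traj = integrate_proteinopathy(st, params, L, 1.0, (0, 1),
                                       region_names=small_con.names)
        df = traj.to_frame()
        assert set(df.columns) == {"year", "region", "Ab", "Abt", "T", "Tt"}
        assert len(df) == 5 * small_con.n
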