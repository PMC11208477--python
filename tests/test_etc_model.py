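"""Electron-transport-chain model: structure, conservation, dynamics."""

import numpy as np
import pytest

from ojipscreen.etc_model import (
    BACKWARD_NAMES,
    FORWARD_NAMES,
    N_STATE,
    InitialStateConfig,
    LightRegime,
    PoolConfig,
    QuenchConfig,
    RateConstantSet,
    build_network,
    default_time_grid,
    extract_ojip_features,
    fluorescence,
    initial_state,
    pool_slices,
    pool_totals_vector,
    rhs,
    rhs_brute_force,
    simulate_fi,
)


@pytest.fixture(scope="module")
def intense_result():
    return simulate_fi(rtol=1e-8, atol=1e-10)


@pytest.fixture(scope="module")
def low_result():
    return simulate_fi(light=LightRegime.low(), rtol=1e-8, atol=1e-10)


class TestStructure:
    def test_state_and_parameter_counts(self):
        assert N_STATE == 43
        assert len(FORWARD_NAMES) == 18
        assert len(BACKWARD_NAMES) == 14

    def test_tabulated_defaults(self):
        rates = RateConstantSet()
        expected = {
            "k1f": 2000, "k2": 20000, "k3": 10000, "k4": 3330, "k5": 1000,
            "k6f": 3500, "k7f": 1750, "k8f": 250, "k9f": 100, "k10f": 2300,
            "k11f": 100, "k12f": 100, "k13f": 100, "k14f": 1, "k15f": 2000,
            "k16f": 200, "k17f": 200, "k18f": 5,
            "k1b": 5000, "k6b": 175, "k7b": 35, "k8b": 250, "k9b": 10,
            "k10b": 7, "k11b": 10, "k12b": 10, "k13b": 100, "k14b": 1,
            "k15b": 10000, "k16b": 10, "k17b": 10, "k18b": 5,
        }
        for name, value in expected.items():
            assert rates[name] == value

    def test_unknown_and_negative_rates_rejected(self):
        with pytest.raises(KeyError):
            RateConstantSet({"k19f": 1.0})
        with pytest.raises(ValueError):
            RateConstantSet({"k6f": -1.0})

    def test_light_scaling_is_linear_in_pfd(self):
        low = RateConstantSet().at_light(LightRegime.low())
        for name in ("k1f", "k1b", "k15f", "k15b"):
            assert low[name] == pytest.approx(RateConstantSet()[name] / 10)
        # non-photochemical constants untouched
        assert low["k6f"] == RateConstantSet()["k6f"]

    def test_zero_backward_constants_leave_forward_families(self):
        zeros = {name: 0.0 for name in BACKWARD_NAMES}
        net = build_network(RateConstantSet(zeros))
        active = {
            rx.rate_name for rx in net.reactions
            if net._rate_value(rx.rate_name) > 0
        }
        assert active == set(FORWARD_NAMES)

    def test_k6f_transitions_are_p680_independent(self):
        net = build_network(RateConstantSet())
        k6f = [rx for rx in net.reactions if rx.rate_name == "k6f"]
        assert len(k6f) == 2  # one per P680 state
        for rx in k6f:
            changed = {idx for idx, _ in rx.stoich}
            assert len(changed) == 2  # pure intra-PSII transfer


class TestRhs:
    def test_dark_state_without_back_reactions_is_stationary(self):
        zeros = {name: 0.0 for name in BACKWARD_NAMES}
        rates = RateConstantSet(zeros).at_light(LightRegime(0.0))
        net = build_network(rates)
        np.testing.assert_allclose(rhs(net, initial_state()), 0.0, atol=1e-14)

    @pytest.mark.parametrize("seed", range(3))
    def test_pool_derivatives_sum_to_zero(self, seed):
        net = build_network(RateConstantSet())
        x = np.random.default_rng(seed).uniform(0.0, 1.0, N_STATE)
        dx = rhs(net, x)
        for name, sl in pool_slices().items():
            assert abs(dx[sl].sum()) < 1e-9, name

    @pytest.mark.parametrize("k8_both", [False, True])
    def test_matrix_rhs_matches_per_reaction_loop(self, k8_both):
        net = build_network(RateConstantSet(), k8_both_qa_states=k8_both)
        rng = np.random.default_rng(1)
        for _ in range(5):
            x = rng.uniform(0.0, 2.0, N_STATE)
            np.testing.assert_allclose(
                rhs(net, x), rhs_brute_force(net, x), atol=1e-12, rtol=1e-12
            )


class TestInitialState:
    def test_dark_defaults(self):
        x = initial_state()
        psii = x[pool_slices()["PSII"]].reshape(2, 2, 3)
        assert psii[:, 1, :].sum() == 0.0  # Q_A fully oxidised
        oec = x[pool_slices()["OEC"]]
        assert oec.sum() == pytest.approx(1.0)
        assert oec[2] == oec[3] == 0.0  # no S2/S3 in darkness
        assert x[pool_slices()["PQ"]][0] == pytest.approx(6.0)  # PQ pool oxidised

    def test_pool_sums_match_configured_totals(self):
        pools = PoolConfig(pq_total=8, pc_total=3, fd_total=4, fnr_total=2)
        x = initial_state(pools=pools)
        totals = pool_totals_vector(pools)
        for name, sl in pool_slices().items():
            assert x[sl].sum() == pytest.approx(totals[name])

    def test_split_overrides(self):
        x = initial_state(InitialStateConfig(s1_fraction=1.0, qb_semi_fraction=0.2))
        assert x[pool_slices()["OEC"]][0] == 0.0  # S0 empty
        psii = x[pool_slices()["PSII"]].reshape(2, 2, 3)
        assert psii[0, 0, 1] == pytest.approx(0.2)


class TestFluorescence:
    def test_open_centres_without_pq_quenching_give_phi_open(self):
        x = initial_state()
        f = fluorescence(x, QuenchConfig(gamma_pq=0.0))
        assert f == pytest.approx(1.0)

    def test_closed_centres_with_reduced_pq_give_phi_closed(self):
        x = initial_state()
        sl = pool_slices()
        x[sl["PSII"]] = 0.0
        x[list(range(12))[4]] = 1.0  # (P680 red, QA red, QB semi)
        x[sl["PQ"]] = [0.0, 0.0, 6.0]  # fully reduced pool
        assert fluorescence(x) == pytest.approx(5.0)

    def test_pq_quenching_factor_applies_exactly(self):
        x = initial_state()
        q0 = fluorescence(x, QuenchConfig(gamma_pq=0.0))
        q3 = fluorescence(x, QuenchConfig(gamma_pq=0.3))
        assert q3 == pytest.approx(q0 * 0.7)


class TestSimulation:
    def test_conservation_and_nonnegativity_full_run(self, intense_result):
        totals = pool_totals_vector(intense_result.pools)
        for name, sl in pool_slices().items():
            sums = intense_result.species[sl].sum(axis=0)
            np.testing.assert_allclose(sums, totals[name], atol=1e-6)
        assert intense_result.species.min() > -1e-9

    def test_dark_simulation_with_oxidised_qb_is_exactly_flat(self):
        res = simulate_fi(
            light=LightRegime(0.0),
            init=InitialStateConfig(qb_semi_fraction=0.0),
        )
        assert np.ptp(res.fluorescence) == pytest.approx(0.0, abs=1e-8)

    def test_dark_simulation_converges_to_acceptor_side_equilibrium(self):
        # under defaults the only dark flux is the k6f/k6b shuttle within the
        # one-electron acceptor manifold; its equilibrium is closed-form
        res = simulate_fi(light=LightRegime(0.0))
        rates, pools, quench = RateConstantSet(), PoolConfig(), QuenchConfig()
        qa_red_eq = 0.5 * rates["k6b"] / (rates["k6f"] + rates["k6b"])
        f_eq = (
            quench.phi_open * (1 - qa_red_eq) + quench.phi_closed * qa_red_eq
        ) * (1 - quench.gamma_pq)
        assert res.fluorescence[-1] == pytest.approx(f_eq, rel=1e-4)
        # flat after the sub-millisecond equilibration
        late = res.fluorescence[res.time_grid > 5e-3]
        assert np.ptp(late) < 1e-8

    def test_electron_bookkeeping_oec_versus_downstream(self, intense_result):
        # electrons injected by the OEC (k1f flux minus k1b recombination)
        # must equal the growth of reduced equivalents on the acceptor side
        res = intense_result
        net = build_network(RateConstantSet().at_light(res.light), res.pools)
        names = [rx.name for rx in net.reactions]
        k1f_idx = [i for i, n in enumerate(names) if n.startswith("k1f")]
        k1b_idx = [i for i, n in enumerate(names) if n.startswith("k1b")]
        fluxes = np.array([net.fluxes(x) for x in res.species.T])
        net_in = fluxes[:, k1f_idx].sum(axis=1) - fluxes[:, k1b_idx].sum(axis=1)
        injected = np.trapezoid(net_in, res.time_grid)

        def reduced_equivalents(x):
            sl = pool_slices()
            psii = x[sl["PSII"]].reshape(2, 2, 3)
            qa = psii[:, 1, :].sum()
            qb = (psii * np.array([0, 1, 2])[None, None, :]).sum()
            pqpool = x[sl["PQ"]] @ np.array([0, 1, 2])
            cyt = x[sl["CYT"]].reshape(2, 2, 3)
            cyt_e = (
                cyt.sum(axis=(1, 2)) @ np.array([0, 1])
                + cyt.sum(axis=(0, 2)) @ np.array([0, 1])
                + cyt.sum(axis=(0, 1)) @ np.array([0, 1, 2])
            )
            pc = x[sl["Pc"]][0]  # reduced fraction carries the electron
            psi = x[sl["PSI"]].reshape(2, 2)
            psi_e = psi[0].sum() + psi[:, 1].sum()  # P700 red + FB red
            fd = x[sl["Fd"]][1]
            fnr = x[sl["FNR"]] @ np.array([0, 0, 1, 2])
            return qa + qb + pqpool + cyt_e + pc + psi_e + fd + fnr

        gained = reduced_equivalents(res.species[:, -1]) - reduced_equivalents(
            res.species[:, 0]
        )
        assert gained == pytest.approx(injected, rel=1e-3)

    def test_integrator_failure_reports_parameters(self):
        with pytest.raises((RuntimeError, ValueError)):
            simulate_fi(time_grid=np.array([1e-3, 1e-4]))  # non-increasing grid

    def test_dcmu_like_block_closes_all_centres_monotonically(self):
        res = simulate_fi(RateConstantSet({"k6f": 0.0, "k6b": 0.0}))
        f = res.fluorescence
        assert np.all(np.diff(f) > -1e-9)
        psii = res.species[pool_slices()["PSII"], -1].reshape(2, 2, 3)
        assert psii[:, 1, :].sum() > 0.99  # Q_A essentially fully reduced


class TestOJIPFeatures:
    def test_intense_light_shows_j_i_p_in_expected_windows(self, intense_result):
        feats = extract_ojip_features(
            intense_result.time_grid, intense_result.fluorescence
        )
        assert feats.t_j is not None and 5e-4 <= feats.t_j <= 6e-3
        assert feats.t_i is not None and 8e-3 <= feats.t_i <= 6e-2
        assert 6e-2 <= feats.t_p <= 6e-1
        assert feats.t_j < feats.t_i < feats.t_p
        assert feats.f_o < feats.f_p

    def test_low_light_loses_the_i_inflection(self, low_result):
        feats = extract_ojip_features(low_result.time_grid, low_result.fluorescence)
        assert feats.t_i is None
        assert feats.t_j is not None  # the J plateau survives

    def test_monotone_featureless_curve_reports_p_at_end(self):
        t = default_time_grid()
        f = np.exp(t)  # log-slope grows monotonically: no plateaus, no knee
        feats = extract_ojip_features(t, f)
        assert feats.t_j is None and feats.t_i is None
        assert feats.t_p == t[-1]

    def test_constructed_triple_step_curve_recovers_known_features(self):
        # equal-amplitude, equal-width logistic steps: the plateau dips sit
        # at the geometric means of consecutive centres and the P landmark
        # at the last centre — derived independently of the detector
        t = default_time_grid()
        lt = np.log10(t)
        c1, c2, c3 = 6e-4, 6.3e-3, 1.5e-1
        f = np.ones_like(t)
        for centre in (c1, c2, c3):
            f = f + 1.0 / (1 + np.exp(-(lt - np.log10(centre)) / 0.15))
        feats = extract_ojip_features(t, f)
        assert feats.t_j == pytest.approx(np.sqrt(c1 * c2), rel=0.2)
        assert feats.t_i == pytest.approx(np.sqrt(c2 * c3), rel=0.2)
        assert feats.t_p == pytest.approx(c3, rel=0.2)

    def test_coarse_grid_rejected(self):
        t = np.logspace(-5, 0, 30)
        with pytest.raises(ValueError, match="points/decade"):
            extract_ojip_features(t, np.linspace(1, 2, 30))
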