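"""Disease dynamics: seeding, transmission, progression, tracing, R0."""

import numpy as np
import pytest

from bubblesim import NetworkConfig
from bubblesim.epi import (
    FREE,
    INFECTED,
    ISOLATED,
    QUARANTINED,
    RECOVERED,
    SUSCEPTIBLE,
    EpiParams,
    EpiState,
    InfectivityCurve,
    default_infectivity_curve,
    estimate_R0,
    progression_step,
    seed_infection,
    trace_and_quarantine,
    transmission_step,
)

STEP = 1.0 / 12


@pytest.fixture
def curve():
    return default_infectivity_curve()


class TestInfectivityCurve:
    def test_omega_shape(self, curve):
        tau = np.linspace(0, 12, 1000)
        w = curve.omega(tau)
        assert (w >= 0).all()
        assert abs(tau[np.argmax(w)] - 5.0) < 0.1  # peak near day 5
        assert curve.omega(np.array([5.0]))[0] == pytest.approx(1.0)
        assert (curve.omega(np.array([10.0, 11.0])) == 0).all()

    def test_symptom_onset_cdf(self, curve):
        tau = np.linspace(0, 30, 500)
        s = curve.s(tau)
        assert s[0] == 0.0
        assert (np.diff(s) >= 0).all()
        assert s[-1] <= 1.0
        # median incubation 5.5 days
        assert curve.s(np.array([5.5]))[0] == pytest.approx(0.5, abs=1e-6)


class TestSeeding:
    def test_exactly_one_infected(self, curve, rng):
        state = EpiState.fresh(680, 84)
        seed_infection(state, rng, EpiParams())
        assert (state.status == INFECTED).sum() == 1
        assert (state.status == SUSCEPTIBLE).sum() == 679

    def test_seed_age_uniform_0_10(self, curve):
        rng = np.random.default_rng(3)
        taus = []
        for _ in range(500):
            state = EpiState.fresh(10, 84)
            node = seed_infection(state, rng, EpiParams())
            taus.append(state.tau[node])
        taus = np.asarray(taus)
        assert taus.min() >= 0.0 and taus.max() <= 10.0
        assert np.mean(taus) == pytest.approx(5.0, abs=0.4)

    def test_refuses_non_susceptible_population(self, curve, rng):
        state = EpiState.fresh(10, 84)
        state.status[3] = RECOVERED
        with pytest.raises(ValueError):
            seed_infection(state, rng, EpiParams())


class TestTransmission:
    def test_beta_zero_never_infects(self, curve, rng):
        state = EpiState.fresh(100, 84)
        state.status[:50] = INFECTED
        state.tau[:50] = 5.0
        edges = np.column_stack([np.arange(50), 50 + np.arange(50)]).astype(np.int64)
        params = EpiParams(beta=0.0)
        newly, _ = transmission_step(state, edges, params, curve, rng)
        assert newly.size == 0

    def test_per_contact_probability_matches_closed_form(self, curve):
        # M independent S-I pairs in one layer: infection fraction -> beta*omega(tau)
        M = 100_000
        tau0 = 4.0
        params = EpiParams(beta=0.1)
        state = EpiState.fresh(2 * M, 84)
        inf = np.arange(0, 2 * M, 2)
        state.status[inf] = INFECTED
        state.tau[inf] = tau0
        edges = np.column_stack([inf, inf + 1]).astype(np.int64)
        rng = np.random.default_rng(11)
        newly, infectors = transmission_step(state, edges, params, curve, rng)
        p_expect = params.beta * curve.omega(np.array([tau0]))[0]
        se = np.sqrt(p_expect * (1 - p_expect) / M)
        assert newly.size / M == pytest.approx(p_expect, abs=4 * se)
        assert np.array_equal(np.sort(infectors), np.sort(newly - 1))

    def test_susceptible_pair_contact_is_inert(self, curve, rng):
        state = EpiState.fresh(4, 84)
        edges = np.array([[0, 1], [2, 3]], dtype=np.int64)
        newly, _ = transmission_step(state, edges, EpiParams(beta=1.0), curve, rng)
        assert newly.size == 0
        assert (state.status == SUSCEPTIBLE).all()

    def test_confined_nodes_do_not_transmit(self, curve, rng):
        state = EpiState.fresh(4, 84)
        state.status[0] = INFECTED
        state.tau[0] = 5.0
        state.conf[0] = ISOLATED
        edges = np.array([[0, 1]], dtype=np.int64)
        newly, _ = transmission_step(state, edges, EpiParams(beta=1.0), curve, rng)
        assert newly.size == 0


class TestProgression:
    def test_no_isolation_when_eps_I_zero(self, curve, rng):
        state = EpiState.fresh(5, 84)
        state.status[:] = INFECTED
        state.will_symptomatic[:] = True
        state.symptomatic[:] = True
        params = EpiParams(eps_I=0.0)
        for t in range(50):
            newly = progression_step(state, params, curve, STEP, t, rng)
            assert newly.size == 0
        assert (state.conf == FREE).all()

    def test_recovery_exactly_at_ten_days(self, curve, rng):
        state = EpiState.fresh(1, 84)
        state.status[0] = INFECTED
        state.will_symptomatic[0] = False
        params = EpiParams(eps_I=1.0)  # irrelevant: asymptomatic
        for t in range(119):
            progression_step(state, params, curve, STEP, t, rng)
        assert state.status[0] == INFECTED  # tau = 119/12 < 10
        progression_step(state, params, curve, STEP, 119, rng)
        assert state.status[0] == RECOVERED  # tau reaches 10

    def test_asymptomatic_never_isolated(self, curve):
        rng = np.random.default_rng(0)
        state = EpiState.fresh(50, 84)
        state.status[:] = INFECTED
        state.will_symptomatic[:] = False
        params = EpiParams(eps_I=1.0)
        for t in range(120):
            newly = progression_step(state, params, curve, STEP, t, rng)
            assert newly.size == 0

    def test_symptomatic_isolated_then_recovered_on_release(self, curve):
        rng = np.random.default_rng(1)
        state = EpiState.fresh(1, 84)
        state.status[0] = INFECTED
        state.will_symptomatic[0] = True
        state.symptomatic[0] = True
        params = EpiParams(eps_I=1.0)
        newly = progression_step(state, params, curve, STEP, 0, rng)
        # eps_I=1 -> isolated at the first symptomatic step
        assert newly.tolist() == [0]
        assert state.conf[0] == ISOLATED
        release = int(state.conf_end[0])
        assert release == 0 + 10 * 12
        for t in range(1, release):
            progression_step(state, params, curve, STEP, t, rng)
            assert state.conf[0] == ISOLATED
        progression_step(state, params, curve, STEP, release, rng)
        assert state.conf[0] == FREE and state.status[0] == RECOVERED

    def test_isolation_hazard_is_per_step(self, curve):
        # eps_I applies at every 2-h update: the daily isolation
        # probability of a symptomatic node is 1 - (1 - eps_I)^12
        rng = np.random.default_rng(2)
        n = 40_000
        state = EpiState.fresh(n, 84)
        state.status[:] = INFECTED
        state.will_symptomatic[:] = True
        state.symptomatic[:] = True
        state.tau[:] = 1.0
        params = EpiParams(eps_I=0.1)
        for t in range(12):
            progression_step(state, params, curve, STEP, t, rng)
        frac = (state.conf == ISOLATED).mean()
        expect = 1 - 0.9**12
        se = np.sqrt(expect * (1 - expect) / n)
        assert frac == pytest.approx(expect, abs=4 * se)


class TestTracing:
    def _state_with_log(self, n_nodes, contacts_by_age_steps):
        """Contact log where node 0 met the given partners some steps ago."""
        state = EpiState.fresh(n_nodes, 84)
        empty = np.empty((0, 2), dtype=np.int64)
        for age in range(84, 0, -1):  # oldest first; deque keeps last 84
            partners = contacts_by_age_steps.get(age, [])
            if partners:
                arr = np.array([[0, p] for p in partners], dtype=np.int64)
            else:
                arr = empty
            state.contact_log.append(arr)
        return state

    def test_eps_T_zero_no_quarantine(self, rng):
        state = self._state_with_log(5, {10: [1, 2, 3]})
        q = trace_and_quarantine(state, 0, EpiParams(eps_T=0.0), rng, 100)
        assert q.size == 0

    def test_eps_T_one_quarantines_all_recent_contacts(self, rng):
        state = self._state_with_log(5, {10: [1, 2], 50: [3]})
        q = trace_and_quarantine(state, 0, EpiParams(eps_T=1.0), rng, 100)
        assert sorted(q.tolist()) == [1, 2, 3]
        assert (state.conf[[1, 2, 3]] == QUARANTINED).all()
        assert state.ever_confined[[1, 2, 3]].all()

    def test_contact_older_than_window_not_traced(self, rng):
        # the log only retains the trailing 7 days (84 steps): a partner last
        # seen 8 days ago has already been dropped
        state = self._state_with_log(5, {84: [1], 10: [2]})
        state.contact_log.append(np.empty((0, 2), dtype=np.int64))  # evict oldest
        q = trace_and_quarantine(state, 0, EpiParams(eps_T=1.0), rng, 100)
        assert q.tolist() == [2]

    def test_recovered_and_isolated_exempt(self, rng):
        state = self._state_with_log(5, {10: [1, 2, 3]})
        state.status[1] = RECOVERED
        state.conf[2] = ISOLATED
        q = trace_and_quarantine(state, 0, EpiParams(eps_T=1.0), rng, 100)
        assert q.tolist() == [3]


class TestR0:
    def test_beta_zero_gives_zero(self, curve, rng):
        cfg = NetworkConfig.from_modularity(60, 6, 40.0, 5.0)
        r0 = estimate_R0(cfg, EpiParams(beta=0.0), curve, 50, rng)
        assert r0 == 0.0

    def test_three_node_clique_matches_closed_form(self):
        # fully connected triangle, omega = 1 on [5, 10) and 0 elsewhere:
        # secondaries never reach infectious age while the seed is active,
        # so the seed's offspring count is exactly 2*(1 - (1-q)^60)
        q = 0.02
        cfg = NetworkConfig.from_probabilities((3,), 1.0, 0.0)
        curve = InfectivityCurve(
            omega=lambda tau: ((tau >= 5.0) & (tau < 10.0)).astype(float),
            s=lambda tau: np.zeros_like(np.asarray(tau, dtype=float)),
        )
        params = EpiParams(beta=q, eps_I=0.0, seed_tau_max_days=0.0)
        n_runs = 3000
        r0 = estimate_R0(cfg, params, curve, n_runs, np.random.default_rng(17))
        expect = 2 * (1 - (1 - q) ** 60)
        se = np.sqrt(2 * (expect / 2) * (1 - expect / 2) / n_runs)
        assert r0 == pytest.approx(expect, abs=4 * se)
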