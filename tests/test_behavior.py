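import numpy as np
import pytest
from scipy import stats

from eldersim.behavior import (
    BehaviorParams,
    PoolIndex,
    choose_facility,
    choose_type,
    decide_outing,
    simulate_agent_day,
)
from eldersim.environment import DistanceModel
from eldersim.errors import ConfigError
from eldersim.population import Facility, OlderAdult


def _agent(h=0.85, home=(5.0, 5.0), living="with_spouse", econ="mid"):
    state = "healthy" if h >= 0.7 else ("weak" if h >= 0.3 else "disabled")
    return OlderAdult(0, home, h, state, living, econ)


def _fac(fid, x, y, ftype, gain=0.001, host=False):
    return Facility(fid, x, y, ftype, gain, host)


class TestDecideOuting:
    @pytest.mark.parametrize("state,p", [("healthy", 0.7), ("weak", 0.5), ("disabled", 0.3)])
    def test_empirical_rate_matches_state_probability(self, state, p, params, rng):
        n = 10_000
        draws = sum(decide_outing(state, params, rng) for _ in range(n))
        se = np.sqrt(p * (1 - p) / n)
        assert abs(draws / n - p) < 3 * se

    def test_degenerate_probabilities(self, rng):
        p0 = BehaviorParams(p_out={"healthy": 0.0, "weak": 0.0, "disabled": 0.0})
        p1 = BehaviorParams(p_out={"healthy": 1.0, "weak": 1.0, "disabled": 1.0})
        assert not any(decide_outing("healthy", p0, rng) for _ in range(100))
        assert all(decide_outing("healthy", p1, rng) for _ in range(100))


class TestChooseType:
    @pytest.mark.parametrize(
        "state,expected",
        [("healthy", (0.6, 0.2, 0.2)), ("weak", (0.3, 0.5, 0.2)), ("disabled", (0.1, 0.3, 0.6))],
    )
    def test_shares_recover_preference_weights(self, state, expected, params, rng):
        n = 10_000
        draws = [choose_type(state, params, rng) for _ in range(n)]
        counts = [draws.count(t) for t in ("prevention", "treatment", "care")]
        # chi-square goodness of fit not rejected at alpha = 0.01
        assert stats.chisquare(counts, [n * w for w in expected]).pvalue > 0.01

    def test_degenerate_weights(self, rng):
        p = BehaviorParams(
            type_weights={
                "healthy": (1.0, 0.0, 0.0),
                "weak": (0.3, 0.5, 0.2),
                "disabled": (0.1, 0.3, 0.6),
            }
        )
        assert all(choose_type("healthy", p, rng) == "prevention" for _ in range(50))

    def test_invalid_weights_rejected(self):
        with pytest.raises(ConfigError):
            BehaviorParams(
                type_weights={
                    "healthy": (0.5, 0.2, 0.2),
                    "weak": (0.3, 0.5, 0.2),
                    "disabled": (0.1, 0.3, 0.6),
                }
            )


class TestChooseFacility:
    def test_single_in_radius_candidate_always_chosen(self, euclid, params, rng):
        agent = _agent()  # healthy, radius 5 km
        fac = [_fac("P001", 6.0, 6.5, "prevention")]  # ~1.8 km away
        for _ in range(20):
            assert choose_facility(agent, "prevention", fac, euclid, params, rng) is fac[0]

    def test_fallback_rate_near_half(self, euclid, params, rng):
        agent = _agent()
        fac = [_fac("P001", 20.0, 20.0, "prevention")]  # far beyond 5 km
        n = 10_000
        taken = sum(
            choose_facility(agent, "prevention", fac, euclid, params, rng) is not None
            for _ in range(n)
        )
        se = np.sqrt(0.25 / n)
        assert abs(taken / n - 0.5) < 3 * se

    def test_fallback_goes_to_nearest(self, euclid, rng):
        params = BehaviorParams(fallback_p=1.0)
        agent = _agent(home=(0.0, 0.0))
        fac = [_fac("P002", 9.0, 0.0, "prevention"), _fac("P001", 6.0, 0.0, "prevention")]
        assert choose_facility(agent, "prevention", fac, euclid, params, rng).id == "P001"

    def test_fallback_tie_broken_by_lowest_id(self, euclid, rng):
        params = BehaviorParams(fallback_p=1.0)
        agent = _agent(home=(0.0, 0.0))
        fac = [_fac("P009", 6.0, 0.0, "prevention"), _fac("P001", 0.0, 6.0, "prevention")]
        assert choose_facility(agent, "prevention", fac, euclid, params, rng).id == "P001"

    def test_no_matching_facility_cancels(self, euclid, params, rng):
        agent = _agent()
        fac = [_fac("T001", 5.0, 5.5, "treatment")]
        assert choose_facility(agent, "care", fac, euclid, params, rng) is None

    def test_comprehensive_matches_every_type(self, euclid, params, rng):
        agent = _agent()
        fac = [_fac("X001", 5.5, 5.0, "comprehensive", gain=0.05, host=True)]
        for t in ("prevention", "treatment", "care"):
            assert choose_facility(agent, t, fac, euclid, params, rng) is fac[0]

    def test_education_host_upweighting(self, euclid, rng):
        # host weight 1 + live_adjust: with live_adjust = 1 the host should
        # draw 2/3 of choices between two equidistant prevention facilities
        params = BehaviorParams(live_adjust=1.0)
        agent = _agent(home=(0.0, 0.0))
        fac = [
            _fac("P001", 1.0, 0.0, "prevention", host=True),
            _fac("P002", 0.0, 1.0, "prevention", host=False),
        ]
        n = 10_000
        host_share = (
            sum(choose_facility(agent, "prevention", fac, euclid, params, rng).id == "P001" for _ in range(n)) / n
        )
        se = np.sqrt(2 / 3 * 1 / 3 / n)
        assert abs(host_share - 2 / 3) < 3 * se

    def test_zero_live_adjust_ignores_host_flags(self, euclid):
        params = BehaviorParams(live_adjust=0.0)
        agent = _agent(home=(0.0, 0.0))
        with_host = [
            _fac("P001", 1.0, 0.0, "prevention", host=True),
            _fac("P002", 0.0, 1.0, "prevention", host=False),
        ]
        no_host = [
            _fac("P001", 1.0, 0.0, "prevention", host=False),
            _fac("P002", 0.0, 1.0, "prevention", host=False),
        ]
        r1, r2 = np.random.default_rng(0), np.random.default_rng(0)
        picks1 = [choose_facility(agent, "prevention", with_host, euclid, params, r1).id for _ in range(200)]
        picks2 = [choose_facility(agent, "prevention", no_host, euclid, params, r2).id for _ in range(200)]
        assert picks1 == picks2


class TestSimulateAgentDay:
    def test_no_outing_gives_no_visit(self, euclid, rng):
        params = BehaviorParams(p_out={"healthy": 0.0, "weak": 0.0, "disabled": 0.0})
        agent = _agent()
        fac = [_fac("P001", 5.5, 5.0, "prevention")]
        assert simulate_agent_day(agent, fac, euclid, params, rng) is None

    def test_in_radius_visit_within_radius(self, euclid, params, rng):
        agent = _agent()
        fac = [
            _fac("P001", 5.5, 5.0, "prevention"),
            _fac("T001", 5.0, 5.5, "treatment"),
            _fac("C001", 4.5, 5.0, "care"),
        ]
        for _ in range(200):
            ev = simulate_agent_day(agent, fac, euclid, params, rng, day=3)
            if ev is not None:
                assert ev.day == 3
                assert ev.distance_km <= params.radius["healthy"]
                assert not ev.fallback_used

    def test_outing_frequency_near_state_probability(self, euclid, params, rng):
        # every type within radius: visits happen iff the outing draw succeeds
        agent = _agent()
        fac = [
            _fac("P001", 5.5, 5.0, "prevention"),
            _fac("T001", 5.0, 5.5, "treatment"),
            _fac("C001", 4.5, 5.0, "care"),
        ]
        n = 10_000
        visits = sum(simulate_agent_day(agent, fac, euclid, params, rng) is not None for _ in range(n))
        se = np.sqrt(0.7 * 0.3 / n)
        assert abs(visits / n - 0.7) < 3 * se


class TestPoolIndex:
    def test_index_agrees_with_direct_choice_probabilities(self, euclid, rng):
        # the fast-path pool draw and choose_facility sample the same pool law
        params = BehaviorParams(live_adjust=0.5)
        agent = _agent(home=(2.0, 2.0))
        fac = [
            _fac("P001", 2.5, 2.0, "prevention", host=True),
            _fac("P002", 2.0, 3.0, "prevention", host=False),
            _fac("X001", 4.0, 2.0, "comprehensive", gain=0.05, host=True),
        ]
        index = PoolIndex(np.array([agent.home]), fac, euclid, params)
        n = 20_000
        u = rng.random(n)
        fast = np.array([index.draw(0, 0, 0, ui) for ui in u])
        fast_shares = np.bincount(fast, minlength=3) / n
        expected = np.array([1.5, 1.0, 1.5])
        expected = expected / expected.sum()
        assert np.abs(fast_shares - expected).max() < 0.02
        direct = [choose_facility(agent, "prevention", fac, euclid, params, rng).id for _ in range(n)]
        direct_share = np.array([direct.count(f.id) for f in fac]) / n
        assert np.abs(direct_share - expected).max() < 0.02

    def test_empty_pool_uses_fallback_probability(self, euclid, params):
        fac = [_fac("P001", 50.0, 50.0, "prevention")]
        index = PoolIndex(np.array([[0.0, 0.0]]), fac, euclid, params)
        picks = [index.draw(0, 0, 0, u) for u in np.linspace(0.001, 0.999, 1000)]
        share = np.mean([p >= 0 for p in picks])
        assert abs(share - params.fallback_p) < 0.01
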