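"""Unit and property tests for the core model functions."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pif4net import (
    BranchViolationError,
    ConfigurationError,
    DomainError,
    GenotypeSpec,
    ModelState,
    ParameterSet,
    Schedule,
    elf3_production,
    rhs,
    schedule_value,
    steady_state_below_threshold,
)
from pif4net.model import WILD_TYPE


class TestElf3Production:
    def test_constant_limits(self, params):
        # all-dark and all-light regimes collapse to the exact extremes
        for t in (0.0, 5.3, 17.0, 48.1):
            assert elf3_production(t, 0.0, params) == pytest.approx(
                params.pE1 + params.pE2, abs=0
            )
            assert elf3_production(t, 24.0, params) == pytest.approx(
                params.pE1 - params.pE2, abs=0
            )

    def test_sharp_transition_plateaus(self, params):
        # with a steep transition the mid-day/mid-night values sit on the
        # theoretical plateaus, within the sigmoid-tail envelope
        # the logistic tails at the plateau midpoint are exp(-alpha*min(D,24-D)/2)
        p = replace(params, alpha=5.0)
        D = 12.0
        eps = 2.0 * 4.0 * p.pE2 * math.exp(-p.alpha * min(D, 24.0 - D) / 2.0)
        assert elf3_production(6.0, D, p) == pytest.approx(p.pE1 - p.pE2, abs=eps)
        assert elf3_production(18.0, D, p) == pytest.approx(p.pE1 + p.pE2, abs=eps)

    def test_zero_factor(self, params):
        assert elf3_production(7.0, 8.0, params, mutE=0.0) == 0.0

    def test_domain_error(self, params):
        with pytest.raises(DomainError):
            elf3_production(0.0, 25.0, params)
        with pytest.raises(DomainError):
            elf3_production(0.0, -1.0, params)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        t=st.floats(0.0, 240.0),
        D=st.floats(0.01, 23.99),
        alpha=st.floats(0.5, 20.0),
        mutE=st.floats(0.0, 3.0),
    )
    def test_bounded_by_extremes(self, t, D, alpha, mutE):
        p = replace(_base(), alpha=alpha)
        eps = 4.0 * p.pE2 * math.exp(-alpha * min(D, 24.0 - D)) + 1e-12
        v = elf3_production(t, D, p, mutE=mutE)
        assert mutE * (p.pE1 - p.pE2) - mutE * eps <= v <= mutE * (p.pE1 + p.pE2) + mutE * eps


def _base():
    from pif4net import default_parameters

    return default_parameters()


class TestSchedule:
    SCHED = Schedule(max_day=1.0, min_val=0.0, max_night=1.0, D1=2.0, D2=6.0)

    @pytest.mark.parametrize(
        "t0, expected",
        [
            (0.0, 1.0),        # start of the cycle: day maximum
            (1.0, 0.5),        # halfway down the descending ramp
            (2.0, 0.0),        # plateau start
            (4.0, 0.0),        # inside the plateau
            (6.0, 0.0),        # plateau end
            (15.0, 0.5),       # halfway up the ascending ramp
            (24.0 - 1e-9, 1.0),  # just before the cycle boundary
        ],
    )
    def test_piecewise_values(self, t0, expected):
        assert schedule_value(t0, self.SCHED) == pytest.approx(expected, abs=1e-8)

    def test_periodic_with_boundary_jump(self):
        s = Schedule(max_day=3.0, min_val=1.0, max_night=2.0, D1=2.0, D2=6.0)
        assert schedule_value(24.0, s) == pytest.approx(3.0)  # next cycle's day max
        assert schedule_value(23.999, s) == pytest.approx(2.0, abs=1e-3)

    def test_scalar_passthrough(self):
        assert schedule_value(13.0, 7.5) == 7.5

    def test_invalid_schedule(self):
        with pytest.raises(ConfigurationError):
            Schedule(max_day=1.0, min_val=0.0, max_night=1.0, D1=6.0, D2=2.0)
        with pytest.raises(ConfigurationError):
            Schedule(max_day=0.5, min_val=1.0, max_night=2.0)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(t=st.floats(0.0, 48.0), delta=st.floats(1e-6, 1e-4))
    def test_continuity_inside_cycle(self, t, delta):
        # continuous except exactly at the 24 h boundary
        s = Schedule(max_day=5.0, min_val=1.0, max_night=3.0, D1=2.0, D2=6.0)
        t0 = math.fmod(t, 24.0)
        if t0 + delta >= 24.0 or t0 == 0.0:
            return
        lip = max(
            (s.max_day - s.min_val) / s.D1, (s.max_night - s.min_val) / (24.0 - s.D2)
        )
        assert abs(schedule_value(t + delta, s) - schedule_value(t, s)) <= lip * delta * 1.01


class TestRhs:
    def test_zero_state_dark(self, params):
        d = rhs(3.0, ModelState.zero(), params, WILD_TYPE, light=0, day_length=0.0)
        assert d[0] == 0.0
        assert d[1] == pytest.approx(params.pE1 + params.pE2)
        assert d[2] == pytest.approx(params.pCD)
        assert d[3] == pytest.approx(params.pP)  # P=0 < Pstar: no self term
        assert d[4] == pytest.approx(params.k0)
        assert d[5] == pytest.approx(params.pG)

    def test_phyb_bounded_at_capacity(self, params):
        state = ModelState(B=1.0, E=0.0, C=0.0, P=0.0, F=0.0, G=0.0)
        d = rhs(0.0, state, params, WILD_TYPE, light=1, day_length=24.0)
        assert d[0] == pytest.approx(-params.kr * 1.0)
        assert d[0] < 0

    def test_branch_production_ratio(self, params):
        # crossing the threshold scales PIF4 production by
        # (1 + pPE E) / (1 + pPE E + pself P)
        E, C, B = 0.7, 1.1, 0.2
        P = params.Pstar
        state = [B, E, C, P, 0.0, 0.0]
        lo = rhs(0.0, state, params, WILD_TYPE, 1, 24.0, branch="below")
        hi = rhs(0.0, state, params, WILD_TYPE, 1, 24.0, branch="above")
        loss = params.dP * P / (1 + params.kPC * C) + params.dPB * B * P
        prod_below = lo[3] + loss
        prod_above = hi[3] + loss
        expected = (1 + params.pPE * E) / (1 + params.pPE * E + params.pself * P)
        assert prod_above / prod_below == pytest.approx(expected, rel=1e-12)

    def test_reporter_gains_term_above_threshold(self, params):
        state = [0.0, 0.0, 0.0, params.Pstar, 0.0, 0.0]
        below = rhs(0.0, state, params, WILD_TYPE, 0, 0.0, branch="below")
        above = rhs(0.0, state, params, WILD_TYPE, 0, 0.0, branch="above")
        gain = params.pF / (1 + params.pFP * params.Pstar)
        assert above[4] - below[4] == pytest.approx(gain, rel=1e-12)

    def test_growth_never_negative(self, params):
        d = rhs(0.0, ModelState.zero(), params, WILD_TYPE, 1, 24.0)
        assert d[5] >= 0

    def test_invalid_inputs(self, params):
        with pytest.raises(DomainError):
            rhs(0.0, [-0.1, 0, 0, 0, 0, 0], params, WILD_TYPE, 0)
        with pytest.raises(DomainError):
            rhs(0.0, ModelState.zero(), params, WILD_TYPE, light=2)


class TestSteadyStateOracle:
    def test_dark_closed_form(self, params):
        # reduced PIF4 production keeps the dark fixed point below threshold
        weak = GenotypeSpec(name="weak", mutP=0.05)
        ss = steady_state_below_threshold(params, weak, light=0)
        assert ss.B == 0.0
        assert ss.C == pytest.approx(params.pCD / params.dC)
        assert ss.F == pytest.approx(params.k0 / params.dF)
        assert ss.P < params.Pstar

    def test_zero_production_genotype(self, params):
        g = GenotypeSpec(name="null", mutP=0.0)
        ss = steady_state_below_threshold(params, g, light=1)
        assert ss.P == 0.0

    def test_full_activation_limit(self, params):
        p = replace(params, kr=0.0)
        g = GenotypeSpec(name="OE", mutB=1.4, mutP=0.0)
        ss = steady_state_below_threshold(p, g, light=1)
        assert ss.B == pytest.approx(1.4)

    def test_branch_violation_detected(self, params):
        # an extreme overexpressor sits above threshold: the oracle must refuse
        g = GenotypeSpec(name="OE", mutP=50.0)
        with pytest.raises(BranchViolationError):
            steady_state_below_threshold(params, g, light=0)


class TestParameterSet:
    def test_validation(self, params):
        with pytest.raises(ConfigurationError):
            replace(params, dP=0.0)
        with pytest.raises(ConfigurationError):
            replace(params, pE1=0.1, pE2=0.5)
        with pytest.raises(ConfigurationError):
            replace(params, Pstar=0.0)
        with pytest.raises(ConfigurationError):
            replace(params, pB=-1.0)

    def test_temperature_variants(self, params):
        warm = params.at_temperature(27)
        assert warm.Pstar != params.Pstar
        assert warm.dC == params.dC  # untouched parameter carried over
        assert params.at_temperature("22").Pstar == params.Pstar
        with pytest.raises(ConfigurationError):
            params.at_temperature("35")
        with pytest.raises(ConfigurationError):
            replace(params, temperature_variants={"27": {"dC": 1.0}})

    def test_genotype_invariants(self):
        with pytest.raises(ConfigurationError):
            GenotypeSpec(name="bad", mutP=-0.5)
        with pytest.raises(ConfigurationError):
            GenotypeSpec(name="bad", overrides={"k0": 1.0})
        assert GenotypeSpec(name="WT").is_wild_type


class TestSerialization:
    def test_params_round_trip(self, params):
        from pif4net.io import params_from_dict, params_to_dict

        scheduled = replace(
            params, pself=Schedule(max_day=12.0, min_val=4.0, max_night=10.0)
        )
        for p in (params, scheduled):
            back = params_from_dict(params_to_dict(p))
            assert back == p

    def test_registry_round_trip(self, registry):
        from pif4net.io import registry_from_dict, registry_to_dict

        back = registry_from_dict(registry_to_dict(registry))
        assert back == registry

    def test_protocol_round_trip(self, sd_protocol):
        from pif4net.io import protocol_from_dict, protocol_to_dict

        back = protocol_from_dict(protocol_to_dict(sd_protocol))
        assert back == sd_protocol

    def test_unknown_field_rejected(self, params):
        from pif4net.io import params_from_dict, params_to_dict

        d = params_to_dict(params)
        d["mystery"] = 1.0
        with pytest.raises(ConfigurationError):
            params_from_dict(d)
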