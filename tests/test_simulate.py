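"""Integration correctness: oracles, events, robustness, periodicity."""

import math
from dataclasses import replace

import numpy as np
import pytest

from pif4net import (
    ConfigurationError,
    DomainError,
    GenotypeSpec,
    ModelState,
    SolverOptions,
    gus_at,
    hypocotyl_at,
    integrate,
    make_constant,
    make_photoperiod,
    make_shift,
    reference_rk4,
    run_panel,
    steady_state_below_threshold,
)
from pif4net.model import STATE_NAMES, WILD_TYPE

TIGHT = SolverOptions(rel_tol=1e-10, abs_tol=1e-13)


class TestClosedFormOracles:
    def test_dark_exponential_decay(self, params):
        # with lights off the photoreceptor decays as B0 * exp(-kr t);
        # compare at solver nodes so interpolation does not enter
        B0 = 2.0
        proto = make_constant(0, 48.0)
        traj = integrate(
            params, WILD_TYPE, proto, options=TIGHT,
            initial_state=ModelState(B=B0, E=0, C=0, P=0, F=0, G=0),
        )
        for t_want in (1.0, 6.0, 12.0, 24.0, 48.0):
            i = int(np.argmin(np.abs(traj.times - t_want)))
            t = traj.times[i]
            expected = B0 * math.exp(-params.kr * t)
            assert traj.states[i, 0] == pytest.approx(expected, rel=1e-6)

    @pytest.mark.parametrize("light", [0, 1])
    def test_constant_forcing_steady_state(self, params, light):
        # in dark the wild-type fixed point sits above threshold, so use a
        # reduced-production genotype there; in light the wild type applies
        genotype = WILD_TYPE if light else GenotypeSpec(name="weak", mutP=0.05)
        ss = steady_state_below_threshold(params, genotype, light=light)
        horizon = 30.0 / min(params.dE, params.dC, params.dP, params.dF, params.kr)
        proto = make_constant(light, horizon)
        traj = integrate(params, genotype, proto, options=TIGHT)
        end = traj.final_state()
        for name in ("B", "E", "C", "P", "F"):
            want = getattr(ss, name)
            got = getattr(end, name)
            assert got == pytest.approx(want, rel=1e-5, abs=1e-9)

    def test_zero_initial_growth(self, params, sd_protocol, fast_opts):
        traj = integrate(params, WILD_TYPE, sd_protocol, options=fast_opts)
        G = traj.states[:, STATE_NAMES.index("G")]
        assert G[0] == 0.0
        assert np.all(np.diff(G) >= -1e-12)

    def test_non_negative_and_phyb_bounded(self, params, sd_protocol, fast_opts):
        traj = integrate(params, WILD_TYPE, sd_protocol, options=fast_opts)
        assert np.all(traj.states >= 0.0)
        B = traj.states[:, 0]
        assert B.max() <= 1.0 + 1e-9  # capacity mutB = 1


class TestThresholdEvents:
    def test_sign_constant_between_events(self, params, registry, sd_protocol):
        # between consecutive threshold events P - Pstar keeps one sign
        # (zero while sliding on the threshold)
        for name in ("WT", "PIF4-OE1"):
            traj = integrate(params, registry[name], sd_protocol)
            pstar = registry[name].effective(params).Pstar
            ev = [t for t, _ in traj.threshold_events()]
            edges = [traj.times[0], *ev, traj.times[-1]]
            P = traj.states[:, 3]
            for a, b in zip(edges[:-1], edges[1:]):
                inside = (traj.times > a + 1e-9) & (traj.times < b - 1e-9)
                signs = np.sign(np.round(P[inside] - pstar, 9))
                assert not {1.0, -1.0} <= set(signs), (name, a, b)

    def test_events_alternate(self, params, wt, sd_protocol):
        traj = integrate(params, wt, sd_protocol)
        kinds = [k for _, k in traj.threshold_events()]
        assert kinds, "expected threshold crossings under a short day"
        for prev, nxt in zip(kinds[:-1], kinds[1:]):
            assert prev != nxt

    def test_strong_feedback_sliding_is_stable(self, params, wt, fast_opts):
        # a printed strong-feedback variant drives sliding on the threshold;
        # the integrator must resolve it without chattering
        strong = replace(params, pself=75.0)
        traj = integrate(strong, wt, make_photoperiod(8, 6), options=fast_opts)
        assert len(traj.threshold_events()) < 50
        P = traj.states[:, 3]
        assert P.max() <= max(params.Pstar * 1.05, P[0])


class TestObservables:
    def test_hypocotyl_day_zero(self, params, wt, sd_protocol, fast_opts):
        traj = integrate(params, wt, sd_protocol, options=fast_opts)
        assert hypocotyl_at(traj, 0) == 0.0
        with pytest.raises(DomainError):
            hypocotyl_at(traj, 7)

    def test_gus_basal_without_reporter_drive(self, params, wt, fast_opts):
        # pF = 0 decouples the reporter from PIF4: F settles at k0/dF
        p = replace(params, pF=0.0)
        traj = integrate(p, wt, make_photoperiod(8, 6), options=fast_opts)
        assert gus_at(traj, 6, 23.0) == pytest.approx(p.k0 / p.dF, rel=1e-4)

    def test_gus_rises_after_lights_off(self, params, wt, fast_opts):
        proto = make_shift(make_constant(1, 120.0), make_constant(0, 24.0))
        traj = integrate(params, wt, proto, options=fast_opts)
        before = gus_at(traj, 6, 0.0)
        late = gus_at(traj, 6, 12.0)
        assert late > 2.0 * before

    def test_unknown_temperature_label(self, params, wt):
        proto = make_photoperiod(8, 1, temperature="35")
        with pytest.raises(ConfigurationError):
            integrate(params, wt, proto)


class TestRunPanel:
    def test_wt_only_normalized_one(self, params, wt, fast_opts):
        df = run_panel(params, [wt], make_photoperiod(8, 6),
                       {"observable": "gus", "day": 6, "zt": 23.0},
                       options=fast_opts)
        assert len(df) == 1
        assert df.normalized.iloc[0] == 1.0

    def test_missing_wt_rejected(self, params, registry, fast_opts):
        with pytest.raises(ConfigurationError):
            run_panel(params, [registry["pif4-101"]], make_photoperiod(8, 6),
                      {"observable": "gus", "day": 6, "zt": 23.0},
                      options=fast_opts)

    def test_gus_needs_harvest_time(self, params, wt, fast_opts):
        with pytest.raises(ConfigurationError):
            run_panel(params, [wt], make_photoperiod(8, 6),
                      {"observable": "gus", "day": 6}, options=fast_opts)


class TestNumericalRobustness:
    def test_tolerance_refinement(self, params, wt, sd_protocol):
        base = SolverOptions(rel_tol=1e-6, abs_tol=1e-9)
        tight = SolverOptions(rel_tol=1e-7, abs_tol=1e-10)
        g_base = hypocotyl_at(integrate(params, wt, sd_protocol, options=base), 6)
        g_tight = hypocotyl_at(integrate(params, wt, sd_protocol, options=tight), 6)
        assert abs(g_base / g_tight - 1.0) < 1e-3

    def test_against_fixed_step_reference(self, params, wt):
        proto = make_photoperiod(8, 1)
        adaptive = integrate(params, wt, proto, options=TIGHT)
        # sample the reference at every step so comparing at the adaptive
        # solver's own nodes involves negligible interpolation error
        fixed = reference_rk4(params, wt, proto, h=1e-3, sample_every=1)
        for i, name in enumerate(STATE_NAMES):
            r = np.array([fixed.value(name, t) for t in adaptive.times])
            diff = np.max(np.abs(r - adaptive.states[:, i]))
            assert diff < 1e-4, name


class TestPeriodicAttractor:
    def test_diurnal_limit_cycle(self, params, wt):
        # after burn-in the molecular state settles on a 24 h periodic orbit
        traj = integrate(params, wt, make_photoperiod(8, 12))
        phases = np.linspace(0.0, 24.0, 97)
        for name in ("B", "E", "C", "P", "F"):
            a = np.array([traj.value(name, 10 * 24.0 + ph) for ph in phases])
            b = np.array([traj.value(name, 11 * 24.0 + ph) for ph in phases])
            assert np.max(np.abs(a - b)) < 1e-4, name


class TestTrajectoryExport:
    def test_tidy_frames(self, params, wt, fast_opts):
        proto = make_shift(make_photoperiod(8, 1, "22"), make_photoperiod(8, 1, "27"))
        traj = integrate(params, wt, proto, options=fast_opts)
        df = traj.to_frame()
        assert list(df.columns) == ["time", *STATE_NAMES, "light", "temperature"]
        assert set(df.temperature) == {"22", "27"}
        ev = traj.events_frame()
        assert {"time", "kind"} == set(ev.columns)
        assert (ev.kind == "temp_shift").any()
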