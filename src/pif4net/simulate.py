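"""Integrate the network over an environment protocol and read out observables.

The right-hand side is discontinuous at light transitions, temperature
shifts and at the PIF4 autoinhibition threshold ``P = Pstar``.  Environmental
discontinuities happen at known times (the protocol's breakpoints); threshold
crossings are localized by the solver's event root-finding and integration is
restarted there, so the state stays continuous and only the vector field
jumps.

When both one-sided vector fields push PIF4 towards the threshold (strong
feedback), the exact solution slides along ``P = Pstar``.  This is handled as
a proper sliding mode: P is pinned at the threshold and integration exits the
sliding segment when one of the one-sided derivatives changes sign.  While
sliding, the trajectory belongs to the ``P >= Pstar`` set, so the
above-threshold reporter branch is active and no spurious threshold events
are emitted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .errors import ConfigurationError, DomainError, IntegrationError
from .model import (
    GenotypeSpec,
    ModelState,
    ParameterSet,
    STATE_NAMES,
    WILD_TYPE,
    elf3_production,
    schedule_value,
)
from .protocols import EnvironmentProtocol, GenotypeRegistry, Segment

__all__ = [
    "SolverOptions",
    "Trajectory",
    "integrate",
    "reference_rk4",
    "hypocotyl_at",
    "gus_at",
    "run_panel",
]


@dataclass(frozen=True)
class SolverOptions:
    """Adaptive-solver settings (recorded so runs are reproducible)."""

    rel_tol: float = 1e-6
    abs_tol: float = 1e-9
    max_step: float = 0.5
    method: str = "RK45"
    #: abort if one inter-breakpoint interval needs more restarts than this
    max_restarts_per_interval: int = 500


@dataclass
class Trajectory:
    """Sampled solution plus the localized discontinuity events."""

    times: np.ndarray
    states: np.ndarray  # shape (n, 6), columns ordered as STATE_NAMES
    events: List[Tuple[float, str]]
    light: np.ndarray
    temperature: np.ndarray
    options: SolverOptions = field(default_factory=SolverOptions)

    def value(self, name: str, t) -> np.ndarray | float:
        """Linear interpolation of one state variable at time(s) ``t``."""
        idx = STATE_NAMES.index(name)
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr < self.times[0] - 1e-9) or np.any(t_arr > self.times[-1] + 1e-9):
            raise DomainError(
                f"time {t} outside trajectory range "
                f"[{self.times[0]}, {self.times[-1]}]"
            )
        out = np.interp(t_arr, self.times, self.states[:, idx])
        return float(out) if np.isscalar(t) else out

    def final_state(self) -> ModelState:
        return ModelState.from_vector(self.states[-1], t=float(self.times[-1]))

    def threshold_events(self) -> List[Tuple[float, str]]:
        return [(t, k) for t, k in self.events if k.startswith("threshold")]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(STATE_NAMES))
        df.insert(0, "time", self.times)
        df["light"] = self.light
        df["temperature"] = self.temperature
        return df

    def events_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.events, columns=["time", "kind"])


class _SegmentModel:
    """Scalar-resolved RHS factory for one inter-breakpoint interval."""

    def __init__(
        self,
        params: ParameterSet,
        genotype: GenotypeSpec,
        segment: Segment,
        light: int,
        seg_start: float,
    ):
        p = genotype.effective(params.at_temperature(segment.temperature))
        self.p = p
        self.g = genotype
        self.L = float(light)
        self.day_length = segment.effective_day_length
        self.seg_start = seg_start
        self.Pstar = p.Pstar

    def _locals(self, t: float):
        # diurnal phase is segment-local (the clock restarts at a shift)
        return t - self.seg_start

    def pself(self, t: float) -> float:
        return schedule_value(self._locals(t), self.p.pself)

    def pFP(self, t: float) -> float:
        return schedule_value(self._locals(t), self.p.pFP)

    def pE(self, t: float) -> float:
        return elf3_production(self._locals(t), self.day_length, self.p, self.g.mutE)

    def dP(self, t: float, y, branch: str) -> float:
        p, g = self.p, self.g
        B, E, C, P = y[0], y[1], y[2], y[3]
        denom = 1.0 + p.pPE * E
        if branch == "above":
            denom += self.pself(t) * P
        return (
            g.mutP * p.pP / denom
            - p.dP * P / (1.0 + p.kPC * C)
            - p.dPB * B * P
        )

    def rhs(self, branch: str) -> Callable:
        p, g, L = self.p, self.g, self.L

        def f(t, y):
            B, E, C, P, F, G = y
            dB = p.pB * L * (g.mutB - B) - p.kr * B
            dE = self.pE(t) - p.dEC * C * E - p.dE * E
            dC = g.mutC * (p.pCL * L + p.pCD * (1.0 - L)) - p.dC * C
            dP = self.dP(t, y, branch)
            dF = p.k0 - p.dF * F
            if branch == "above":
                dF += p.pF / (1.0 + self.pFP(t) * P)
            num = p.kG * p.pGP * P
            den = 1.0 + p.pGE * E + p.pGB * B
            if p.growth_grouping_shared_denominator:
                dG = (p.pG + num) / den
            else:
                dG = p.pG + num / den
            return (dB, dE, dC, dP, dF, dG)

        return f

    def rhs_sliding(self) -> Callable:
        """RHS with P pinned at the threshold (Filippov sliding segment)."""
        above = self.rhs("above")

        def f(t, y):
            y = np.array(y, dtype=float)
            y[3] = self.Pstar
            d = list(above(t, y))
            d[3] = 0.0
            return d

        return f

    def decide_mode(self, t: float, y) -> str:
        P = y[3]
        if P < self.Pstar:
            return "below"
        if P > self.Pstar:
            return "above"
        fb = self.dP(t, y, "below")
        fa = self.dP(t, y, "above")
        if fb >= 0.0 >= fa:
            return "slide"
        return "above" if fa > 0.0 else "below"


_NUDGE = 1e-12


def integrate(
    params: ParameterSet,
    genotype: GenotypeSpec,
    protocol: EnvironmentProtocol,
    options: SolverOptions | None = None,
    initial_state: ModelState | None = None,
) -> Trajectory:
    """Solve the network ODEs over ``protocol`` from an all-zero default state.

    Integration restarts at every protocol breakpoint (light transition,
    temperature shift) and at every localized crossing of the PIF4
    threshold; the state is continuous across restarts.

    Raises
    ------
    IntegrationError
        if the solver fails or an interval needs pathologically many
        restarts (chattering guard).
    ConfigurationError
        if a segment's temperature label has no parameter variant.
    """
    opts = options or SolverOptions()
    for label in protocol.temperatures():
        params.at_temperature(label)  # raises ConfigurationError if missing

    y = np.array(
        (initial_state or ModelState.zero()).as_vector(), dtype=float
    )
    t = 0.0
    ts: List[np.ndarray] = [np.array([0.0])]
    ys: List[np.ndarray] = [y.reshape(1, -1).copy()]
    events: List[Tuple[float, str]] = list(protocol.transition_events())

    breaks = protocol.breakpoints()
    mode: str | None = None
    for a, b in zip(breaks[:-1], breaks[1:]):
        if b - a <= 1e-12:
            continue
        mid = 0.5 * (a + b)
        seg, local_mid = protocol.segment_at(mid)
        seg_start = mid - local_mid
        light = seg.light_at(mid - seg_start)
        sm = _SegmentModel(params, genotype, seg, light, seg_start)
        mode = sm.decide_mode(a, y)
        t = a
        restarts = 0
        while t < b - 1e-12:
            restarts += 1
            if restarts > opts.max_restarts_per_interval:
                raise IntegrationError(
                    f"chattering guard tripped: more than "
                    f"{opts.max_restarts_per_interval} restarts in [{a}, {b}] "
                    f"(genotype {genotype.name!r}, mode {mode!r})"
                )
            if mode == "slide":
                y[3] = sm.Pstar
                exit_down = lambda tt, yy: sm.dP(tt, yy, "below")  # noqa: E731
                exit_down.terminal = True
                exit_down.direction = -1.0
                exit_up = lambda tt, yy: sm.dP(tt, yy, "above")  # noqa: E731
                exit_up.terminal = True
                exit_up.direction = 1.0
                sol = solve_ivp(
                    sm.rhs_sliding(), (t, b), y,
                    method=opts.method, rtol=opts.rel_tol, atol=opts.abs_tol,
                    max_step=opts.max_step, events=[exit_down, exit_up],
                )
                _check(sol, genotype, t, mode)
                _append(ts, ys, sol, pin=(3, sm.Pstar))
                t = float(sol.t[-1])
                y = np.array(sol.y[:, -1])
                y[3] = sm.Pstar
                if sol.status == 1:
                    if len(sol.t_events[0]):  # below-branch pull turned negative
                        mode = "below"
                        y[3] = sm.Pstar * (1.0 - _NUDGE)
                        events.append((t, "threshold_down"))
                    else:  # above-branch push turned positive
                        mode = "above"
                        y[3] = sm.Pstar * (1.0 + _NUDGE)
            else:
                branch = mode
                direction = 1.0 if branch == "below" else -1.0
                crossing = lambda tt, yy: yy[3] - sm.Pstar  # noqa: E731
                crossing.terminal = True
                crossing.direction = direction
                sol = solve_ivp(
                    sm.rhs(branch), (t, b), y,
                    method=opts.method, rtol=opts.rel_tol, atol=opts.abs_tol,
                    max_step=opts.max_step, events=[crossing],
                )
                _check(sol, genotype, t, mode)
                _append(ts, ys, sol)
                t = float(sol.t[-1])
                y = np.array(sol.y[:, -1])
                if sol.status == 1:  # hit the threshold
                    y[3] = sm.Pstar
                    fb = sm.dP(t, y, "below")
                    fa = sm.dP(t, y, "above")
                    if branch == "below":
                        events.append((t, "threshold_up"))
                        if fa > 0.0:
                            mode = "above"
                            y[3] = sm.Pstar * (1.0 + _NUDGE)
                        else:
                            mode = "slide"
                    else:
                        if fb < 0.0:
                            mode = "below"
                            y[3] = sm.Pstar * (1.0 - _NUDGE)
                            events.append((t, "threshold_down"))
                        else:
                            mode = "slide"
        # non-negativity: clip solver-scale negative round-off
        np.clip(y, 0.0, None, out=y)

    times = np.concatenate(ts)
    states = np.vstack(ys)
    keep = np.ones(len(times), dtype=bool)
    keep[1:] = np.diff(times) > 0
    times, states = times[keep], states[keep]
    np.clip(states, 0.0, None, out=states)

    light_arr = np.array([light_of(protocol, tt) for tt in times], dtype=int)
    temp_arr = np.array(
        [protocol.segment_at(tt)[0].temperature for tt in times], dtype=object
    )
    all_events = sorted(events, key=lambda e: e[0])
    return Trajectory(times, states, all_events, light_arr, temp_arr, opts)


def light_of(protocol: EnvironmentProtocol, t: float) -> int:
    seg, local = protocol.segment_at(min(t, protocol.total_duration))
    return seg.light_at(local)


def _check(sol, genotype, t, mode) -> None:
    if sol.status < 0:
        raise IntegrationError(
            f"solver failed at t={t:.3f} h (genotype {genotype.name!r}, "
            f"mode {mode!r}): {sol.message}"
        )


def _append(ts, ys, sol, pin=None) -> None:
    t_chunk = sol.t
    y_chunk = sol.y.T.copy()
    if pin is not None:
        y_chunk[:, pin[0]] = pin[1]
    ts.append(t_chunk)
    ys.append(y_chunk)


def reference_rk4(
    params: ParameterSet,
    genotype: GenotypeSpec,
    protocol: EnvironmentProtocol,
    h: float = 1e-3,
    t_end: float | None = None,
    initial_state: ModelState | None = None,
    sample_every: int = 100,
) -> Trajectory:
    """Fixed-step classical Runge-Kutta reference integrator.

    Independent cross-check for :func:`integrate`: steps at a fixed ``h``
    on the smooth branch selected by the current side of the threshold,
    localizes crossings by bisection inside the step, and pins P on the
    threshold while both one-sided fields point inward (sliding).  Slow;
    meant for short horizons.
    """
    t_end = protocol.total_duration if t_end is None else t_end
    y = np.array((initial_state or ModelState.zero()).as_vector(), dtype=float)
    breaks = [p for p in protocol.breakpoints() if p <= t_end + 1e-12]
    if breaks[-1] < t_end:
        breaks.append(t_end)
    ts = [0.0]
    ys = [y.copy()]
    for a, b in zip(breaks[:-1], breaks[1:]):
        if b - a <= 1e-12:
            continue
        mid = 0.5 * (a + b)
        seg, local_mid = protocol.segment_at(mid)
        seg_start = mid - local_mid
        light = seg.light_at(mid - seg_start)
        sm = _SegmentModel(params, genotype, seg, light, seg_start)

        def rk4_step(fun, tt, yy, hh):
            k1 = np.asarray(fun(tt, yy))
            k2 = np.asarray(fun(tt + hh / 2, yy + hh / 2 * k1))
            k3 = np.asarray(fun(tt + hh / 2, yy + hh / 2 * k2))
            k4 = np.asarray(fun(tt + hh, yy + hh * k3))
            return yy + hh / 6 * (k1 + 2 * k2 + 2 * k3 + k4)

        t = a
        i = 0
        while t < b - 1e-12:
            hh = min(h, b - t)
            if y[3] == sm.Pstar:
                fb = sm.dP(t, y, "below")
                fa = sm.dP(t, y, "above")
                if fb >= 0.0 >= fa:  # Filippov sliding: stay pinned
                    fs = sm.rhs_sliding()

                    def pinned(hh_frac):
                        out = rk4_step(fs, t, y, hh_frac)
                        out[3] = sm.Pstar
                        return out

                    y_new = pinned(hh)
                    exit_dn = sm.dP(t + hh, y_new, "below") < 0.0
                    exit_up = sm.dP(t + hh, y_new, "above") > 0.0
                    if exit_dn or exit_up:
                        # bisect the exit time (sign change of the one-sided
                        # derivative along the sliding flow)
                        which = "below" if exit_dn else "above"
                        g0 = sm.dP(t, y, which)
                        lo, hi = 0.0, 1.0
                        for _ in range(60):
                            mid = 0.5 * (lo + hi)
                            if g0 * sm.dP(t + mid * hh, pinned(mid * hh), which) <= 0.0:
                                hi = mid
                            else:
                                lo = mid
                        # keep a minimum step so a zero derivative at entry
                        # cannot stall the walk
                        hh = max(hi, 1e-6) * hh
                        y_new = pinned(hh)
                    y = y_new
                    t += hh
                    i += 1
                    if i % sample_every == 0 or t >= b - 1e-12:
                        ts.append(t)
                        ys.append(y.copy())
                    continue
                # leaving the surface: restart on the consistent side
                y[3] = sm.Pstar * (1.0 - _NUDGE if fb < 0.0 else 1.0 + _NUDGE)
            branch = "above" if y[3] > sm.Pstar else "below"
            fun = sm.rhs(branch)
            y_new = rk4_step(fun, t, y, hh)
            if (y[3] - sm.Pstar) * (y_new[3] - sm.Pstar) < 0.0:
                # localize the crossing by bisection on the same smooth
                # branch, so the kink does not degrade the 4th-order accuracy
                lo, hi = 0.0, 1.0
                for _ in range(60):
                    mid = 0.5 * (lo + hi)
                    y_mid = rk4_step(fun, t, y, mid * hh)
                    if (y[3] - sm.Pstar) * (y_mid[3] - sm.Pstar) < 0.0:
                        hi = mid
                    else:
                        lo = mid
                hh = hi * hh
                y_new = rk4_step(fun, t, y, hh)
                y_new[3] = sm.Pstar
            y = y_new
            t = t + hh
            i += 1
            if i % sample_every == 0 or t >= b - 1e-12:
                ts.append(t)
                ys.append(y.copy())
    times = np.array(ts)
    states = np.vstack(ys)
    light_arr = np.array([light_of(protocol, tt) for tt in times], dtype=int)
    temp_arr = np.array(
        [protocol.segment_at(min(tt, protocol.total_duration))[0].temperature for tt in times],
        dtype=object,
    )
    return Trajectory(times, states, [], light_arr, temp_arr, SolverOptions())


def hypocotyl_at(traj: Trajectory, day: int) -> float:
    """Hypocotyl length (mm) at the end of ``day`` (t = 24*day hours)."""
    t = 24.0 * day
    if t > traj.times[-1] + 1e-9:
        raise DomainError(f"day {day} beyond trajectory end {traj.times[-1]} h")
    return float(traj.value("G", t))


def gus_at(traj: Trajectory, day: int, zt: float) -> float:
    """Reporter concentration at Zeitgeber time ``zt`` of ``day`` (1-based)."""
    t = (day - 1) * 24.0 + zt
    if not traj.times[0] <= t <= traj.times[-1] + 1e-9:
        raise DomainError(f"day {day} ZT{zt} outside the trajectory")
    return float(traj.value("F", min(t, traj.times[-1])))


def run_panel(
    params: ParameterSet,
    registry_subset: GenotypeRegistry | Sequence[GenotypeSpec],
    protocol: EnvironmentProtocol,
    observable_spec: dict,
    options: SolverOptions | None = None,
) -> pd.DataFrame:
    """Simulate a genotype panel and tabulate one observable, WT-normalized.

    ``observable_spec`` keys: ``observable`` ("gus" or "hypocotyl"),
    ``day`` (int), ``zt`` (hours; GUS only), ``normalize`` (default True).
    Normalization divides by the WT value at the same day/ZT and requires a
    "WT" entry in the panel.
    """
    if isinstance(registry_subset, dict):
        genotypes = list(registry_subset.values())
    else:
        genotypes = list(registry_subset)
    obs = observable_spec.get("observable", "gus")
    day = int(observable_spec.get("day", 6))
    zt = observable_spec.get("zt", None)
    normalize = observable_spec.get("normalize", True)
    if obs == "gus" and zt is None:
        raise ConfigurationError("GUS panels need a 'zt' harvest time")
    if normalize and not any(g.name == "WT" for g in genotypes):
        raise ConfigurationError("normalization requested but no 'WT' in panel")

    rows = []
    for g in genotypes:
        traj = integrate(params, g, protocol, options=options)
        if obs == "gus":
            raw = gus_at(traj, day, float(zt))
        elif obs == "hypocotyl":
            raw = hypocotyl_at(traj, day)
        else:
            raise ConfigurationError(f"unknown observable {obs!r}")
        rows.append({"genotype": g.name, "observable": obs, "day": day,
                     "zt": zt, "raw": raw})
    df = pd.DataFrame(rows)
    if normalize:
        wt = df.loc[df.genotype == "WT", "raw"].iloc[0]
        if wt == 0:
            warnings.warn("WT observable is zero; normalized column set to NaN")
            df["normalized"] = np.nan
        else:
            df["normalized"] = df["raw"] / wt
    else:
        df["normalized"] = np.nan
    return df
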